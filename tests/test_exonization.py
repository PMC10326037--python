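"""Pseudoexon arithmetic, HGVS r. formatting, cryptic-site scanning,
frameshift translation against a naive codon-loop oracle, and the 50-nt
NMD rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_transcript
from pseudoexon.exonization import (
    ExonizationError,
    ScanParams,
    define_pseudoexon,
    format_hgvs_r,
    nmd_predict,
    parse_hgvs_r,
    protein_consequence,
    scan_cryptic_sites,
    variant_to_donor_distance,
)
from pseudoexon.genemodel import CodingPosition, c_to_g, cds_sequence, parse_cpos
from pseudoexon.synthetic_data import ScenarioSpec, make_gene
from pseudoexon.workflow import derive_event, mutant_junctions

VARIANT = parse_cpos("c.531+1482")
ACCEPTOR = parse_cpos("c.531+1422")
DONOR = parse_cpos("c.531+1477")


class TestDefinePseudoexon:
    def test_worked_example(self):
        ev = define_pseudoexon(VARIANT, ACCEPTOR, DONOR)
        assert ev.inserted_length == 56
        assert ev.frame_remainder == 2
        assert tuple(str(p) for p in ev.insertion_site) == ("c.531", "c.532")
        assert ev.hgvs_r == "r.531_532ins531+1422_531+1477"

    def test_degenerate_single_base(self):
        p = parse_cpos("c.99+10")
        ev = define_pseudoexon(p, p, p)
        assert ev.inserted_length == 1
        assert ev.hgvs_r == "r.99_100ins99+10_99+10"

    @given(
        anchor=st.integers(1, 2000),
        a_off=st.integers(1, 3000),
        length=st.integers(1, 500),
    )
    def test_length_matches_counting_oracle(self, anchor, a_off, length):
        a = CodingPosition(anchor, a_off)
        d = CodingPosition(anchor, a_off + length - 1)
        ev = define_pseudoexon(CodingPosition(anchor, a_off + length + 4), a, d)
        # oracle: count the inclusive span one offset at a time
        counted = sum(1 for k in range(a.offset, d.offset + 1))
        assert ev.inserted_length == counted
        assert ev.frame_remainder == counted % 3

    def test_different_anchors_rejected(self):
        with pytest.raises(ExonizationError):
            define_pseudoexon(VARIANT, parse_cpos("c.530+10"), DONOR)

    def test_inverted_boundaries_rejected(self):
        with pytest.raises(ExonizationError):
            define_pseudoexon(VARIANT, DONOR, ACCEPTOR)

    def test_exonic_boundary_rejected(self):
        with pytest.raises(ExonizationError):
            define_pseudoexon(VARIANT, parse_cpos("c.531"), DONOR)


class TestDonorDistance:
    def test_worked_example_five_nt(self):
        assert variant_to_donor_distance(VARIANT, DONOR) == 5

    def test_zero_at_donor(self):
        assert variant_to_donor_distance(DONOR, DONOR) == 0

    def test_negative_upstream_sign_matches_genomic_axis(self):
        """The sign of the offset difference agrees with genomic geometry."""
        gene = make_gene(ScenarioSpec(seed=4))
        tm = gene.transcript
        upstream_variant = CodingPosition(531, 1400)
        d = variant_to_donor_distance(upstream_variant, DONOR)
        assert d == -77
        g_var = c_to_g(tm, upstream_variant)
        g_don = c_to_g(tm, DONOR)
        sense = 1 if tm.strand == "+" else -1
        assert sense * (g_var - g_don) == d


class TestHgvsR:
    def test_parse_format_roundtrip(self):
        ev = define_pseudoexon(VARIANT, ACCEPTOR, DONOR)
        site, a, d = parse_hgvs_r(format_hgvs_r(ev))
        assert site == ev.insertion_site
        assert a == ev.acceptor_first_base
        assert d == ev.donor_last_base

    def test_whitespace_normalized(self):
        site, a, d = parse_hgvs_r("r.531_532ins531 + 1422_531 + 1477")
        assert a == ACCEPTOR and d == DONOR


def _planted_intron(seed=0, n=900, a=400, d=455, scrub_window=ScanParams().max_window):
    """Random intron with exactly one AG...GT pair planted at offsets a, d."""
    rng = np.random.default_rng(seed)
    s = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)]))
    for i in range(len(s) - 1):
        if (s[i] == "G" and s[i + 1] == "T") or (s[i] == "A" and s[i + 1] == "G"):
            s[i + 1] = "C"
    s[a - 3], s[a - 2] = "A", "G"
    if s[a - 1] == "T":
        s[a - 1] = "C"
    if s[d - 1] == "A":
        s[d - 1] = "C"  # an A before the donor G would plant a spurious AG
    s[d], s[d + 1] = "G", "T"
    return "".join(s)


class TestScanCrypticSites:
    def test_single_planted_pair(self):
        intron = _planted_intron()
        pairs = scan_cryptic_sites(intron, variant_offset=460)
        assert pairs == [(400, 455)]

    def test_no_acceptor_upstream_empty(self):
        intron = _planted_intron()
        # remove the planted AG -> no acceptor within a viable distance
        intron = intron[: 397 - 1] + "CC" + intron[399:]
        assert scan_cryptic_sites(intron, variant_offset=460) == []

    def test_no_donor_empty(self):
        rng = np.random.default_rng(1)
        s = "".join(np.array(list("AC"))[rng.integers(0, 2, size=500)])
        assert scan_cryptic_sites(s, variant_offset=250) == []

    def test_two_acceptors_ranked(self):
        intron = _planted_intron()
        # plant a second AG giving a 240-bp pseudoexon (midpoint is 150:
        # |56-150|=94 beats |240-150|=90 -> the longer pair ranks first)
        a2 = 455 - 240 + 1
        s = list(intron)
        s[a2 - 3], s[a2 - 2] = "A", "G"
        if s[a2 - 1] == "T":
            s[a2 - 1] = "C"
        pairs = scan_cryptic_sites("".join(s), variant_offset=460)
        assert set(pairs) == {(400, 455), (a2, 455)}
        # oracle: enumerate all AG x GT pairs and apply the ranking rule
        expected = sorted(
            [(400, 455), (a2, 455)],
            key=lambda ad: (abs((ad[1] - ad[0] + 1) - 150), -ad[0]),
        )
        assert pairs == expected

    def test_dominated_donor_suppressed(self):
        """A GT inside a candidate span that is closer to the predicted
        donor-gain position suppresses the more distal donor's pairs."""
        intron = _planted_intron()
        s = list(intron)
        # second donor_last at offset 480: |480-460|=20 vs |455-460|=5, and
        # offset 455's GT lies inside the span (400, 480)
        s[480], s[481] = "G", "T"
        pairs = scan_cryptic_sites("".join(s), variant_offset=460)
        assert pairs == [(400, 455)]
        for a, d in pairs:  # the stated internal-consistency property
            assert not any(
                a <= d2 < d and abs(d2 - 460) < abs(d - 460) for d2 in (455, 480)
            )

    def test_min_length_respected(self):
        intron = _planted_intron(a=445, d=455)  # 11-bp candidate < 20
        assert scan_cryptic_sites(intron, variant_offset=460) == []


def _naive_translate(cds: str) -> str:
    """Independent codon-loop translation using the standard table."""
    from Bio.Data.CodonTable import standard_dna_table

    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in stops:
            out.append("*")
            break
        out.append(table[codon])
    return "".join(out)


def _oracle_protein(ref_cds: str, anchor: int, insert: str):
    """Brute-force mutant translation and frameshift description."""
    from Bio.SeqUtils import seq3

    mut = ref_cds[:anchor] + insert + ref_cds[anchor:]
    ref_p, mut_p = _naive_translate(ref_cds), _naive_translate(mut)
    i = 0
    while i < min(len(ref_p), len(mut_p)) and ref_p[i] == mut_p[i]:
        i += 1
    first = i + 1
    if len(insert) % 3 != 0:
        new = mut_p[first - 1]
        if new == "*":
            return f"p.({seq3(ref_p[first - 1])}{first}*)"
        assert mut_p.endswith("*")
        k = len(mut_p) - first + 1
        return f"p.({seq3(ref_p[first - 1])}{first}{seq3(new)}fs{k}*)"
    return None


class TestProteinConsequence:
    def test_first_affected_codon_is_178(self):
        """Insertion between c.531 and c.532 first touches codon 178."""
        gene = make_gene(ScenarioSpec(seed=1))
        tm = gene.transcript
        ev = derive_event(tm, VARIANT, "A", "G")
        p, ptc = protein_consequence(tm, ev)
        assert p.startswith("p.(") and "178" in p.split("fs")[0]
        assert ptc is not None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_translation_oracle(self, seed):
        gene = make_gene(ScenarioSpec(seed=seed + 500))
        tm = gene.transcript
        ev = derive_event(tm, VARIANT, "A", "G")
        p, _ = protein_consequence(tm, ev)
        expected = _oracle_protein(cds_sequence(tm), 531, ev.inserted_sequence)
        assert p == expected

    def test_in_frame_insert_without_stop(self):
        gene = make_gene(ScenarioSpec(seed=9))
        tm = gene.transcript
        insert = "GCTGCAGCT"  # Ala-Ala-Ala, no stop, length 9
        ev = define_pseudoexon(
            VARIANT, ACCEPTOR, CodingPosition(531, 1422 + 8),
            inserted_sequence=insert,
        )
        p, ptc = protein_consequence(tm, ev)
        assert ptc is None
        assert "ins" in p and "fs" not in p
        # downstream protein unchanged
        ref_p = _naive_translate(cds_sequence(tm))
        mut_p = _naive_translate(
            cds_sequence(tm)[:531] + insert + cds_sequence(tm)[531:]
        )
        assert mut_p[: 531 // 3] == ref_p[: 531 // 3]
        assert mut_p[531 // 3 + 3 :] == ref_p[531 // 3 :]

    def test_missing_insert_sequence_rejected(self):
        gene = make_gene(ScenarioSpec(seed=1))
        ev = define_pseudoexon(VARIANT, ACCEPTOR, DONOR)
        with pytest.raises(ExonizationError):
            protein_consequence(gene.transcript, ev)


class TestNmdRule:
    def test_deep_ptc_true(self):
        assert nmd_predict(100, [50, 200, 400]) is True

    def test_near_last_junction_false(self):
        assert nmd_predict(390, [50, 200, 400]) is False

    def test_threshold_boundary(self):
        assert nmd_predict(350, [400]) is True  # exactly 50 nt
        assert nmd_predict(351, [400]) is False

    def test_empty_junctions_error(self):
        with pytest.raises(ExonizationError):
            nmd_predict(100, [])

    def test_default_scenario_gene_is_nmd_substrate(self):
        """PTC in the pseudoexon frame with downstream junctions: NMD
        substrate, consistent with halved allele expression."""
        gene = make_gene(ScenarioSpec(seed=1))
        tm = gene.transcript
        ev = derive_event(tm, VARIANT, "A", "G")
        p, ptc = protein_consequence(tm, ev)
        anchor_t = tm.cds_start_c + 530
        junctions = mutant_junctions(tm, anchor_t, ev.inserted_length)
        # re-apply the rule by hand
        assert nmd_predict(ptc, junctions) is (max(junctions) - ptc >= 50)
        assert nmd_predict(ptc, junctions) is True
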