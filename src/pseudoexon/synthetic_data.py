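"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design end to end: a multi-exon gene on
either strand carrying a deep-intronic SNV that activates a cryptic GT donor
with a nearby upstream AG acceptor; a duo VCF in which the planted variant
is heterozygous in the affected sample and absent in the unaffected one,
among background variants engineered to exercise every filter's rejection
path; and electropherogram peak tables under a configurable NMD-degradation
efficiency with multiplicative log-normal noise.

Generation is a pure function of the :class:`ScenarioSpec`: the same spec
yields byte-identical FASTA/VCF/tables.  A manifest records the planted
truth so tests can assert against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio.Seq import Seq

from .genemodel import CodingPosition, TranscriptModel, c_to_g, parse_cpos
from .rna_assays import PeakSet, TaggingObservation

__all__ = [
    "ScenarioSpec",
    "SyntheticGene",
    "SyntheticDataError",
    "make_gene",
    "plant_variant_and_duo_vcf",
    "simulate_assays",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic study scenario.

    Defaults mirror the worked scenario: a 6-exon gene whose 3rd intron
    opens after coding base 531 and hosts a 56-bp pseudoexon at offsets
    +1422..+1477 with the activating SNV five nucleotides downstream of the
    cryptic donor (offset +1482), an affected/unaffected duo with 500
    background variants, and RNA peaks at NMD efficiency 0.5 ("reduced by
    about half") with 5% multiplicative noise.
    """

    seed: int = 1
    n_exons: int = 6
    exon_len_range: Tuple[int, int] = (120, 200)
    intron_len_range: Tuple[int, int] = (200, 600)
    strand: str = "+"
    anchor_cds_base: int = 531           # host intron opens after this CDS base
    target_intron: int = 3               # 1-based intron index hosting the event
    pseudoexon_length: int = 56
    acceptor_offset: int = 1422          # +offset of the first exonized base
    variant_to_donor_distance: int = 5   # variant sits this many nt 3' of donor_last
    in_frame: bool = False               # negative scenario: 57-bp in-frame event
    scan_window: int = 300               # GT/AG-free guard half-width around variant
    nmd_efficiency: float = 0.5
    peak_noise_cv: float = 0.05
    n_background_variants: int = 500
    background_af_beta: Tuple[float, float] = (0.5, 8.0)  # AF ~ Beta(a, b) for common class
    chrom: str = "chrS"
    transcript_id: str = "SYNT1"
    gene_name: str = "SYNGENE1"
    affected: str = "PROBAND"
    unaffected: str = "SIBLING"

    def __post_init__(self) -> None:
        if not (0.0 <= self.nmd_efficiency <= 1.0):
            raise SyntheticDataError("nmd_efficiency must be in [0, 1]")
        if self.pseudoexon_length < 1 or self.acceptor_offset < 3:
            raise SyntheticDataError("pseudoexon geometry infeasible")
        if self.strand not in ("+", "-"):
            raise SyntheticDataError("strand must be '+' or '-'")
        if not (1 <= self.target_intron < self.n_exons):
            raise SyntheticDataError("target_intron must name an existing intron")

    # derived geometry ------------------------------------------------------

    @property
    def effective_pseudoexon_length(self) -> int:
        return self.pseudoexon_length + 1 if self.in_frame else self.pseudoexon_length

    @property
    def donor_offset(self) -> int:
        """+offset of the last exonized base."""
        return self.acceptor_offset + self.effective_pseudoexon_length - 1

    @property
    def variant_offset(self) -> int:
        return self.donor_offset + self.variant_to_donor_distance

    @property
    def target_intron_length(self) -> int:
        # room for the event plus the full scan window beyond the variant;
        # also keep the variant in the upstream half of the intron so its
        # canonical HGVS description uses a donor-side (+) offset
        return max(self.variant_offset + self.scan_window + 120,
                   2 * self.variant_offset + 40)


@dataclass
class SyntheticGene:
    """A generated gene: model, chromosome sequence and planted truth."""

    transcript: TranscriptModel
    sequences: Dict[str, str]
    manifest: Dict

    def fasta(self) -> str:
        return "".join(
            _format_fasta_record(name, seq) for name, seq in self.sequences.items()
        )


def _format_fasta_record(name: str, seq: str, width: int = 60) -> str:
    lines = [f">{name}"]
    lines += [seq[i : i + width] for i in range(0, len(seq), width)]
    return "\n".join(lines) + "\n"


def write_fasta(sequences: Dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(_format_fasta_record(name, seq))


# --------------------------------------------------------------------------
# Gene construction
# --------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    body = "".join(
        _CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons - 2)
    )
    return "ATG" + body + "TAA"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _scrub_dinucleotides(seq: list, lo: int, hi: int) -> None:
    """Remove every GT and AG whose first base lies in [lo, hi] (0-based),
    by rewriting the second base to C (a single left-to-right pass suffices:
    C can start neither dinucleotide and ends neither)."""
    for i in range(lo, min(hi + 1, len(seq) - 1)):
        if (seq[i] == "G" and seq[i + 1] == "T") or (seq[i] == "A" and seq[i + 1] == "G"):
            seq[i + 1] = "C"


def make_gene(spec: ScenarioSpec) -> SyntheticGene:
    """Generate the synthetic gene with its planted exonization scenario.

    Postconditions: the CDS translates end to end (ATG start, single
    terminal stop); the host intron is canonical (GT...AG) and long enough
    for the event; within the donor-scan guard region the only GT is the
    planted cryptic donor and the only AG the planted cryptic acceptor.
    """
    rng = np.random.default_rng([int(spec.seed), 101])
    k = spec.target_intron
    if spec.anchor_cds_base < k * 30:
        raise SyntheticDataError(
            f"anchor_cds_base {spec.anchor_cds_base} too small for {k} upstream exons"
        )

    # exon lengths: exons 1..k sum exactly to the anchor base; total CDS is
    # a whole number of codons
    lo, hi = spec.exon_len_range
    upstream_budget = spec.anchor_cds_base
    head = []
    for i in range(k - 1):
        draws_after = k - 2 - i
        hi_i = min(hi, upstream_budget - draws_after * lo - 30)
        if hi_i < lo:
            raise SyntheticDataError("exon_len_range cannot reach anchor_cds_base")
        head.append(int(rng.integers(lo, hi_i + 1)))
        upstream_budget -= head[-1]
    head.append(upstream_budget)
    if head[-1] < 30:
        raise SyntheticDataError("exon_len_range cannot reach anchor_cds_base")
    tail = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_exons - k)]
    total = sum(head) + sum(tail)
    tail[-1] += (-total) % 3
    exon_lengths = head + tail
    cds_len = sum(exon_lengths)

    cds = _random_cds(rng, cds_len // 3)

    # introns: canonical GT...AG; the target intron carries the planted event
    intron_lengths = [
        int(rng.integers(spec.intron_len_range[0], spec.intron_len_range[1] + 1))
        for _ in range(spec.n_exons - 1)
    ]
    intron_lengths[k - 1] = spec.target_intron_length

    introns = []
    for i, ilen in enumerate(intron_lengths):
        s = list(_random_seq(rng, ilen))
        s[0], s[1], s[-2], s[-1] = "G", "T", "A", "G"
        if i == k - 1:
            v = spec.variant_offset  # 1-based offset within the intron
            guard_lo = max(2, v - spec.scan_window - spec.scan_window - 20)
            guard_hi = min(ilen - 4, v + spec.scan_window + 10)
            _scrub_dinucleotides(s, guard_lo - 1, guard_hi - 1)
            # plant acceptor AG (ends 1 nt before the first exonized base),
            # donor GT (starts 1 nt after the last exonized base), variant A
            a, d = spec.acceptor_offset, spec.donor_offset
            s[a - 3], s[a - 2] = "A", "G"
            if s[a - 1] == "T":
                s[a - 1] = "C"  # a GT here would be a spurious second donor
            s[d], s[d + 1] = "G", "T"
            s[v - 1] = "A"
            if v < ilen:
                s[v] = "C"  # the alt G must not itself create a GT
        introns.append("".join(s))

    flank5 = _random_seq(rng, 100)
    flank3 = _random_seq(rng, 100)

    # assemble the plus-sense chromosome and exon coordinates
    parts = [flank5]
    exons: List[Tuple[int, int]] = []
    cursor = len(flank5)
    cds_cursor = 0
    for i, elen in enumerate(exon_lengths):
        exons.append((cursor + 1, cursor + elen))
        parts.append(cds[cds_cursor : cds_cursor + elen])
        cds_cursor += elen
        cursor += elen
        if i < spec.n_exons - 1:
            parts.append(introns[i])
            cursor += len(introns[i])
    parts.append(flank3)
    chrom_seq = "".join(parts)

    strand = spec.strand
    if strand == "-":
        L = len(chrom_seq)
        chrom_seq = str(Seq(chrom_seq).reverse_complement())
        exons = sorted((L - e + 1, L - s + 1) for s, e in exons)

    tm = TranscriptModel(
        transcript_id=spec.transcript_id,
        chrom=spec.chrom,
        strand=strand,
        exons=exons,
        cds_start_c=1,
        cds_end_c=cds_len,
        sequence_source={spec.chrom: chrom_seq},
    )

    anchor = spec.anchor_cds_base
    variant_c = CodingPosition(anchor, spec.variant_offset)
    acceptor_c = CodingPosition(anchor, spec.acceptor_offset)
    donor_c = CodingPosition(anchor, spec.donor_offset)
    target_intron_seq = introns[k - 1]
    inserted = target_intron_seq[spec.acceptor_offset - 1 : spec.donor_offset]

    manifest = {
        "chrom": spec.chrom,
        "strand": strand,
        "transcript_id": spec.transcript_id,
        "gene": spec.gene_name,
        "variant_c": str(variant_c),
        "variant_g": c_to_g(tm, variant_c),
        "variant_ref": "A",
        "variant_alt": "G",
        "acceptor_first_base_c": str(acceptor_c),
        "donor_last_base_c": str(donor_c),
        "pseudoexon_length": spec.effective_pseudoexon_length,
        "inserted_sequence": inserted,
        "target_intron": k,
        "target_intron_sequence": target_intron_seq,
        "exon_lengths": exon_lengths,
        "cds_length": cds_len,
        "affected": spec.affected,
        "unaffected": spec.unaffected,
        "nmd_efficiency": spec.nmd_efficiency,
        "splice_score_planted": 0.93,
    }
    return SyntheticGene(transcript=tm, sequences={spec.chrom: chrom_seq}, manifest=manifest)


# --------------------------------------------------------------------------
# Duo VCF
# --------------------------------------------------------------------------

_VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">
##INFO=<ID=SPLICEAI,Number=.,Type=String,Description="Splice delta scores: ALT|GENE|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{affected}\t{unaffected}
"""

_GT_FIELD = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def _sample_field(gt: str, dp: Optional[int], ad: Optional[Tuple[int, int]]) -> str:
    dp_s = "." if dp is None else str(dp)
    ad_s = "." if ad is None else f"{ad[0]},{ad[1]}"
    return f"{_GT_FIELD[gt]}:{dp_s}:{ad_s}"


def plant_variant_and_duo_vcf(spec: ScenarioSpec, gene: SyntheticGene, path: str) -> Dict:
    """Write the duo VCF: the planted candidate plus background variants.

    The planted record is het in the affected sample, hom_ref in the
    unaffected one, has no AF annotation and carries a donor-gain delta
    score of 0.93.  Background variants are drawn across five rejection
    classes (low quality, off panel, common, shared between the duo,
    below the splice gate) plus an indeterminate class with a missing
    unaffected genotype, so that exactly the planted variant survives the
    full filter chain.  Returns a truth dict of planted/background counts.
    """
    rng = np.random.default_rng([int(spec.seed), 202])
    chrom_seq = gene.sequences[spec.chrom]
    m = gene.manifest
    L = len(chrom_seq)

    taken = {m["variant_g"]}
    rows = []

    # planted candidate
    dp_gain_pos = -spec.variant_to_donor_distance if gene.transcript.strand == "+" else spec.variant_to_donor_distance
    ref, alt = m["variant_ref"], m["variant_alt"]
    if gene.transcript.strand == "-":
        ref = str(Seq(ref).reverse_complement())
        alt = str(Seq(alt).reverse_complement())
    spliceai = f"{alt}|{m['gene']}|0.02|0.01|0.93|0.01|12|-44|{dp_gain_pos}|30"
    rows.append(
        (
            m["variant_g"], ref, alt,
            f"GENE={m['gene']};SPLICEAI={spliceai}",
            _sample_field("het", 42, (20, 22)),
            _sample_field("hom_ref", 40, (40, 0)),
        )
    )

    classes = ["low_quality", "off_panel", "common", "shared", "low_score", "missing_unaffected"]
    weights = np.array([0.2, 0.2, 0.2, 0.18, 0.17, 0.05])
    counts = {c: 0 for c in classes}
    for _ in range(spec.n_background_variants):
        while True:
            pos = int(rng.integers(1, L + 1))
            if pos not in taken and chrom_seq[pos - 1] != "N":
                taken.add(pos)
                break
        b_ref = chrom_seq[pos - 1]
        b_alt = str(rng.choice([b for b in "ACGT" if b != b_ref]))
        cls = str(rng.choice(classes, p=weights))
        counts[cls] += 1

        gene_tag = f"GENE={m['gene']}"
        af_tag = None
        splice_tag = None
        aff = _sample_field("het", 45, (22, 23))
        un = _sample_field("hom_ref", 44, (44, 0))

        if cls == "low_quality":
            aff = _sample_field("het", int(rng.integers(2, 12)), (4, 3))
        elif cls == "off_panel":
            gene_tag = "GENE=OTHERG1" if rng.random() < 0.5 else None
        elif cls == "common":
            af = float(np.clip(rng.beta(*spec.background_af_beta), 0.011, 0.95))
            af_tag = f"AF={af:.4f}"
        elif cls == "shared":
            un = _sample_field("het", 46, (23, 23))
            if rng.random() < 0.5:
                splice_tag = f"SPLICEAI={b_alt}|{m['gene']}|0.30|0.01|0.05|0.01|-3|5|9|1"
        elif cls == "low_score":
            if rng.random() < 0.5:
                splice_tag = f"SPLICEAI={b_alt}|{m['gene']}|{rng.integers(0, 21)/100:.2f}|0.00|0.01|0.00|-8|2|6|4"
            if rng.random() < 0.5:
                af_tag = f"AF={rng.uniform(1e-5, 0.009):.5f}"
        elif cls == "missing_unaffected":
            un = _sample_field("missing", None, None)

        info = ";".join(x for x in (gene_tag, af_tag, splice_tag) if x)
        rows.append((pos, b_ref, b_alt, info or ".", aff, un))

    rows.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write(
            _VCF_HEADER_TEMPLATE.format(
                chrom=spec.chrom, length=L,
                affected=spec.affected, unaffected=spec.unaffected,
            )
        )
        for pos, ref_b, alt_b, info, aff, un in rows:
            fh.write(
                f"{spec.chrom}\t{pos}\t.\t{ref_b}\t{alt_b}\t100\tPASS\t{info}\tGT:DP:AD\t{aff}\t{un}\n"
            )
    return {"n_records": len(rows), "background_counts": counts,
            "planted_pos": m["variant_g"]}


# --------------------------------------------------------------------------
# RNA assays
# --------------------------------------------------------------------------

def simulate_assays(
    spec: ScenarioSpec,
    n_markers: int = 2,
    base_area: float = 10_000.0,
    seed_stream: int = 303,
) -> Tuple[List[PeakSet], List[TaggingObservation]]:
    """Simulate electropherogram peaks and tagging-SNP observations.

    At each heterozygous marker the cDNA alt-allele quantity is scaled by
    ``1 - nmd_efficiency`` (the variant-phased transcript is degraded) under
    multiplicative log-normal noise of the stated CV; gDNA peaks are
    balanced.  The tagging observations describe a *complete* aberrant
    event: the wild-type-selective amplicon carries only the reference
    (non-variant-haplotype) alleles.
    """
    rng = np.random.default_rng([int(spec.seed), seed_stream])
    cv = spec.peak_noise_cv
    sigma = float(np.sqrt(np.log1p(cv * cv)))

    def noise() -> float:
        if sigma == 0.0:
            return 1.0
        return float(np.exp(rng.normal(-sigma * sigma / 2.0, sigma)))

    surviving = 1.0 - spec.nmd_efficiency
    peaks: List[PeakSet] = []
    tags: List[TaggingObservation] = []
    for i in range(1, n_markers + 1):
        locus = f"tag{i}"
        peaks.append(
            PeakSet(locus, "gDNA", {"ref": base_area * noise(), "alt": base_area * noise()})
        )
        peaks.append(
            PeakSet(locus, "cDNA", {"ref": base_area * noise(),
                                    "alt": base_area * surviving * noise()})
        )
        tags.append(TaggingObservation(locus, "het", frozenset({"ref"})))
    return peaks, tags
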