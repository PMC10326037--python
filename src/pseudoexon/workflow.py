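"""End-to-end orchestration: genotype filtering → splice-consequence
derivation → RNA-assay interpretation → point-based classification.

:func:`run_scenario` drives the whole pipeline on a synthetic scenario and
returns a single JSON-serializable report; the CLI's ``run-all`` subcommand
and the acceptance script are thin wrappers around it.  The stages run in
the study's order: variant prioritization from the duo VCF first, then
pseudoexon discovery on the winning candidate, then the RNA read-outs, and
finally the summed ACMG evidence.
"""

from __future__ import annotations

import logging
import os
import tempfile
from typing import Dict, List, Optional

from . import rna_assays
from .acmg import auto_assert, classify, total_score
from .config import PipelineConfig
from .exonization import (
    PseudoexonEvent,
    ScanParams,
    define_pseudoexon,
    nmd_predict,
    protein_consequence,
    scan_cryptic_sites,
    variant_to_donor_distance,
)
from .genemodel import (
    CodingPosition,
    TranscriptModel,
    cds_sequence,
    extract_sequence,
    g_to_c,
)
from .io import read_vcf
from .prioritize import run_prioritization
from .synthetic_data import (
    ScenarioSpec,
    SyntheticGene,
    make_gene,
    plant_variant_and_duo_vcf,
    simulate_assays,
)

logger = logging.getLogger(__name__)

__all__ = ["run_scenario", "derive_event", "mutant_junctions", "WorkflowError"]


class WorkflowError(RuntimeError):
    pass


def mutant_junctions(tm: TranscriptModel, anchor_t: int, inserted_length: int) -> List[int]:
    """Exon–exon junction positions (last nt of each upstream exon) of the
    pseudoexon-containing transcript, in mutant-transcript coordinates."""
    junctions = []
    spans = tm.exon_transcript_spans()
    for ts, te in spans[:-1]:
        if te <= anchor_t:
            junctions.append(te)
        else:
            junctions.append(te + inserted_length)
    junctions.append(anchor_t + inserted_length)  # pseudoexon|downstream-exon
    return sorted(junctions)


def derive_event(
    tm: TranscriptModel,
    variant_c: CodingPosition,
    variant_ref: str,
    variant_alt: str,
    scan_params: ScanParams = ScanParams(),
) -> PseudoexonEvent:
    """Discovery mode: scan the host intron for the activated GT/AG pair and
    build the pseudoexon event for the top-ranked pair."""
    if variant_c.offset == 0:
        raise WorkflowError(f"candidate {variant_c} is not intronic")
    spans = tm.exon_transcript_spans()
    if variant_c.offset < 0:
        # re-anchor an acceptor-side position to the upstream exon boundary
        t_dn = tm.cds_start_c + variant_c.base - 1
        idx = next((i for i, (ts, te) in enumerate(spans[1:]) if ts == t_dn), None)
        if idx is None:
            raise WorkflowError(f"{variant_c} does not anchor an exon boundary")
        length = tm.intron_lengths_transcript_order()[idx]
        variant_c = CodingPosition(variant_c.base - 1, length + variant_c.offset + 1)
    anchor = variant_c.base
    anchor_t = tm.cds_start_c + anchor - 1
    intron_index = next(
        (i for i, (ts, te) in enumerate(spans[:-1]) if te == anchor_t), None
    )
    if intron_index is None:
        raise WorkflowError(f"{variant_c} does not anchor an exon boundary")
    intron_len = tm.intron_lengths_transcript_order()[intron_index]
    intron_seq = extract_sequence(
        tm, CodingPosition(anchor, 1), CodingPosition(anchor, intron_len)
    )
    pairs = scan_cryptic_sites(intron_seq, variant_c.offset, scan_params)
    if not pairs:
        raise WorkflowError(f"no cryptic GT/AG pair found near {variant_c}")
    a, d = pairs[0]
    return define_pseudoexon(
        variant=variant_c,
        acceptor_first_base=CodingPosition(anchor, a),
        donor_last_base=CodingPosition(anchor, d),
        variant_ref=variant_ref,
        variant_alt=variant_alt,
        inserted_sequence=intron_seq[a - 1 : d],
    )


def _amplicon_check(tm: TranscriptModel, event: PseudoexonEvent) -> Dict:
    """Predict selective RT-PCR product sizes for the normal and aberrant
    spliced transcripts with primers flanking the insertion site."""
    ref_cds = cds_sequence(tm)
    anchor = event.insertion_site[0].base
    mut_cds = ref_cds[:anchor] + event.inserted_sequence + ref_cds[anchor:]
    fwd_start = max(0, anchor - 80)
    fwd = ref_cds[fwd_start : fwd_start + 20]
    rev_site_start = min(len(ref_cds), anchor + 60)
    rev_site = ref_cds[rev_site_start : rev_site_start + 20]
    from Bio.Seq import Seq

    rev_primer = str(Seq(rev_site).reverse_complement())
    lengths = rna_assays.predict_amplicon_lengths(
        {"normal": ref_cds, "aberrant": mut_cds}, fwd, rev_primer
    )
    delta = None
    if lengths.get("normal") is not None and lengths.get("aberrant") is not None:
        delta = lengths["aberrant"] - lengths["normal"]
    return {"lengths": lengths, "aberrant_minus_normal": delta}


def run_scenario(
    spec: ScenarioSpec,
    cfg: Optional[PipelineConfig] = None,
    user_pp1: bool = False,
    user_pp4: bool = False,
    workdir: Optional[str] = None,
) -> Dict:
    """Run the full pipeline on one synthetic scenario and report everything.

    Writes the duo VCF under ``workdir`` (a temporary directory when None),
    reads it back through the VCF reader, prioritizes, derives the
    pseudoexon event for the top candidate, interprets the simulated RNA
    assays and assembles the ACMG evidence (PP1/PP4 only from the caller's
    flags).
    """
    cfg = cfg or PipelineConfig(
        gene_panel=(spec.gene_name,), affected=spec.affected, unaffected=spec.unaffected
    )
    gene = make_gene(spec)
    tm = gene.transcript

    own_tmp = workdir is None
    tmpctx = tempfile.TemporaryDirectory() if own_tmp else None
    wd = tmpctx.name if own_tmp else workdir
    try:
        vcf_path = os.path.join(wd, "duo.vcf")
        truth = plant_variant_and_duo_vcf(spec, gene, vcf_path)
        variants = read_vcf(
            vcf_path,
            splice_info_key=cfg.splice_info_key,
            required_samples=(cfg.affected, cfg.unaffected),
        )
        report = run_prioritization(
            variants, cfg.filter_config(), cfg.affected, cfg.unaffected
        )
        result: Dict = {
            "funnel": report.stages,
            "n_candidates": len(report.candidates),
            "truth": {"planted_pos": truth["planted_pos"],
                      "n_records": truth["n_records"]},
        }
        if not report.candidates:
            raise WorkflowError("no candidate survived prioritization")
        top = report.candidates[0]
        variant_c = g_to_c(tm, top.pos)

        # strand-aware ref/alt in transcript sense
        ref, alt = top.ref, top.alt
        if tm.strand == "-":
            from Bio.Seq import Seq

            ref = str(Seq(ref).reverse_complement())
            alt = str(Seq(alt).reverse_complement())

        event = derive_event(tm, variant_c, ref, alt,
                             ScanParams(max_window=spec.scan_window))
        p_string, ptc = protein_consequence(tm, event)
        event.protein_consequence = p_string
        anchor_t = tm.cds_start_c + event.insertion_site[0].base - 1
        if ptc is not None:
            junctions = mutant_junctions(tm, anchor_t, event.inserted_length)
            event.nmd_predicted = nmd_predict(ptc, junctions, cfg.nmd_threshold_nt)
        else:
            event.nmd_predicted = False

        peaks, tags = simulate_assays(spec)
        by_locus: Dict[str, Dict[str, rna_assays.PeakSet]] = {}
        for ps in peaks:
            by_locus.setdefault(ps.locus, {})[ps.template] = ps
        ratios = {
            locus: rna_assays.allelic_imbalance(d["cDNA"], d["gDNA"])
            for locus, d in by_locus.items()
        }
        completeness = rna_assays.completeness_test(tags)

        evidence = auto_assert(
            population_af=top.population_af,
            max_splice_delta=top.max_splice_delta(),
            splice_score_min=cfg.splice_score_min,
            frame_remainder=event.frame_remainder,
            completeness=completeness,
            nmd_predicted=event.nmd_predicted,
            user_pp1=user_pp1,
            user_pp4=user_pp4,
            weights=cfg.acmg_weights,
            threshold=cfg.acmg_threshold,
        )

        result.update(
            {
                "candidate": {
                    "chrom": top.chrom, "pos": top.pos,
                    "ref": top.ref, "alt": top.alt,
                    "coding_position": str(variant_c),
                    "max_splice_delta": top.max_splice_delta(),
                },
                "pseudoexon": {
                    "hgvs_r": event.hgvs_r,
                    "acceptor_first_base": str(event.acceptor_first_base),
                    "donor_last_base": str(event.donor_last_base),
                    "inserted_length": event.inserted_length,
                    "frame_remainder": event.frame_remainder,
                    "variant_to_donor_nt": variant_to_donor_distance(
                        event.variant, event.donor_last_base
                    ),
                    "protein_consequence": p_string,
                    "nmd_predicted": event.nmd_predicted,
                },
                "rna_assays": {
                    "allelic_imbalance": {
                        locus: {
                            "ratio": round(r, 4),
                            "call": rna_assays.classify_imbalance(
                                r, cfg.imbalance_threshold
                            ),
                        }
                        for locus, r in ratios.items()
                    },
                    "completeness": completeness,
                    "amplicons": _amplicon_check(tm, event),
                },
                "acmg": {
                    "criteria": dict(sorted(evidence.criteria.items())),
                    "not_evaluable": sorted(evidence.not_evaluable),
                    "total": total_score(evidence),
                    "class": classify(evidence),
                },
            }
        )
        return result
    finally:
        if tmpctx is not None:
            tmpctx.cleanup()
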