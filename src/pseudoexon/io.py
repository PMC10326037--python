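"""VCF reading/writing for the duo pipeline (pysam-backed).

The supported dialect is a VCF v4.2 subset: two samples with FORMAT
``GT:DP:AD`` and INFO keys ``GENE`` (gene symbol), ``AF`` (population
allele frequency) and a pipe-delimited splice-delta annotation (default
key ``SPLICEAI``: ``ALT|GENE|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|
DP_DL``).  Multi-allelic records are split on read into one
:class:`~pseudoexon.prioritize.AnnotatedVariant` per alt allele, with AD
re-paired as (ref, that alt).
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Tuple

import pysam

from .prioritize import AnnotatedVariant, Genotype, PrioritizeError, SpliceScores

logger = logging.getLogger(__name__)

__all__ = ["read_vcf", "write_vcf", "parse_splice_annotation", "VcfFormatError"]

SPLICE_INFO_KEY = "SPLICEAI"


class VcfFormatError(ValueError):
    pass


def parse_splice_annotation(raw: str, alt: str) -> Optional[SpliceScores]:
    """Parse one pipe-delimited splice annotation, selecting the entry whose
    first field matches ``alt`` (single-entry annotations match any alt)."""
    entries = raw.split(",")
    chosen = None
    for entry in entries:
        fields = entry.split("|")
        if len(fields) < 10:
            raise VcfFormatError(f"splice annotation needs 10 pipe fields: {entry!r}")
        if fields[0] == alt or len(entries) == 1:
            chosen = fields
            break
    if chosen is None:
        return None
    return SpliceScores(
        acceptor_gain=float(chosen[2]),
        acceptor_loss=float(chosen[3]),
        donor_gain=float(chosen[4]),
        donor_loss=float(chosen[5]),
        pos_acceptor_gain=int(chosen[6]),
        pos_acceptor_loss=int(chosen[7]),
        pos_donor_gain=int(chosen[8]),
        pos_donor_loss=int(chosen[9]),
    )


def _call_genotype(sample, alt_index: int) -> str:
    gt = sample.get("GT")
    if gt is None or all(a is None for a in gt):
        return Genotype.MISSING
    if any(a is None for a in gt):
        return Genotype.MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    n_ref = sum(1 for a in gt if a == 0)
    if n_alt == len(gt):
        return Genotype.HOM_ALT
    if n_alt > 0:
        return Genotype.HET
    if n_ref == len(gt):
        return Genotype.HOM_REF
    # carries only other alt alleles: no copy of this alt
    return Genotype.HOM_REF


def read_vcf(
    path: str,
    splice_info_key: str = SPLICE_INFO_KEY,
    required_samples: Optional[Tuple[str, str]] = None,
) -> List[AnnotatedVariant]:
    """Read a duo VCF into AnnotatedVariants, splitting multi-allelic rows."""
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot open {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if required_samples:
        missing = [s for s in required_samples if s not in samples]
        if missing:
            raise VcfFormatError(f"samples {missing} not in VCF header of {path}")
    out: List[AnnotatedVariant] = []
    for rec in vf:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            genotypes: Dict[str, str] = {}
            depth: Dict[str, int] = {}
            allele_depth: Dict[str, Tuple[int, int]] = {}
            for s in samples:
                smp = rec.samples[s]
                if "GT" not in smp:
                    raise VcfFormatError(
                        f"{path}: record {rec.chrom}:{rec.pos} sample {s} lacks GT"
                    )
                genotypes[s] = _call_genotype(smp, ai)
                dp = smp.get("DP")
                if dp is not None:
                    depth[s] = int(dp)
                ad = smp.get("AD")
                if ad is not None and ad[0] is not None:
                    # re-pair: reference depth plus this alt's depth
                    if len(ad) > ai and ad[ai] is not None:
                        allele_depth[s] = (int(ad[0]), int(ad[ai]))
            info = rec.info
            gene = info.get("GENE")
            af = info.get("AF")
            if af is not None:
                af = float(af[ai - 1]) if isinstance(af, tuple) else float(af)
            splice = None
            if splice_info_key in info:
                raw = info[splice_info_key]
                raw = ",".join(raw) if isinstance(raw, tuple) else str(raw)
                splice = parse_splice_annotation(raw, alt)
            out.append(
                AnnotatedVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    genotypes=genotypes,
                    depth=depth,
                    allele_depth=allele_depth,
                    gene=gene,
                    population_af=af,
                    splice_scores=splice,
                )
            )
    vf.close()
    return out


_GT_OUT = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf(
    variants: List[AnnotatedVariant],
    path: str,
    samples: Tuple[str, str],
    contig_lengths: Optional[Dict[str, int]] = None,
    splice_info_key: str = SPLICE_INFO_KEY,
) -> None:
    """Write AnnotatedVariants back to the same VCF v4.2 dialect.

    Splice annotations are re-emitted verbatim from the parsed deltas; the
    writer emits the dialect :func:`read_vcf` reads, so supported fields
    round-trip.
    """
    contigs = contig_lengths or {}
    seen = {v.chrom for v in variants}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(seen | set(contigs)):
            if c in contigs:
                fh.write(f"##contig=<ID={c},length={contigs[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">\n')
        fh.write(
            f'##INFO=<ID={splice_info_key},Number=.,Type=String,Description='
            '"Splice delta scores: ALT|GENE|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.alt)):
            info_parts = []
            if v.gene:
                info_parts.append(f"GENE={v.gene}")
            if v.population_af is not None:
                info_parts.append(f"AF={v.population_af:.6g}")
            if v.splice_scores is not None:
                ss = v.splice_scores
                info_parts.append(
                    f"{splice_info_key}={v.alt}|{v.gene or '.'}|"
                    f"{ss.acceptor_gain:.2f}|{ss.acceptor_loss:.2f}|"
                    f"{ss.donor_gain:.2f}|{ss.donor_loss:.2f}|"
                    f"{ss.pos_acceptor_gain}|{ss.pos_acceptor_loss}|"
                    f"{ss.pos_donor_gain}|{ss.pos_donor_loss}"
                )
            info = ";".join(info_parts) or "."
            fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, "100", "PASS", info, "GT:DP:AD"]
            for s in samples:
                gt = _GT_OUT[v.genotypes.get(s, Genotype.MISSING)]
                dp = v.depth.get(s)
                ad = v.allele_depth.get(s)
                fields.append(
                    f"{gt}:{'.' if dp is None else dp}:"
                    f"{'.' if ad is None else f'{ad[0]},{ad[1]}'}"
                )
            fh.write("\t".join(fields) + "\n")
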