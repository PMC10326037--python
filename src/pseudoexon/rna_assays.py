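"""RNA-level evidence: allelic imbalance, splicing completeness, amplicons.

Three read-outs support (or refute) a functional splice defect:

* **Allelic imbalance** — at an exonic heterozygous marker, the alt/ref peak
  ratio in cDNA normalized by the same ratio in gDNA.  A ratio of 1 means
  both alleles' transcripts are equally represented; a ratio near 0.5 means
  the variant-phased transcript is reduced by about half (consistent with
  partial NMD degradation of an aberrant product).
* **Completeness of aberrant splicing** — if an RT-PCR amplicon selective
  for the *normal* transcript shows only one allele at every heterozygous
  tagging SNP, no normal transcript is produced from the variant allele:
  the aberrant event is complete.
* **Amplicon-length prediction** — expected RT-PCR product sizes per
  transcript isoform; with primers flanking the insertion the aberrant
  minus normal length difference equals the pseudoexon length.

Peak quantities may be areas or heights; both are accepted — only ratios
are used, so the choice cancels as long as it is consistent per locus.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "TaggingObservation",
    "AssayError",
    "allelic_imbalance",
    "classify_imbalance",
    "completeness_test",
    "predict_amplicon_lengths",
    "read_peak_table",
    "write_peak_table",
    "read_tagging_table",
    "write_tagging_table",
]

IMBALANCE_THRESHOLD = 0.8  # default; chosen so a "reduced by about half" ratio flags


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class PeakSet:
    """Electropherogram peak quantities for one locus on one template.

    ``areas`` maps allele (nucleotide) to a non-negative fluorescence
    quantity (peak area or height, arbitrary units).
    """

    locus: str
    template: str  # "cDNA" or "gDNA"
    areas: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.template not in ("cDNA", "gDNA"):
            raise AssayError(f"template must be cDNA or gDNA, got {self.template!r}")
        for allele, a in self.areas.items():
            if not (math.isfinite(a) and a >= 0.0):
                raise AssayError(f"{self.locus} {allele}: invalid area {a!r}")


@dataclass(frozen=True)
class TaggingObservation:
    """One tagging SNP: gDNA genotype plus the alleles seen in the
    wild-type-selective cDNA amplicon."""

    marker: str
    gdna_genotype: str  # het / hom_ref / hom_alt
    observed_alleles: frozenset  # subset of {"ref", "alt"} labels

    def __post_init__(self) -> None:
        if self.gdna_genotype not in ("het", "hom_ref", "hom_alt"):
            raise AssayError(f"{self.marker}: bad genotype {self.gdna_genotype!r}")
        obs = frozenset(self.observed_alleles)
        if not obs or not obs <= {"ref", "alt"}:
            raise AssayError(f"{self.marker}: observed alleles must be a non-empty "
                             f"subset of {{ref, alt}}, got {set(obs)}")
        object.__setattr__(self, "observed_alleles", obs)


# --------------------------------------------------------------------------
# Allelic imbalance
# --------------------------------------------------------------------------

def allelic_imbalance(cdna: PeakSet, gdna: PeakSet,
                      ref_allele: str | None = None,
                      alt_allele: str | None = None) -> float:
    """Ratio-of-ratios (alt/ref)_cDNA / (alt/ref)_gDNA at one het locus.

    1.0 = balanced; < 1 = the alt-bearing transcript is depleted.  The gDNA
    ratio normalizes away allele-specific amplification/detection biases.
    Ref/alt default to the two alleles in gDNA order of appearance.
    """
    if cdna.locus != gdna.locus:
        raise AssayError(f"locus mismatch: {cdna.locus} vs {gdna.locus}")
    if cdna.template != "cDNA" or gdna.template != "gDNA":
        raise AssayError("pass (cDNA, gDNA) PeakSets in that order")
    alleles = list(gdna.areas)
    if ref_allele is None or alt_allele is None:
        if len(alleles) < 2:
            raise AssayError(f"{gdna.locus}: need two alleles for an informative locus")
        ref_allele, alt_allele = alleles[0], alleles[1]
    g_ref, g_alt = gdna.areas[ref_allele], gdna.areas[alt_allele]
    if g_ref <= 0 or g_alt <= 0:
        raise AssayError(f"{gdna.locus}: zero gDNA peak area; ratio undefined")
    c_ref = cdna.areas.get(ref_allele, 0.0)
    c_alt = cdna.areas.get(alt_allele, 0.0)
    if c_ref <= 0:
        raise AssayError(f"{cdna.locus}: zero cDNA reference peak; ratio undefined")
    if c_alt <= 0:
        logger.warning("%s: alt allele absent from cDNA; ratio 0 (complete loss)",
                       cdna.locus)
        return 0.0
    return (c_alt / c_ref) / (g_alt / g_ref)


def classify_imbalance(ratio: float, threshold: float = IMBALANCE_THRESHOLD) -> str:
    """'imbalanced' iff ratio < threshold or ratio > 1/threshold (strict)."""
    if ratio < 0:
        raise AssayError(f"ratio must be non-negative, got {ratio}")
    if not (0 < threshold <= 1):
        raise AssayError(f"threshold must be in (0, 1], got {threshold}")
    return "imbalanced" if (ratio < threshold or ratio > 1.0 / threshold) else "balanced"


# --------------------------------------------------------------------------
# Completeness of aberrant splicing
# --------------------------------------------------------------------------

def completeness_test(observations: Sequence[TaggingObservation]) -> str:
    """Adjudicate whether the aberrant splicing event is complete.

    * ``complete`` — every gDNA-het marker shows exactly one allele in the
      wild-type-selective amplicon and all such markers agree on phase
      (all show ref, or all show alt): the normal transcript comes from a
      single allele only.
    * ``incomplete`` — some het marker shows both alleles: the variant
      allele still yields normal transcript.
    * ``uninformative`` — no heterozygous markers.
    """
    het = [o for o in observations if o.gdna_genotype == "het"]
    if not het:
        return "uninformative"
    if any(len(o.observed_alleles) != 1 for o in het):
        return "incomplete"
    phases = {next(iter(o.observed_alleles)) for o in het}
    if len(phases) != 1:
        # markers disagree on which haplotype the normal transcript uses —
        # mutually inconsistent with a single complete event
        return "incomplete"
    return "complete"


# --------------------------------------------------------------------------
# Selective RT-PCR amplicon prediction
# --------------------------------------------------------------------------

def predict_amplicon_lengths(
    transcripts: Mapping[str, str],
    forward_primer: str,
    reverse_primer: str,
) -> Dict[str, Optional[int]]:
    """Expected amplicon length per spliced transcript, or None (no product).

    The forward primer is matched as-is; the reverse primer anneals to the
    given strand's reverse complement, so its reverse complement is searched
    in the transcript.  Length spans the 5' end of the forward primer to the
    3' end of the reverse primer site.
    """
    fwd = forward_primer.upper()
    rev_site = str(Seq(reverse_primer.upper()).reverse_complement())
    out: Dict[str, Optional[int]] = {}
    for name, seq in transcripts.items():
        s = seq.upper()
        i = s.find(fwd)
        j = s.find(rev_site, i + len(fwd)) if i != -1 else -1
        if i == -1 or j == -1:
            logger.info("amplicon prediction: no product from %s", name)
            out[name] = None
        else:
            out[name] = j + len(rev_site) - i
    return out


# --------------------------------------------------------------------------
# Tab-separated I/O and JSON summaries
# --------------------------------------------------------------------------

def read_peak_table(path: str) -> List[PeakSet]:
    """Read (locus, template, allele, area) TSV into PeakSets."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "template": str, "allele": str})
    required = {"locus", "template", "allele", "area"}
    if not required <= set(df.columns):
        raise AssayError(f"peak table needs columns {sorted(required)}")
    sets = []
    for (locus, template), grp in df.groupby(["locus", "template"], sort=False):
        sets.append(PeakSet(locus, template, dict(zip(grp["allele"], grp["area"].astype(float)))))
    return sets


def write_peak_table(peak_sets: Iterable[PeakSet], path: str) -> None:
    rows = [
        {"locus": ps.locus, "template": ps.template, "allele": al, "area": area}
        for ps in peak_sets
        for al, area in ps.areas.items()
    ]
    pd.DataFrame(rows, columns=["locus", "template", "allele", "area"]).to_csv(
        path, sep="\t", index=False
    )


def read_tagging_table(path: str) -> List[TaggingObservation]:
    """Read (marker, gDNA_gt, observed_alleles) TSV; alleles comma-separated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker", "gDNA_gt", "observed_alleles"}
    if not required <= set(df.columns):
        raise AssayError(f"tagging table needs columns {sorted(required)}")
    return [
        TaggingObservation(r.marker, r.gDNA_gt,
                           frozenset(r.observed_alleles.split(",")))
        for r in df.itertuples()
    ]


def write_tagging_table(observations: Iterable[TaggingObservation], path: str) -> None:
    rows = [
        {"marker": o.marker, "gDNA_gt": o.gdna_genotype,
         "observed_alleles": ",".join(sorted(o.observed_alleles))}
        for o in observations
    ]
    pd.DataFrame(rows, columns=["marker", "gDNA_gt", "observed_alleles"]).to_csv(
        path, sep="\t", index=False
    )


def assay_summary(ratios: Mapping[str, float], completeness: str,
                  threshold: float = IMBALANCE_THRESHOLD) -> str:
    """JSON summary of one RNA-assay round."""
    return json.dumps(
        {
            "allelic_imbalance": {
                locus: {"ratio": round(r, 4),
                        "call": classify_imbalance(r, threshold)}
                for locus, r in ratios.items()
            },
            "completeness": completeness,
        },
        indent=2,
    )
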