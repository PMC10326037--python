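"""Carrier-aware variant prioritization for an affected/unaffected duo.

Implements the WGS short-list funnel used to surface a deep-intronic
candidate: per-sample quality gates (depth, allele depth, variant allele
fraction), gene-panel restriction, population-frequency filter, duo
(affected-only) filter, and a splice-impact gate on precomputed delta
scores.  Each stage reports its survivor count, so the result is the
familiar prioritization funnel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "SpliceScores",
    "AnnotatedVariant",
    "FilterConfig",
    "PrioritizationReport",
    "filter_quality",
    "filter_panel",
    "filter_frequency",
    "filter_duo",
    "filter_splice_score",
    "run_prioritization",
    "PrioritizeError",
]


class PrioritizeError(ValueError):
    pass


# Genotype calls are plain strings; a tiny enum-like namespace keeps call
# sites readable without ceremony.
class Genotype:
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class SpliceScores:
    """Splice-impact delta scores with relative positions, as annotated by
    a splice predictor (donor/acceptor gain and loss, each in [0, 1])."""

    acceptor_gain: float = 0.0
    acceptor_loss: float = 0.0
    donor_gain: float = 0.0
    donor_loss: float = 0.0
    pos_acceptor_gain: int = 0
    pos_acceptor_loss: int = 0
    pos_donor_gain: int = 0
    pos_donor_loss: int = 0

    def max_delta(self) -> float:
        return max(self.acceptor_gain, self.acceptor_loss,
                   self.donor_gain, self.donor_loss)


@dataclass(frozen=True)
class AnnotatedVariant:
    """One (bi-allelic) VCF record with duo genotypes and annotations.

    ``genotypes``/``depth``/``allele_depth`` are keyed by sample name;
    ``allele_depth`` holds (ref, alt) read counts.  ``population_af`` is
    None for variants absent from population databases (treated as novel).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: Mapping[str, str]
    depth: Mapping[str, int] = field(default_factory=dict)
    allele_depth: Mapping[str, Tuple[int, int]] = field(default_factory=dict)
    gene: Optional[str] = None
    population_af: Optional[float] = None
    splice_scores: Optional[SpliceScores] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise PrioritizeError(f"{self.chrom}:{self.pos} ref == alt ({self.ref})")

    def vf(self, sample: str) -> Optional[float]:
        """Variant allele fraction alt/(ref+alt) for one sample."""
        ad = self.allele_depth.get(sample)
        if ad is None:
            return None
        total = ad[0] + ad[1]
        return ad[1] / total if total > 0 else None

    def max_splice_delta(self) -> Optional[float]:
        return self.splice_scores.max_delta() if self.splice_scores else None


@dataclass
class FilterConfig:
    """Thresholds for the prioritization funnel.

    DP/AD/VF cut-offs follow conventional germline heterozygous-call
    heuristics and are fully overridable; the frequency and splice gates
    default to AF < 0.01 and max delta score > 0.2.
    """

    min_dp: int = 20
    min_ad_alt: int = 5
    vf_range: Tuple[float, float] = (0.2, 0.8)
    gene_panel: frozenset = frozenset()
    max_af: float = 0.01
    splice_score_min: float = 0.2

    def __post_init__(self) -> None:
        if self.min_dp < 0 or self.min_ad_alt < 0:
            raise PrioritizeError("depth thresholds must be non-negative")
        lo, hi = self.vf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise PrioritizeError(f"vf_range {self.vf_range} outside [0, 1]")
        if not (0.0 < self.max_af <= 1.0):
            raise PrioritizeError(f"max_af {self.max_af} outside (0, 1]")
        if not (0.0 <= self.splice_score_min <= 1.0):
            raise PrioritizeError("splice_score_min outside [0, 1]")
        self.gene_panel = frozenset(self.gene_panel)


@dataclass
class PrioritizationReport:
    """Per-stage survivor counts plus the final candidate list."""

    stages: list  # list of (stage name, surviving count)
    candidates: list  # final AnnotatedVariant list
    indeterminate: list = field(default_factory=list)  # duo-stage drop-outs

    def __post_init__(self) -> None:
        counts = [n for _, n in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise PrioritizeError("stage survivor counts must be non-increasing")

    def as_tsv(self) -> str:
        lines = ["stage\tsurviving"]
        lines += [f"{name}\t{n}" for name, n in self.stages]
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Individual filters
# --------------------------------------------------------------------------

def filter_quality(
    variants: Iterable[AnnotatedVariant], cfg: FilterConfig, affected: str
) -> list[AnnotatedVariant]:
    """Keep variants with DP >= min_dp, alt AD >= min_ad_alt and VF inside
    ``vf_range`` in the affected sample; missing metrics fail the gate."""
    kept = []
    lo, hi = cfg.vf_range
    for v in variants:
        dp = v.depth.get(affected)
        ad = v.allele_depth.get(affected)
        vf = v.vf(affected)
        if dp is None or ad is None or vf is None:
            continue
        if dp >= cfg.min_dp and ad[1] >= cfg.min_ad_alt and lo <= vf <= hi:
            kept.append(v)
    return kept


def filter_panel(
    variants: Iterable[AnnotatedVariant], gene_panel: frozenset | set
) -> list[AnnotatedVariant]:
    """Keep variants whose gene annotation is in the panel (exact match)."""
    if not gene_panel:
        raise PrioritizeError("gene panel is empty; refusing to filter everything out")
    return [v for v in variants if v.gene is not None and v.gene in gene_panel]


def filter_frequency(
    variants: Iterable[AnnotatedVariant], max_af: float
) -> list[AnnotatedVariant]:
    """Keep variants with population AF strictly below ``max_af``; variants
    never seen in population databases (AF absent) are kept as novel."""
    return [v for v in variants if v.population_af is None or v.population_af < max_af]


def filter_duo(
    variants: Iterable[AnnotatedVariant],
    affected: str,
    unaffected: str,
    indeterminate: Optional[list] = None,
) -> list[AnnotatedVariant]:
    """Keep variants carried by the affected sample (het or hom_alt) and
    absent (hom_ref) in the unaffected one.

    Records whose unaffected genotype is missing cannot be adjudicated: they
    are dropped and appended to ``indeterminate`` (and logged).
    """
    kept = []
    for v in variants:
        if affected not in v.genotypes or unaffected not in v.genotypes:
            raise PrioritizeError(
                f"sample {affected!r}/{unaffected!r} not genotyped at {v.chrom}:{v.pos}"
            )
        g_aff = v.genotypes[affected]
        g_un = v.genotypes[unaffected]
        if g_un == Genotype.MISSING:
            logger.info(
                "duo filter: %s:%s indeterminate (unaffected genotype missing)",
                v.chrom, v.pos,
            )
            if indeterminate is not None:
                indeterminate.append(v)
            continue
        if g_aff in (Genotype.HET, Genotype.HOM_ALT) and g_un == Genotype.HOM_REF:
            kept.append(v)
    return kept


def filter_splice_score(
    variants: Iterable[AnnotatedVariant], splice_score_min: float
) -> list[AnnotatedVariant]:
    """Keep variants whose maximum splice delta score is strictly above the
    gate; unscored variants are dropped."""
    kept = []
    for v in variants:
        d = v.max_splice_delta()
        if d is not None and d > splice_score_min:
            kept.append(v)
    return kept


# --------------------------------------------------------------------------
# Full funnel
# --------------------------------------------------------------------------

def run_prioritization(
    variants: Sequence[AnnotatedVariant],
    cfg: FilterConfig,
    affected: str,
    unaffected: str,
) -> PrioritizationReport:
    """Run quality -> panel -> frequency -> duo -> splice and report the
    funnel; final candidates sorted by descending max splice delta."""
    stages = [("input", len(list(variants)))]
    cur = list(variants)

    cur = filter_quality(cur, cfg, affected)
    stages.append(("quality", len(cur)))

    cur = filter_panel(cur, cfg.gene_panel)
    stages.append(("panel", len(cur)))

    cur = filter_frequency(cur, cfg.max_af)
    stages.append(("frequency", len(cur)))

    indeterminate: list = []
    cur = filter_duo(cur, affected, unaffected, indeterminate)
    stages.append(("duo", len(cur)))

    cur = filter_splice_score(cur, cfg.splice_score_min)
    stages.append(("splice", len(cur)))

    cur = sorted(cur, key=lambda v: (-(v.max_splice_delta() or 0.0), v.chrom, v.pos))
    for name, n in stages:
        logger.info("prioritization stage %-10s: %d surviving", name, n)
    return PrioritizationReport(stages=stages, candidates=cur,
                                indeterminate=indeterminate)
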