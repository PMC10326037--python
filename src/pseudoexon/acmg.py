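"""Point-based ACMG classification with fixed integer criterion weights.

Evidence codes carry explicit positive integer points and are summed
against a pathogenicity threshold: PVS1 (null/loss-of-function effect) is
worth 8 points, and PM2 (absent from population databases), PP1
(co-segregation), PP3 (computational support) and PP4 (specific phenotype)
are worth 1 each; a total >= 10 is called pathogenic.  Any total below the
threshold is reported as ``not_demonstrated`` — this scheme carries no
benign-side evidence and does not grade intermediate classes.

:func:`auto_assert` derives the data-driven criteria (PM2, PP3, PVS1) from
upstream pipeline results; the family-level criteria PP1 and PP4 are only
ever asserted on explicit user input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_WEIGHTS",
    "DEFAULT_THRESHOLD",
    "AcmgEvidence",
    "AcmgError",
    "total_score",
    "classify",
    "auto_assert",
]

DEFAULT_WEIGHTS: Dict[str, int] = {
    "PVS1": 8,
    "PM2": 1,
    "PP1": 1,
    "PP3": 1,
    "PP4": 1,
}
DEFAULT_THRESHOLD = 10

PATHOGENIC = "pathogenic"
NOT_DEMONSTRATED = "not_demonstrated"


class AcmgError(ValueError):
    pass


@dataclass
class AcmgEvidence:
    """Asserted criteria with their point weights.

    ``criteria`` maps criterion code -> positive integer weight.  Codes not
    in the default table need an explicit weight — there are no silent
    defaults for criteria the scheme never assigned points to.
    ``not_evaluable`` records criteria that could not be adjudicated for
    lack of upstream results (they contribute nothing to the score but are
    reported).
    """

    criteria: Dict[str, int] = field(default_factory=dict)
    threshold_pathogenic: int = DEFAULT_THRESHOLD
    not_evaluable: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for code, w in self.criteria.items():
            if not isinstance(w, int) or w <= 0:
                raise AcmgError(f"criterion {code}: weight must be a positive integer, got {w!r}")

    @classmethod
    def from_codes(cls, codes: Iterable[str],
                   weights: Optional[Mapping[str, int]] = None,
                   threshold: int = DEFAULT_THRESHOLD) -> "AcmgEvidence":
        table = dict(DEFAULT_WEIGHTS if weights is None else weights)
        crit: Dict[str, int] = {}
        for code in codes:
            if code in crit:
                raise AcmgError(f"criterion {code} asserted twice")
            if code not in table:
                raise AcmgError(f"criterion {code} has no assigned weight")
            crit[code] = table[code]
        return cls(criteria=crit, threshold_pathogenic=threshold)

    def to_json(self) -> str:
        return json.dumps(
            {
                "criteria": dict(sorted(self.criteria.items())),
                "not_evaluable": sorted(self.not_evaluable),
                "total": total_score(self),
                "class": classify(self),
            },
            indent=2,
        )


def total_score(evidence: AcmgEvidence) -> int:
    """Sum of the asserted criteria's weights."""
    return sum(evidence.criteria.values())


def classify(evidence: AcmgEvidence) -> str:
    """'pathogenic' iff the summed score reaches the threshold (inclusive)."""
    return PATHOGENIC if total_score(evidence) >= evidence.threshold_pathogenic else NOT_DEMONSTRATED


def auto_assert(
    population_af: Optional[float] = None,
    max_splice_delta: Optional[float] = None,
    splice_score_min: float = 0.2,
    frame_remainder: Optional[int] = None,
    completeness: Optional[str] = None,
    nmd_predicted: Optional[bool] = None,
    user_pp1: bool = False,
    user_pp4: bool = False,
    weights: Optional[Mapping[str, int]] = None,
    threshold: int = DEFAULT_THRESHOLD,
) -> AcmgEvidence:
    """Assemble evidence from pipeline outputs plus user-supplied flags.

    Rules:

    * **PM2** — population AF absent or 0 (novel variant).
    * **PP3** — maximum splice delta score strictly above the gate.
    * **PVS1** — out-of-frame pseudoexon (``frame_remainder != 0``) AND the
      aberrant event is ``complete`` AND the transcript is an NMD substrate:
      together these demonstrate a loss-of-function allele.
    * **PP1 / PP4** — never inferred; asserted only from the caller's
      segregation / phenotype flags.

    Inputs left as None make the corresponding criterion *not evaluable*
    (recorded, never asserted).
    """
    codes = []
    not_evaluable = []

    if population_af is None:
        # AF annotation absent = never observed in population screens
        codes.append("PM2")
    elif population_af == 0.0:
        codes.append("PM2")

    if max_splice_delta is None:
        not_evaluable.append("PP3")
    elif max_splice_delta > splice_score_min:
        codes.append("PP3")

    if frame_remainder is None or completeness is None or nmd_predicted is None:
        not_evaluable.append("PVS1")
    elif frame_remainder != 0 and completeness == "complete" and nmd_predicted:
        codes.append("PVS1")

    if user_pp1:
        codes.append("PP1")
    if user_pp4:
        codes.append("PP4")

    ev = AcmgEvidence.from_codes(codes, weights=weights, threshold=threshold)
    ev.not_evaluable = not_evaluable
    if not_evaluable:
        logger.info("ACMG: criteria not evaluable from available results: %s",
                    ", ".join(not_evaluable))
    return ev
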