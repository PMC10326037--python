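"""Pseudoexon (exonization) consequence derivation.

A deep-intronic variant can activate a cryptic GT donor and recruit a nearby
upstream AG acceptor, splicing an intronic segment — a pseudoexon — into the
mature transcript.  This module defines the event from its boundaries, emits
the HGVS ``r.`` insertion description, determines the reading-frame effect
and protein consequence, and applies the 50-nt rule to predict whether the
resulting transcript is a nonsense-mediated-decay (NMD) substrate.

Boundary conventions (transcript sense): the donor GT dinucleotide is
intronic and begins 1 nt after ``donor_last_base``; the acceptor AG is
intronic and ends 1 nt before ``acceptor_first_base``.  Both boundaries are
intronic offsets anchored to the same exonic base (the last coding base of
the exon upstream of the host intron).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genemodel import (
    CodingPosition,
    CoordinateError,
    HgvsParseError,
    TranscriptModel,
    c_to_g,
    cds_sequence,
    codon_index,
    format_cpos,
    parse_cpos,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PseudoexonEvent",
    "ExonizationError",
    "define_pseudoexon",
    "variant_to_donor_distance",
    "format_hgvs_r",
    "parse_hgvs_r",
    "ScanParams",
    "scan_cryptic_sites",
    "protein_consequence",
    "nmd_predict",
    "pseudoexon_bed_line",
]

NMD_RULE_NT = 50  # distance of the PTC upstream of the last junction


class ExonizationError(ValueError):
    pass


@dataclass
class PseudoexonEvent:
    """A single intronic segment exonized between two canonical exons."""

    variant: CodingPosition
    variant_ref: str
    variant_alt: str
    acceptor_first_base: CodingPosition
    donor_last_base: CodingPosition
    inserted_length: int
    insertion_site: Tuple[CodingPosition, CodingPosition]
    frame_remainder: int
    hgvs_r: str = ""
    inserted_sequence: Optional[str] = None
    protein_consequence: Optional[str] = None
    nmd_predicted: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.inserted_sequence is not None and len(self.inserted_sequence) != self.inserted_length:
            raise ExonizationError(
                f"inserted_sequence length {len(self.inserted_sequence)} != "
                f"inserted_length {self.inserted_length}"
            )
        if self.frame_remainder != self.inserted_length % 3:
            raise ExonizationError("frame_remainder must equal inserted_length mod 3")


def _check_same_intron(a: CodingPosition, b: CodingPosition) -> None:
    if a.base != b.base:
        raise ExonizationError(
            f"boundaries {format_cpos(a)} and {format_cpos(b)} anchor different exons"
        )
    if a.offset < 1 or b.offset < 1:
        raise ExonizationError("pseudoexon boundaries must be intronic (+ offsets)")


def define_pseudoexon(
    variant: CodingPosition,
    acceptor_first_base: CodingPosition,
    donor_last_base: CodingPosition,
    variant_ref: str = "N",
    variant_alt: str = "N",
    inserted_sequence: Optional[str] = None,
) -> PseudoexonEvent:
    """Build the event from its boundaries.

    ``inserted_length`` is the inclusive span donor - acceptor + 1; the
    insertion site is between the shared anchor base and the next coding
    base; ``frame_remainder = inserted_length mod 3`` (non-zero means the
    pseudoexon shifts the reading frame).
    """
    _check_same_intron(acceptor_first_base, donor_last_base)
    _check_same_intron(acceptor_first_base, variant)
    if donor_last_base.offset < acceptor_first_base.offset:
        raise ExonizationError(
            f"inverted boundaries: acceptor {format_cpos(acceptor_first_base)} "
            f"after donor {format_cpos(donor_last_base)}"
        )
    length = donor_last_base.offset - acceptor_first_base.offset + 1
    anchor = acceptor_first_base.base
    event = PseudoexonEvent(
        variant=variant,
        variant_ref=variant_ref,
        variant_alt=variant_alt,
        acceptor_first_base=acceptor_first_base,
        donor_last_base=donor_last_base,
        inserted_length=length,
        insertion_site=(CodingPosition(anchor), CodingPosition(anchor + 1)),
        frame_remainder=length % 3,
        inserted_sequence=inserted_sequence,
    )
    event.hgvs_r = format_hgvs_r(event)
    return event


def variant_to_donor_distance(variant: CodingPosition, donor_last_base: CodingPosition) -> int:
    """Signed distance (nt) from the new exon/intron boundary to the variant.

    Positive when the variant lies downstream (intron side) of the donor's
    last exonized base — e.g. +5 for a variant five nucleotides downstream
    of the donor site it activates.
    """
    _check_same_intron(variant, donor_last_base)
    return variant.offset - donor_last_base.offset


# --------------------------------------------------------------------------
# HGVS r. formatting
# --------------------------------------------------------------------------

def _r_pos(p: CodingPosition) -> str:
    return format_cpos(p)[2:]  # strip the "c." prefix; r. uses bare numbers


def format_hgvs_r(event: PseudoexonEvent) -> str:
    """``r.<a>_<a+1>ins<acceptor>_<donor>`` with intronic offsets, no spaces."""
    a, b = event.insertion_site
    return (
        f"r.{_r_pos(a)}_{_r_pos(b)}"
        f"ins{_r_pos(event.acceptor_first_base)}_{_r_pos(event.donor_last_base)}"
    )


_HGVS_R_RE = re.compile(
    r"^r\.(\d+)_(\d+)ins(\d+[+-]\d+)_(\d+[+-]\d+)$"
)


def parse_hgvs_r(text: str) -> Tuple[Tuple[CodingPosition, CodingPosition],
                                     CodingPosition, CodingPosition]:
    """Inverse of :func:`format_hgvs_r`: returns (insertion_site, acceptor,
    donor) boundaries of a pseudoexon insertion description."""
    compact = re.sub(r"\s+", "", text)
    m = _HGVS_R_RE.match(compact)
    if not m:
        raise HgvsParseError(f"not a pseudoexon insertion description: {text!r}")
    site = (CodingPosition(int(m.group(1))), CodingPosition(int(m.group(2))))
    acceptor = parse_cpos("c." + m.group(3))
    donor = parse_cpos("c." + m.group(4))
    return site, acceptor, donor


# --------------------------------------------------------------------------
# Cryptic-site discovery
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanParams:
    """Window and length constraints for cryptic-site scanning.

    ``max_window`` bounds how far (nt) a candidate donor may sit from the
    predicted donor-gain position and how far upstream the acceptor search
    extends; ``min_length`` discards implausibly short pseudoexons.
    """

    max_window: int = 300
    min_length: int = 20


def scan_cryptic_sites(
    intron_sequence: str,
    variant_offset: int,
    params: ScanParams = ScanParams(),
) -> List[Tuple[int, int]]:
    """Enumerate candidate (acceptor_first, donor_last) offset pairs.

    ``intron_sequence`` is the host intron in transcript sense; offsets are
    1-based within it.  A donor candidate is a GT dinucleotide within
    ``max_window`` of the predicted donor-gain position (taken as the
    variant's offset): the last exonized base is the base just 5' of the GT.
    An acceptor candidate is an AG dinucleotide upstream: the first exonized
    base is the base just 3' of the AG.  Pairs shorter than ``min_length``
    are discarded; a pair whose exonized span contains another GT strictly
    closer to the donor-gain position is suppressed (that GT would outcompete
    the distal donor).  Remaining pairs are ranked by
    ``|length - max_window/2|`` ascending, nearest acceptor first on ties.
    """
    seq = intron_sequence.upper()
    n = len(seq)
    target = variant_offset

    # candidate donor_last offsets d: GT occupies offsets d+1, d+2
    donors = [
        i  # i is 1-based offset of the last exonized base
        for i in range(1, n - 1)
        if seq[i] == "G" and seq[i + 1] == "T" and abs(i - target) <= params.max_window
    ]
    # candidate acceptor_first offsets a: AG occupies offsets a-2, a-1
    acceptors = [
        i
        for i in range(3, n + 1)
        if seq[i - 3] == "A" and seq[i - 2] == "G"
    ]
    pairs = []
    for d in donors:
        for a in acceptors:
            length = d - a + 1
            if not (params.min_length <= length <= params.max_window):
                continue
            # dominance: a GT inside the exonized span closer to the target
            # would be used instead of this donor
            dominated = any(
                a <= d2 < d and abs(d2 - target) < abs(d - target) for d2 in donors
            )
            if not dominated:
                pairs.append((a, d))
    if not pairs:
        logger.info("cryptic-site scan: no viable GT/AG pair near offset %d", target)
        return []
    midpoint = params.max_window / 2
    pairs.sort(key=lambda ad: (abs((ad[1] - ad[0] + 1) - midpoint), -ad[0]))
    return pairs


# --------------------------------------------------------------------------
# Protein consequence and NMD
# --------------------------------------------------------------------------

def _translate(cds: str) -> str:
    """Codon-by-codon translation, stopping at the first stop codon."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = prot.find("*")
    return prot if stop == -1 else prot[: stop + 1]


def protein_consequence(tm: TranscriptModel, event: PseudoexonEvent) -> Tuple[str, Optional[int]]:
    """Translate the pseudoexon-containing CDS and describe the protein change.

    Returns ``(p_string, ptc_transcript_pos)`` where ``ptc_transcript_pos``
    is the 1-based coordinate (in the mutant spliced transcript) of the
    first nucleotide of the premature termination codon, or None when the
    change is in-frame / no new stop arises.

    For a frameshift the description follows the printed form
    ``p.(<Ref><idx><New>fs<k>*)`` with k the 1-based ordinal of the new stop
    counting the first altered residue as 1; an in-frame insertion is
    reported as ``p.(<A><i>_<B><i+1>ins<residues>)``; exhaustion of the
    transcript without a stop is reported as ``fs?`` (no-stop), not raised.
    """
    if event.inserted_sequence is None:
        raise ExonizationError("event lacks inserted_sequence; attach it first")
    ref_cds = cds_sequence(tm)
    anchor = event.insertion_site[0].base
    if anchor >= len(ref_cds):
        raise ExonizationError(f"insertion anchor c.{anchor} outside the CDS")
    mut_cds = ref_cds[:anchor] + event.inserted_sequence + ref_cds[anchor:]

    ref_prot = _translate(ref_cds)
    mut_prot = _translate(mut_cds)

    # first altered residue
    i = 0
    while i < min(len(ref_prot), len(mut_prot)) and ref_prot[i] == mut_prot[i]:
        i += 1
    first = i + 1  # 1-based codon index

    if event.frame_remainder == 0:
        if mut_prot[: len(ref_prot)] == ref_prot or ref_prot[first - 1:] == mut_prot[first - 1 + event.inserted_length // 3:]:
            ins_block = mut_prot[first - 1 : first - 1 + event.inserted_length // 3]
            left = ref_prot[first - 2] if first >= 2 else "?"
            right = ref_prot[first - 1] if first <= len(ref_prot) else "?"
            p = (
                f"p.({seq3(left)}{first - 1}_{seq3(right)}{first}"
                f"ins{seq3(ins_block).replace('Ter', '*')})"
            )
            return p, None
        # in-frame but with a substitution/stop at the junction
        new = mut_prot[first - 1]
        p = f"p.({seq3(ref_prot[first - 1])}{first}{seq3(new) if new != '*' else '*'})"
        return p, None

    # frameshift
    ref_aa = ref_prot[first - 1] if first <= len(ref_prot) else "?"
    if first > len(mut_prot):
        return f"p.({seq3(ref_aa)}{first}fs?)", None
    new_aa = mut_prot[first - 1]
    if new_aa == "*":
        # the first altered codon is itself the termination codon
        p = f"p.({seq3(ref_aa)}{first}*)"
        stop_codon_idx = first
        ptc = tm.cds_start_c + 3 * (stop_codon_idx - 1)
        return p, ptc
    if not mut_prot.endswith("*"):
        logger.warning("frameshift runs off the transcript without a stop codon")
        return f"p.({seq3(ref_aa)}{first}{seq3(new_aa)}fs?)", None
    stop_codon_idx = len(mut_prot)  # '*' position, 1-based codon
    k = stop_codon_idx - first + 1  # stop ordinal with first altered residue = 1
    p = f"p.({seq3(ref_aa)}{first}{seq3(new_aa)}fs{k}*)"
    ptc = tm.cds_start_c + 3 * (stop_codon_idx - 1)
    return p, ptc


def nmd_predict(
    ptc_transcript_pos: int,
    exon_junction_transcript_positions: Sequence[int],
    threshold_nt: int = NMD_RULE_NT,
) -> bool:
    """50-nt rule: True iff the PTC starts >= ``threshold_nt`` upstream of
    the last exon–exon junction (positions in mutant-transcript coordinates;
    a junction is the last nucleotide of its upstream exon)."""
    if not exon_junction_transcript_positions:
        raise ExonizationError("no exon junctions supplied; cannot apply the 50-nt rule")
    last_junction = max(exon_junction_transcript_positions)
    return last_junction - ptc_transcript_pos >= threshold_nt


def pseudoexon_bed_line(tm: TranscriptModel, event: PseudoexonEvent, name: str = "pseudoexon") -> str:
    """BED interval (0-based half-open, genomic) of the exonized segment."""
    g1 = c_to_g(tm, event.acceptor_first_base)
    g2 = c_to_g(tm, event.donor_last_base)
    lo, hi = min(g1, g2), max(g1, g2)
    return f"{tm.chrom}\t{lo - 1}\t{hi}\t{name}\t0\t{tm.strand}"
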