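"""Transcript coordinate system with HGVS-style intronic offsets.

A :class:`TranscriptModel` describes one transcript (exons in genomic order,
CDS bounds in transcript coordinates) on either strand.  Positions inside the
CDS and its introns are addressed by :class:`CodingPosition`, the familiar
HGVS ``c.`` coordinate: ``c.531`` is the 531st base of the coding sequence,
``c.531+1482`` is 1482 nt into the intron that follows it, and ``c.101-50``
is 50 nt upstream of coding base 101 across the preceding intron.

Internally every interval is 0-based half-open; 1-based inclusive coordinates
appear only at the HGVS and file-format boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

__all__ = [
    "CodingPosition",
    "TranscriptModel",
    "GeneModelError",
    "CoordinateError",
    "HgvsParseError",
    "parse_cpos",
    "format_cpos",
    "c_to_g",
    "g_to_c",
    "codon_index",
    "extract_sequence",
    "read_gff3",
    "write_gff3",
    "read_bed12",
    "write_bed12",
    "load_fasta",
]


class GeneModelError(ValueError):
    """Invalid transcript model."""


class CoordinateError(ValueError):
    """A position cannot be mapped under the given transcript model."""


class HgvsParseError(ValueError):
    """Malformed HGVS coding-position string."""


# --------------------------------------------------------------------------
# Coding positions
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class CodingPosition:
    """HGVS ``c.``-style position: CDS base plus signed intronic offset.

    ``offset == 0`` means exonic.  ``offset = +k`` is k nt into the intron
    downstream (transcript sense) of coding base ``base``, which must be the
    last coding base of its exon; ``offset = -k`` is k nt upstream of coding
    base ``base``, which must be the first coding base of its exon.  The
    derived lexicographic order ``(base, offset)`` is exactly transcript-plus-
    intron order: c.100 < c.100+1 < c.100+999 < c.101-999 < c.101.
    """

    base: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.base < 1:
            raise HgvsParseError(f"coding base must be >= 1, got {self.base}")

    def __str__(self) -> str:
        return format_cpos(self)


_CPOS_RE = re.compile(r"^c\.(\d+)(?:([+-])(\d+))?$")


def parse_cpos(text: str) -> CodingPosition:
    """Parse ``c.<base>`` or ``c.<base>[+-]<offset>`` (whitespace tolerated).

    >>> parse_cpos("c.531+1482")
    CodingPosition(base=531, offset=1482)
    """
    compact = re.sub(r"\s+", "", text)
    m = _CPOS_RE.match(compact)
    if not m:
        raise HgvsParseError(f"not a coding position: {text!r}")
    base = int(m.group(1))
    if base == 0:
        raise HgvsParseError(f"zero coding base in {text!r}")
    offset = 0
    if m.group(2) is not None:
        offset = int(m.group(3))
        if offset == 0:
            raise HgvsParseError(f"explicit zero offset in {text!r}")
        if m.group(2) == "-":
            offset = -offset
    return CodingPosition(base, offset)


def format_cpos(p: CodingPosition) -> str:
    """Canonical whitespace-free HGVS string for a coding position."""
    if p.offset == 0:
        return f"c.{p.base}"
    sign = "+" if p.offset > 0 else "-"
    return f"c.{p.base}{sign}{abs(p.offset)}"


# --------------------------------------------------------------------------
# Transcript model
# --------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on a genome, either strand.

    Parameters
    ----------
    exons
        Genomic intervals, 1-based inclusive, sorted by genomic start,
        non-overlapping.  On strand ``-`` the transcript reads them in
        reverse genomic order.
    cds_start_c, cds_end_c
        First and last transcript coordinate (1-based position in the
        spliced transcript) covered by the CDS.
    sequence_source
        Optional mapping ``chrom -> sequence`` (anything sliceable whose
        slices stringify to nucleotides, e.g. a ``pyfaidx.Fasta`` or a plain
        dict of strings).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: Sequence[Tuple[int, int]]
    cds_start_c: int
    cds_end_c: int
    sequence_source: Optional[Mapping[str, object]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise GeneModelError("transcript needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise GeneModelError(f"exon start {s} > end {e}")
            if prev_end is not None and s <= prev_end:
                raise GeneModelError("exons overlap or are unsorted")
            prev_end = e
        if not (1 <= self.cds_start_c <= self.cds_end_c <= self.transcript_length):
            raise GeneModelError(
                f"CDS bounds [{self.cds_start_c}, {self.cds_end_c}] outside "
                f"transcript of length {self.transcript_length}"
            )

    # -- derived geometry --------------------------------------------------

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end_c - self.cds_start_c + 1

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exons_transcript_order(self) -> list[Tuple[int, int]]:
        """Exons in the order the transcript reads them."""
        return list(self.exons if self.strand == "+" else reversed(self.exons))

    def exon_transcript_spans(self) -> list[Tuple[int, int]]:
        """1-based inclusive transcript-coordinate span of each exon
        (transcript order)."""
        spans = []
        t = 1
        for s, e in self.exons_transcript_order():
            length = e - s + 1
            spans.append((t, t + length - 1))
            t += length
        return spans

    def intron_lengths_transcript_order(self) -> list[int]:
        ex = self.exons_transcript_order()
        out = []
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if self.strand == "+":
                out.append(s2 - e1 - 1)
            else:
                out.append(s1 - e2 - 1)
        return out

    def genomic_span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    # -- transcript <-> genomic (exonic only) ------------------------------

    def t_to_g(self, t: int) -> int:
        """Genomic base (1-based) carrying transcript position ``t``."""
        if not (1 <= t <= self.transcript_length):
            raise CoordinateError(f"transcript position {t} outside 1..{self.transcript_length}")
        for (ts, te), (gs, ge) in zip(self.exon_transcript_spans(), self.exons_transcript_order()):
            if ts <= t <= te:
                if self.strand == "+":
                    return gs + (t - ts)
                return ge - (t - ts)
        raise AssertionError("unreachable")

    def g_to_t(self, g: int) -> Optional[int]:
        """Transcript position of genomic base ``g``, or None if intronic."""
        for (ts, te), (gs, ge) in zip(self.exon_transcript_spans(), self.exons_transcript_order()):
            if gs <= g <= ge:
                if self.strand == "+":
                    return ts + (g - gs)
                return ts + (ge - g)
        return None


# --------------------------------------------------------------------------
# Coding-position <-> genomic conversion
# --------------------------------------------------------------------------

def _cds_base_to_t(tm: TranscriptModel, base: int) -> int:
    if not (1 <= base <= tm.cds_length):
        raise CoordinateError(
            f"coding base {base} beyond CDS length {tm.cds_length} of {tm.transcript_id}"
        )
    return tm.cds_start_c + base - 1


def _exon_index_of_t(tm: TranscriptModel, t: int) -> int:
    for i, (ts, te) in enumerate(tm.exon_transcript_spans()):
        if ts <= t <= te:
            return i
    raise CoordinateError(f"transcript position {t} not exonic")


def c_to_g(tm: TranscriptModel, p: CodingPosition) -> int:
    """Genomic position (1-based) of a coding position, strand-aware.

    For ``offset 0`` this is the genomic base carrying CDS base ``p.base``;
    for ``+k`` it is k bases 3'-ward (transcript sense) of the exon-final
    base; for ``-k``, k bases 5'-ward of the exon-initial base.  Offsets may
    not walk past the intron into the next exon.
    """
    t = _cds_base_to_t(tm, p.base)
    g = tm.t_to_g(t)
    sense = 1 if tm.strand == "+" else -1
    if p.offset == 0:
        return g
    spans = tm.exon_transcript_spans()
    i = _exon_index_of_t(tm, t)
    intron_lens = tm.intron_lengths_transcript_order()
    if p.offset > 0:
        if t != spans[i][1]:
            raise CoordinateError(
                f"{format_cpos(p)}: base is not the last base of its exon"
            )
        if i >= tm.n_introns or p.offset > intron_lens[i]:
            raise CoordinateError(
                f"{format_cpos(p)}: offset walks past the downstream intron"
            )
        return g + sense * p.offset
    if t != spans[i][0]:
        raise CoordinateError(
            f"{format_cpos(p)}: base is not the first base of its exon"
        )
    if i == 0 or -p.offset > intron_lens[i - 1]:
        raise CoordinateError(
            f"{format_cpos(p)}: offset walks past the upstream intron"
        )
    return g + sense * p.offset


def g_to_c(tm: TranscriptModel, g: int) -> CodingPosition:
    """Coding position of genomic base ``g`` (inverse of :func:`c_to_g`).

    Exonic positions get offset 0.  Intronic positions are assigned to the
    nearer exon boundary: ``+`` offsets from the upstream exon up to and
    including the midpoint, ``-`` beyond it; for an even-length intron the
    two central bases take ``+`` and ``-`` respectively.
    """
    lo, hi = tm.genomic_span()
    if not (lo <= g <= hi):
        raise CoordinateError(f"g.{g} outside transcript span {lo}..{hi}")
    t = tm.g_to_t(g)
    if t is not None:
        base = t - tm.cds_start_c + 1
        if not (1 <= base <= tm.cds_length):
            raise CoordinateError(
                f"g.{g} is exonic but outside the CDS (UTR notation unsupported)"
            )
        return CodingPosition(base, 0)
    # intronic: locate the flanking exons in transcript order
    spans = tm.exon_transcript_spans()
    ex = tm.exons_transcript_order()
    for i in range(tm.n_introns):
        gs_up, ge_up = ex[i]
        gs_dn, ge_dn = ex[i + 1]
        if tm.strand == "+":
            in_intron = ge_up < g < gs_dn
            dist_from_up = g - ge_up  # 1-based position within intron
        else:
            in_intron = ge_dn < g < gs_up
            dist_from_up = gs_up - g
        if not in_intron:
            continue
        length = tm.intron_lengths_transcript_order()[i]
        anchor_up_t = spans[i][1]
        anchor_dn_t = spans[i + 1][0]
        base_up = anchor_up_t - tm.cds_start_c + 1
        base_dn = anchor_dn_t - tm.cds_start_c + 1
        if dist_from_up <= (length + 1) // 2:
            if not (1 <= base_up <= tm.cds_length):
                raise CoordinateError(
                    f"g.{g}: flanking exon boundary lies outside the CDS"
                )
            return CodingPosition(base_up, dist_from_up)
        if not (1 <= base_dn <= tm.cds_length):
            raise CoordinateError(
                f"g.{g}: flanking exon boundary lies outside the CDS"
            )
        return CodingPosition(base_dn, -(length - dist_from_up + 1))
    raise CoordinateError(f"g.{g} could not be placed on {tm.transcript_id}")


def codon_index(p: CodingPosition) -> int:
    """1-based index of the codon containing an exonic coding base.

    ``codon_index(c.532) == 178``: the first codon touched by an insertion
    between c.531 and c.532 — the anchor of the Phe178 frameshift call.
    """
    if p.offset != 0:
        raise CoordinateError(f"{format_cpos(p)} is intronic; codons are exonic")
    return (p.base + 2) // 3


# --------------------------------------------------------------------------
# Sequence extraction
# --------------------------------------------------------------------------

def _fetch(tm: TranscriptModel, g_start: int, g_end: int) -> str:
    """Plus-strand genomic slice, 1-based inclusive."""
    if tm.sequence_source is None:
        raise GeneModelError(f"{tm.transcript_id} has no sequence source attached")
    try:
        seq = tm.sequence_source[tm.chrom]
    except KeyError as exc:
        raise GeneModelError(f"chromosome {tm.chrom!r} not in sequence source") from exc
    s = str(seq[g_start - 1 : g_end]).upper()
    if len(s) != g_end - g_start + 1:
        raise CoordinateError(
            f"span g.{g_start}-g.{g_end} crosses the end of {tm.chrom}"
        )
    return s


def extract_sequence(tm: TranscriptModel, start: CodingPosition, stop: CodingPosition) -> str:
    """Nucleotides from ``start`` to ``stop`` inclusive, transcript sense.

    The span is taken on the unspliced pre-mRNA axis (exons and introns),
    so its length always equals the inclusive coordinate span; on strand
    ``-`` the plus-strand slice is reverse-complemented.
    """
    if stop < start:
        raise CoordinateError(f"span {format_cpos(start)}..{format_cpos(stop)} is inverted")
    g1 = c_to_g(tm, start)
    g2 = c_to_g(tm, stop)
    lo, hi = min(g1, g2), max(g1, g2)
    s = _fetch(tm, lo, hi)
    if tm.strand == "-":
        s = str(Seq(s).reverse_complement())
    return s


def spliced_transcript_sequence(tm: TranscriptModel) -> str:
    """Mature (spliced) transcript sequence, transcript sense."""
    parts = []
    for gs, ge in tm.exons_transcript_order():
        s = _fetch(tm, gs, ge)
        if tm.strand == "-":
            s = str(Seq(s).reverse_complement())
        parts.append(s)
    return "".join(parts)


def cds_sequence(tm: TranscriptModel) -> str:
    """Reference coding sequence (spliced, CDS span only)."""
    return spliced_transcript_sequence(tm)[tm.cds_start_c - 1 : tm.cds_end_c]


# --------------------------------------------------------------------------
# Gene-model I/O: GFF3 and BED12; FASTA loading
# --------------------------------------------------------------------------

def load_fasta(path: str):
    """Open a (multi-record, wrapped) FASTA as a chrom -> sequence mapping."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=False, sequence_always_upper=True)


def _cds_bounds_from_genomic(
    exons: Sequence[Tuple[int, int]], strand: str,
    cds_intervals: Sequence[Tuple[int, int]],
) -> Tuple[int, int]:
    """Transcript-coordinate CDS bounds from genomic CDS intervals."""
    tm = TranscriptModel("tmp", "tmp", strand, exons, 1, sum(e - s + 1 for s, e in exons))
    g_first = min(s for s, _ in cds_intervals)
    g_last = max(e for _, e in cds_intervals)
    t1 = tm.g_to_t(g_first)
    t2 = tm.g_to_t(g_last)
    if t1 is None or t2 is None:
        raise GeneModelError("CDS boundary does not fall inside an exon")
    return min(t1, t2), max(t1, t2)


def read_gff3(path: str, sequence_source=None) -> list[TranscriptModel]:
    """Read transcript models from GFF3 (gene/mRNA/exon/CDS, ID/Parent)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if not exons or not cds:
            raise GeneModelError(f"mRNA {mrna.id} lacks exon or CDS features")
        c1, c2 = _cds_bounds_from_genomic(exons, mrna.strand, cds)
        models.append(
            TranscriptModel(
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_start_c=c1,
                cds_end_c=c2,
                sequence_source=sequence_source,
            )
        )
    return models


def write_gff3(models: Sequence[TranscriptModel], path: str, gene_name: str | None = None) -> None:
    """Write transcript models as GFF3 (same dialect :func:`read_gff3` reads)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tm in models:
            gene_id = gene_name or f"{tm.transcript_id}.gene"
            lo, hi = tm.genomic_span()
            cols = lambda ft, s, e, attrs: "\t".join(  # noqa: E731
                [tm.chrom, "pseudoexon", ft, str(s), str(e), ".", tm.strand, ".", attrs]
            )
            fh.write(cols("gene", lo, hi, f"ID={gene_id}") + "\n")
            fh.write(cols("mRNA", lo, hi, f"ID={tm.transcript_id};Parent={gene_id}") + "\n")
            spans = tm.exon_transcript_spans()
            for i, (gs, ge) in enumerate(tm.exons):
                fh.write(cols("exon", gs, ge, f"ID={tm.transcript_id}.exon{i+1};Parent={tm.transcript_id}") + "\n")
            # CDS features: intersect each exon's transcript span with the CDS span
            for (gs, ge), (ts, te) in zip(tm.exons_transcript_order(), spans):
                cs, ce = max(ts, tm.cds_start_c), min(te, tm.cds_end_c)
                if cs > ce:
                    continue
                g1, g2 = tm.t_to_g(cs), tm.t_to_g(ce)
                fh.write(cols("CDS", min(g1, g2), max(g1, g2), f"ID={tm.transcript_id}.cds;Parent={tm.transcript_id}") + "\n")


def read_bed12(path: str, sequence_source=None) -> list[TranscriptModel]:
    """Read transcript models from BED12 (one line per transcript)."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise GeneModelError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(f)}")
            chrom, chrom_start, _chrom_end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            tm0 = TranscriptModel(name, chrom, strand, exons, 1, sum(sizes))
            t1 = tm0.g_to_t(thick_start + 1)
            t2 = tm0.g_to_t(thick_end)
            if t1 is None or t2 is None:
                raise GeneModelError(f"{path}:{lineno}: thickStart/thickEnd not exonic")
            models.append(
                TranscriptModel(name, chrom, strand, exons, min(t1, t2), max(t1, t2),
                                sequence_source=sequence_source)
            )
    return models


def write_bed12(models: Sequence[TranscriptModel], path: str) -> None:
    """Write transcript models as BED12 (same dialect :func:`read_bed12` reads)."""
    with open(path, "w") as fh:
        for tm in models:
            lo, hi = tm.genomic_span()
            chrom_start = lo - 1
            g_cds = sorted(
                (c_to_g(tm, CodingPosition(1)), c_to_g(tm, CodingPosition(tm.cds_length)))
            )
            sizes = ",".join(str(e - s + 1) for s, e in tm.exons) + ","
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in tm.exons) + ","
            fh.write(
                "\t".join(
                    [
                        tm.chrom, str(chrom_start), str(hi), tm.transcript_id, "0",
                        tm.strand, str(g_cds[0] - 1), str(g_cds[1]), "0",
                        str(len(tm.exons)), sizes, starts,
                    ]
                )
                + "\n"
            )
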