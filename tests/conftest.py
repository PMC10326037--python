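import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pseudoexon.genemodel import TranscriptModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("pseudoexon").setLevel(logging.ERROR)
logging.getLogger("pseudoexon.prioritize").setLevel(logging.ERROR)


def _random_chrom(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture
def toyg1():
    """Three-exon plus-strand toy gene: exons 101-200, 301-400, 501-600,
    CDS c.1 at g.101 (the CDS spans the whole transcript)."""
    rng = np.random.default_rng(7)
    chrom_seq = _random_chrom(rng, 700)
    tm = TranscriptModel(
        transcript_id="TOYG1",
        chrom="chrT",
        strand="+",
        exons=[(101, 200), (301, 400), (501, 600)],
        cds_start_c=1,
        cds_end_c=300,
        sequence_source={"chrT": chrom_seq},
    )
    return tm


def random_transcript(seed: int, strand: str | None = None) -> TranscriptModel:
    """Small random transcript (2-5 exons, mixed even/odd intron lengths,
    either strand, CDS covering the whole transcript) for property tests."""
    rng = np.random.default_rng(seed)
    n_exons = int(rng.integers(2, 6))
    exon_lens = rng.integers(6, 31, size=n_exons)
    intron_lens = rng.integers(3, 16, size=n_exons - 1)
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    start = int(rng.integers(1, 50))
    exons = []
    g = start
    for i, el in enumerate(exon_lens):
        exons.append((g, g + int(el) - 1))
        g += int(el)
        if i < n_exons - 1:
            g += int(intron_lens[i])
    total = int(exon_lens.sum())
    chrom_seq = _random_chrom(rng, g + 50)
    return TranscriptModel(
        transcript_id=f"RND{seed}",
        chrom="chrR",
        strand=strand,
        exons=exons,
        cds_start_c=1,
        cds_end_c=total,
        sequence_source={"chrR": chrom_seq},
    )


def enumerate_coordinate_table(tm: TranscriptModel):
    """Exhaustive (base, offset) -> genomic lookup built by walking the
    transcript one position at a time; the independent oracle for the
    coordinate conversions."""
    table = {}
    spans = tm.exon_transcript_spans()
    ex = tm.exons_transcript_order()
    sense = 1 if tm.strand == "+" else -1
    for (ts, te), (gs, ge) in zip(spans, ex):
        for t in range(ts, te + 1):
            g = gs + (t - ts) if tm.strand == "+" else ge - (t - ts)
            base = t - tm.cds_start_c + 1
            if 1 <= base <= tm.cds_length:
                table[(base, 0)] = g
    for i in range(tm.n_introns):
        up_end_g = tm.t_to_g(spans[i][1])
        length = tm.intron_lengths_transcript_order()[i]
        base_up = spans[i][1] - tm.cds_start_c + 1
        base_dn = spans[i + 1][0] - tm.cds_start_c + 1
        for j in range(1, length + 1):
            g = up_end_g + sense * j
            if j <= (length + 1) // 2:
                table[(base_up, j)] = g
            else:
                table[(base_dn, -(length - j + 1))] = g
    return table
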