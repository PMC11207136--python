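"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gigasplice.coverage import AlignmentRecord
from gigasplice.gene_models import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    exon_span_projection,
)


def make_transcript(
    exons, strand="+", chrom="chr1", tid="t1", gid="g1"
) -> TranscriptModel:
    return TranscriptModel(
        tid, gid, [GenomicInterval(chrom, a, b, strand) for a, b in exons]
    )


def make_gene(exons, strand="+", chrom="chr1", gid="g1") -> GeneModel:
    return GeneModel(gid, [make_transcript(exons, strand, chrom, f"{gid}-t1", gid)])


def random_gene(rng: np.random.Generator, max_exons=5, strand=None) -> GeneModel:
    """Random small multi-isoform gene for oracle comparisons."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    chrom = "chr1"
    n_tx = int(rng.integers(1, 4))
    transcripts = []
    for t in range(n_tx):
        n_exons = int(rng.integers(1, max_exons + 1))
        pos = int(rng.integers(0, 50))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(1, 30))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(2, 40))
        transcripts.append(
            TranscriptModel(
                f"g-t{t}", "g", [GenomicInterval(chrom, a, b, strand) for a, b in exons]
            )
        )
    return GeneModel("g", transcripts)


def simple_read(blocks, strand="+", chrom="chr1", qid="r", **kw) -> AlignmentRecord:
    return AlignmentRecord(
        query_id=qid, chrom=chrom, blocks=list(blocks), assigned_strand=strand, **kw
    )


def brute_force_coverage(records, gene, projection) -> np.ndarray:
    """Per-base counter over every exonic genomic base, independent of the
    pileup implementation: a record covers a span position iff any of its
    blocks contains the corresponding genomic base."""
    values = np.zeros(projection.length)
    for idx in range(projection.length):
        g = projection.to_genomic(idx)
        for rec in records:
            if rec.chrom != gene.chrom or not rec.is_primary:
                continue
            if not rec.matches_strand(gene.strand):
                continue
            if any(a <= g < b for a, b in rec.blocks):
                values[idx] += 1
    return values


@pytest.fixture
def two_exon_gene() -> GeneModel:
    return make_gene([(100, 200), (400, 500)])


@pytest.fixture
def projection(two_exon_gene):
    return exon_span_projection(two_exon_gene.transcripts[0])
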