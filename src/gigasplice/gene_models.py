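"""Gene/transcript models and intron-architecture metrics.

Parses GTF/GFF3 annotation into exon-level gene models and computes the
metrics used throughout the attenuation analysis: the intron proportion of a
gene (1 - sum(exon)/span on its largest isoform), the maximum intron size
over all isoforms, intron-size bin assignment, and the exon-span coordinate
projection (position along the concatenated exons, 5'->3') on which all
coverage profiles are expressed.

Coordinates are 0-based half-open internally; GTF/GFF3 input and output are
1-based closed, converted at the boundary.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: Default intron-size bins (half-open, bp). "average" captures the mode of
#: the max-intron distribution of typical genes; "large" holds genes whose
#: biggest intron is big but still far below the gigantic (Mb-scale) class.
DEFAULT_BIN_INTERVALS: tuple[tuple[str, int, int], ...] = (
    ("average", 0, 100),
    ("large", 50_000, 100_001),
)

#: Genes with gigantic (hundreds of kb to Mb) introns in the D. melanogaster
#: testis: the Y-linked fertility genes plus the three autosomal gigantic
#: genes. Designated by name because their introns contain assembly gaps that
#: defeat size inference from annotation alone.
GIGANTIC_GENE_NAMES: tuple[str, ...] = (
    "kl-5", "kl-3", "kl-2", "ORY", "CCY", "Pzl", "Myo81F", "Mitf",
)

UNBINNED_LABEL = "unbinned"


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on one strand of one sequence."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start},{self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One isoform: ordered, non-overlapping exons on a single chrom/strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons on multiple chroms {chroms}"
            )
        if len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons on mixed strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def span_length(self) -> int:
        return self.exons[-1].end - self.exons[0].start

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    """A gene: one or more isoforms sharing a gene_id."""

    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass
class IntronMetrics:
    """Architecture metrics of one gene, computed on its largest isoform."""

    gene_id: str
    intron_proportion: float
    max_intron_bp: int
    largest_isoform_id: str
    bin_label: str
    span_bp: int = 0
    exon_bp: int = 0


@dataclass
class BinSpec:
    """Ordered half-open max-intron-size bins plus explicit gigantic-gene list.

    Genes named in ``gigantic_ids`` are assigned ``gigantic_label`` regardless
    of annotated intron size (their introns span assembly gaps).
    """

    intervals: tuple[tuple[str, int, int], ...] = DEFAULT_BIN_INTERVALS
    gigantic_ids: frozenset[str] = frozenset(GIGANTIC_GENE_NAMES)
    gigantic_label: str = "gigantic"

    def __post_init__(self) -> None:
        self.gigantic_ids = frozenset(self.gigantic_ids)
        ivals = sorted(self.intervals, key=lambda b: b[1])
        for (la, lo_a, hi_a), (lb, lo_b, hi_b) in zip(ivals, ivals[1:]):
            if lo_b < hi_a:
                raise ValueError(f"overlapping bins {la!r} and {lb!r}")
        for label, lo, hi in self.intervals:
            if not (0 <= lo < hi):
                raise ValueError(f"bad bin interval {label!r}: [{lo},{hi})")


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def _open_text(source) -> Iterator[str]:
    if hasattr(source, "read"):
        yield from source
        return
    opener = gzip.open if str(source).endswith(".gz") else open
    with opener(source, "rt") as fh:
        yield from fh


def _merge_bookended(
    exons: list[GenomicInterval], transcript_id: str
) -> list[GenomicInterval]:
    """Merge book-ended/overlapping exon records (annotation-dialect tolerance)."""
    exons = sorted(exons, key=lambda e: e.start)
    merged = [exons[0]]
    warned = False
    for e in exons[1:]:
        last = merged[-1]
        if e.start <= last.end:
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, e.end), last.strand
            )
            if not warned:
                logger.warning(
                    "transcript %s: merging book-ended/overlapping exon records",
                    transcript_id,
                )
                warned = True
        else:
            merged.append(e)
    return merged


def parse_annotation(source) -> list[GeneModel]:
    """Parse GTF or GFF3 ``exon`` features into GeneModels.

    ``source`` is a path (gzip-transparent) or an open text stream. Input
    coordinates are 1-based closed and converted to 0-based half-open.
    GTF attributes gene_id/transcript_id and GFF3 ID/Parent dialects are both
    accepted. Raises :class:`AnnotationError` naming the offending line for
    malformed input.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    gene_of_tx: dict[str, str] = {}
    tx_order: list[str] = []

    for lineno, line in enumerate(_open_text(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.count("\t") != 8:
            raise AnnotationError(
                f"line {lineno}: malformed record (expected 9 tab-separated fields)"
            )
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise AnnotationError(f"line {lineno}: malformed record ({exc})") from exc
        if feat.featuretype != "exon":
            continue
        if feat.end < feat.start:
            raise AnnotationError(f"line {lineno}: exon end < start")
        if feat.strand not in STRANDS:
            raise AnnotationError(f"line {lineno}: exon without usable strand")
        attrs = feat.attributes
        tx_ids = attrs.get("transcript_id") or attrs.get("Parent")
        if not tx_ids:
            raise AnnotationError(f"line {lineno}: exon without transcript identifier")
        gene_ids = attrs.get("gene_id") or attrs.get("gene") or attrs.get("ID")
        interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        for tx_id in tx_ids:
            if tx_id not in exons_by_tx:
                exons_by_tx[tx_id] = []
                tx_order.append(tx_id)
            exons_by_tx[tx_id].append(interval)
            if gene_ids:
                gene_of_tx.setdefault(tx_id, gene_ids[0])

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tx_id in tx_order:
        exons = exons_by_tx[tx_id]
        strands = {e.strand for e in exons}
        if len(strands) > 1:
            raise AnnotationError(f"transcript {tx_id}: exons on mixed strands")
        chroms = {e.chrom for e in exons}
        if len(chroms) > 1:
            raise AnnotationError(f"transcript {tx_id}: exons on multiple chroms")
        gene_id = gene_of_tx.get(tx_id, tx_id)
        tx = TranscriptModel(tx_id, gene_id, _merge_bookended(exons, tx_id))
        if gene_id not in genes:
            genes[gene_id] = []
            gene_order.append(gene_id)
        genes[gene_id].append(tx)

    return [GeneModel(gid, genes[gid]) for gid in gene_order]


def write_gtf(genes: Iterable[GeneModel], handle_or_path) -> None:
    """Write gene models as GTF exon features (1-based closed)."""
    own = not hasattr(handle_or_path, "write")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        for gene in genes:
            for tx in gene.transcripts:
                for e in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    fh.write(
                        f"{e.chrom}\tgigasplice\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{attrs}\n"
                    )
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Intron metrics
# ---------------------------------------------------------------------------

def introns_of(transcript: TranscriptModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons, in genomic order. [] for single-exon."""
    return [
        GenomicInterval(transcript.chrom, a.end, b.start, transcript.strand)
        for a, b in zip(transcript.exons, transcript.exons[1:])
        if b.start > a.end
    ]


def largest_isoform(gene: GeneModel) -> TranscriptModel:
    """Isoform with the greatest genomic span.

    Ties broken by greater summed exon length, then lexicographic
    transcript_id, so the choice is deterministic.
    """
    return max(
        gene.transcripts,
        key=lambda t: (t.span_length, t.exonic_length, _NegStr(t.transcript_id)),
    )


class _NegStr:
    """Orders strings descending under max() (lexicographically smallest wins)."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s


def intron_proportion(gene: GeneModel) -> float:
    """1 - sum(exon lengths)/span on the gene's largest isoform; in [0, 1]."""
    iso = largest_isoform(gene)
    return 1.0 - iso.exonic_length / iso.span_length


def max_intron_size(gene: GeneModel) -> int:
    """Longest intron present in any of the gene's isoforms (0 if none)."""
    sizes = [len(i) for tx in gene.transcripts for i in introns_of(tx)]
    return max(sizes, default=0)


def assign_bin(metrics: IntronMetrics, spec: BinSpec | None = None) -> str:
    """Bin label for a gene's max intron size.

    Explicit gigantic-gene designation takes precedence; otherwise the first
    interval containing max_intron_bp wins; no match -> "unbinned".
    """
    spec = spec or BinSpec()
    if metrics.gene_id in spec.gigantic_ids:
        return spec.gigantic_label
    for label, lo, hi in spec.intervals:
        if lo <= metrics.max_intron_bp < hi:
            return label
    return UNBINNED_LABEL


def compute_metrics(gene: GeneModel, spec: BinSpec | None = None) -> IntronMetrics:
    """All architecture metrics for one gene, bin label included."""
    iso = largest_isoform(gene)
    m = IntronMetrics(
        gene_id=gene.gene_id,
        intron_proportion=1.0 - iso.exonic_length / iso.span_length,
        max_intron_bp=max_intron_size(gene),
        largest_isoform_id=iso.transcript_id,
        bin_label="",
        span_bp=iso.span_length,
        exon_bp=iso.exonic_length,
    )
    m.bin_label = assign_bin(m, spec)
    return m


def write_metrics_tsv(metrics: Sequence[IntronMetrics], handle_or_path) -> None:
    own = not hasattr(handle_or_path, "write")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write(
            "gene_id\tlargest_isoform_id\tspan_bp\texon_bp\t"
            "intron_proportion\tmax_intron_bp\tbin_label\n"
        )
        for m in metrics:
            fh.write(
                f"{m.gene_id}\t{m.largest_isoform_id}\t{m.span_bp}\t{m.exon_bp}\t"
                f"{m.intron_proportion:.10g}\t{m.max_intron_bp}\t{m.bin_label}\n"
            )
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Exon-span projection
# ---------------------------------------------------------------------------

@dataclass
class ExonSpanProjection:
    """Bijection between exonic genomic bases and exon-span indices 0..L-1.

    Index 0 is the transcript's 5'-most base: genomic leftmost on '+',
    genomic rightmost on '-'. ``exon_offsets`` are the span-coordinate
    boundaries of the exons in 5'->3' order (first 0, last L).
    """

    transcript_id: str
    strand: str
    exon_starts: np.ndarray  # genomic, ascending
    exon_ends: np.ndarray
    length: int = field(init=False)
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lens = self.exon_ends - self.exon_starts
        self._cum = np.concatenate([[0], np.cumsum(lens)])
        self.length = int(self._cum[-1])

    @property
    def exon_offsets(self) -> np.ndarray:
        """Span offsets of exon boundaries, 5'->3' (len = n_exons + 1)."""
        if self.strand == "+":
            return self._cum.copy()
        # reversing the coordinate reverses which genomic exon is first, but
        # cumulative lengths of the reversed exon order give the offsets
        lens = (self.exon_ends - self.exon_starts)[::-1]
        return np.concatenate([[0], np.cumsum(lens)])

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)

    def to_span(self, gpos: int) -> int:
        """Span index of one exonic genomic base; KeyError if intronic."""
        i = int(np.searchsorted(self.exon_starts, gpos, side="right")) - 1
        if i < 0 or gpos >= self.exon_ends[i]:
            raise KeyError(f"genomic position {gpos} is not exonic")
        plus = int(self._cum[i]) + (gpos - int(self.exon_starts[i]))
        return plus if self.strand == "+" else self.length - 1 - plus

    def to_genomic(self, idx: int) -> int:
        """Genomic base of one span index (inverse of :meth:`to_span`)."""
        if not 0 <= idx < self.length:
            raise KeyError(f"span index {idx} out of range [0,{self.length})")
        plus = idx if self.strand == "+" else self.length - 1 - idx
        i = int(np.searchsorted(self._cum, plus, side="right")) - 1
        return int(self.exon_starts[i]) + (plus - int(self._cum[i]))

    def plus_span_of_block(self, bstart: int, bend: int) -> list[tuple[int, int]]:
        """Plus-orientation span intervals covered by genomic block [bstart,bend).

        Intronic portions contribute nothing. Intervals are half-open in the
        genomic-leftmost span orientation; callers reflect for '-' strand.
        """
        out = []
        lo = int(np.searchsorted(self.exon_ends, bstart, side="right"))
        for i in range(lo, len(self.exon_starts)):
            es, ee = int(self.exon_starts[i]), int(self.exon_ends[i])
            if es >= bend:
                break
            a, b = max(bstart, es), min(bend, ee)
            if a < b:
                c = int(self._cum[i])
                out.append((c + a - es, c + b - es))
        return out


def exon_span_projection(transcript: TranscriptModel) -> ExonSpanProjection:
    """Exon-span coordinate map for one isoform (see ExonSpanProjection)."""
    return ExonSpanProjection(
        transcript_id=transcript.transcript_id,
        strand=transcript.strand,
        exon_starts=np.array([e.start for e in transcript.exons], dtype=np.int64),
        exon_ends=np.array([e.end for e in transcript.exons], dtype=np.int64),
    )
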