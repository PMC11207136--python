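"""Strand-specific exon-span read coverage and library-size normalization.

Reads are assigned a transcript-of-origin strand from their paired-end flags
(dUTP "reverse" chemistry by default), piled up per base over the exon-span
coordinate of a gene's largest isoform, and normalized by the library's
primary-aligned record count scaled by 1e7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np
import pysam

from .gene_models import ExonSpanProjection, GeneModel

logger = logging.getLogger(__name__)

NORMALIZATION_SCALE = 1e7
PROTOCOLS = ("reverse", "forward", "unstranded")

#: assigned_strand value meaning "matches either strand" (unstranded protocol)
BOTH_STRANDS = "*"


class CoverageError(ValueError):
    pass


@dataclass
class AlignmentRecord:
    """One aligned read (mate), reduced to what coverage/junction counting needs.

    ``blocks`` are the aligned genomic segments, 0-based half-open, sorted and
    non-overlapping; more than one block means a split (spliced) alignment.
    ``assigned_strand`` is the strand of the originating transcript after
    protocol decoding ('*' when the protocol is unstranded).
    """

    query_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    assigned_strand: str
    is_primary: bool = True
    mate_role: str = "first"  # {first, second, unpaired}
    is_reverse: bool = False  # genomic orientation of this mate

    def __post_init__(self) -> None:
        if not self.blocks:
            raise CoverageError(f"record {self.query_id}: no aligned blocks")
        for (a1, b1), (a2, b2) in zip(self.blocks, self.blocks[1:]):
            if a2 < b1:
                raise CoverageError(
                    f"record {self.query_id}: unsorted/overlapping blocks"
                )

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def matches_strand(self, strand: str) -> bool:
        return self.assigned_strand in (strand, BOTH_STRANDS)


@dataclass
class CoverageProfile:
    """Per-base depth along the exon-span coordinate of one gene, 5'->3'."""

    gene_id: str
    values: np.ndarray
    library_total: int
    normalized: bool
    exon_offsets: np.ndarray
    isoform_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.exon_offsets = np.asarray(self.exon_offsets, dtype=np.int64)
        if self.exon_offsets[0] != 0 or self.exon_offsets[-1] != len(self.values):
            raise CoverageError("exon_offsets must run from 0 to span length")
        if np.any(np.diff(self.exon_offsets) <= 0):
            raise CoverageError("exon_offsets must be strictly increasing")
        if np.any(self.values < 0):
            raise CoverageError("coverage values must be non-negative")

    @property
    def length(self) -> int:
        return len(self.values)

    @property
    def n_exons(self) -> int:
        return len(self.exon_offsets) - 1


# ---------------------------------------------------------------------------
# Strand decoding (dUTP and mirror protocols)
# ---------------------------------------------------------------------------

def decode_strand(mate_role: str, is_reverse: bool, protocol: str) -> str:
    """Transcript strand implied by a mate's role and genomic orientation.

    "reverse" is the dUTP chemistry: the first mate sequences the strand
    opposite the transcript, so first-mate-on-minus means transcript '+'.
    "forward" is the mirror. "unstranded" matches both strands ('*').
    Unpaired reads are treated as first mates (dUTP semantics are defined by
    mate role; the caller counts these).
    """
    if protocol not in PROTOCOLS:
        raise CoverageError(f"unknown protocol {protocol!r}")
    if protocol == "unstranded":
        return BOTH_STRANDS
    first = mate_role in ("first", "unpaired")
    if protocol == "reverse":
        antisense = first
    else:  # forward
        antisense = not first
    if antisense:
        return "+" if is_reverse else "-"
    return "-" if is_reverse else "+"


def read_alignments(
    path,
    protocol: str = "reverse",
    region: tuple[str, int, int] | None = None,
    counters: dict | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file, decoding strands.

    Secondary/supplementary/unmapped records are skipped (counted in
    ``counters`` if given); unpaired reads under a paired protocol are
    assigned as first mates and counted, never silently dropped.
    """
    counters = counters if counters is not None else {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        it = fh.fetch(*region) if region is not None else fh
        for seg in it:
            if seg.is_unmapped:
                counters["unmapped"] = counters.get("unmapped", 0) + 1
                continue
            if seg.is_secondary or seg.is_supplementary:
                counters["non_primary"] = counters.get("non_primary", 0) + 1
                continue
            if seg.is_paired:
                mate_role = "second" if seg.is_read2 else "first"
            else:
                mate_role = "unpaired"
                counters["unpaired"] = counters.get("unpaired", 0) + 1
            blocks = [(int(a), int(b)) for a, b in seg.get_blocks()]
            merged: list[tuple[int, int]] = []
            for a, b in blocks:  # merge abutting M ops (e.g. around I/D)
                if merged and a <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], b))
                else:
                    merged.append((a, b))
            yield AlignmentRecord(
                query_id=seg.query_name,
                chrom=seg.reference_name,
                blocks=merged,
                assigned_strand=decode_strand(mate_role, seg.is_reverse, protocol),
                is_primary=True,
                mate_role=mate_role,
                is_reverse=seg.is_reverse,
            )


def count_library_total(path) -> int:
    """Number of primary aligned records in a SAM/BAM library."""
    n = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if not (seg.is_unmapped or seg.is_secondary or seg.is_supplementary):
                n += 1
    return n


# ---------------------------------------------------------------------------
# Pileup over the exon-span coordinate
# ---------------------------------------------------------------------------

def exon_coverage(
    alignments: Iterable[AlignmentRecord],
    gene: GeneModel,
    projection: ExonSpanProjection,
    library_total: int = 0,
) -> CoverageProfile:
    """Per-base read coverage of a gene over its exon-span coordinate.

    A record contributes 1 to each exon-span position its blocks overlap,
    provided it is primary, on the gene's chromosome, and its assigned strand
    matches the gene strand. Intronic block portions contribute nothing.
    """
    if projection.transcript_id not in {
        t.transcript_id for t in gene.transcripts
    }:
        raise CoverageError(
            f"projection isoform {projection.transcript_id} not in gene {gene.gene_id}"
        )
    L = projection.length
    diff = np.zeros(L + 1, dtype=np.int64)
    # single-block records overwhelmingly dominate; batch them through a
    # vectorized exon lookup and keep the general per-block path for the rest
    sa: list[int] = []
    sb: list[int] = []
    slow_blocks: list[tuple[int, int]] = []
    strand = gene.strand
    chrom = gene.chrom
    for rec in alignments:
        if not rec.is_primary or rec.chrom != chrom:
            continue
        if not rec.matches_strand(strand):
            continue
        blocks = rec.blocks
        if len(blocks) == 1:
            sa.append(blocks[0][0])
            sb.append(blocks[0][1])
        else:
            slow_blocks.extend(blocks)
    if sa:
        a = np.asarray(sa, dtype=np.int64)
        b = np.asarray(sb, dtype=np.int64)
        starts, ends = projection.exon_starts, projection.exon_ends
        cum = projection._cum
        i = np.searchsorted(starts, a, side="right") - 1
        ic = np.clip(i, 0, len(starts) - 1)
        inside = (i >= 0) & (a < ends[ic]) & (b <= ends[ic])
        lo = cum[ic] + a - starts[ic]
        hi = cum[ic] + b - starts[ic]
        if projection.strand == "-":
            lo, hi = L - hi, L - lo
        np.add.at(diff, lo[inside], 1)
        np.add.at(diff, hi[inside], -1)
        # entirely intronic/outside blocks contribute nothing; anything that
        # straddles an exon boundary goes through the general path
        intronic = (i < 0) & (b <= starts[0])
        nxt = np.clip(i + 1, 0, len(starts) - 1)
        intronic |= (i >= 0) & (a >= ends[ic]) & (
            (i + 1 >= len(starts)) | (b <= starts[nxt])
        )
        for j in np.nonzero(~inside & ~intronic)[0]:
            slow_blocks.append((int(a[j]), int(b[j])))
    for bstart, bend in slow_blocks:
        for lo, hi in projection.plus_span_of_block(bstart, bend):
            if projection.strand == "-":
                lo, hi = L - hi, L - lo
            diff[lo] += 1
            diff[hi] -= 1
    values = np.cumsum(diff[:-1]).astype(float)
    return CoverageProfile(
        gene_id=gene.gene_id,
        values=values,
        library_total=library_total,
        normalized=False,
        exon_offsets=projection.exon_offsets,
        isoform_id=projection.transcript_id,
    )


def normalize_profile(profile: CoverageProfile) -> CoverageProfile:
    """Scale depth by 1e7 / library_total (library-size normalization)."""
    if profile.normalized:
        raise CoverageError("profile already normalized")
    if profile.library_total <= 0:
        raise CoverageError("library_total must be positive to normalize")
    return replace(
        profile,
        values=profile.values * (NORMALIZATION_SCALE / profile.library_total),
        normalized=True,
    )


def exon_mean(profile: CoverageProfile, exon_index: int) -> float:
    """Mean depth over one exon's span range (exons in 5'->3' order)."""
    if not 0 <= exon_index < profile.n_exons:
        raise CoverageError(
            f"exon index {exon_index} out of range [0,{profile.n_exons})"
        )
    lo = int(profile.exon_offsets[exon_index])
    hi = int(profile.exon_offsets[exon_index + 1])
    return float(np.mean(profile.values[lo:hi]))


# ---------------------------------------------------------------------------
# bedGraph round trip
# ---------------------------------------------------------------------------

def _projection_for(profile: CoverageProfile, gene: GeneModel) -> ExonSpanProjection:
    from .gene_models import exon_span_projection

    for tx in gene.transcripts:
        if tx.transcript_id == profile.isoform_id:
            return exon_span_projection(tx)
    raise CoverageError(
        f"profile isoform {profile.isoform_id} not found in gene {gene.gene_id}"
    )


def write_bedgraph(
    profile: CoverageProfile, gene: GeneModel, handle_or_path
) -> None:
    """Write exonic coverage as genomic-coordinate bedGraph (0-based half-open).

    Runs of equal depth are merged; zero-depth runs are omitted, per the
    format's convention. Restricted to exons, so re-import reproduces the
    exonic values exactly.
    """
    proj = _projection_for(profile, gene)
    own = not hasattr(handle_or_path, "write")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        for i in range(proj.n_exons):
            es, ee = int(proj.exon_starts[i]), int(proj.exon_ends[i])
            vals = np.array(
                [profile.values[proj.to_span(g)] for g in range(es, ee)]
            )
            run_start = 0
            for j in range(1, len(vals) + 1):
                if j == len(vals) or vals[j] != vals[run_start]:
                    v = vals[run_start]
                    if v != 0:
                        fh.write(
                            f"{gene.chrom}\t{es + run_start}\t{es + j}\t{v:.10g}\n"
                        )
                    run_start = j
    finally:
        if own:
            fh.close()


def read_bedgraph(
    handle_or_path,
    gene: GeneModel,
    isoform_id: str,
    library_total: int = 0,
    normalized: bool = False,
) -> CoverageProfile:
    """Re-import a bedGraph written by :func:`write_bedgraph`."""
    from .gene_models import exon_span_projection

    tx = next(
        t for t in gene.transcripts if t.transcript_id == isoform_id
    )
    proj = exon_span_projection(tx)
    own = not hasattr(handle_or_path, "read")
    fh = open(handle_or_path) if own else handle_or_path
    values = np.zeros(proj.length, dtype=float)
    try:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            _, start, end, val = line.rstrip("\n").split("\t")
            for g in range(int(start), int(end)):
                values[proj.to_span(g)] = float(val)
    finally:
        if own:
            fh.close()
    return CoverageProfile(
        gene_id=gene.gene_id,
        values=values,
        library_total=library_total,
        normalized=normalized,
        exon_offsets=proj.exon_offsets,
        isoform_id=isoform_id,
    )
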