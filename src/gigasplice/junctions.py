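"""Junction-class read counting and per-intron splicing efficiency.

Mirrors the junction-probe logic used cytologically to distinguish nascent
from spliced transcripts: for every intron there are three junction classes —
exon-intron (5' boundary, nascent signal), intron-exon (3' boundary,
unspliced signal) and exon-exon (spliced signal). A contiguous alignment
block supports a boundary class when it spans the boundary with at least
``min_flank`` aligned bases on each side (default 15, the probe half-length);
a split alignment supports the exon-exon class when two consecutive blocks
end exactly at the donor and start exactly at the acceptor.

Splicing efficiency of an intron is read from its 3' splice site:
s_hat = spliced / (spliced + unspliced) with a Wilson 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from statsmodels.stats.proportion import proportion_confint

from .coverage import AlignmentRecord
from .gene_models import TranscriptModel, introns_of

DEFAULT_MIN_FLANK = 15

EXON_INTRON = "exon_intron"
INTRON_EXON = "intron_exon"
EXON_EXON = "exon_exon"
JUNCTION_KINDS = (EXON_INTRON, INTRON_EXON, EXON_EXON)


class JunctionError(ValueError):
    pass


@dataclass(frozen=True)
class JunctionSpec:
    """One junction of one intron.

    ``donor`` and ``acceptor`` are the genomic 0-based boundaries of the
    intron: donor = intron start (exon end), acceptor = intron end (next exon
    start) in genomic orientation. Kinds are oriented 5'->3' in transcript
    direction, so on the '-' strand the exon_intron (nascent) junction sits
    at the genomic *right* boundary of the intron.
    """

    gene_id: str
    intron_index: int
    kind: str
    donor: int
    acceptor: int
    strand: str
    min_flank: int = DEFAULT_MIN_FLANK

    def __post_init__(self) -> None:
        if self.kind not in JUNCTION_KINDS:
            raise JunctionError(f"unknown junction kind {self.kind!r}")
        if self.min_flank < 1:
            raise JunctionError("min_flank must be >= 1")
        if self.donor >= self.acceptor:
            raise JunctionError("donor must lie left of acceptor genomically")


@dataclass
class JunctionCounts:
    """Supporting-read count per junction spec of one gene."""

    gene_id: str
    counts: dict[JunctionSpec, int] = field(default_factory=dict)

    def by_intron(self, intron_index: int) -> dict[str, int]:
        return {
            spec.kind: n
            for spec, n in self.counts.items()
            if spec.intron_index == intron_index
        }


@dataclass
class SplicingEfficiency:
    """Spliced fraction at one intron's 3' splice site, with Wilson 95% CI."""

    gene_id: str
    intron_index: int
    spliced_count: int
    unspliced_count: int
    s_hat: float
    ci: tuple[float, float]


def enumerate_junctions(
    transcript: TranscriptModel, min_flank: int = DEFAULT_MIN_FLANK
) -> list[JunctionSpec]:
    """Three junction specs per intron, ordered 5'->3' in transcript direction.

    Intron indices are transcript-directional: intron 0 separates the first
    and second exons encountered 5'->3'. Empty list for single-exon
    transcripts.
    """
    introns = introns_of(transcript)
    if transcript.strand == "-":
        introns = introns[::-1]
    specs: list[JunctionSpec] = []
    for i, intron in enumerate(introns):
        for kind in JUNCTION_KINDS:
            specs.append(
                JunctionSpec(
                    gene_id=transcript.gene_id,
                    intron_index=i,
                    kind=kind,
                    donor=intron.start,
                    acceptor=intron.end,
                    strand=transcript.strand,
                    min_flank=min_flank,
                )
            )
    return specs


def _five_prime_boundary(spec: JunctionSpec) -> int:
    """Genomic boundary where the exon_intron (nascent) junction sits."""
    return spec.donor if spec.strand == "+" else spec.acceptor


def _three_prime_boundary(spec: JunctionSpec) -> int:
    return spec.acceptor if spec.strand == "+" else spec.donor


def classify_alignment(record: AlignmentRecord, spec: JunctionSpec) -> bool:
    """True iff the record supports the junction.

    Boundary classes (exon_intron / intron_exon) need one contiguous block
    spanning the boundary with >= min_flank aligned bases on each side.
    The exon_exon class needs two consecutive blocks abutting the donor and
    acceptor *exactly* (zero tolerance, keeping misaligned splice junctions
    out), each contributing >= min_flank bases next to the junction.
    """
    if not record.is_primary or not record.matches_strand(spec.strand):
        return False
    f = spec.min_flank
    if spec.kind == EXON_EXON:
        for (a1, b1), (a2, b2) in zip(record.blocks, record.blocks[1:]):
            if b1 == spec.donor and a2 == spec.acceptor:
                if b1 - a1 >= f and b2 - a2 >= f:
                    return True
        return False
    boundary = (
        _five_prime_boundary(spec) if spec.kind == EXON_INTRON
        else _three_prime_boundary(spec)
    )
    for a, b in record.blocks:
        if a <= boundary - f and b >= boundary + f:
            return True
    return False


def count_junctions(
    alignments: Iterable[AlignmentRecord], specs: Sequence[JunctionSpec]
) -> JunctionCounts:
    """Supporting-read count per spec. A read may support several distinct
    specs (e.g. a long read spanning an exon and both its junctions)."""
    if not specs:
        raise JunctionError("no junction specs given")
    gene_ids = {s.gene_id for s in specs}
    if len(gene_ids) > 1:
        raise JunctionError("specs must come from a single gene")
    counts = JunctionCounts(gene_id=specs[0].gene_id)
    counts.counts = {s: 0 for s in specs}
    for rec in alignments:
        for spec in specs:
            if classify_alignment(rec, spec):
                counts.counts[spec] += 1
    return counts


def splicing_efficiency(
    counts: JunctionCounts, intron_index: int
) -> SplicingEfficiency:
    """Spliced fraction at one intron: exon_exon vs intron_exon support.

    The 5' exon_intron class is nascent signal and deliberately not in the
    denominator; splicing status is read from the 3' splice site.
    """
    per = counts.by_intron(intron_index)
    if not per:
        raise JunctionError(f"no junction counts for intron {intron_index}")
    spliced = per.get(EXON_EXON, 0)
    unspliced = per.get(INTRON_EXON, 0)
    n = spliced + unspliced
    if n == 0:
        raise JunctionError(
            f"intron {intron_index}: no informative (spliced+unspliced) reads"
        )
    lo, hi = proportion_confint(spliced, n, alpha=0.05, method="wilson")
    return SplicingEfficiency(
        gene_id=counts.gene_id,
        intron_index=intron_index,
        spliced_count=spliced,
        unspliced_count=unspliced,
        s_hat=spliced / n,
        ci=(float(lo), float(hi)),
    )


def aberrant_splicing_flag(
    efficiencies: Sequence[SplicingEfficiency], threshold: float = 0.5
) -> bool:
    """Gene-level aberrant-splicing flag (emulation of an external q-value call).

    True iff any intron's estimated splicing efficiency is confidently below
    ``threshold`` (upper Wilson bound < threshold). This is a deliberate
    simplification standing in for splice-graph-based aberrance calls so the
    binned expression analyses are runnable without external tooling; it is
    not presented as such a call.
    """
    if not efficiencies:
        raise JunctionError("no defined efficiencies: flag undefined")
    return any(e.ci[1] < threshold for e in efficiencies)


def write_junction_tsv(all_counts: Sequence[JunctionCounts], handle_or_path) -> None:
    own = not hasattr(handle_or_path, "write")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write("gene_id\tintron_index\tkind\tcount\n")
        for jc in all_counts:
            for spec in sorted(
                jc.counts, key=lambda s: (s.intron_index, JUNCTION_KINDS.index(s.kind))
            ):
                fh.write(
                    f"{jc.gene_id}\t{spec.intron_index}\t{spec.kind}\t"
                    f"{jc.counts[spec]}\n"
                )
    finally:
        if own:
            fh.close()


def write_efficiency_tsv(
    effs: Sequence[SplicingEfficiency], handle_or_path
) -> None:
    own = not hasattr(handle_or_path, "write")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write(
            "gene_id\tintron_index\tspliced\tunspliced\ts_hat\tci_low\tci_high\n"
        )
        for e in effs:
            fh.write(
                f"{e.gene_id}\t{e.intron_index}\t{e.spliced_count}\t"
                f"{e.unspliced_count}\t{e.s_hat:.6g}\t{e.ci[0]:.6g}\t{e.ci[1]:.6g}\n"
            )
    finally:
        if own:
            fh.close()
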