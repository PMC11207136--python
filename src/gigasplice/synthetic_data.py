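"""Generative model of spermatocyte transcription of gigantic-intron genes.

The testis is a developmental conveyor: spermatocytes (SCs) of all ages
0..T (T ~ 85 h) coexist, each transcribing its genes 5'->3' at elongation
rate v with Poisson initiation (rate r per hour per cell). Introns are
spliced co-transcriptionally: as soon as an intron's 3' splice site has been
transcribed it is removed with probability s (the genotype's splicing
efficiency); failed introns persist in the transcript. At the 5' boundary of
each *gigantic* intron the polymerase prematurely terminates with
probability d (the genotype's drop-off probability); the truncated
transcript, ending at the donor site, persists as RNA. A sequencing layer
samples fragments uniformly over all existing RNA and emits paired,
strand-protocol-consistent alignment records.

Every observable upstream has a closed form. With tau_x = (template
distance from the TSS to position x) / v, the expected number of transcripts
covering exonic position x per cell is

    E[C(x)] = S_x * r * (T - tau_x)^2 / (2 T)          (tau_x < T, else 0)

where S_x = prod over gigantic introns 5' of x of (1 - d): a polymerase
initiated a hours ago covers x iff a > tau_x (uniform ages and uniform
initiation times give the (T - tau)^2 / 2T factor) and iff it survived every
gigantic-intron entry upstream of x. Expected intron-drop fold changes and
ratio-profile slopes follow by integrating this expression over exons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import AlignmentRecord, decode_strand
from .expression_bins import CountTable
from .gene_models import GeneModel, GenomicInterval, TranscriptModel, write_gtf

DEFAULT_MAX_AGE_H = 85.0  # SC development spans ~80-90 h
DEFAULT_ELONGATION_BP_H = 60_000.0
DEFAULT_INITIATION_PER_H = 2.0


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class SimGeneSpec:
    """Architecture of one simulated gene.

    Template coordinates run 0..span 5'->3' from the TSS regardless of
    genomic strand; ``offset`` places the gene on ``chrom`` (for '-' genes
    the TSS sits at the genomic right end).
    """

    gene_id: str
    exon_lengths: list[int]
    intron_lengths: list[int]
    gigantic_flags: list[bool]
    strand: str = "+"
    chrom: str = "chrSim"
    offset: int = 0

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise SimulationError(
                f"{self.gene_id}: need one fewer intron than exons"
            )
        if len(self.gigantic_flags) != len(self.intron_lengths):
            raise SimulationError(f"{self.gene_id}: flags must align with introns")
        if any(v <= 0 for v in self.exon_lengths + self.intron_lengths):
            raise SimulationError(f"{self.gene_id}: lengths must be positive")

    @property
    def n_introns(self) -> int:
        return len(self.intron_lengths)

    @property
    def span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    @property
    def exon_template(self) -> list[tuple[int, int]]:
        """Exon intervals in template coordinates, 5'->3'."""
        out, pos = [], 0
        for i, e in enumerate(self.exon_lengths):
            out.append((pos, pos + e))
            pos += e
            if i < self.n_introns:
                pos += self.intron_lengths[i]
        return out

    @property
    def intron_template(self) -> list[tuple[int, int]]:
        out, pos = [], 0
        for i, e in enumerate(self.exon_lengths):
            pos += e
            if i < self.n_introns:
                out.append((pos, pos + self.intron_lengths[i]))
                pos += self.intron_lengths[i]
        return out

    def template_to_genomic(self, t0: int, t1: int) -> tuple[int, int]:
        """Genomic interval of template interval [t0, t1)."""
        if self.strand == "+":
            return self.offset + t0, self.offset + t1
        span = self.span
        return self.offset + span - t1, self.offset + span - t0

    def to_gene_model(self) -> GeneModel:
        exons = [
            GenomicInterval(self.chrom, *self.template_to_genomic(t0, t1), self.strand)
            for t0, t1 in self.exon_template
        ]
        tx = TranscriptModel(f"{self.gene_id}-RA", self.gene_id, exons)
        return GeneModel(self.gene_id, [tx])


@dataclass
class GenotypeParams:
    """Per-genotype mechanism parameters.

    drop_prob: probability that a polymerase terminates on entering a
    gigantic intron. splice_prob: probability an intron is removed once its
    3' splice site has been transcribed.
    """

    label: str
    drop_prob: float
    splice_prob: float

    def __post_init__(self) -> None:
        for name in ("drop_prob", "splice_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{self.label}: {name}={v} outside [0,1]")


@dataclass
class SimConfig:
    genes: list[SimGeneSpec]
    genotypes: list[GenotypeParams]
    elongation_rate: float = DEFAULT_ELONGATION_BP_H  # bp per hour
    max_age: float = DEFAULT_MAX_AGE_H  # hours
    initiation_rate: float = DEFAULT_INITIATION_PER_H  # polymerases/h/cell
    n_cells: int = 50
    read_length: int = 250
    fragment_length: int = 500
    n_reads: int = 20_000  # fragments per library (2 mates each)
    n_replicates: int = 3  # count-table replicates per genotype
    count_depth: float = 500.0  # target mean count of a typical gene
    seed: int = 0
    protocol: str = "reverse"
    coverage_genes: list[str] | None = None  # genes emitted to SAM (None = all)

    def __post_init__(self) -> None:
        for name in ("elongation_rate", "max_age", "initiation_rate"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        for name in ("n_cells", "n_reads", "read_length", "fragment_length"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")

    def genotype(self, label: str) -> GenotypeParams:
        for g in self.genotypes:
            if g.label == label:
                return g
        raise SimulationError(f"unknown genotype {label!r}")


# ---------------------------------------------------------------------------
# Transcript population
# ---------------------------------------------------------------------------

#: intron states in a transcript
INTRON_PENDING = 0  # 3' splice site not yet transcribed
INTRON_RETAINED = 1
INTRON_SPLICED = 2


@dataclass
class TranscriptPopulation:
    """All transcripts of one gene across the simulated cell population.

    ``fronts`` is each polymerase's template position (bp transcribed so
    far, capped at the span or at a failed gigantic-intron donor site);
    ``states`` is (n_transcripts, n_introns) with PENDING/RETAINED/SPLICED;
    ``truncated`` marks premature terminations.
    """

    gene: SimGeneSpec
    fronts: np.ndarray
    states: np.ndarray
    truncated: np.ndarray

    @property
    def n_transcripts(self) -> int:
        return len(self.fronts)

    def molecule_lengths(self) -> np.ndarray:
        """Retained RNA length of every transcript, vectorized.

        Equals exonic sequence up to the front, plus fully transcribed
        retained introns, plus the partial intron currently being
        transcribed (never spliced before completion).
        """
        g = self.gene
        # piecewise-linear cumulative exonic length over template position
        knots = [0.0]
        cum = [0.0]
        introns = g.intron_template
        for k, (e0, e1) in enumerate(g.exon_template):
            knots.append(float(e1))
            cum.append(cum[-1] + (e1 - e0))
            if k < len(introns):
                knots.append(float(introns[k][1]))
                cum.append(cum[-1])
        fronts = self.fronts.astype(float)
        exonic = np.interp(fronts, knots, cum)
        intronic_transcribed = fronts - exonic
        if g.n_introns:
            lens = np.array(g.intron_lengths, dtype=float)
            ends = np.array([i1 for _, i1 in introns], dtype=float)
            full = fronts[:, None] >= ends[None, :]
            fully_intronic = full @ lens
            retained_full = (self.states == INTRON_RETAINED) @ lens
        else:
            fully_intronic = np.zeros(len(fronts))
            retained_full = np.zeros(len(fronts))
        partial = intronic_transcribed - fully_intronic
        return np.rint(exonic + retained_full + partial).astype(np.int64)

    def molecule_segments(self, i: int) -> list[tuple[int, int]]:
        """Retained RNA of transcript i as template intervals, 5'->3'.

        Exonic sequence up to the front is always retained; a fully
        transcribed intron is retained unless spliced; a partially
        transcribed intron is retained up to the front.
        """
        front = int(self.fronts[i])
        segs: list[tuple[int, int]] = []
        exons = self.gene.exon_template
        introns = self.gene.intron_template
        for k, (e0, e1) in enumerate(exons):
            if front <= e0:
                break
            hi = min(front, e1)
            _push(segs, e0, hi)
            if k < len(introns):
                i0, i1 = introns[k]
                if front <= i0:
                    break
                if self.states[i, k] == INTRON_SPLICED:
                    continue
                _push(segs, i0, min(front, i1))
        return segs


def _push(segs: list[tuple[int, int]], a: int, b: int) -> None:
    if b <= a:
        return
    if segs and segs[-1][1] == a:
        segs[-1] = (segs[-1][0], b)
    else:
        segs.append((a, b))


def simulate_cells(
    config: SimConfig,
    gene: SimGeneSpec,
    genotype: GenotypeParams,
    rng: np.random.Generator,
) -> TranscriptPopulation:
    """Simulate the transcript population of one gene in n_cells SCs.

    Cell ages are Uniform(0, T); each cell initiates Poisson(r*t)
    polymerases with start times uniform over its lifetime, so elapsed
    transcription times are Uniform(0, t). Fronts advance at v bp/h. On
    entering a gigantic intron a polymerase terminates with probability d
    (transcript kept, truncated at the donor). Fully transcribed introns are
    spliced with probability s.
    """
    ages = rng.uniform(0.0, config.max_age, config.n_cells)
    counts = rng.poisson(config.initiation_rate * ages)
    elapsed = np.concatenate(
        [rng.uniform(0.0, t, k) for t, k in zip(ages, counts)]
    ) if counts.sum() else np.empty(0)
    fronts = np.minimum(elapsed * config.elongation_rate, gene.span)

    truncated = np.zeros(len(fronts), dtype=bool)
    introns = gene.intron_template
    for k, flag in enumerate(gene.gigantic_flags):
        if not flag:
            continue
        entry = introns[k][0]
        crossing = fronts > entry
        dropped = crossing & (rng.random(len(fronts)) < genotype.drop_prob)
        fronts[dropped] = entry
        truncated |= dropped

    fronts = np.floor(fronts).astype(np.int64)
    n = len(fronts)
    n_introns = gene.n_introns
    states = np.zeros((n, n_introns), dtype=np.int8)
    if n and n_introns:
        ends = np.array([i1 for _, i1 in introns])
        full = fronts[:, None] >= ends[None, :]
        spliced = rng.random((n, n_introns)) < genotype.splice_prob
        states[full & spliced] = INTRON_SPLICED
        states[full & ~spliced] = INTRON_RETAINED
    return TranscriptPopulation(gene, fronts, states, truncated)


# ---------------------------------------------------------------------------
# Closed-form expectations
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Analytic twin of the generative model for one gene x genotype."""

    gene_id: str
    genotype: str
    span_profile: np.ndarray  # expected relative coverage per exon-span base
    exonic_mass: float  # integral of span_profile (expected exonic RNA mass)
    drop_folds: dict[int, float]  # per intron index, flanking-exon mean ratio
    survival: dict[int, float]  # per gigantic intron, P(pass)
    splice_prob: float

    def to_jsonable(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "genotype": self.genotype,
            "exonic_mass": self.exonic_mass,
            "drop_folds": {str(k): v for k, v in self.drop_folds.items()},
            "survival": {str(k): v for k, v in self.survival.items()},
            "splice_prob": self.splice_prob,
            "span_profile": [round(float(v), 8) for v in self.span_profile],
        }


def expected_profile(
    spec: SimGeneSpec, genotype: GenotypeParams, config: SimConfig
) -> GroundTruth:
    """Closed-form expected exon-span coverage shape and drop fold changes.

    The profile is the per-cell expected transcript count covering each
    exonic base (see module docstring); fold change across intron m is the
    ratio of profile means over the flanking exons.
    """
    v, T, r = config.elongation_rate, config.max_age, config.initiation_rate
    introns = spec.intron_template
    exons = spec.exon_template
    d = genotype.drop_prob

    pieces = []
    offsets = [0]
    for e0, e1 in exons:
        t = np.arange(e0, e1, dtype=float)
        tau = t / v
        w = np.where(tau < T, r * (T - tau) ** 2 / (2 * T), 0.0)
        n_upstream = sum(
            1 for k, flag in enumerate(spec.gigantic_flags)
            if flag and introns[k][0] < e0
        )
        pieces.append(w * (1.0 - d) ** n_upstream)
        offsets.append(offsets[-1] + (e1 - e0))
    profile = np.concatenate(pieces)

    drop_folds: dict[int, float] = {}
    for m in range(spec.n_introns):
        before = profile[offsets[m]:offsets[m + 1]].mean()
        after = profile[offsets[m + 1]:offsets[m + 2]].mean()
        drop_folds[m] = float(before / after) if after > 0 else float("inf")

    survival = {
        k: 1.0 - d for k, flag in enumerate(spec.gigantic_flags) if flag
    }
    return GroundTruth(
        gene_id=spec.gene_id,
        genotype=genotype.label,
        span_profile=profile,
        exonic_mass=float(profile.sum()),
        drop_folds=drop_folds,
        survival=survival,
        splice_prob=genotype.splice_prob,
    )


def expected_ratio_slope(
    spec: SimGeneSpec,
    control: GroundTruth,
    mutant: GroundTruth,
) -> float:
    """Slope of the expected mutant/control profile ratio on span/[0,1].

    The measured ratio carries a library-composition constant; its *sign*
    is the guaranteed ground truth (negative iff the mutant drop-off exceeds
    the control's somewhere along the span).
    """
    ok = control.span_profile > 0
    x = np.nonzero(ok)[0] / len(control.span_profile)
    ratio = mutant.span_profile[ok] / control.span_profile[ok]
    return float(np.polyfit(x, ratio, 1)[0])


# ---------------------------------------------------------------------------
# Sequencing layer
# ---------------------------------------------------------------------------

def emit_alignments(
    population: TranscriptPopulation,
    spec: SimGeneSpec,
    config: SimConfig,
    rng: np.random.Generator,
    n_reads: int | None = None,
) -> list[AlignmentRecord]:
    """Sample paired reads uniformly over all existing RNA of one gene.

    Each of ``n_reads`` fragments (length ``fragment_length``, clipped to
    its molecule) yields two mates of ``read_length``; fragment starts are
    uniform over the valid start positions of each molecule, molecules
    weighted by that number. Reads crossing a spliced-out intron become
    split alignments with blocks abutting donor and acceptor exactly;
    retained-intron RNA yields contiguous alignments. Mate orientation
    follows the configured strandedness protocol.
    """
    n_reads = config.n_reads if n_reads is None else n_reads
    fl, rl = config.fragment_length, config.read_length
    mol_len = population.molecule_lengths()
    weights = np.maximum(mol_len - fl + 1, 1) * (mol_len > 0)
    if weights.sum() == 0:
        return []
    counts = rng.multinomial(n_reads, weights / weights.sum())
    # retained-segment lists are needed only for molecules that receive reads
    segments = {
        int(i): population.molecule_segments(int(i)) for i in np.nonzero(counts)[0]
    }

    # orientation/strand decoding is per (mate role), not per read
    mate_meta = {}
    for role in ("first", "second"):
        is_rev = _mate_orientation(role, spec.strand, config.protocol)
        mate_meta[role] = (is_rev, decode_strand(role, is_rev, config.protocol))

    records: list[AlignmentRecord] = []
    read_idx = 0
    for i in np.nonzero(counts)[0]:
        segs = segments[int(i)]
        m = int(mol_len[i])
        seg_lens = [b - a for a, b in segs]
        bounds = np.concatenate([[0], np.cumsum(seg_lens)])
        flen = min(fl, m)
        rlen = min(rl, flen)
        starts = rng.integers(0, max(m - flen, 0) + 1, counts[i])
        for u in starts:
            u = int(u)
            qname = f"{spec.gene_id}.{i}.{read_idx}"
            read_idx += 1
            mate_ivals = (
                ("second", u, u + rlen),
                ("first", u + flen - rlen, u + flen),
            )
            for role, a, b in mate_ivals:
                if len(segs) == 1:
                    s0 = segs[0][0]
                    blocks = [spec.template_to_genomic(s0 + a, s0 + b)]
                else:
                    blocks = _molecule_to_genomic(segs, bounds, a, b, spec)
                is_rev, assigned = mate_meta[role]
                records.append(
                    AlignmentRecord(
                        query_id=qname,
                        chrom=spec.chrom,
                        blocks=blocks,
                        assigned_strand=assigned,
                        is_primary=True,
                        mate_role=role,
                        is_reverse=is_rev,
                    )
                )
    return records


def _mate_orientation(role: str, strand: str, protocol: str) -> bool:
    """Genomic orientation (is_reverse) of a mate under the protocol.

    dUTP ("reverse") chemistry: the first mate sequences antisense to the
    transcript; "forward" is the mirror; unstranded libraries are emitted
    with forward geometry (the information is simply not used in decoding).
    """
    sense = strand == "-"  # genomic orientation of a transcript-sense read
    if protocol == "reverse":
        return not sense if role == "first" else sense
    return sense if role == "first" else not sense


def _molecule_to_genomic(
    segs: list[tuple[int, int]],
    bounds: np.ndarray,
    a: int,
    b: int,
    spec: SimGeneSpec,
) -> list[tuple[int, int]]:
    """Genomic alignment blocks of molecule-coordinate interval [a, b)."""
    template: list[tuple[int, int]] = []
    k0 = int(np.searchsorted(bounds, a, side="right")) - 1
    for k in range(max(k0, 0), len(segs)):
        s0, s1 = segs[k]
        lo = max(a, int(bounds[k]))
        hi = min(b, int(bounds[k + 1]))
        if hi <= lo:
            break
        t0 = s0 + (lo - int(bounds[k]))
        t1 = s0 + (hi - int(bounds[k]))
        # abutting template segments (retained intron) merge into one block
        if template and template[-1][1] == t0:
            template[-1] = (template[-1][0], t1)
        else:
            template.append((t0, t1))
    blocks = [spec.template_to_genomic(t0, t1) for t0, t1 in template]
    blocks.sort()
    return blocks


def write_sam(
    records: Sequence[AlignmentRecord],
    chrom_lengths: dict[str, int],
    path,
) -> None:
    """Serialize records as a coordinate-sorted SAM file with proper header."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_lengths.items())],
    }
    tid = {c: i for i, (c, _) in enumerate(sorted(chrom_lengths.items()))}
    ordered = sorted(records, key=lambda r: (tid[r.chrom], r.start, r.query_id))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in ordered:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.query_id
            seg.reference_id = tid[rec.chrom]
            seg.reference_start = rec.start
            seg.mapping_quality = 60
            cigar = []
            prev_end = None
            for a, b in rec.blocks:
                if prev_end is not None and a > prev_end:
                    cigar.append((3, a - prev_end))  # N: spliced gap
                cigar.append((0, b - a))  # M
                prev_end = b
            seg.cigartuples = cigar
            flag = 16 if rec.is_reverse else 0
            if rec.mate_role != "unpaired":
                flag |= 1 | 2  # paired, proper pair
                flag |= 64 if rec.mate_role == "first" else 128
                flag |= 0 if rec.is_reverse else 32  # mate on opposite strand
                seg.next_reference_id = tid[rec.chrom]
                seg.next_reference_start = 0
            seg.flag |= flag
            out.write(seg)


# ---------------------------------------------------------------------------
# Count tables from the closed form
# ---------------------------------------------------------------------------

def simulate_count_table(
    config: SimConfig,
    truths: dict[tuple[str, str], GroundTruth],
    rng: np.random.Generator,
) -> CountTable:
    """Per-gene counts: Poisson around closed-form expected exonic mass.

    Expected counts are the gene's expected exonic RNA mass scaled so a
    median gene in the first genotype receives ``count_depth`` counts;
    per-replicate library factors are mildly lognormal to exercise
    size-factor normalization. (Count tabulation from reads is the job of
    external counting tools; the generative shortcut samples directly from
    the model's expectation.)
    """
    ref = config.genotypes[0].label
    ref_mass = np.array([truths[(g.gene_id, ref)].exonic_mass for g in config.genes])
    scale = config.count_depth / max(np.median(ref_mass), 1e-12)
    data = {}
    conditions = {}
    for gt in config.genotypes:
        mass = np.array(
            [truths[(g.gene_id, gt.label)].exonic_mass for g in config.genes]
        )
        for j in range(config.n_replicates):
            lib = float(np.exp(rng.normal(0.0, 0.1)))
            sample = f"{gt.label}_rep{j + 1}"
            data[sample] = rng.poisson(np.maximum(mass * scale * lib, 0.0))
            conditions[sample] = gt.label
    df = pd.DataFrame(data, index=[g.gene_id for g in config.genes])
    df.index.name = "gene_id"
    return CountTable(df, conditions)


# ---------------------------------------------------------------------------
# One-call experiment bundle
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    config: SimConfig
    gene_models: list[GeneModel]
    truths: dict[tuple[str, str], GroundTruth]
    counts: CountTable
    alignments: dict[str, list[AlignmentRecord]]  # per genotype
    chrom_lengths: dict[str, int]


def simulate_experiment(config: SimConfig) -> SimBundle:
    """Run the full generative process: annotation, reads, counts, truth.

    Deterministic given ``config.seed``; all randomness flows from one seed
    sequence, split per (genotype, gene) so gene sets can be extended
    without perturbing unrelated streams.
    """
    truths = {
        (g.gene_id, gt.label): expected_profile(g, gt, config)
        for g in config.genes
        for gt in config.genotypes
    }
    root = np.random.SeedSequence(config.seed)
    counts_seed, reads_seed = root.spawn(2)
    counts = simulate_count_table(
        config, truths, np.random.default_rng(counts_seed)
    )

    cov_genes = (
        [g for g in config.genes if g.gene_id in set(config.coverage_genes)]
        if config.coverage_genes is not None
        else list(config.genes)
    )
    # reads allocated across genes in proportion to expected exonic mass
    alignments: dict[str, list[AlignmentRecord]] = {}
    gene_streams = reads_seed.spawn(len(config.genotypes))
    for gt, gt_seed in zip(config.genotypes, gene_streams):
        rngs = [np.random.default_rng(s) for s in gt_seed.spawn(len(cov_genes))]
        mass = np.array(
            [truths[(g.gene_id, gt.label)].exonic_mass for g in cov_genes]
        )
        alloc = np.maximum(
            np.round(config.n_reads * mass / mass.sum()).astype(int), 1
        )
        recs: list[AlignmentRecord] = []
        for g, rng, k in zip(cov_genes, rngs, alloc):
            pop = simulate_cells(config, g, gt, rng)
            recs.extend(emit_alignments(pop, g, config, rng, n_reads=int(k)))
        alignments[gt.label] = recs

    chrom_lengths: dict[str, int] = {}
    for g in config.genes:
        end = g.offset + g.span + 1000
        chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), end)

    return SimBundle(
        config=config,
        gene_models=[g.to_gene_model() for g in config.genes],
        truths=truths,
        counts=counts,
        alignments=alignments,
        chrom_lengths=chrom_lengths,
    )


def write_bundle(bundle: SimBundle, outdir) -> dict[str, str]:
    """Serialize a bundle: GTF, per-genotype SAM, counts TSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    gtf = outdir / "genes.gtf"
    write_gtf(bundle.gene_models, gtf)
    paths["annotation"] = str(gtf)

    for label, recs in bundle.alignments.items():
        sam = outdir / f"{label}.sam"
        write_sam(recs, bundle.chrom_lengths, sam)
        paths[f"sam:{label}"] = str(sam)

    counts = outdir / "counts.tsv"
    bundle.counts.to_tsv(counts)
    paths["counts"] = str(counts)

    truth = outdir / "ground_truth.json"
    with open(truth, "w") as fh:
        json.dump(
            {
                f"{gid}|{label}": t.to_jsonable()
                for (gid, label), t in sorted(bundle.truths.items())
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    paths["ground_truth"] = str(truth)

    cfg = outdir / "config.json"
    with open(cfg, "w") as fh:
        json.dump(_config_jsonable(bundle.config), fh, indent=1, sort_keys=True)
    paths["config"] = str(cfg)
    return paths


def _config_jsonable(config: SimConfig) -> dict:
    d = asdict(config)
    return d


# ---------------------------------------------------------------------------
# Study-condition gene sets and default configuration
# ---------------------------------------------------------------------------

def make_average_gene(gene_id: str, rng: np.random.Generator, **kw) -> SimGeneSpec:
    """Typical gene: a few modest exons, all introns < 100 bp."""
    n_exons = int(rng.integers(3, 8))
    exons = rng.integers(150, 600, n_exons).tolist()
    introns = rng.integers(40, 90, n_exons - 1).tolist()
    return SimGeneSpec(
        gene_id, [int(v) for v in exons], [int(v) for v in introns],
        [False] * (n_exons - 1), **kw
    )


def make_large_gene(gene_id: str, rng: np.random.Generator, **kw) -> SimGeneSpec:
    """Gene whose max intron sits in the 50-100 kb bin (not gigantic)."""
    n_exons = int(rng.integers(4, 9))
    exons = rng.integers(150, 600, n_exons).tolist()
    introns = rng.integers(1_000, 10_000, n_exons - 1).tolist()
    introns[int(rng.integers(0, n_exons - 1))] = int(rng.integers(50_000, 95_000))
    return SimGeneSpec(
        gene_id, [int(v) for v in exons], [int(v) for v in introns],
        [False] * (n_exons - 1), **kw
    )


def make_gigantic_gene(gene_id: str, rng: np.random.Generator, **kw) -> SimGeneSpec:
    """Y-linked-style gigantic gene: 16 short exons, Mb-scale introns.

    A short first exon followed by fifteen ~917 bp exons (~14 kb exonic in
    total) over a ~4.3 Mb span with three gigantic introns (after exons 1,
    5 and 10): intron proportion above 0.99, most exonic mass downstream of
    the first gigantic intron.
    """
    exons = [250] + [917] * 15
    introns = [int(v) for v in rng.integers(20_000, 60_000, 15)]
    gigantic = [False] * 15
    for idx, size in zip((0, 4, 9), (1_500_000, 1_400_000, 1_200_000)):
        introns[idx] = size
        gigantic[idx] = True
    return SimGeneSpec(gene_id, exons, introns, gigantic, **kw)


def paper_like_config(
    seed: int = 0,
    n_gigantic: int = 5,
    n_average: int = 200,
    n_large: int = 20,
    d_control: float = 0.55,
    d_mutant: float = 0.9,
    s_control: float = 0.95,
    s_mutant: float = 0.2,
    **overrides,
) -> SimConfig:
    """Default study conditions: a testis-like gene population and two genotypes.

    Five gigantic genes among 200 average and 20 large genes; the control
    genotype splices efficiently (s = 0.95) with moderate per-gigantic-intron
    drop-off (d = 0.55), the splicing-factor-knockdown genotype splices
    poorly (s = 0.2) with strongly exacerbated drop-off (d = 0.9). The
    elongation rate is set so transcribing the largest gene takes ~90% of
    the SC lifespan, which makes the developmental-timing factor (T - tau)^2
    damp downstream-exon signal in both genotypes; under that damping the
    closed-form expected gigantic-gene depletion is ~ -1.5 log2 units.
    """
    rng = np.random.default_rng(seed)
    genes: list[SimGeneSpec] = []
    offset = 0

    def place(spec_fn, gene_id):
        nonlocal offset
        strand = "-" if rng.random() < 0.33 else "+"
        spec = spec_fn(gene_id, rng, strand=strand, chrom="chrSim", offset=offset)
        offset += spec.span + 10_000
        genes.append(spec)

    for i in range(n_gigantic):
        place(make_gigantic_gene, f"gigantic_{i + 1}")
    for i in range(n_large):
        place(make_large_gene, f"large_{i + 1}")
    for i in range(n_average):
        place(make_average_gene, f"average_{i + 1}")

    genotypes = [
        GenotypeParams("control", drop_prob=d_control, splice_prob=s_control),
        GenotypeParams("mutant", drop_prob=d_mutant, splice_prob=s_mutant),
    ]
    max_span = max((g.span for g in genes), default=1)
    T = overrides.pop("max_age", DEFAULT_MAX_AGE_H)
    v = overrides.pop("elongation_rate", max_span / (0.9 * T))
    cov = overrides.pop(
        "coverage_genes", [g.gene_id for g in genes if g.gene_id.startswith("gigantic")]
    )
    return SimConfig(
        genes=genes,
        genotypes=genotypes,
        elongation_rate=v,
        max_age=T,
        seed=seed,
        coverage_genes=cov,
        **overrides,
    )


def sim_bin_spec(config: SimConfig):
    """BinSpec whose gigantic-gene list matches the simulated gene ids."""
    from .gene_models import BinSpec

    gig = [
        g.gene_id for g in config.genes if any(g.gigantic_flags)
    ]
    return BinSpec(gigantic_ids=frozenset(gig))
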