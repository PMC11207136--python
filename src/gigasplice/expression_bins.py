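"""Intron-size-binned differential expression and splicing-burden regression.

Gene-level counts are normalized with median-of-ratios size factors, log2
fold changes (with pseudocount) are computed per gene, and the distribution
of log2FC in each intron-size bin is compared with the reference ("average")
bin by a Mann-Whitney U test. A second analysis bins genes by intron
proportion and regresses the per-bin aberrantly-spliced fraction on the bin
midpoint (ordinary least squares, two-sided slope t-test).

Formal DE inference (dispersion estimation, Wald tests) is intentionally
absent: the binned analysis needs only fold-change point estimates, and
external DE tables can be supplied instead of the internal estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_models import BinSpec, IntronMetrics, UNBINNED_LABEL, assign_bin

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5
EXACT_MW_MAX_N = 8


class ExpressionError(ValueError):
    pass


@dataclass
class CountTable:
    """Genes x samples integer counts with sample -> condition labels."""

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ExpressionError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ExpressionError(f"samples without condition label: {missing}")

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.counts.columns if self.conditions[s] == condition]
        if not out:
            raise ExpressionError(f"no samples with condition {condition!r}")
        return out

    @classmethod
    def from_tsv(cls, path, conditions: Mapping[str, str]) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, dict(conditions))

    def to_tsv(self, handle_or_path) -> None:
        self.counts.to_csv(handle_or_path, sep="\t")


@dataclass
class DEResult:
    gene_id: str
    log2fc: float
    mean_norm_count: float


@dataclass
class BinTestResult:
    bin_label: str
    n_genes: int
    median_log2fc: float
    U: float
    p: float


@dataclass
class SplicingBurdenFit:
    """Per-bin aberrant fraction regressed on intron-proportion bin midpoint."""

    proportions: np.ndarray
    midpoints: np.ndarray
    n_per_bin: np.ndarray
    slope: float
    intercept: float
    p: float


# ---------------------------------------------------------------------------
# Normalization and fold changes
# ---------------------------------------------------------------------------

def size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each gene nonzero in all samples, the ratio of its count to its
    geometric mean across samples; a sample's factor is the median of those
    ratios. Scale-equivariant: scaling one sample's counts by k scales its
    factor by k.
    """
    counts = table.counts.astype(float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ExpressionError(
            "no gene has nonzero counts in every sample; "
            "consider a pseudocount before normalization"
        )
    sub = counts.loc[nonzero]
    log_geo = np.log(sub).mean(axis=1)
    factors = np.exp(np.log(sub).sub(log_geo, axis=0).median(axis=0))
    return factors


def log2_fold_change(
    table: CountTable,
    condition: str,
    control: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DEResult]:
    """Per-gene log2((mean norm condition + pc)/(mean norm control + pc)).

    Antisymmetric under swapping condition and control. ``mean_norm_count``
    is the mean of size-factor-normalized counts over all samples of the two
    conditions.
    """
    cond_samples = table.samples_of(condition)
    ctrl_samples = table.samples_of(control)
    factors = size_factors(table)
    norm = table.counts.astype(float) / factors
    mean_cond = norm[cond_samples].mean(axis=1)
    mean_ctrl = norm[ctrl_samples].mean(axis=1)
    log2fc = np.log2((mean_cond + pseudocount) / (mean_ctrl + pseudocount))
    mean_all = norm[cond_samples + ctrl_samples].mean(axis=1)
    return [
        DEResult(gene_id=g, log2fc=float(log2fc[g]), mean_norm_count=float(mean_all[g]))
        for g in table.counts.index
    ]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Mann-Whitney U (pair-counting convention) and two-sided p.

    U = #{(i,j): x_i > y_j} + 0.5 * #{x_i = y_j}. The p-value is exact
    (complete enumeration of rank assignments) when min(n1, n2) <= 8 and the
    pooled sample has no ties, otherwise a normal approximation with tie and
    continuity corrections is used. Tied exact-mode requests fall back to the
    approximation (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ExpressionError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ExpressionError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if min(len(x), len(y)) <= EXACT_MW_MAX_N else "normal"
    if mode == "exact" and has_ties:
        logger.info("ties present: falling back to normal approximation")
        mode = "normal"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Binned comparisons
# ---------------------------------------------------------------------------

def bin_comparison(
    de: Sequence[DEResult],
    metrics: Sequence[IntronMetrics],
    spec: BinSpec | None = None,
    reference: str = "average",
    aberrant_flags: Mapping[str, bool] | None = None,
) -> list[BinTestResult]:
    """Per-bin log2FC medians and Mann-Whitney tests against the reference bin.

    When ``aberrant_flags`` is given, the analysis is restricted to
    aberrantly-spliced genes (the flagged-genes variant of the binned
    comparison). The reference bin's own row carries U = n^2/2-style
    self-comparison and p = 1.
    """
    spec = spec or BinSpec()
    label_of = {m.gene_id: (m.bin_label or assign_bin(m, spec)) for m in metrics}
    fc_of = {r.gene_id: r.log2fc for r in de}
    genes = [g for g in fc_of if g in label_of]
    if aberrant_flags is not None:
        genes = [g for g in genes if aberrant_flags.get(g, False)]

    by_bin: dict[str, list[float]] = {}
    for g in genes:
        by_bin.setdefault(label_of[g], []).append(fc_of[g])

    labels = [lbl for lbl, _, _ in spec.intervals]
    if spec.gigantic_label not in labels:
        labels.append(spec.gigantic_label)
    if UNBINNED_LABEL in by_bin:
        labels.append(UNBINNED_LABEL)

    ref_values = by_bin.get(reference, [])
    if not ref_values:
        raise ExpressionError(f"reference bin {reference!r} is empty")

    results = []
    for label in labels:
        values = by_bin.get(label, [])
        if not values:
            results.append(
                BinTestResult(label, 0, float("nan"), float("nan"), float("nan"))
            )
            continue
        if label == reference:
            U, p = len(values) ** 2 / 2, 1.0
        else:
            U, p = mann_whitney_u(values, ref_values)
        results.append(
            BinTestResult(
                bin_label=label,
                n_genes=len(values),
                median_log2fc=float(np.median(values)),
                U=U,
                p=p,
            )
        )
    return results


def splicing_burden_regression(
    flags: Mapping[str, bool],
    metrics: Sequence[IntronMetrics],
    n_bins: int = 10,
) -> SplicingBurdenFit:
    """Aberrant fraction per intron-proportion bin, regressed on bin midpoint.

    Genes are binned by intron proportion into ``n_bins`` equal-width bins on
    [0, 1]; each non-empty bin contributes its aberrantly-spliced fraction at
    the bin midpoint; ordinary least squares with a two-sided t-test on the
    slope quantifies the burden/intron-proportion association.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    tot = np.zeros(n_bins, dtype=int)
    hit = np.zeros(n_bins, dtype=int)
    for m in metrics:
        if m.gene_id not in flags:
            continue
        b = min(int(np.searchsorted(edges, m.intron_proportion, side="right")) - 1,
                n_bins - 1)
        tot[b] += 1
        if flags[m.gene_id]:
            hit[b] += 1
    keep = tot > 0
    if keep.sum() < 3:
        raise ExpressionError("need >= 3 non-empty intron-proportion bins")
    mids = ((edges[:-1] + edges[1:]) / 2)[keep]
    props = hit[keep] / tot[keep]
    fit = stats.linregress(mids, props)
    return SplicingBurdenFit(
        proportions=props,
        midpoints=mids,
        n_per_bin=tot[keep],
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p=float(fit.pvalue),
    )


# ---------------------------------------------------------------------------
# I/O and plotting
# ---------------------------------------------------------------------------

def write_de_tsv(de: Sequence[DEResult], handle_or_path) -> None:
    own = not hasattr(handle_or_path, "write")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write("gene_id\tlog2fc\tmean_norm_count\n")
        for r in de:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.mean_norm_count:.6g}\n")
    finally:
        if own:
            fh.close()


def write_bin_tests_tsv(results: Sequence[BinTestResult], handle_or_path) -> None:
    own = not hasattr(handle_or_path, "write")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write("bin_label\tn_genes\tmedian_log2fc\tU\tp\n")
        for r in results:
            fh.write(
                f"{r.bin_label}\t{r.n_genes}\t{r.median_log2fc:.6g}\t"
                f"{r.U:.6g}\t{r.p:.6g}\n"
            )
    finally:
        if own:
            fh.close()


def plot_bins(
    de: Sequence[DEResult],
    metrics: Sequence[IntronMetrics],
    spec: BinSpec,
    path,
    title: str = "",
) -> None:
    """Per-bin log2FC distributions (binned-expression panel style)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    label_of = {m.gene_id: m.bin_label for m in metrics}
    fc_of = {r.gene_id: r.log2fc for r in de}
    labels = [lbl for lbl, _, _ in spec.intervals] + [spec.gigantic_label]
    data = [
        [fc_of[g] for g in fc_of if label_of.get(g) == lbl] for lbl in labels
    ]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.boxplot([d if d else [math.nan] for d in data], tick_labels=labels)
    ax.axhline(0.0, ls="--", lw=0.8, color="gray")
    ax.set_ylabel("log2 fold change")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
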