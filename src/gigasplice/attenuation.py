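"""Transcription-attenuation statistics from mutant/control coverage profiles.

The attenuation signature of a splicing-perturbed gigantic gene has two
faces: a negative slope of the mutant/control coverage ratio along the gene
span, and an exacerbated read-depth drop across each gigantic intron. Both
are quantified here: per-base ratio profiles (control-zero positions masked),
degree-1 least-squares fits on the span normalized to [0, 1] with a
position-block bootstrap CI, and flanking-exon fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coverage import CoverageProfile, exon_mean


class AttenuationError(ValueError):
    pass


@dataclass
class RatioProfile:
    """Mutant/control normalized depth at positions where control > 0."""

    gene_id: str
    positions: np.ndarray
    ratios: np.ndarray
    masked_fraction: float
    span_length: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise AttenuationError("positions must be strictly increasing")
        if np.any(self.ratios < 0):
            raise AttenuationError("ratios must be non-negative")
        if not 0.0 <= self.masked_fraction <= 1.0:
            raise AttenuationError("masked_fraction out of [0,1]")

    @property
    def n_points(self) -> int:
        return len(self.positions)


@dataclass
class AttenuationFit:
    """Degree-1 fit of ratio against span position scaled to [0, 1].

    The slope is the fitted change in mutant/control ratio over the full
    gene span; negative means expression falls relative to the control
    toward the 3' end.
    """

    gene_id: str
    slope: float
    intercept: float
    n_points: int
    slope_ci: tuple[float, float]


@dataclass
class IntronDropStat:
    """Read-depth drop across one intron: flanking-exon mean ratio."""

    gene_id: str
    intron_index: int
    mean_before: float
    mean_after: float
    fold_change: float
    defined: bool


DEFAULT_RATIO_WINDOW = 200


def ratio_profile(
    mutant: CoverageProfile,
    control: CoverageProfile,
    window: int = DEFAULT_RATIO_WINDOW,
) -> RatioProfile:
    """Windowed mutant/control depth ratio; control-zero windows masked.

    The span is tiled with contiguous ``window``-bp windows and the ratio of
    window sums is taken (``window=1`` recovers a per-base ratio). The
    windowed ratio-of-sums is used by default because the per-base ratio of
    counts is biased upward by ~1/depth — and since depth falls toward the
    3' end, that bias grows along the span and tilts downstream regression
    slopes; summing windows makes it negligible. Windows whose control sum
    is zero are masked rather than pseudocounted, and the masked fraction of
    the span is reported. Positions are window centers.

    Both profiles must be library-size normalized and on the same isoform
    projection.
    """
    if not (mutant.normalized and control.normalized):
        raise AttenuationError("both profiles must be normalized")
    if mutant.gene_id != control.gene_id:
        raise AttenuationError("profiles are for different genes")
    if mutant.isoform_id != control.isoform_id or mutant.length != control.length:
        raise AttenuationError("profiles use different projections")
    if window < 1:
        raise AttenuationError("window must be >= 1")
    L = mutant.length
    if window == 1:
        keep = control.values > 0
        positions = np.nonzero(keep)[0]
        ratios = mutant.values[keep] / control.values[keep]
        masked = 1.0 - keep.mean() if L else 0.0
    else:
        edges = np.arange(0, L + window, window)
        edges[-1] = min(edges[-1], L)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        csum_m = np.concatenate([[0.0], np.cumsum(mutant.values)])
        csum_c = np.concatenate([[0.0], np.cumsum(control.values)])
        wm = csum_m[edges[1:]] - csum_m[edges[:-1]]
        wc = csum_c[edges[1:]] - csum_c[edges[:-1]]
        keep = wc > 0
        centers = (edges[:-1] + edges[1:]) // 2
        positions = centers[keep]
        ratios = wm[keep] / wc[keep]
        widths = np.diff(edges)
        masked = float(widths[~keep].sum() / L) if L else 0.0
    return RatioProfile(
        gene_id=mutant.gene_id,
        positions=positions,
        ratios=ratios,
        masked_fraction=masked,
        span_length=L,
    )


def fit_attenuation(
    ratio: RatioProfile,
    span_length: int | None = None,
    n_blocks: int = 50,
    n_boot: int = 400,
    rng: np.random.Generator | None = None,
) -> AttenuationFit:
    """Degree-1 least squares of ratio on position/L, with bootstrap CI.

    The 95% CI resamples contiguous position blocks (default 50) because
    neighboring per-base ratios are strongly dependent under read-length
    autocorrelation; single-position resampling would understate uncertainty.
    """
    if ratio.n_points < 2:
        raise AttenuationError("need >= 2 retained positions for a fit")
    L = span_length if span_length is not None else ratio.span_length
    x = ratio.positions / L
    y = ratio.ratios
    slope, intercept = np.polyfit(x, y, 1)

    rng = rng if rng is not None else np.random.default_rng(0)
    n_blocks = max(2, min(n_blocks, ratio.n_points))
    edges = np.linspace(0, ratio.n_points, n_blocks + 1).astype(int)
    blocks = [
        (edges[i], edges[i + 1])
        for i in range(n_blocks)
        if edges[i + 1] > edges[i]
    ]
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, len(blocks), len(blocks))
        idx = np.concatenate([np.arange(*blocks[i]) for i in pick])
        if len(np.unique(x[idx])) < 2:
            slopes[b] = slope
            continue
        slopes[b] = np.polyfit(x[idx], y[idx], 1)[0]
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    ci = (min(float(lo), float(slope)), max(float(hi), float(slope)))
    return AttenuationFit(
        gene_id=ratio.gene_id,
        slope=float(slope),
        intercept=float(intercept),
        n_points=ratio.n_points,
        slope_ci=ci,
    )


def intron_drop(profile: CoverageProfile, intron_index: int) -> IntronDropStat:
    """Fold change of mean depth between the exons flanking one intron.

    ``mean_before`` is the exon immediately 5' of intron ``intron_index``
    (exon indices in the 5'->3' exon-span order), ``mean_after`` the exon
    immediately 3'. A zero mean_after flags the statistic undefined rather
    than propagating infinity.
    """
    if not profile.normalized:
        raise AttenuationError("profile must be normalized")
    if not 0 <= intron_index < profile.n_exons - 1:
        raise AttenuationError(
            f"intron index {intron_index} out of range for {profile.n_exons} exons"
        )
    before = exon_mean(profile, intron_index)
    after = exon_mean(profile, intron_index + 1)
    defined = after > 0
    return IntronDropStat(
        gene_id=profile.gene_id,
        intron_index=intron_index,
        mean_before=before,
        mean_after=after,
        fold_change=before / after if defined else float("nan"),
        defined=defined,
    )


def exacerbation(mutant_stat: IntronDropStat, control_stat: IntronDropStat) -> float:
    """Mutant drop fold change over control's; > 1 means an exacerbated drop."""
    if not (mutant_stat.defined and control_stat.defined):
        raise AttenuationError("both drop statistics must be defined")
    if (
        mutant_stat.gene_id != control_stat.gene_id
        or mutant_stat.intron_index != control_stat.intron_index
    ):
        raise AttenuationError("statistics are for different genes or introns")
    if control_stat.fold_change == 0:
        raise AttenuationError("control fold change is zero")
    return mutant_stat.fold_change / control_stat.fold_change


def write_attenuation_tsv(
    rows: Sequence[dict], handle_or_path
) -> None:
    """TSV of per-(gene, mutant, control) fits and drop statistics."""
    cols = [
        "gene_id", "mutant", "control", "slope", "intercept",
        "slope_ci_low", "slope_ci_high", "n_points", "masked_fraction",
        "intron_index", "fold_change_mutant", "fold_change_control",
        "exacerbation",
    ]
    own = not hasattr(handle_or_path, "write")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write(
                "\t".join(_fmt(row.get(c)) for c in cols) + "\n"
            )
    finally:
        if own:
            fh.close()


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def plot_ratio_fit(ratio: RatioProfile, fit: AttenuationFit, path) -> None:
    """Ratio profile with its linear best fit (coverage-ratio panel style)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = ratio.positions / ratio.span_length
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(x, ratio.ratios, ".", ms=1, alpha=0.3, color="gray")
    ax.plot(
        [0, 1],
        [fit.intercept, fit.intercept + fit.slope],
        color="crimson",
        label=f"slope {fit.slope:.3f}",
    )
    ax.axhline(1.0, ls="--", lw=0.8, color="black")
    ax.set_xlabel("gene span (exons only, normalized)")
    ax.set_ylabel("mutant / control coverage")
    ax.set_title(ratio.gene_id)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
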