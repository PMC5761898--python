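"""Subsampling of virtual cores: how many biopsies approximate a slide/block?

Each slide's set of retained cores plays the role of a finite parent
population with known mean and SD (the "slide reference").  Drawing k cores
without replacement (k = 1..5) and summarising by mean or max yields an
estimate of the slide's CD8 staining; three views of its quality are
computed:

* the within-1-SD rate — how often |estimate − core mean| ≤ core SD;
* out-of-bag differences — summary(selected) − summary(unselected cores),
  whose mean is 0 for the mean summary by finite-population symmetry and
  whose SD measures sampling variability without reusing the same cores on
  both sides;
* ROC-style accuracy/sensitivity/specificity of the dichotomised estimate
  against the unit's core-mean "truth" across candidate cut-offs
  (1/2/5/10% by default).

Blocks are handled by pooling retained cores over a block's slides
(unweighted, or cell-count-weighted behind a flag) and treating the pooled
set the same way.  A loess smoother (tricube-weighted local quadratic)
summarises how out-of-bag variability scales with a unit's mean staining.

Mirroring the published restriction, subsampling can be limited to units
with at least 15 retained cores so that drawing up to 5 leaves a
substantial out-of-bag set; an unrestricted mode exists for exhaustive
small-case checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CUTOFFS = (1.0, 2.0, 5.0, 10.0)
MIN_CORES_RESTRICTED = 15


@dataclass(frozen=True)
class SlideReference:
    """A unit's parent statistics over its retained cores."""

    slide_id: str
    core_mean: float
    core_sd: float  # nan when n_cores < 2 (n-1 denominator)
    n_cores: int


@dataclass(frozen=True)
class SubsampleSummary:
    slide_id: str
    k: int
    summary_stat: str
    n_reps: int
    estimates: np.ndarray = field(repr=False)
    within_1sd_rate: float
    oob_diffs: np.ndarray = field(repr=False)

    @property
    def oob_diff_mean(self) -> float:
        return float(self.oob_diffs.mean())

    @property
    def oob_diff_sd(self) -> float:
        return float(self.oob_diffs.std(ddof=1))


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    k: int
    summary_stat: str
    truth_level: str  # slide | block
    sensitivity: float  # percent, nan when no positive unit exists
    specificity: float  # percent, nan when no negative unit exists
    accuracy: float  # percent
    n_units: int
    n_positive_units: int


def slide_reference(core_percents, slide_id: str = "") -> SlideReference:
    """Mean and sample SD (n−1) of a unit's core percents."""
    v = np.asarray(core_percents, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one core")
    sd = float(v.std(ddof=1)) if v.size >= 2 else math.nan
    return SlideReference(
        slide_id=slide_id, core_mean=float(v.mean()), core_sd=sd, n_cores=v.size
    )


def _draw_indices(rng, n_reps: int, n: int, k: int) -> np.ndarray:
    """(n_reps, n) matrix whose first k columns are distinct draws."""
    return np.argsort(rng.random((n_reps, n)), axis=1)


def _summaries(values: np.ndarray, order: np.ndarray, k: int, stat: str):
    """Per-rep (selected, out-of-bag) summaries from a permutation matrix."""
    drawn = values[order[:, :k]]
    oob = values[order[:, k:]]
    if oob.shape[1] == 0:  # exhaustive draw: no out-of-bag sample
        oob_summary = np.full(order.shape[0], np.nan)
    if stat == "mean":
        return drawn.mean(axis=1), (
            oob.mean(axis=1) if oob.shape[1] else oob_summary
        )
    if stat == "max":
        return drawn.max(axis=1), (
            oob.max(axis=1) if oob.shape[1] else oob_summary
        )
    raise ValueError(f"unknown summary_stat {stat!r}")


def subsample_cores(
    core_percents,
    k: int,
    summary_stat: str = "mean",
    n_reps: int = 1000,
    seed: int = 0,
    min_cores: int = MIN_CORES_RESTRICTED,
    restricted: bool = True,
    slide_id: str = "",
) -> SubsampleSummary:
    """Draw k distinct cores per replicate and summarise the estimates.

    In restricted mode the unit must have at least ``max(k + 1, min_cores)``
    cores; unrestricted mode only requires a nonempty out-of-bag set
    (k < n_cores).
    """
    v = np.asarray(core_percents, dtype=float)
    n = v.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if k >= n:
        raise ValueError(f"k = {k} leaves an empty out-of-bag set (n = {n})")
    if restricted and n < max(k + 1, min_cores):
        raise ValueError(
            f"restricted mode needs >= {max(k + 1, min_cores)} cores, got {n}"
        )

    ref = slide_reference(v, slide_id)
    rng = np.random.default_rng(seed)
    order = _draw_indices(rng, n_reps, n, k)
    est, oob = _summaries(v, order, k, summary_stat)
    within = np.abs(est - ref.core_mean) <= ref.core_sd
    return SubsampleSummary(
        slide_id=slide_id,
        k=k,
        summary_stat=summary_stat,
        n_reps=n_reps,
        estimates=est,
        within_1sd_rate=float(within.mean()),
        oob_diffs=est - oob,
    )


def block_pool(
    slides: list, weights: str = "unweighted"
) -> tuple[np.ndarray, SlideReference]:
    """Pool retained-core percents of a block's slides into one unit.

    ``slides`` is a list of per-slide core-percent sequences.  Pooling is
    unweighted (each core counts once); ``weights='cells'`` expects
    (percents, n_cells) pairs and weights the block mean by cell counts
    while the pooled core list stays flat.
    """
    if weights == "unweighted":
        pooled = np.concatenate([np.asarray(s, float) for s in slides if len(s)])
        if pooled.size == 0:
            raise ValueError("empty block")
        return pooled, slide_reference(pooled, "block")
    if weights == "cells":
        percents = np.concatenate([np.asarray(p, float) for p, _ in slides])
        counts = np.concatenate([np.asarray(c, float) for _, c in slides])
        if percents.size == 0:
            raise ValueError("empty block")
        mean = float(np.average(percents, weights=counts))
        sd = float(percents.std(ddof=1)) if percents.size >= 2 else math.nan
        return percents, SlideReference("block", mean, sd, percents.size)
    raise ValueError("weights must be 'unweighted' or 'cells'")


def roc_over_cutoffs(
    units: dict[str, np.ndarray],
    ks=(1, 2, 3, 4, 5),
    summary_stats=("mean", "max"),
    cutoffs=DEFAULT_CUTOFFS,
    truth_level: str = "slide",
    n_reps: int = 1000,
    seed: int = 0,
    min_cores: int = MIN_CORES_RESTRICTED,
    restricted: bool = True,
) -> list[RocPoint]:
    """Classification performance of core subsamples against unit truths.

    ``units`` maps unit id -> retained core percents.  Truth per unit is
    its core mean; truth class at a cutoff uses the >= rule.  Sensitivity,
    specificity and accuracy are computed per replicate across units and
    averaged over replicates; a cutoff with no positive (negative) units
    yields nan sensitivity (specificity) rather than a zero fill.
    """
    if not units:
        raise ValueError("empty unit list")
    rng = np.random.default_rng(seed)
    out: list[RocPoint] = []
    max_k = max(ks)
    if restricted:
        eligible = {
            uid: np.asarray(v, float)
            for uid, v in units.items()
            if len(v) >= max(max_k + 1, min_cores)
        }
    else:
        eligible = {uid: np.asarray(v, float) for uid, v in units.items()}
    if not eligible:
        raise ValueError("no unit satisfies the core-count restriction")

    truths = np.array([v.mean() for v in eligible.values()])
    # one permutation matrix per unit and k reused across cutoffs/stats
    estimates: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for uid, v in eligible.items():
        order = _draw_indices(rng, n_reps, v.size, 0)
        for k in ks:
            # k == n_cores is legal here (the estimate is exhaustive and
            # equals the truth for the mean summary); only k > n is not.
            if k > v.size:
                raise ValueError(
                    f"unit {uid!r} has {v.size} cores, cannot draw k = {k}"
                )
            est_by_stat = {}
            for stat in summary_stats:
                est, _ = _summaries(v, order, k, stat)
                est_by_stat[stat] = est
            estimates[(uid, k)] = est_by_stat

    uids = list(eligible)
    for k in ks:
        for stat in summary_stats:
            est_matrix = np.column_stack(
                [estimates[(uid, k)][stat] for uid in uids]
            )  # (n_reps, n_units)
            for cutoff in cutoffs:
                truth_pos = truths >= cutoff
                called_pos = est_matrix >= cutoff
                n_pos = int(truth_pos.sum())
                n_neg = truth_pos.size - n_pos
                tp = (called_pos & truth_pos).sum(axis=1)
                tn = (~called_pos & ~truth_pos).sum(axis=1)
                sens = float((tp / n_pos).mean() * 100.0) if n_pos else math.nan
                spec = float((tn / n_neg).mean() * 100.0) if n_neg else math.nan
                acc = float(((tp + tn) / truth_pos.size).mean() * 100.0)
                out.append(
                    RocPoint(
                        cutoff=cutoff,
                        k=k,
                        summary_stat=stat,
                        truth_level=truth_level,
                        sensitivity=sens,
                        specificity=spec,
                        accuracy=acc,
                        n_units=truth_pos.size,
                        n_positive_units=n_pos,
                    )
                )
    return out


def roc_to_frame(points: list[RocPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])


# ---------------------------------------------------------------------------
# Loess: tricube-weighted local quadratic regression
# ---------------------------------------------------------------------------


def loess_fit(
    x,
    y,
    span: float = 0.75,
    degree: int = 2,
    grid: np.ndarray | None = None,
    n_grid: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Local polynomial regression with tricube weights.

    At each grid point the nearest ``ceil(span * n)`` observations are
    weighted by ``(1 - (d / d_max)^3)^3`` and a degree-``degree`` polynomial
    is fitted by weighted least squares on the centred predictor.  Exactly
    reproduces any polynomial of degree <= ``degree``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (0.0 < span <= 1.0):
        raise ValueError("span must lie in (0, 1]")
    n_min = max(5, degree + 2)
    if np.unique(x).size < n_min:
        raise ValueError(f"need at least {n_min} distinct predictor values")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    q = max(int(math.ceil(span * x.size)), degree + 1)
    fitted = np.array([_loess_point(x, y, float(x0), q, degree) for x0 in grid])
    return np.asarray(grid, float), fitted


def _loess_point(x: np.ndarray, y: np.ndarray, x0: float, q: int, degree: int) -> float:
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:q]
    dmax = d[idx].max()
    if dmax == 0:  # all neighbours coincide with x0
        return float(y[idx].mean())
    w = (1.0 - np.clip(d[idx] / dmax, 0.0, 1.0) ** 3) ** 3
    if w.sum() == 0:
        w = np.ones_like(w)
    xc = x[idx] - x0  # centre for conditioning; intercept = fit at x0
    design = np.vander(xc, degree + 1, increasing=True)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
    return float(coef[0])


def loess_sd_curve(
    points,
    span: float = 0.75,
    scale: str = "raw",
    n_grid: int = 50,
) -> pd.DataFrame:
    """Smooth out-of-bag SD as a function of unit mean staining.

    ``points`` is a sequence of (core_mean, oob_diff_sd) pairs.  On the
    ``log2`` scale the predictor is ``log2(x + 0.1)``; the 0.1 offset keeps
    zero-percent units finite.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (core_mean, oob_diff_sd) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if scale == "log2":
        x = np.log2(x + 0.1)
    elif scale != "raw":
        raise ValueError("scale must be 'raw' or 'log2'")
    grid, fitted = loess_fit(x, y, span=span, degree=2, n_grid=n_grid)
    return pd.DataFrame({"grid": grid, "fitted_sd": fitted, "scale": scale})
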