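"""Agreement and comparison statistics.

* ``dalign`` — alignment dissimilarity: mean absolute TRT difference
  between two co-registered maps of the same eye,
  ``(1/M) * sum |a_ij - b_ij|`` over the M cells defined in both maps.
* ``fitting_rmse`` — root mean square difference between raw and fitted
  thickness values.
* ``relative_bias`` — percent change a model introduces in a parameter
  estimate; negative values are underestimation.
* ``icc_2_1`` — intraclass correlation, two-way, absolute agreement,
  single measurement (Shrout–Fleiss ICC(2,1)), with a percentile
  bootstrap confidence interval resampling subjects.
* ``compare_distributions`` — Kruskal–Wallis across groups plus pairwise
  Mann–Whitney U, with Shapiro–Wilk normality screening, flagged at
  alpha = 0.01.

Cells that are undefined (NaN) in either input are skipped pairwise and
the averages renormalized by the number of cells actually compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .preprocessing import RadialProfileSet, RegularGrid

ALPHA = 0.01
DEFAULT_N_BOOTSTRAP = 10_000


def _paired_values(a, b, what: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, RegularGrid) != isinstance(b, RegularGrid):
        raise ValueError(f"{what}: mixed input types")
    if isinstance(a, RegularGrid):
        if a.x_axis.size != b.x_axis.size or not (
            np.allclose(a.x_axis, b.x_axis) and np.allclose(a.y_axis, b.y_axis)
        ):
            raise ValueError(f"{what}: grids have different axes")
        va, vb = a.values_um, b.values_um
    elif isinstance(a, RadialProfileSet):
        va, vb = a.values_um, b.values_um
    else:
        va, vb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"{what}: shape mismatch {va.shape} vs {vb.shape}")
    mask = np.isfinite(va) & np.isfinite(vb)
    if not mask.any():
        raise ValueError(f"{what}: no cell is defined in both inputs")
    return va[mask], vb[mask]


def dalign(a: RegularGrid, b: RegularGrid) -> float:
    """Alignment dissimilarity in µm (mean absolute difference)."""
    va, vb = _paired_values(a, b, "dalign")
    return float(np.mean(np.abs(va - vb)))


def fitting_rmse(raw, fitted) -> float:
    """Root mean square difference in µm between raw and fitted maps."""
    va, vb = _paired_values(raw, fitted, "fitting_rmse")
    return float(np.sqrt(np.mean((va - vb) ** 2)))


def relative_bias(x_model: float, x_raw: float) -> float:
    """Relative difference in percent; negative means underestimation."""
    if x_raw == 0:
        raise ValueError("relative bias undefined for x_raw = 0")
    return 100.0 * (x_model - x_raw) / x_raw


def icc_2_1(pairs: np.ndarray) -> float:
    """ICC(2,1): two-way, absolute agreement, single measurement.

    Rows are subjects (eyes), columns the k repeated measurements
    (here k = 2: raster and star).  Mean-squares form::

        ICC = (MS_subj - MS_err) /
              (MS_subj + (k-1) MS_err + k (MS_meas - MS_err) / n)
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("pairs must be an n x k matrix with k >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("pairs must be finite")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ValueError("ICC undefined: zero total variance")
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    return float((ms_rows - ms_err) / denom)


def bootstrap_ci(
    pairs: np.ndarray,
    statistic: Callable[[np.ndarray], float] = icc_2_1,
    n_resamples: int = DEFAULT_N_BOOTSTRAP,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a subject-resampled statistic.

    Rows (subjects) are resampled with replacement, keeping each row's
    paired measurements intact.  Resamples on which the statistic is
    undefined are dropped; more than 50% undefined is an error.
    """
    x = np.asarray(pairs, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.shape[0]
    values = np.empty(n_resamples)
    bad = 0
    for i in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            values[i] = statistic(x[idx])
        except (ValueError, ZeroDivisionError, FloatingPointError):
            values[i] = np.nan
            bad += 1
    if bad > n_resamples / 2:
        raise ValueError(
            f"statistic undefined on {bad}/{n_resamples} bootstrap resamples"
        )
    good = values[np.isfinite(values)]
    tail = (1 - level) / 2 * 100
    lo, hi = np.percentile(good, [tail, 100 - tail])
    return float(lo), float(hi)


@dataclass
class DistributionComparison:
    """Rank-based group comparison report (alpha = 0.01)."""

    group_names: list[str]
    kruskal_h: float
    kruskal_p: float
    pairwise: list[dict] = field(default_factory=list)
    shapiro_p: dict[str, float] = field(default_factory=dict)
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.kruskal_p < self.alpha


def compare_distributions(
    groups: Sequence[np.ndarray],
    names: Sequence[str] | None = None,
    alpha: float = ALPHA,
) -> DistributionComparison:
    """Kruskal–Wallis across groups plus pairwise Mann–Whitney U tests.

    The Mann–Whitney test uses exact enumeration when both groups have at
    most 20 observations with no ties, and the tie-corrected normal
    approximation otherwise.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 3:
            raise ValueError(f"group {i} has fewer than 3 observations")
    if names is None:
        names = [f"group{i}" for i in range(len(groups))]
    names = list(names)

    h, p = stats.kruskal(*groups)
    shapiro = {
        nm: float(stats.shapiro(g).pvalue) for nm, g in zip(names, groups)
    }
    pairwise = []
    for (i, a), (j, b) in combinations(enumerate(groups), 2):
        pooled = np.concatenate([a, b])
        exact = a.size <= 20 and b.size <= 20 and np.unique(pooled).size == pooled.size
        method = "exact" if exact else "asymptotic"
        u, pu = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        pairwise.append(
            {
                "a": names[i],
                "b": names[j],
                "u": float(u),
                "p": float(pu),
                "significant": bool(pu < alpha),
            }
        )
    return DistributionComparison(
        group_names=names,
        kruskal_h=float(h),
        kruskal_p=float(p),
        pairwise=pairwise,
        shapiro_p=shapiro,
        alpha=alpha,
    )
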