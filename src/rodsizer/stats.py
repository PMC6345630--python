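"""Size-homeostasis statistics.

A homeostasis plot shows the increment of a size measure over one cell
cycle against the value of that measure at birth.  A perfect sizer gives
slope -1 (division size independent of birth size), an adder slope 0, and
a timer with linear growth and symmetric division slope 0.  To decide
WHICH geometric quantity is sensed, the regression lines of three strains
of different radius are compared on a common range with a normalized
root-mean-square deviation: the strains collapse (small RMSD) only in the
measure that is actually under control.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .simulate import CellCycleRecord

__all__ = [
    "BinnedSeries",
    "RegressionLine",
    "RMSDReport",
    "RmsdComparison",
    "homeostasis_points",
    "bin_series",
    "fit_line",
    "binned_line",
    "normalized_rmsd",
    "rmsd_difference_pvalue",
    "division_cv",
]


@dataclass(frozen=True)
class BinnedSeries:
    """Bin centres with mean, standard error and count of y per bin."""

    bin_centers: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.bin_centers[0]), float(self.bin_centers[-1])


@dataclass(frozen=True)
class RegressionLine:
    """Straight line with parameter uncertainties and their covariance."""

    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    covariance: np.ndarray  # 2x2, order (slope, intercept)
    x_range: tuple[float, float]

    def __call__(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, float) + self.intercept


@dataclass(frozen=True)
class RMSDReport:
    """Pairwise and normalized RMSD between three strain regression lines."""

    pairwise_rmsds: tuple[float, float, float]
    normalized_rmsd: float
    mean_y: float
    common_range: tuple[float, float]
    n_points: int = 20


def homeostasis_points(
    records: Sequence[CellCycleRecord],
    measure: str = "area",
    gamma: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(birth size, birth-to-division increment) in the chosen measure.

    ``measure`` is one of ``length``, ``area``, ``volume`` or ``general``;
    the general measure is ``R**gamma * L`` with the cell's own radius
    (gamma=0 reduces to length, gamma=1 to area up to the 2*pi factor).
    """
    if measure == "length":
        birth = np.array([r.L_birth for r in records])
        div = np.array([r.L_div for r in records])
    elif measure == "area":
        birth = np.array([r.A_birth for r in records])
        div = np.array([r.A_div for r in records])
    elif measure == "volume":
        birth = np.array([r.V_birth for r in records])
        div = np.array([r.V_div for r in records])
    elif measure == "general":
        if gamma is None:
            raise ValueError("general measure requires gamma")
        R = np.array([r.R for r in records])
        birth = R**gamma * np.array([r.L_birth for r in records])
        div = R**gamma * np.array([r.L_div for r in records])
    else:
        raise ValueError(f"unknown size measure: {measure!r}")
    return birth, div - birth


def bin_series(
    x,
    y,
    n_bins: int = 10,
    min_per_bin: int = 5,
) -> BinnedSeries:
    """Equal-width binning of y against x over the central 95% of x.

    Bins with fewer than ``min_per_bin`` points are merged into their
    right-hand neighbour (the last bin merges leftward), so reported bins
    always satisfy the minimum count.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo, hi = np.percentile(x, [2.5, 97.5])
    inside = (x >= lo) & (x <= hi)
    x, y = x[inside], y[inside]
    if x.size < 2 * min_per_bin:
        raise ValueError("not enough points to form two usable bins")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    groups: list[np.ndarray] = []
    pending: list[int] = []
    for b in range(n_bins):
        members = np.flatnonzero(idx == b)
        pending.extend(members.tolist())
        if len(pending) >= min_per_bin:
            groups.append(np.array(pending))
            pending = []
    if pending:
        if groups:
            groups[-1] = np.concatenate([groups[-1], np.array(pending)])
        elif len(pending) >= min_per_bin:
            groups.append(np.array(pending))
    if len(groups) < 2:
        raise ValueError("fewer than 2 usable bins after merging")
    centers = np.array([x[g].mean() for g in groups])
    means = np.array([y[g].mean() for g in groups])
    counts = np.array([g.size for g in groups])
    sds = np.array([y[g].std(ddof=1) if g.size > 1 else 0.0 for g in groups])
    return BinnedSeries(
        bin_centers=centers, means=means, sems=sds / np.sqrt(counts), counts=counts
    )


def fit_line(binned: BinnedSeries, weighted: bool = False) -> RegressionLine:
    """Ordinary (default) or SE-weighted least squares on the bin means."""
    import statsmodels.api as sm

    xb, yb = binned.bin_centers, binned.means
    if xb.size < 2:
        raise ValueError("need at least 2 bins to fit a line")
    X = sm.add_constant(xb)  # columns: (intercept, slope)
    if weighted:
        se = np.where(binned.sems > 0, binned.sems, binned.sems[binned.sems > 0].min())
        res = sm.WLS(yb, X, weights=1.0 / se**2).fit()
    else:
        res = sm.OLS(yb, X).fit()
    cov = np.asarray(res.cov_params())[::-1, ::-1]  # reorder to (slope, intercept)
    return RegressionLine(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_sd=float(res.bse[1]),
        intercept_sd=float(res.bse[0]),
        covariance=cov,
        x_range=binned.x_range,
    )


def binned_line(
    x, y, n_bins: int = 10, min_per_bin: int = 5, weighted: bool = False
) -> tuple[BinnedSeries, RegressionLine]:
    """Convenience: bin then fit."""
    b = bin_series(x, y, n_bins=n_bins, min_per_bin=min_per_bin)
    return b, fit_line(b, weighted=weighted)


def normalized_rmsd(
    lines: Sequence[RegressionLine],
    ranges: Sequence[tuple[float, float]] | None = None,
    n_points: int = 20,
) -> RMSDReport:
    """Normalized RMSD between three regression lines on their common range.

    The common range is the intersection of the three x-ranges, discretised
    with ``n_points`` equally spaced points x_i.  For each pair of lines
    ``RMSD = sqrt(mean_i (y(x_i) - y'(x_i))^2)``; the three pairwise RMSDs
    are summed and divided by the mean of all 3 x n_points line values.
    """
    if len(lines) != 3:
        raise ValueError("normalized RMSD is defined for exactly 3 strains")
    if ranges is None:
        ranges = [ln.x_range for ln in lines]
    lo = max(r[0] for r in ranges)
    hi = min(r[1] for r in ranges)
    if hi <= lo:
        raise ValueError(
            f"strain x-ranges do not overlap: common range [{lo:.4g}, {hi:.4g}]"
        )
    xi = np.linspace(lo, hi, n_points)
    ys = np.array([ln(xi) for ln in lines])
    pairwise = tuple(
        float(np.sqrt(np.mean((ys[i] - ys[j]) ** 2)))
        for i, j in combinations(range(3), 2)
    )
    mean_y = float(ys.mean())
    return RMSDReport(
        pairwise_rmsds=pairwise,
        normalized_rmsd=sum(pairwise) / mean_y,
        mean_y=mean_y,
        common_range=(lo, hi),
        n_points=n_points,
    )


@dataclass(frozen=True)
class RmsdComparison:
    """Monte-Carlo comparison of two normalized-RMSD statistics."""

    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_mc: int


def _sample_rmsds(
    lines: Sequence[RegressionLine],
    ranges,
    n_mc: int,
    rng: np.random.Generator,
    n_points: int,
) -> np.ndarray:
    draws = []
    for ln in lines:
        if not np.any(ln.covariance):
            raise ValueError("degenerate uncertainty: zero-variance regression")
        draws.append(
            rng.multivariate_normal(
                [ln.slope, ln.intercept], ln.covariance, size=n_mc
            )
        )
    if ranges is None:
        ranges = [ln.x_range for ln in lines]
    lo = max(r[0] for r in ranges)
    hi = min(r[1] for r in ranges)
    xi = np.linspace(lo, hi, n_points)
    # (strain, draw, point)
    ys = np.array([d[:, 0:1] * xi[None, :] + d[:, 1:2] for d in draws])
    total = np.zeros(n_mc)
    for i, j in combinations(range(3), 2):
        total += np.sqrt(np.mean((ys[i] - ys[j]) ** 2, axis=1))
    mean_y = ys.mean(axis=(0, 2))
    return total / mean_y


def rmsd_difference_pvalue(
    lines_a: Sequence[RegressionLine],
    lines_b: Sequence[RegressionLine],
    ranges_a=None,
    ranges_b=None,
    n_mc: int = 10_000,
    seed: int | None = None,
    n_points: int = 20,
) -> RmsdComparison:
    """p-value for two normalized RMSDs being different.

    Slope/intercept pairs are drawn per strain from a bivariate normal with
    the regression's estimated covariance; the normalized RMSD is
    recomputed per draw and the two resulting samples compared with a
    two-sample t-test.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for a stable comparison")
    same = len(lines_a) == len(lines_b) and all(
        (la.slope, la.intercept, la.x_range) == (lb.slope, lb.intercept, lb.x_range)
        and np.allclose(la.covariance, lb.covariance)
        for la, lb in zip(lines_a, lines_b)
    )
    rng = np.random.default_rng(seed)
    ra = _sample_rmsds(lines_a, ranges_a, n_mc, rng, n_points)
    if same and ranges_a == ranges_b:
        # identical setups: the statistic is the same distribution; no test
        return RmsdComparison(0.0, 1.0, float(ra.mean()), float(ra.mean()), n_mc)
    rb = _sample_rmsds(lines_b, ranges_b, n_mc, rng, n_points)
    t, p = sps.ttest_ind(ra, rb, equal_var=False)
    return RmsdComparison(float(t), float(p), float(ra.mean()), float(rb.mean()), n_mc)


def division_cv(division_sizes) -> float:
    """Coefficient of variation sd/mean of division sizes."""
    s = np.asarray(division_sizes, float)
    if s.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = float(s.mean())
    if mean <= 0:
        raise ValueError("mean division size must be positive")
    return float(s.std(ddof=0)) / mean
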