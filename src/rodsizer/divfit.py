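"""Division-geometry fits and segmented homeostasis regressions.

On log-log axes, the division length of a rod cell dividing at a fixed
geometric threshold is a straight line in the cell radius: a flat line for
a length sizer, slope -1 for an area sizer (``log L_div = log(A_div/2pi) -
log R``), and slope approximately -2 for a volume sizer (``log L_div ~
log(V_div/pi) - 2 log R`` in the cylinder approximation).  A crossover
sizer — length control in thin cells handing over to volume control in
fat cells — is a continuous flat-then-slope(-2) curve with the kink at
radius ``R*`` satisfying ``L* = V*/(pi R*^2)``.  Fits are chi-square fits
to radius-binned mean +/- SE of log10(L_div), so competing sensing models
can be accepted or rejected with a goodness-of-fit p-value.

The segmented homeostasis fit handles populations whose increment-versus-
birth-size relation changes slope partway (e.g. a secondary sizer taking
over above a size threshold): two independent lines split at a breakpoint
chosen either as a fixed fraction of the mean division size or by grid
search over candidate breakpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .simulate import CellCycleRecord
from .stats import RegressionLine, bin_series

__all__ = [
    "DivisionGeometryModel",
    "DivisionGeometryResults",
    "SegmentedHomeostasis",
    "SegmentedFit",
]

_MODELS = ("length", "area", "volume", "crossover", "free")


@dataclass(frozen=True)
class DivisionGeometryResults:
    """Chi-square fit of one sensing model to binned log L_div vs log R."""

    model: str
    params: dict
    chi2: float
    dof: int
    p_value: float
    log_R: np.ndarray
    log_L_mean: np.ndarray
    log_L_sem: np.ndarray
    predicted: np.ndarray

    def summary(self) -> str:
        par = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return "\n".join(
            [
                f"Division-geometry fit: {self.model} sizer model",
                f"  {self.log_R.size} radius bins",
                f"  parameters: {par}",
                f"  chi2 = {self.chi2:.2f} on {self.dof} dof "
                f"(p = {self.p_value:.3g})",
            ]
        )


class DivisionGeometryModel:
    """Fit sensing models to pooled division lengths across radii.

    Records are binned by their single-cell radius; within each bin the
    mean and standard error of log10(L_div) are computed and plotted
    against the mean log10(R).  Available models: ``length`` (flat),
    ``area`` (slope fixed at -1), ``volume`` (slope fixed at -2),
    ``free`` (slope fitted), ``crossover`` (flat then slope -2, continuous
    at the crossover radius).
    """

    def __init__(
        self,
        records: Sequence[CellCycleRecord],
        n_bins: int = 10,
        min_per_bin: int = 5,
    ) -> None:
        R = np.array([r.R for r in records])
        L = np.array([r.L_div for r in records])
        binned = bin_series(np.log10(R), np.log10(L), n_bins, min_per_bin)
        if binned.bin_centers.size < 3:
            raise ValueError("division-geometry fit needs at least 3 radius bins")
        self.binned = binned
        # guard against zero SE in degenerate noise-free bins
        se = binned.sems.copy()
        floor = max(se[se > 0].min() if np.any(se > 0) else 1e-6, 1e-6)
        self.se = np.where(se > 0, se, floor)

    # -- individual models ---------------------------------------------------

    def _chi2(self, predicted: np.ndarray) -> float:
        return float(np.sum(((self.binned.means - predicted) / self.se) ** 2))

    def _fixed_slope(self, slope: float) -> tuple[float, np.ndarray]:
        """Weighted intercept fit for a fixed-slope line; returns (intercept, yhat)."""
        w = 1.0 / self.se**2
        resid = self.binned.means - slope * self.binned.bin_centers
        intercept = float(np.sum(w * resid) / np.sum(w))
        return intercept, slope * self.binned.bin_centers + intercept

    def fit(self, model: str = "area", crossover_grid: int = 200) -> DivisionGeometryResults:
        if model not in _MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
        x, y = self.binned.bin_centers, self.binned.means
        if model == "length":
            intercept, yhat = self._fixed_slope(0.0)
            params = {"L_div": 10.0**intercept}
            k = 1
        elif model == "area":
            intercept, yhat = self._fixed_slope(-1.0)
            params = {"A_div": 2.0 * math.pi * 10.0**intercept}
            k = 1
        elif model == "volume":
            intercept, yhat = self._fixed_slope(-2.0)
            params = {"V_div": math.pi * 10.0**intercept}
            k = 1
        elif model == "free":
            w = 1.0 / self.se**2
            X = np.column_stack([x, np.ones_like(x)])
            Xw, yw = X * np.sqrt(w)[:, None], y * np.sqrt(w)
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            yhat = X @ beta
            cov = np.linalg.inv(Xw.T @ Xw)
            params = {
                "slope": float(beta[0]),
                "intercept": float(beta[1]),
                "slope_sd": float(np.sqrt(cov[0, 0])),
            }
            k = 2
        else:  # crossover
            best = None
            w = 1.0 / self.se**2
            for logRstar in np.linspace(x[0], x[-1], crossover_grid):
                eff = np.maximum(x, logRstar)  # flat below R*, slope -2 above
                u = float(np.sum(w * (y + 2.0 * eff)) / np.sum(w))
                yhat_c = u - 2.0 * eff
                chi2_c = self._chi2(yhat_c)
                if best is None or chi2_c < best[0]:
                    best = (chi2_c, logRstar, u, yhat_c)
            _, logRstar, u, yhat = best
            Rstar = 10.0**logRstar
            Vstar = math.pi * 10.0**u
            params = {
                "R_star": Rstar,
                "V_star": Vstar,
                "L_star": Vstar / (math.pi * Rstar**2),
            }
            k = 2
        chi2 = self._chi2(yhat)
        dof = max(x.size - k, 1)
        return DivisionGeometryResults(
            model=model,
            params=params,
            chi2=chi2,
            dof=dof,
            p_value=float(sps.chi2.sf(chi2, dof)),
            log_R=x,
            log_L_mean=y,
            log_L_sem=self.se,
            predicted=yhat,
        )


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentedFit:
    """Two-slope homeostasis fit split at a breakpoint."""

    slope1: float
    slope2: float
    breakpoint: float
    line1: RegressionLine
    line2: RegressionLine
    sse: float

    def summary(self) -> str:
        return (
            "Segmented homeostasis fit\n"
            f"  breakpoint: {self.breakpoint:.3g}\n"
            f"  slope below: {self.slope1:.3f} +/- {self.line1.slope_sd:.3f}\n"
            f"  slope above: {self.slope2:.3f} +/- {self.line2.slope_sd:.3f}"
        )


class SegmentedHomeostasis:
    """Two-regime homeostasis regression on (birth size, increment) points.

    ``breakpoint='fixed-fraction'`` places the split at ``fraction`` (default
    0.60) of the mean division size, the regime boundary below which the
    primary sizer dominates; ``breakpoint='grid-search'`` scans candidate
    breakpoints minimising the total sum of squared errors of the two
    independent OLS lines (continuity is not enforced).
    """

    def __init__(
        self,
        birth: np.ndarray,
        delta: np.ndarray,
        min_per_side: int = 10,
    ) -> None:
        self.birth = np.asarray(birth, float)
        self.delta = np.asarray(delta, float)
        if self.birth.size != self.delta.size:
            raise ValueError("birth and delta must have equal length")
        self.min_per_side = min_per_side

    def _ols(self, mask: np.ndarray) -> tuple[RegressionLine, float]:
        x, y = self.birth[mask], self.delta[mask]
        X = np.column_stack([x, np.ones_like(x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = float(resid @ resid)
        dof = max(x.size - 2, 1)
        cov = (sse / dof) * np.linalg.inv(X.T @ X)
        line = RegressionLine(
            slope=float(beta[0]),
            intercept=float(beta[1]),
            slope_sd=float(np.sqrt(cov[0, 0])),
            intercept_sd=float(np.sqrt(cov[1, 1])),
            covariance=cov,
            x_range=(float(x.min()), float(x.max())),
        )
        return line, sse

    def _fit_at(self, bp: float) -> SegmentedFit:
        below = self.birth < bp
        if below.sum() < self.min_per_side or (~below).sum() < self.min_per_side:
            raise ValueError(
                f"breakpoint {bp:.3g} leaves fewer than {self.min_per_side} "
                "points on one side"
            )
        l1, s1 = self._ols(below)
        l2, s2 = self._ols(~below)
        return SegmentedFit(
            slope1=l1.slope, slope2=l2.slope, breakpoint=bp,
            line1=l1, line2=l2, sse=s1 + s2,
        )

    def fit(
        self,
        breakpoint: str | float = "fixed-fraction",
        fraction: float = 0.60,
        grid: int = 50,
    ) -> SegmentedFit:
        if isinstance(breakpoint, (int, float)):
            return self._fit_at(float(breakpoint))
        if breakpoint == "fixed-fraction":
            mean_division = float((self.birth + self.delta).mean())
            return self._fit_at(fraction * mean_division)
        if breakpoint == "grid-search":
            order = np.sort(self.birth)
            lo = order[self.min_per_side]
            hi = order[-self.min_per_side - 1]
            if hi <= lo:
                raise ValueError("too few points for a grid search")
            best: SegmentedFit | None = None
            for bp in np.linspace(lo, hi, grid):
                try:
                    fit = self._fit_at(float(bp))
                except ValueError:
                    continue
                if best is None or fit.sse < best.sse:
                    best = fit
            if best is None:
                raise ValueError("no admissible breakpoint found")
            return best
        raise ValueError(f"unknown breakpoint spec: {breakpoint!r}")
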