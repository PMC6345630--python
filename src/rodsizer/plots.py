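"""Plot helpers mirroring the standard figures of the analysis."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .scans import AlphaBetaScanResults, GammaScanResults
from .simulate import CellCycleRecord
from .stats import binned_line, homeostasis_points

__all__ = ["homeostasis_plot", "scan_plot", "division_geometry_plot"]

_COLORS = {"thin": "tab:green", "normal": "tab:red", "fat": "tab:blue"}


def homeostasis_plot(
    records_by_strain: Mapping[str, Sequence[CellCycleRecord]],
    measure: str = "area",
    ax=None,
    n_bins: int = 10,
):
    """Binned size-increment vs birth-size plot, one line per strain."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, recs in records_by_strain.items():
        birth, delta = homeostasis_points(recs, measure)
        binned, line = binned_line(birth, delta, n_bins=n_bins)
        color = _COLORS.get(name)
        ax.errorbar(
            binned.bin_centers, binned.means, yerr=binned.sems,
            fmt="o", ms=4, color=color, label=f"{name} (slope {line.slope:.2f})",
        )
        xs = np.array(binned.x_range)
        ax.plot(xs, line(xs), "-", color=color, lw=1)
    unit = {"length": "μm", "area": "μm$^2$", "volume": "μm$^3$"}.get(measure, "")
    ax.set_xlabel(f"size at birth ({unit})")
    ax.set_ylabel(f"size increment ({unit})")
    ax.legend(fontsize=8)
    return ax


def scan_plot(result: GammaScanResults | AlphaBetaScanResults, ax=None):
    """Objective curve of an exponent scan with its minimum marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    finite = np.isfinite(result.objective)
    ax.plot(result.grid[finite], result.objective[finite], "-")
    if isinstance(result, GammaScanResults):
        opt, label = result.gamma_opt, r"$\gamma$"
    else:
        opt, label = result.alpha_opt, r"$\alpha$"
    ax.axvline(opt, color="k", ls="--", lw=1)
    ax.set_xlabel(label)
    ax.set_ylabel("normalized RMSD")
    ax.set_title(f"optimum {label} = {opt:.2f}")
    return ax


def division_geometry_plot(results, ax=None):
    """Binned log L_div vs log R with the fitted sensing-model curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        results.log_R, results.log_L_mean, yerr=results.log_L_sem,
        fmt="o", ms=4, color="tab:gray",
    )
    ax.plot(results.log_R, results.predicted, "-", color="tab:orange",
            label=f"{results.model} (p={results.p_value:.2g})")
    ax.set_xlabel(r"$\log_{10} R$")
    ax.set_ylabel(r"$\log_{10} L_\mathrm{div}$")
    ax.legend(fontsize=8)
    return ax
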