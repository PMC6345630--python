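"""Steady-state flux-balance model of cortical-node protein scaling.

A cytoplasmic pool of unphosphorylated Cdr2 (copy number N_u) is consumed
by two routes — phosphorylation by cytoplasmic Ssp1 at overall rate
``kp*[Ssp1]*[Cdr2_u]*V_cell`` and direct membrane binding at rate
``kb*[Cdr2_u]*A_memb`` — and replenished by nodal dissociation at rate
``lam*N_nodal``.  Setting dN_u/dt = 0 gives the steady-state balance

    kp*[Ssp1]*[Cdr2_u]*V_cell + kb*[Cdr2_u]*A_memb = lam*N_nodal.

Two limits follow.  When cytoplasmic phosphorylation dominates (wild type)
the membrane term drops and, with constant cytoplasmic concentrations, the
prefactor collapses to a single constant K = kp*[Ssp1]*[Cdr2]:

    K*V_cell = lam*N_nodal          (nodal amount ~ volume).

When phosphorylation is removed (non-phosphorylatable T166A mutant, kp=0)
only the membrane route remains:

    kb*[Cdr2]*A_memb = lam*N_nodal  (nodal amount ~ surface area).

Dividing by the nodal membrane area A_nodal = 2*pi*R*W (constant axial
band width W) converts amounts into densities: density ~ R*L ~ area in the
wild type, ~ L in the mutant.  Concentrations and rates are in effective
(fluorescence) units throughout — only the geometric scalings are
meaningful, not absolute numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import CellGeometry

__all__ = [
    "ModelParams",
    "steady_state_nodal",
    "predicted_density",
    "apply_mobile_fraction",
    "accessible_volume",
    "flux_imbalance",
]


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and geometric parameters of the nodal scaling model.

    Attributes
    ----------
    kp : phosphorylation rate constant (effective, per conc per min).
    kb : membrane binding constant (effective, um/min).
    Ssp1, Cdr2 : constant cytoplasmic concentrations (a.u.).
    Cdr2_u : unphosphorylated cytoplasmic concentration; defaults to Cdr2,
        the fast-binding limit in which little Cdr2 accumulates
        phosphorylated in the cytoplasm.
    lam : nodal dissociation rate (1/min).
    f : immobile nodal fraction in [0, 1).
    c : accessible-volume fraction in (0, 1]; the cytoplasm available for
        the phosphorylation reaction is ``c*V_cell`` (nucleus and vacuoles
        occupy a constant fraction).
    W : axial width of the nodal band (um).
    K : optional pre-lumped constant; must equal kp*Ssp1*Cdr2 when given.
    """

    kp: float = 1.0
    kb: float = 1.0
    Ssp1: float = 1.0
    Cdr2: float = 1.0
    Cdr2_u: float | None = None
    lam: float = 1.0
    f: float = 0.0
    c: float = 1.0
    W: float = 2.0
    K: float | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("dissociation rate lam must be positive")
        if self.kp < 0 or self.kb < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.f < 1.0:
            raise ValueError("immobile fraction f must lie in [0, 1)")
        if not 0.0 < self.c <= 1.0:
            raise ValueError("accessible fraction c must lie in (0, 1]")
        if self.W <= 0:
            raise ValueError("nodal width W must be positive")
        if self.Cdr2_u is None:
            object.__setattr__(self, "Cdr2_u", self.Cdr2)
        if self.K is not None:
            expected = self.kp * self.Ssp1 * self.Cdr2
            if expected > 0 and abs(self.K - expected) / expected > 1e-9:
                raise ValueError(
                    f"inconsistent K={self.K}: kp*[Ssp1]*[Cdr2]={expected}"
                )

    @property
    def K_eff(self) -> float:
        """Lumped volume-route constant kp*[Ssp1]*[Cdr2]."""
        return self.K if self.K is not None else self.kp * self.Ssp1 * self.Cdr2


def _geom_AV(geom, volume: str) -> tuple[float, float]:
    if isinstance(geom, CellGeometry):
        if volume == "cylinder":
            return geom.A_sc, math.pi * geom.R_mean**2 * geom.L
        if volume == "exact":
            return geom.A_sc, geom.V_sc
        raise ValueError(f"unknown volume convention: {volume!r}")
    A, V = geom
    return float(A), float(V)


def steady_state_nodal(
    params: ModelParams, geom, mode: str = "general", volume: str = "cylinder"
) -> float:
    """Closed-form steady-state nodal amount for one cell.

    ``geom`` is a :class:`~rodsizer.geometry.CellGeometry` or an ``(A, V)``
    pair.  For ``CellGeometry`` input the cell volume defaults to the
    cylinder approximation ``V = pi*R**2*L`` that the model's scaling
    predictions are phrased in (``volume="exact"`` switches to the
    spherocylinder closed form).  Modes:

    - ``general``: both routes,
      ``N = (kp*Ssp1*Cdr2_u*c*V + kb*Cdr2_u*A) / lam``;
    - ``wt``: phosphorylation-dominated limit (kb -> 0, Cdr2_u -> Cdr2),
      ``N = K*c*V / lam``;
    - ``t166a``: no phosphorylation (kp = 0, Cdr2_u -> Cdr2),
      ``N = kb*Cdr2*A / lam``.
    """
    A, V = _geom_AV(geom, volume)
    if mode == "general":
        influx = (
            params.kp * params.Ssp1 * params.Cdr2_u * params.c * V
            + params.kb * params.Cdr2_u * A
        )
        return influx / params.lam
    if mode == "wt":
        return params.K_eff * params.c * V / params.lam
    if mode == "t166a":
        return params.kb * params.Cdr2 * A / params.lam
    raise ValueError(f"unknown mode: {mode!r}")


def predicted_density(N_nodal: float, R: float, W: float) -> float:
    """Nodal density N / (2*pi*R*W): amount per unit nodal membrane area."""
    if R <= 0 or W <= 0:
        raise ValueError("R and W must be positive")
    return N_nodal / (2.0 * math.pi * R * W)


def apply_mobile_fraction(N_nodal, f: float):
    """Mobile nodal amount (1-f)*N; a constant immobile fraction leaves all
    geometric scaling exponents unchanged."""
    if not 0.0 <= f < 1.0:
        raise ValueError("immobile fraction f must lie in [0, 1)")
    return (1.0 - f) * np.asarray(N_nodal) if np.ndim(N_nodal) else (1.0 - f) * N_nodal


def accessible_volume(V_cell, c: float):
    """Cytoplasm available to the volume route, c*V_cell with constant c."""
    if not 0.0 < c <= 1.0:
        raise ValueError("accessible fraction c must lie in (0, 1]")
    return c * np.asarray(V_cell) if np.ndim(V_cell) else c * V_cell


def flux_imbalance(
    params: ModelParams, geom, N_nodal: float, mode: str = "general",
    volume: str = "cylinder",
) -> float:
    """Influx minus efflux at nodal amount N (zero at steady state)."""
    return params.lam * (steady_state_nodal(params, geom, mode, volume) - N_nodal)
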