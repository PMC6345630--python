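"""Synthetic cell-cycle lineages and contours.

Generates populations of rod-shaped cells whose division is triggered by a
geometric rule — a threshold on length, surface area, volume (exact
spherocylinder or cylinder approximation), the generalized size measure
``R**gamma * L``, an adder increment, a timer, or the first of several
competing thresholds.  Three strain families of distinct radius emulate
the thin (rga2-delete), normal (wild-type) and fat (rga4-delete) rods used
to discriminate length, area and volume sensing.

Every stochastic choice is driven by an explicit seed; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import CellContour, spherocylinder_area, spherocylinder_volume

__all__ = [
    "DivisionRule",
    "StrainConfig",
    "CellCycleRecord",
    "simulate_lineages",
    "simulate_strains",
    "strain_presets",
    "make_contour",
    "records_frame",
    "records_from_frame",
]

_MEASURES = (
    "length",
    "area",
    "volume_exact",
    "volume_cylinder",
    "general_gamma",
)


@dataclass(frozen=True)
class DivisionRule:
    """Geometric division trigger.

    ``kind`` selects the sensed quantity.  For sizer kinds the cell divides
    when the quantity reaches ``threshold`` (in the rule's own units:
    micrometres for length, um^2 for area, um^3 for volumes,
    ``um^(gamma+1)`` for ``general_gamma``).  ``adder`` divides when the
    chosen ``measure`` has increased by ``threshold`` since birth; ``timer``
    divides after ``threshold`` minutes.  ``competing`` divides when the
    FIRST member rule is satisfied.
    """

    kind: str
    threshold: float | None = None
    gamma: float | None = None
    measure: str = "length"  # adder only
    members: tuple["DivisionRule", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "competing":
            if len(self.members) < 2:
                raise ValueError("competing rule needs >= 2 member rules")
            return
        if self.kind not in _MEASURES + ("adder", "timer"):
            raise ValueError(f"unknown division rule kind: {self.kind!r}")
        if self.threshold is None or self.threshold <= 0:
            raise ValueError("division threshold must be positive")
        if self.kind == "general_gamma" and self.gamma is None:
            raise ValueError("general_gamma rule requires gamma")
        if self.kind == "adder" and self.measure not in _MEASURES[:4]:
            raise ValueError(f"unsupported adder measure: {self.measure!r}")


def measure_value(kind: str, R: float, L: float, gamma: float | None = None) -> float:
    """Evaluate a geometric size measure at radius R and length L."""
    if kind == "length":
        return L
    if kind == "area":
        return spherocylinder_area(L, R)
    if kind == "volume_exact":
        return spherocylinder_volume(L, R)
    if kind == "volume_cylinder":
        return math.pi * R * R * L
    if kind == "general_gamma":
        return R**gamma * L
    raise ValueError(f"unknown measure: {kind!r}")


def _length_at_threshold(kind: str, R: float, S: float, gamma: float | None = None) -> float:
    """Length at which the measure ``kind`` equals S, at fixed radius."""
    if kind == "length":
        return S
    if kind == "area":
        return S / (2.0 * math.pi * R)
    if kind == "volume_exact":
        return S / (math.pi * R * R) + 2.0 * R / 3.0
    if kind == "volume_cylinder":
        return S / (math.pi * R * R)
    if kind == "general_gamma":
        return S / R**gamma
    raise ValueError(f"unknown measure: {kind!r}")


@dataclass(frozen=True)
class StrainConfig:
    """Parameters of one synthetic strain.

    Radii are drawn per cell from a normal distribution
    (mean ``radius_mean``, CV ``radius_cv``) and held constant within a
    cycle; length grows linearly at ``growth_rate``.  The division rule's
    threshold is perturbed per cycle by mean-one lognormal noise of CV
    ``threshold_cv``; daughters receive half the mother's division length
    times ``1 + N(0, division_asymmetry_cv)``.  ``nuclear_fraction`` is the
    constant nuclear-to-cell volume ratio used when rendering images and
    when correcting volumes to accessible cytoplasm.
    """

    name: str
    radius_mean: float
    division_rule: DivisionRule
    radius_cv: float = 0.02
    growth_rate: float = 0.06  # um/min, length-linear
    threshold_cv: float = 0.075
    division_asymmetry_cv: float = 0.02
    nuclear_fraction: float = 0.08
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be positive")
        for name in ("radius_cv", "threshold_cv", "division_asymmetry_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.nuclear_fraction < 1.0:
            raise ValueError("nuclear_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class CellCycleRecord:
    """Birth and division geometry of one cell cycle."""

    strain: str
    cell_id: str
    R: float
    L_birth: float
    A_birth: float
    V_birth: float
    L_div: float
    A_div: float
    V_div: float
    birth_time: float
    division_time: float


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _division_length(
    rule: DivisionRule,
    R: float,
    L_birth: float,
    noise: float,
    growth_rate: float,
) -> float:
    """Length at division under ``rule`` with multiplicative threshold noise."""
    if rule.kind == "competing":
        return min(
            _division_length(m, R, L_birth, noise, growth_rate)
            for m in rule.members
        )
    if rule.kind == "timer":
        return L_birth + growth_rate * rule.threshold * noise
    if rule.kind == "adder":
        S_target = measure_value(rule.measure, R, L_birth) + rule.threshold * noise
        return _length_at_threshold(rule.measure, R, S_target)
    return _length_at_threshold(rule.kind, R, rule.threshold * noise, rule.gamma)


def simulate_lineages(
    strain: StrainConfig,
    n_cells: int,
    seed: int | None = None,
    *,
    burn_in: int = 5,
) -> list[CellCycleRecord]:
    """Follow a single lineage for ``n_cells`` cycles after ``burn_in`` cycles.

    Each cycle draws a fresh radius, grows length linearly, divides when the
    rule's (noise-perturbed) threshold is crossed, and passes roughly half
    the division length to the daughter.  Raises ``ValueError`` when the
    rule's threshold is unreachable from birth (division not larger than
    birth), which signals an inconsistent threshold/geometry combination.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(strain.seed if seed is None else seed)
    R0 = strain.radius_mean
    L0 = _division_length(strain.division_rule, R0, 0.0, 1.0, strain.growth_rate)
    if L0 <= 2.0 * R0:
        raise ValueError(
            "division threshold unreachable: noiseless division length "
            f"{L0:.3g} um is not a rod at radius {R0:.3g} um"
        )
    L_birth = 0.5 * L0
    t = 0.0
    records: list[CellCycleRecord] = []
    for i in range(burn_in + n_cells):
        R = R0 * (1.0 + strain.radius_cv * rng.standard_normal()) if strain.radius_cv else R0
        R = max(R, 0.2 * R0)
        noise = _lognormal_factor(rng, strain.threshold_cv)
        L_div = _division_length(
            strain.division_rule, R, L_birth, noise, strain.growth_rate
        )
        if L_div <= L_birth:
            raise ValueError(
                f"division threshold unreachable: division length {L_div:.3g} "
                f"<= birth length {L_birth:.3g} at radius {R:.3g}"
            )
        t_div = t + (L_div - L_birth) / strain.growth_rate
        if i >= burn_in:
            records.append(
                CellCycleRecord(
                    strain=strain.name,
                    cell_id=f"{strain.name}-{i - burn_in:05d}",
                    R=R,
                    L_birth=L_birth,
                    A_birth=spherocylinder_area(L_birth, R),
                    V_birth=spherocylinder_volume(L_birth, R),
                    L_div=L_div,
                    A_div=spherocylinder_area(L_div, R),
                    V_div=spherocylinder_volume(L_div, R),
                    birth_time=t,
                    division_time=t_div,
                )
            )
        frac = 0.5 * (1.0 + strain.division_asymmetry_cv * rng.standard_normal())
        L_birth = L_div * frac
        t = t_div
    return records


def simulate_strains(
    strains: Sequence[StrainConfig],
    n_cells: int,
    seed: int | None = None,
    **kwargs,
) -> dict[str, list[CellCycleRecord]]:
    """Simulate several strains with independent child seeds of ``seed``."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(strains))
    return {
        s.name: simulate_lineages(
            s, n_cells, seed=int(child.generate_state(1)[0] % 2**31), **kwargs
        )
        for s, child in zip(strains, children)
    }


#: division surface area of normal-width cells, um^2
WT_AREA_THRESHOLD = 165.0
#: division volume when area sensing is lost, um^3
VOLUME_THRESHOLD = 180.0
#: radius implied by dividing at 165 um^2 when 14 um long: R = A/(2 pi L)
NORMAL_RADIUS = WT_AREA_THRESHOLD / (2.0 * math.pi * 14.0)


def strain_presets(
    division_rule: DivisionRule | None = None,
    **overrides,
) -> dict[str, StrainConfig]:
    """Thin / normal / fat strain family.

    The normal radius (~1.876 um) is the one implied by dividing at a
    surface area of 165 um^2 with a division length of 14 um; the thin
    (1.5 um) and fat (2.2 um) radii bracket it the way the RhoGAP
    radius mutants do.  Growth rates differ by under 5% across presets.
    All presets share the division rule (default: area sizer at 165 um^2).
    """
    rule = division_rule or DivisionRule("area", WT_AREA_THRESHOLD)
    base = dict(division_rule=rule, **overrides)
    return {
        "thin": StrainConfig(name="thin", radius_mean=1.5, growth_rate=0.059, **base),
        "normal": StrainConfig(
            name="normal", radius_mean=NORMAL_RADIUS, growth_rate=0.060, **base
        ),
        "fat": StrainConfig(name="fat", radius_mean=2.2, growth_rate=0.061, **base),
    }


def make_contour(
    L: float,
    R: float,
    n_vertices: int = 128,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    cell_id: str = "cell",
) -> CellContour:
    """Spherocylinder outline with optional Gaussian vertex jitter.

    Vertices are placed at equal arc-length spacing along the ideal outline
    (axis along x, poles at x=0 and x=L); jitter is i.i.d. on both
    coordinates.
    """
    if L <= 2.0 * R:
        raise ValueError(f"not a rod: L={L} <= 2R={2 * R}")
    if n_vertices < 12:
        raise ValueError("need at least 12 vertices")
    straight = L - 2.0 * R
    cap = math.pi * R
    per = 2.0 * straight + 2.0 * cap
    s = np.linspace(0.0, per, n_vertices, endpoint=False)
    pts = np.empty((n_vertices, 2))
    for i, si in enumerate(s):
        if si < straight:  # top edge, left to right
            pts[i] = (R + si, R)
        elif si < straight + cap:  # right cap, pi/2 -> -pi/2
            a = math.pi / 2.0 - (si - straight) / R
            pts[i] = (L - R + R * math.cos(a), R * math.sin(a))
        elif si < 2.0 * straight + cap:  # bottom edge, right to left
            pts[i] = (L - R - (si - straight - cap), -R)
        else:  # left cap, -pi/2 -> -3pi/2
            a = -math.pi / 2.0 - (si - 2.0 * straight - cap) / R
            pts[i] = (R + R * math.cos(a), R * math.sin(a))
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
    return CellContour(vertices=pts, cell_id=cell_id)


# ---------------------------------------------------------------------------
# record tables

_RECORD_COLUMNS = [
    "strain", "cell_id", "R", "L_birth", "A_birth", "V_birth",
    "L_div", "A_div", "V_div", "birth_time", "division_time",
]


def records_frame(records: Sequence[CellCycleRecord]) -> pd.DataFrame:
    """Tidy table of cell-cycle records."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in _RECORD_COLUMNS} for r in records]
    )


def records_from_frame(df: pd.DataFrame) -> list[CellCycleRecord]:
    """Inverse of :func:`records_frame`."""
    return [
        CellCycleRecord(**{c: row[c] for c in _RECORD_COLUMNS})
        for _, row in df.iterrows()
    ]
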