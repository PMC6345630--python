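"""Cell geometry from segmented contours.

Rod-shaped cells (fission yeast and its radius mutants) are modelled as
spherocylinders: a cylinder of length ``L - 2R`` capped by two hemispheres
of radius ``R``, giving surface area ``A = 2*pi*R*L`` and volume
``V = pi*R**2*(L - 2R/3)``.  This module measures length, the axial radius
profile ``R(x)``, and surface area / volume from a closed cell contour by
three methodologies:

1. *rotation* — revolve the measured radius profile of each single cell
   around its symmetry axis (no shape assumption beyond axisymmetry);
2. *single cell* — use each cell's own mean radius in the spherocylinder
   closed forms;
3. *population* — use the strain-average radius in the closed forms.

All coordinates are in micrometres; pixel-to-micrometre conversion belongs
to I/O, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellContour",
    "RadiusProfile",
    "CellGeometry",
    "SymmetryAxis",
    "AxisUndefinedError",
    "compute_symmetry_axis",
    "radius_profile",
    "geometry_by_rotation",
    "geometry_spherocylinder",
    "spherocylinder_area",
    "spherocylinder_volume",
    "population_mean_radius",
    "measure_contour",
    "measure_contours",
    "read_contour_csv",
    "write_geometry_csv",
]


class AxisUndefinedError(ValueError):
    """Raised when a contour has no dominant elongation direction."""


@dataclass(frozen=True)
class CellContour:
    """Closed polygon outlining one cell, in micrometres.

    ``vertices`` is an (n, 2) array of ordered polygon vertices; the polygon
    is implicitly closed (last vertex connects back to the first).
    """

    vertices: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if v.shape[0] < 12:
            raise ValueError("contour needs at least 12 vertices")
        if self.signed_area(v) == 0.0:
            raise ValueError("contour encloses zero area")
        object.__setattr__(self, "vertices", v)

    @staticmethod
    def signed_area(v: np.ndarray) -> float:
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        """Enclosed polygon area (always positive)."""
        return abs(self.signed_area(self.vertices))


@dataclass(frozen=True)
class SymmetryAxis:
    """Unit direction of the long axis plus the contour centroid."""

    direction: np.ndarray  # unit 2-vector
    centroid: np.ndarray  # 2-vector

    def axial_coordinate(self, points: np.ndarray) -> np.ndarray:
        """Signed projection of points onto the axis, centroid at 0."""
        return (np.asarray(points, float) - self.centroid) @ self.direction

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned perpendicular distance of points from the axis line."""
        d = np.asarray(points, float) - self.centroid
        normal = np.array([-self.direction[1], self.direction[0]])
        return np.abs(d @ normal)


@dataclass(frozen=True)
class RadiusProfile:
    """Radius ``r(x)`` sampled along the symmetry axis, 0 <= x <= L."""

    x: np.ndarray
    r: np.ndarray
    L: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, float)
        r = np.asarray(self.r, float)
        if x.shape != r.shape or x.ndim != 1:
            raise ValueError("x and r must be 1-D arrays of equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("radii must be non-negative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "r", r)

    @property
    def mean_radius(self) -> float:
        """Mean radius over the cylindrical mid-zone.

        The hemispherical caps (within R_max of either pole) are excluded so
        the estimate reflects the rod width rather than the cap taper.
        """
        r_max = float(self.r.max())
        mid = (self.x > r_max) & (self.x < self.L - r_max)
        if not mid.any():  # short cell: fall back to the global maximum zone
            mid = self.r > 0.9 * r_max
        return float(self.r[mid].mean())


@dataclass(frozen=True)
class CellGeometry:
    """Length, radius and derived areas/volumes for one cell.

    ``A_rot``/``V_rot`` come from revolving the radius profile (methodology
    1) and are NaN when the cell was specified by (L, R) only.  ``A_sc`` and
    ``V_sc`` are the spherocylinder closed forms evaluated with the radius
    the chosen methodology dictates.
    """

    cell_id: str
    L: float
    R_mean: float
    A_sc: float
    V_sc: float
    A_rot: float = math.nan
    V_rot: float = math.nan
    methodology: int = 2

    @classmethod
    def from_length_radius(
        cls, L: float, R: float, cell_id: str = "cell", methodology: int = 2
    ) -> "CellGeometry":
        A, V = geometry_spherocylinder(L, R)
        return cls(cell_id=cell_id, L=L, R_mean=R, A_sc=A, V_sc=V,
                   methodology=methodology)


# ---------------------------------------------------------------------------
# axis and profile


def _polygon_moments(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and second central moment matrix of a uniform polygon lamina.

    Closed forms from the shoelace decomposition; equivalent to PCA of the
    cloud of points interior to the contour, without rasterising.
    """
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    # second moments about the origin
    sxx = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    syy = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    sxy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    # signed area keeps the moments orientation-independent
    cov = np.array([
        [sxx / a - cx * cx, sxy / a - cx * cy],
        [sxy / a - cx * cy, syy / a - cy * cy],
    ])
    return np.array([cx, cy]), cov


def compute_symmetry_axis(
    contour: CellContour, *, eccentricity_tol: float = 0.05
) -> SymmetryAxis:
    """Long axis of the cell by principal-component analysis of its interior.

    Raises
    ------
    AxisUndefinedError
        If the two principal variances differ by less than
        ``eccentricity_tol`` (relative), i.e. the contour is nearly circular
        and the elongation direction is meaningless.
    """
    centroid, cov = _polygon_moments(contour.vertices)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major, minor = evals[1], evals[0]
    if major <= 0 or (major - minor) / major < eccentricity_tol:
        raise AxisUndefinedError(
            f"principal variances {minor:.4g} and {major:.4g} are within "
            f"{eccentricity_tol:.0%}: symmetry axis undefined"
        )
    direction = evecs[:, 1]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction  # canonical orientation
    return SymmetryAxis(direction=direction, centroid=centroid)


def radius_profile(
    contour: CellContour,
    axis: SymmetryAxis | None = None,
    *,
    bin_width: float | None = None,
) -> RadiusProfile:
    """Radius profile ``r(x)`` from vertex distances to the symmetry axis.

    Vertices are projected on the axis; their perpendicular distances are
    averaged in axial bins (default width ``max(0.1 um, L/100)``), pooling
    the two sides of the contour.  The profile is pinned to zero at both
    poles, where the contour meets the axis.
    """
    if axis is None:
        axis = compute_symmetry_axis(contour)
    t = axis.axial_coordinate(contour.vertices)
    d = axis.radial_distance(contour.vertices)
    t0, t1 = float(t.min()), float(t.max())
    L = t1 - t0
    if L <= 0:
        raise ValueError("empty projection range along the symmetry axis")
    x = t - t0  # pole with the smaller projection sits at x = 0
    if bin_width is None:
        bin_width = max(0.1, L / 100.0)
    n_bins = max(int(np.ceil(L / bin_width)), 4)
    edges = np.linspace(0.0, L, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=d, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    filled = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    xs = np.concatenate(([0.0], centers[filled], [L]))
    rs = np.concatenate(([0.0], sums[filled] / counts[filled], [0.0]))
    keep = np.concatenate(([True], np.diff(xs) > 0))
    return RadiusProfile(x=xs[keep], r=rs[keep], L=L)


# ---------------------------------------------------------------------------
# area / volume


def geometry_by_rotation(profile: RadiusProfile) -> tuple[float, float]:
    """Surface area and volume by revolving ``r(x)`` around the axis.

    A = integral 2*pi*r*sqrt(1 + r'(x)^2) dx and V = integral pi*r^2 dx,
    evaluated by the trapezoidal rule with central-difference derivatives on
    the sampled profile.
    """
    if profile.x.size < 8:
        raise ValueError("rotation integration needs at least 8 profile samples")
    x, r = profile.x, profile.r
    dr = np.gradient(r, x)
    A = float(np.trapezoid(2.0 * np.pi * r * np.sqrt(1.0 + dr * dr), x))
    V = float(np.trapezoid(np.pi * r * r, x))
    return A, V


def spherocylinder_area(L: float, R: float) -> float:
    """A = 2*pi*R*L — cylinder wall plus two hemispherical caps."""
    return 2.0 * math.pi * R * L


def spherocylinder_volume(L: float, R: float) -> float:
    """V = pi*R^2*(L - 2R/3)."""
    return math.pi * R * R * (L - 2.0 * R / 3.0)


def geometry_spherocylinder(L: float, R: float) -> tuple[float, float]:
    """Closed-form (A, V) of a spherocylinder; requires L >= 2R > 0.

    At ``L == 2R`` the rod degenerates to a sphere, which is allowed (the
    formulas remain exact there); ``L < 2R`` is not a rod and raises.
    """
    if R <= 0:
        raise ValueError("radius must be positive")
    if L < 2.0 * R:
        raise ValueError(f"not a rod: L={L} < 2R={2 * R}")
    return spherocylinder_area(L, R), spherocylinder_volume(L, R)


def population_mean_radius(
    cells: Sequence[CellGeometry],
) -> tuple[float, list[CellGeometry]]:
    """Strain-average radius and methodology-3 geometry for every cell.

    Returns the mean of the single-cell mean radii and a new list in which
    the closed-form area/volume of each cell are recomputed with that shared
    radius (methodology 3).  Lengths and rotation-method values are kept.
    """
    if len(cells) == 0:
        raise ValueError("population_mean_radius needs at least one cell")
    R_bar = float(np.mean([c.R_mean for c in cells]))
    out = []
    for c in cells:
        out.append(
            CellGeometry(
                cell_id=c.cell_id,
                L=c.L,
                R_mean=R_bar,
                A_sc=spherocylinder_area(c.L, R_bar),
                V_sc=spherocylinder_volume(c.L, R_bar),
                A_rot=c.A_rot,
                V_rot=c.V_rot,
                methodology=3,
            )
        )
    return R_bar, out


def measure_contour(
    contour: CellContour, *, bin_width: float | None = None
) -> CellGeometry:
    """Full single-cell measurement: axis, profile, both methodologies 1/2."""
    axis = compute_symmetry_axis(contour)
    prof = radius_profile(contour, axis, bin_width=bin_width)
    A_rot, V_rot = geometry_by_rotation(prof)
    R = prof.mean_radius
    A_sc = spherocylinder_area(prof.L, R)
    V_sc = spherocylinder_volume(prof.L, R)
    return CellGeometry(
        cell_id=contour.cell_id,
        L=prof.L,
        R_mean=R,
        A_sc=A_sc,
        V_sc=V_sc,
        A_rot=A_rot,
        V_rot=V_rot,
        methodology=2,
    )


def measure_contours(
    contours: Iterable[CellContour],
    *,
    methodology: int = 3,
    bin_width: float | None = None,
) -> list[CellGeometry]:
    """Measure a population of contours with the requested methodology."""
    cells = [measure_contour(c, bin_width=bin_width) for c in contours]
    if methodology == 3:
        _, cells = population_mean_radius(cells)
    elif methodology not in (1, 2):
        raise ValueError("methodology must be 1, 2 or 3")
    return cells


# ---------------------------------------------------------------------------
# I/O


def read_contour_csv(path) -> list[CellContour]:
    """Read contours from CSV with columns cell_id, vertex_index, x_um, y_um."""
    df = pd.read_csv(path)
    required = {"cell_id", "vertex_index", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contour CSV missing columns: {sorted(missing)}")
    contours = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("vertex_index")
        contours.append(
            CellContour(vertices=grp[["x_um", "y_um"]].to_numpy(), cell_id=str(cid))
        )
    return contours


def geometry_frame(cells: Sequence[CellGeometry]) -> pd.DataFrame:
    """Tidy per-cell geometry table."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "L": [c.L for c in cells],
            "R_mean": [c.R_mean for c in cells],
            "A_rot": [c.A_rot for c in cells],
            "V_rot": [c.V_rot for c in cells],
            "A_sc": [c.A_sc for c in cells],
            "V_sc": [c.V_sc for c in cells],
            "methodology": [c.methodology for c in cells],
        }
    )


def write_geometry_csv(cells: Sequence[CellGeometry], path) -> None:
    geometry_frame(cells).to_csv(path, index=False)
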