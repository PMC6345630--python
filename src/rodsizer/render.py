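"""Synthetic fluorescence images of rod cells with a medial nodal band.

Each rendered cell is a z-sum projection (the analogue of summing a
19-slice confocal stack) built from three components inside the cell mask:
a constant cytoplasmic background proportional to the cytoplasmic protein
concentration, a constant membrane background, and a medial band whose
axial profile is Gaussian (sd ``sigma_band = W/4``) and whose integrated
amount is the steady-state nodal amount of the chosen flux-balance model
times multiplicative lognormal noise.  A mid-focal-plane image and cell /
nucleus masks accompany the projection.  No point-spread-function blur or
photon noise is modelled beyond the optional per-pixel Gaussian noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .geometry import CellGeometry, SymmetryAxis
from .model import ModelParams, steady_state_nodal

__all__ = ["SyntheticCellImage", "render_cell", "save_image", "load_image"]

#: midplane nuclear intensity relative to cytoplasm (GFP largely excluded)
_NUCLEUS_DIMMING = 0.3


@dataclass(frozen=True)
class SyntheticCellImage:
    """Rendered cell: z-sum + midplane images, masks, and ground truth."""

    zsum: np.ndarray
    midplane: np.ndarray
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    pixel_size: float
    origin: np.ndarray  # world coordinates (um) of pixel (0, 0) centre
    axis: SymmetryAxis
    true_m: float  # band centre, axial um
    true_sigma: float  # band axial sd, um
    true_amount: float  # integrated band intensity actually rendered
    cell_id: str = "cell"

    def axial_coordinates(self) -> np.ndarray:
        """Axial coordinate (um, 0 at the left pole) of every pixel centre."""
        ny, nx = self.zsum.shape
        xs = self.origin[0] + self.pixel_size * np.arange(nx)
        return np.broadcast_to(xs, (ny, nx))


def render_cell(
    geometry: CellGeometry,
    params: ModelParams,
    which_model: str = "wt",
    noise: float = 0.0,
    pixel_size: float = 0.1,
    seed: int | None = None,
    *,
    cyto_background: float = 10.0,
    membrane_background: float = 2.0,
    pixel_noise_sd: float = 0.0,
    nucleus_area_fraction: float = 0.10,
) -> SyntheticCellImage:
    """Render one cell.

    ``noise`` is the CV of the mean-one lognormal factor applied to the
    model's steady-state nodal amount; ``pixel_noise_sd`` adds i.i.d.
    Gaussian read noise to the z-sum.  The cytoplasmic background scales
    with the model's cytoplasmic Cdr2 concentration so that concentration
    read-back is meaningful.
    """
    L, R = geometry.L, geometry.R_mean
    sigma_band = params.W / 4.0
    if pixel_size > sigma_band:
        raise ValueError(
            f"pixel size {pixel_size} um too coarse for band sd {sigma_band} um"
        )
    rng = np.random.default_rng(seed)

    margin = 3.0 * pixel_size
    x0, y0 = -margin, -(R + margin)
    nx = int(math.ceil((L + 2 * margin) / pixel_size))
    ny = int(math.ceil((2 * R + 2 * margin) / pixel_size))
    xs = x0 + pixel_size * (np.arange(nx) + 0.5)
    ys = y0 + pixel_size * (np.arange(ny) + 0.5)
    X, Y = np.meshgrid(xs, ys)

    # spherocylinder footprint: distance to the axis segment [R, L-R] <= R
    ax_clamped = np.clip(X, R, L - R)
    cell_mask = (X - ax_clamped) ** 2 + Y**2 <= R * R

    N_true = steady_state_nodal(params, geometry, mode=which_model)
    if noise > 0:
        s = math.sqrt(math.log(1.0 + noise * noise))
        N_true *= float(rng.lognormal(-0.5 * s * s, s))

    zsum = np.zeros((ny, nx))
    cyto_level = cyto_background * params.Cdr2
    zsum[cell_mask] = cyto_level + membrane_background
    band = np.exp(-((X - L / 2.0) ** 2) / (2.0 * sigma_band**2))
    band[~cell_mask] = 0.0
    total = band.sum()
    if total > 0:
        zsum += band * (N_true / total)
    if pixel_noise_sd > 0:
        zsum = zsum + rng.normal(0.0, pixel_noise_sd, zsum.shape)

    # nucleus: medial disc occupying a constant fraction of the midplane area
    r_nuc = math.sqrt(nucleus_area_fraction * cell_mask.sum() * pixel_size**2 / math.pi)
    nucleus_mask = ((X - L / 2.0) ** 2 + Y**2 <= r_nuc**2) & cell_mask

    midplane = np.zeros((ny, nx))
    midplane[cell_mask] = params.Cdr2
    midplane[nucleus_mask] = _NUCLEUS_DIMMING * params.Cdr2
    if pixel_noise_sd > 0:
        midplane = midplane + rng.normal(0.0, pixel_noise_sd, midplane.shape)

    axis = SymmetryAxis(
        direction=np.array([1.0, 0.0]), centroid=np.array([L / 2.0, 0.0])
    )
    return SyntheticCellImage(
        zsum=zsum,
        midplane=midplane,
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        pixel_size=pixel_size,
        origin=np.array([xs[0], ys[0]]),
        axis=axis,
        true_m=L / 2.0,
        true_sigma=sigma_band,
        true_amount=N_true,
        cell_id=geometry.cell_id,
    )


def save_image(img: SyntheticCellImage, tiff_path, json_path) -> None:
    """Write the z-sum/midplane stack as TIFF plus a ground-truth sidecar."""
    import tifffile

    stack = np.stack(
        [
            img.zsum,
            img.midplane,
            img.cell_mask.astype(float),
            img.nucleus_mask.astype(float),
        ]
    )
    tifffile.imwrite(tiff_path, stack.astype(np.float32), photometric="minisblack")
    meta = {
        "cell_id": img.cell_id,
        "pixel_size": img.pixel_size,
        "origin": img.origin.tolist(),
        "axis_direction": img.axis.direction.tolist(),
        "axis_centroid": img.axis.centroid.tolist(),
        "true_m": img.true_m,
        "true_sigma": img.true_sigma,
        "true_amount": img.true_amount,
        "planes": ["zsum", "midplane", "cell_mask", "nucleus_mask"],
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def load_image(tiff_path, json_path) -> SyntheticCellImage:
    """Read an image stack written by :func:`save_image`."""
    import tifffile

    stack = tifffile.imread(tiff_path)
    with open(json_path) as fh:
        meta = json.load(fh)
    return SyntheticCellImage(
        zsum=stack[0].astype(float),
        midplane=stack[1].astype(float),
        cell_mask=stack[2] > 0.5,
        nucleus_mask=stack[3] > 0.5,
        pixel_size=float(meta["pixel_size"]),
        origin=np.array(meta["origin"]),
        axis=SymmetryAxis(
            direction=np.array(meta["axis_direction"]),
            centroid=np.array(meta["axis_centroid"]),
        ),
        true_m=float(meta["true_m"]),
        true_sigma=float(meta["true_sigma"]),
        true_amount=float(meta["true_amount"]),
        cell_id=str(meta["cell_id"]),
    )
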