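"""Lobe volume, network density, tiled density heatmaps and QC montages.

The *lobe volume* is the tissue volume actually occupied by the specimen
inside a stack.  Sparse networks (vessels, nerve fibers) sketch the lobe
envelope; the estimate is the voxelwise union of the channel masks, bridged
by an anisotropy-aware morphological closing of physical radius
``closing_radius_um`` and 3D hole filling, converted to physical volume.

*Network density* is network length per lobe volume.  Internal math is in
um and um^3; the reporting unit (default m/m^3) is an exact power-of-ten
conversion applied at output only, so the arithmetic stays auditable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .skeleton import build_skeleton_graph, measure_length
from .stacks import LabelMask, CalibratedStack, Spacing

logger = logging.getLogger(__name__)

#: (length numerator, volume denominator) conversion factors from um / um^3.
UNIT_FACTORS = {
    "um/um3": (1.0, 1.0),
    "mm/mm3": (1e-3, 1e-9),
    "m/m3": (1e-6, 1e-18),
}


@dataclass
class LobeVolumeResult:
    volume_um3: float
    lobe_mask: LabelMask
    closing_radius_um: float
    min_hole: int | None


@dataclass
class DensityRecord:
    """One (sample, tile) quantification row.

    ``flagged`` marks tiles whose lobe volume was zero or below the floor;
    their densities are NaN, never silently zero.  Vessel fields are None in
    single-channel mode.
    """

    sample: str
    tile_index: int
    tile_z: float
    tile_y: float
    tile_x: float
    neuron_length_um: float
    lobe_volume_um3: float
    neuron_density: float
    density_units: str
    vessel_length_um: float | None = None
    vessel_density: float | None = None
    flagged: bool = False


@dataclass
class HeatmapGrid:
    """Per-tile density values over a (ny_tiles, nx_tiles) grid.

    ``values[i, j]`` is the density of the tile whose (y, x) origin in
    micrometres is ``origins_um[i, j]``; flagged tiles hold NaN.
    """

    values: np.ndarray
    tile_shape_vox: tuple[int, int]
    spacing: Spacing
    units: str

    def origins_um(self) -> np.ndarray:
        ny, nx = self.values.shape
        ty, tx = self.tile_shape_vox
        _, dy, dx = self.spacing
        out = np.zeros((ny, nx, 2))
        for i in range(ny):
            for j in range(nx):
                out[i, j] = (i * ty * dy, j * tx * dx)
        return out


def _closing_euclidean(mask: np.ndarray, radius_um: float, spacing: Spacing) -> np.ndarray:
    """Morphological closing with a Euclidean ball of physical radius.

    Implemented with two distance transforms (dilation: background distance
    <= r; erosion: complement of dilating the complement), which is exact,
    anisotropy-aware via the EDT sampling, and memory-friendly for large
    radii.  The volume is padded by the radius so border structures are
    never clipped; closing therefore always contains the input.
    """
    pad = [int(math.ceil(radius_um / s)) + 1 for s in spacing]
    padded = np.pad(mask, [(p, p) for p in pad])
    # dilation: voxels within r of the mask (EDT of the complement)
    dilated = ndi.distance_transform_edt(~padded, sampling=spacing) <= radius_um
    # erosion of the dilated set: voxels deeper than r inside it
    closed = ndi.distance_transform_edt(dilated, sampling=spacing) > radius_um
    closed |= padded  # guard extensivity against EDT boundary ties
    return closed[
        pad[0] : pad[0] + mask.shape[0],
        pad[1] : pad[1] + mask.shape[1],
        pad[2] : pad[2] + mask.shape[2],
    ]


def _fill_holes(mask: np.ndarray, min_hole: int | None) -> np.ndarray:
    if min_hole is None:
        return ndi.binary_fill_holes(mask)
    # fill only enclosed background components of size <= min_hole
    bg_labels, n = ndi.label(~mask)
    if n == 0:
        return mask
    border = np.zeros_like(mask, dtype=bool)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    touches = np.unique(bg_labels[border & ~mask])
    sizes = np.bincount(bg_labels.ravel(), minlength=n + 1)
    out = mask.copy()
    for lab in range(1, n + 1):
        if lab not in touches and sizes[lab] <= min_hole:
            out[bg_labels == lab] = True
    return out


def estimate_lobe_volume(
    masks: Sequence[LabelMask],
    closing_radius_um: float = 50.0,
    min_hole: int | None = None,
) -> LobeVolumeResult:
    """Estimate the specimen (lobe) volume from the union of channel masks.

    union -> morphological closing (ellipsoidal structuring element of
    physical radius ``closing_radius_um``, so closing reach is isotropic in
    micrometres, not voxels) -> hole filling -> voxel count x voxel volume.
    The result mask always contains the input union (closing is extensive;
    the volume is padded before closing so the border never clips it).
    """
    if not masks:
        raise ValueError("at least one mask is required")
    spacing = masks[0].spacing
    shape = masks[0].voxels.shape
    for m in masks[1:]:
        if m.voxels.shape != shape or tuple(m.spacing) != tuple(spacing):
            raise ValueError("all masks must share shape and spacing")
    union = np.zeros(shape, dtype=bool)
    for m in masks:
        union |= m.binary

    if not union.any():
        warnings.warn("empty mask union: lobe volume is 0; downstream tiles will be flagged")
        lobe = union
    elif closing_radius_um > 0:
        lobe = _fill_holes(_closing_euclidean(union, closing_radius_um, spacing), min_hole)
    else:
        lobe = _fill_holes(union, min_hole)

    voxvol = float(np.prod(spacing))
    return LobeVolumeResult(
        volume_um3=float(np.count_nonzero(lobe)) * voxvol,
        lobe_mask=LabelMask(voxels=lobe.astype(np.uint8), spacing=spacing, class_names={1: "lobe"}),
        closing_radius_um=closing_radius_um,
        min_hole=min_hole,
    )


def compute_density(length_um: float, volume_um3: float, units: str = "m/m3") -> float:
    """Network density = length / lobe volume, in the requested unit.

    Zero (or negative) volume is a flagged condition: the return value is
    NaN, distinct from a genuine density of 0 (zero length over positive
    volume).
    """
    if units not in UNIT_FACTORS:
        raise ValueError(f"unknown units {units!r}; choose from {sorted(UNIT_FACTORS)}")
    if length_um < 0:
        raise ValueError("length must be non-negative")
    if volume_um3 <= 0:
        warnings.warn("zero lobe volume: density flagged (NaN), not zero")
        return float("nan")
    f_len, f_vol = UNIT_FACTORS[units]
    return (length_um * f_len) / (volume_um3 * f_vol)


def tile_slices(
    shape_yx: tuple[int, int], tile_shape: tuple[int, int]
) -> tuple[list[tuple[slice, slice]], tuple[int, int]]:
    """Partition a (ny, nx) extent into row-major tiles (last tiles ragged)."""
    ny, nx = shape_yx
    ty, tx = tile_shape
    if ty < 1 or tx < 1:
        raise ValueError("tile shape must be >= 1 in both axes")
    n_ty = -(-ny // ty)
    n_tx = -(-nx // tx)
    slices = [
        (slice(i * ty, min((i + 1) * ty, ny)), slice(j * tx, min((j + 1) * tx, nx)))
        for i in range(n_ty)
        for j in range(n_tx)
    ]
    return slices, (n_ty, n_tx)


def measure_tiles(
    skeleton: LabelMask, lobe_mask: LabelMask, tile_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tile (length_um, lobe_volume_um3) over a (y, x) tiling.

    The lobe mask must be built on the whole stack *before* tiling so that
    per-tile volumes add up to the whole-stack volume.  Skeleton edges that
    cross a tile boundary are not counted (both endpoints must fall inside
    the tile), a bias bounded by (number of cut edges) x max edge length.
    """
    if skeleton.voxels.shape != lobe_mask.voxels.shape:
        raise ValueError("skeleton and lobe mask must share shape")
    slices, (n_ty, n_tx) = tile_slices(skeleton.voxels.shape[1:], tile_shape)
    lengths = np.zeros((n_ty, n_tx))
    volumes = np.zeros((n_ty, n_tx))
    voxvol = lobe_mask.voxel_volume_um3
    for k, (sy, sx) in enumerate(slices):
        i, j = divmod(k, n_tx)
        sub = LabelMask(
            voxels=skeleton.voxels[:, sy, sx], spacing=skeleton.spacing
        )
        lengths[i, j] = measure_length(build_skeleton_graph(sub)).total_length_um
        volumes[i, j] = float(np.count_nonzero(lobe_mask.voxels[:, sy, sx])) * voxvol
    return lengths, volumes


def tile_density_map(
    length_by_tile: np.ndarray,
    volume_by_tile: np.ndarray,
    tile_shape: tuple[int, int],
    spacing: Spacing,
    units: str = "m/m3",
    volume_floor_frac: float = 0.01,
    tile_extent_um3: float | None = None,
) -> tuple[HeatmapGrid, pd.DataFrame]:
    """Per-tile density grid plus its CSV-ready table.

    Tiles whose lobe volume is below ``volume_floor_frac`` of the full tile
    extent are reported NaN ("outside lobe"), distinguishing no-tissue tiles
    from tissue-without-network tiles.
    """
    length_by_tile = np.asarray(length_by_tile, dtype=float)
    volume_by_tile = np.asarray(volume_by_tile, dtype=float)
    if length_by_tile.shape != volume_by_tile.shape:
        raise ValueError(
            f"tile grids disagree: {length_by_tile.shape} vs {volume_by_tile.shape}"
        )
    f_len, f_vol = UNIT_FACTORS[units]
    if tile_extent_um3 is None:
        # a full tile spans every z slice; callers with ragged tilings can
        # pass the exact extent instead
        tile_extent_um3 = float("nan")
    floor = (
        volume_floor_frac * tile_extent_um3 if np.isfinite(tile_extent_um3) else 0.0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (length_by_tile * f_len) / (volume_by_tile * f_vol)
    values = np.where(volume_by_tile <= max(floor, 0.0), np.nan, values)

    grid = HeatmapGrid(
        values=values, tile_shape_vox=tuple(tile_shape), spacing=tuple(spacing), units=units
    )
    ny, nx = values.shape
    origins = grid.origins_um()
    rows = []
    for i in range(ny):
        for j in range(nx):
            rows.append(
                {
                    "tile_index": i * nx + j,
                    "tile_y_um": origins[i, j, 0],
                    "tile_x_um": origins[i, j, 1],
                    "length_um": length_by_tile[i, j],
                    "lobe_volume_um3": volume_by_tile[i, j],
                    "density": values[i, j],
                    "units": units,
                }
            )
    return grid, pd.DataFrame(rows)


def render_heatmap(
    grid: HeatmapGrid, path: str | Path, cmap: str = "inferno", title: str | None = None
) -> Path:
    """Render the per-tile density grid to an image file (NaN tiles hatched gray)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    masked = np.ma.masked_invalid(grid.values)
    cm = matplotlib.colormaps[cmap].copy()
    cm.set_bad("0.85")
    im = ax.imshow(masked, cmap=cm, origin="upper", interpolation="nearest")
    fig.colorbar(im, ax=ax, label=f"network density [{grid.units}]")
    if title:
        ax.set_title(title)
    ax.set_xlabel("tile x")
    ax.set_ylabel("tile y")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _to_uint8(mip: np.ndarray, bit_depth: int) -> np.ndarray:
    if bit_depth == 8:
        return mip.astype(np.uint8)
    return (mip.astype(np.float32) / 257.0).round().astype(np.uint8)


def make_qc_montage(
    stack: CalibratedStack, skeleton: LabelMask, separator: int = 4
) -> np.ndarray:
    """Side-by-side QC panel: MIP of the raw stack, MIP of the skeleton, and
    the overlay with the skeleton in magenta.

    Returns an RGB uint8 image of width ``3 * nx + 2 * separator``.
    """
    if stack.voxels.ndim != 3:
        raise ValueError("make_qc_montage expects a single-channel stack")
    if stack.grid_shape != skeleton.voxels.shape:
        raise ValueError("stack and skeleton shapes must match")
    raw_mip = _to_uint8(stack.voxels.max(axis=0), stack.bit_depth)
    skel_mip = (skeleton.binary.any(axis=0).astype(np.uint8)) * 255

    ny, nx = raw_mip.shape
    raw_rgb = np.repeat(raw_mip[..., None], 3, axis=2)
    skel_rgb = np.zeros((ny, nx, 3), dtype=np.uint8)
    skel_rgb[..., 0] = skel_mip
    skel_rgb[..., 2] = skel_mip
    overlay = raw_rgb.copy()
    on = skel_mip > 0
    overlay[on] = (255, 0, 255)

    sep = np.full((ny, separator, 3), 255, dtype=np.uint8)
    return np.concatenate([raw_rgb, sep, skel_rgb, sep, overlay], axis=1)


def save_montage(montage: np.ndarray, path: str | Path) -> Path:
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, montage)
    return path
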