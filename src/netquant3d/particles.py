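"""Per-slice particle exclusion on segmentation masks.

Small, compact connected components (debris, antibody aggregates, cell-body
cross sections) can inflate the measured network length.  This filter
removes, slice by slice, every 2D component whose area is at or below a size
limit and whose circularity falls inside a configurable band, leaving the
elongated network structures untouched.

Circularity is 4*pi*A/P^2 with P the boundary crack length (the number of
exposed pixel edges); a single pixel is defined to have circularity 1.
Circularity values are clamped to <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stacks import LabelMask

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class ParticleFilterSpec:
    """Which components count as excludable particles."""

    max_size: float = 50.0  # px^2, inclusive upper area limit
    circularity_range: tuple[float, float] = (0.5, 1.0)
    connectivity: Literal[4, 8] = 8
    enabled: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.circularity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"circularity range must satisfy 0 <= lo <= hi <= 1, got {(lo, hi)}")
        if self.max_size < 0:
            raise ValueError("max_size must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _crack_perimeters(labels: np.ndarray, n: int) -> np.ndarray:
    """Boundary crack length per label: exposed pixel edges in 4 directions."""
    perim = np.zeros(n + 1, dtype=np.int64)
    padded = np.pad(labels, 1)
    for axis in (0, 1):
        for shift in (1, -1):
            neighbor = np.roll(padded, shift, axis=axis)
            exposed = (padded > 0) & (padded != neighbor)
            perim += np.bincount(padded[exposed], minlength=n + 1)
    return perim


def component_shape_stats(slice_mask: np.ndarray, connectivity: Literal[4, 8] = 8) -> pd.DataFrame:
    """Area (px^2) and circularity of each 2D connected component.

    Returns a frame with columns ``label, area, perimeter, circularity``;
    empty input yields an empty frame.
    """
    slice_mask = np.asarray(slice_mask)
    if slice_mask.ndim != 2:
        raise ValueError("component_shape_stats expects a 2D slice")
    labels, n = ndi.label(slice_mask > 0, structure=_STRUCTURES[connectivity])
    if n == 0:
        return pd.DataFrame(columns=["label", "area", "perimeter", "circularity"])
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    perims = _crack_perimeters(labels, n)[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = np.minimum(1.0, 4.0 * np.pi * areas / perims.astype(float) ** 2)
    circ[areas == 1] = 1.0  # degenerate component convention
    return pd.DataFrame(
        {"label": np.arange(1, n + 1), "area": areas, "perimeter": perims, "circularity": circ}
    )


def exclude_particles(
    mask: LabelMask, spec: ParticleFilterSpec, return_counts: bool = False
):
    """Remove particle-like 2D components from every slice of a binary mask.

    A component is removed iff ``area <= max_size`` and its circularity lies
    in ``circularity_range`` (inclusive).  Slices are processed independently,
    so the result does not depend on slice order.  A disabled spec returns
    the input unchanged.
    """
    if not spec.enabled:
        return (mask, []) if return_counts else mask
    lo, hi = spec.circularity_range
    out = (mask.voxels > 0).astype(np.uint8)
    removed_per_slice: list[int] = []
    for z in range(out.shape[0]):
        labels, n = ndi.label(out[z], structure=_STRUCTURES[spec.connectivity])
        if n == 0:
            removed_per_slice.append(0)
            continue
        stats = component_shape_stats(out[z], spec.connectivity)
        kill = stats.loc[
            (stats["area"] <= spec.max_size)
            & (stats["circularity"] >= lo)
            & (stats["circularity"] <= hi),
            "label",
        ].to_numpy()
        if len(kill):
            out[z][np.isin(labels, kill)] = 0
        removed_per_slice.append(len(kill))
    result = LabelMask(voxels=out, spacing=mask.spacing, class_names=dict(mask.class_names))
    return (result, removed_per_slice) if return_counts else result
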