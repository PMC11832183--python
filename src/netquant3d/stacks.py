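"""Calibrated image stacks, masks, run configuration and tabular results.

All spatial arrays are indexed ``(z, y, x)`` (channel-first when a channel
axis is present) and carry a physical voxel spacing ``(dz, dy, dx)`` in
micrometres.  Lengths are always micrometres and volumes cubic micrometres
internally; conversion to reporting units happens only at output time.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

Spacing = tuple[float, float, float]

#: Column order of the results CSV (two-channel mode).
RESULT_COLUMNS = [
    "sample",
    "tile_index",
    "tile_z",
    "tile_y",
    "tile_x",
    "neuron_length_um",
    "vessel_length_um",
    "lobe_volume_um3",
    "neuron_density",
    "vessel_density",
    "density_units",
]

_VESSEL_COLUMNS = ["vessel_length_um", "vessel_density"]


def _validate_spacing(spacing: Sequence[float]) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must be (dz, dy, dx), got {spacing!r}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be positive, got {spacing!r}")
    return spacing


@dataclass
class CalibratedStack:
    """A 3D (or channel + 3D) intensity grid with physical voxel spacing.

    Parameters
    ----------
    voxels
        Array of shape ``(z, y, x)`` or ``(c, z, y, x)``.
    spacing
        Physical voxel size ``(dz, dy, dx)`` in micrometres.
    channel_names
        Names of the channels when a channel axis is present.
    bit_depth
        8 or 16; intensities must fit the corresponding unsigned range.
    """

    voxels: np.ndarray
    spacing: Spacing
    channel_names: tuple[str, ...] | None = None
    bit_depth: int = 8
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError(
                f"voxels must be 3D (z,y,x) or 4D (c,z,y,x), got ndim={self.voxels.ndim}"
            )
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"every axis must have extent >= 1, got {self.voxels.shape}")
        self.spacing = _validate_spacing(self.spacing)
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.voxels.ndim == 4:
            n_chan = self.voxels.shape[0]
            if self.channel_names is None:
                self.channel_names = tuple(f"ch{i}" for i in range(n_chan))
            elif len(self.channel_names) != n_chan:
                raise ValueError(
                    f"{len(self.channel_names)} channel names for {n_chan} channels"
                )
            else:
                self.channel_names = tuple(self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0] if self.voxels.ndim == 4 else 1

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(nz, ny, nx)`` regardless of channels."""
        return tuple(self.voxels.shape[-3:])

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def channel(self, key: int | str) -> "CalibratedStack":
        """Extract a single channel as a 3D stack (identity for 3D input)."""
        if self.voxels.ndim == 3:
            if key in (0, self.name, None) or key == "ch0":
                return self
            raise KeyError(f"single-channel stack has no channel {key!r}")
        if isinstance(key, str):
            if key not in self.channel_names:
                raise KeyError(f"no channel {key!r} in {self.channel_names}")
            idx = self.channel_names.index(key)
        else:
            idx = int(key)
        return CalibratedStack(
            voxels=self.voxels[idx],
            spacing=self.spacing,
            bit_depth=self.bit_depth,
            name=f"{self.name}:{self.channel_names[idx]}" if self.name else self.channel_names[idx],
            meta=dict(self.meta),
        )


@dataclass
class LabelMask:
    """Integer label volume aligned to a source stack (0 = background)."""

    voxels: np.ndarray
    spacing: Spacing
    class_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D (z,y,x), got ndim={self.voxels.ndim}")
        if np.issubdtype(self.voxels.dtype, np.signedinteger) and self.voxels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def binary(self) -> np.ndarray:
        return self.voxels > 0

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class RunConfig:
    """Configuration of a full quantification run.

    ``classifier_paths`` maps channel name (``"neuron"``, ``"vessel"``) to a
    trained classifier archive.  ``mode`` selects the single- or two-channel
    workflow.  ``z_correction_factor`` rescales the z step to undo the
    apparent z compression caused by refractive-index mismatch between
    immersion and clearing media (1.0 = no correction).
    """

    input_dir: str = "."
    output_dir: str = "out"
    classifier_paths: dict = field(default_factory=dict)
    mode: str = "two_channel"  # "single_channel" | "two_channel"
    spacing: Spacing = (15.0, 1.21, 1.21)
    exclude_particles: bool = False
    particle_max_size: float = 50.0
    particle_circ_lo: float = 0.5
    particle_circ_hi: float = 1.0
    acceleration: bool = False
    z_correction_factor: float = 1.0
    closing_radius_um: float = 50.0
    tile_shape: tuple[int, int] | None = None
    density_units: str = "m/m3"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("single_channel", "two_channel"):
            raise ValueError(f"mode must be single_channel or two_channel, got {self.mode!r}")
        if not (0.0 <= self.particle_circ_lo <= self.particle_circ_hi <= 1.0):
            raise ValueError(
                "circularity range must satisfy 0 <= lo <= hi <= 1, got "
                f"[{self.particle_circ_lo}, {self.particle_circ_hi}]"
            )
        if self.particle_max_size < 0:
            raise ValueError("particle_max_size must be >= 0")
        if self.z_correction_factor <= 0:
            raise ValueError("z_correction_factor must be > 0")
        self.spacing = _validate_spacing(self.spacing)
        if self.tile_shape is not None:
            self.tile_shape = (int(self.tile_shape[0]), int(self.tile_shape[1]))

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["tile_shape"] = list(self.tile_shape) if self.tile_shape else None
        d["spacing"] = list(self.spacing)
        path = Path(path)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("tile_shape") is not None:
            d["tile_shape"] = tuple(d["tile_shape"])
        d["spacing"] = tuple(d["spacing"])
        return cls(**d)


def _bit_depth_of(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ValueError(f"unsupported stack dtype {dtype}; expected uint8 or uint16")


def read_stack(
    path: str | Path,
    spacing: Sequence[float],
    channel_names: Sequence[str] | None = None,
    name: str | None = None,
) -> CalibratedStack:
    """Read a multi-page TIFF z-stack and attach physical voxel spacing.

    Spacing is supplied by the caller (config), not parsed from TIFF tags;
    if resolution tags are present and disagree, a warning is logged and the
    supplied spacing wins.
    """
    spacing = _validate_spacing(spacing)
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            arr = series.asarray()
            axes = series.axes
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            if xres is not None:
                num, den = xres.value
                if num and den:
                    tag_dx = den / num
                    if not np.isclose(tag_dx, spacing[2], rtol=0.05):
                        logger.warning(
                            "%s: TIFF XResolution implies dx=%.4g but config says dx=%.4g; "
                            "using config",
                            path.name, tag_dx, spacing[2],
                        )
    except OSError:
        raise
    except Exception as exc:  # truncated / malformed pages
        raise OSError(f"unreadable TIFF {path}: {exc}") from exc

    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4 and "C" in axes:
        c_pos = axes.index("C")
        arr = np.moveaxis(arr, c_pos, 0)
    elif arr.ndim not in (3, 4):
        raise OSError(f"{path}: cannot interpret TIFF with axes {axes!r} shape {arr.shape}")

    return CalibratedStack(
        voxels=arr,
        spacing=spacing,
        channel_names=tuple(channel_names) if channel_names else None,
        bit_depth=_bit_depth_of(arr.dtype),
        name=name if name is not None else path.stem,
    )


def write_stack(stack: CalibratedStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF (channel-first when 4D).

    Round-trips bit-exactly through :func:`read_stack`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = stack.voxels
    if arr.ndim == 4:
        tifffile.imwrite(path, arr, photometric="minisblack", metadata={"axes": "CZYX"})
    else:
        tifffile.imwrite(path, arr, photometric="minisblack", metadata={"axes": "ZYX"})
    return path


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit TIFF stack (foreground = 255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        mask.binary.astype(np.uint8) * 255,
        photometric="minisblack",
        metadata={"axes": "ZYX"},
    )
    return path


def read_mask(path: str | Path, spacing: Sequence[float]) -> LabelMask:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return LabelMask(voxels=(arr > 0).astype(np.uint8), spacing=_validate_spacing(spacing))


def apply_z_correction(stack: CalibratedStack, factor: float) -> CalibratedStack:
    """Rescale the z step by ``factor`` to undo refractive-index z compression.

    Voxel data are untouched; only ``dz`` changes, and the applied factor is
    recorded in the stack metadata (composing corrections multiplies factors).
    """
    factor = float(factor)
    if factor <= 0:
        raise ValueError(f"z correction factor must be > 0, got {factor}")
    dz, dy, dx = stack.spacing
    meta = dict(stack.meta)
    meta["z_correction_factor"] = meta.get("z_correction_factor", 1.0) * factor
    return CalibratedStack(
        voxels=stack.voxels,
        spacing=(dz * factor, dy, dx),
        channel_names=stack.channel_names,
        bit_depth=stack.bit_depth,
        name=stack.name,
        meta=meta,
    )


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Densify a list of :class:`~netquant3d.density.DensityRecord` to a frame."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        df = df.sort_values(["sample", "tile_index"], kind="stable").reset_index(drop=True)
    return df


def write_results_csv(
    records: Sequence, path: str | Path, include_vessel: bool | None = None
) -> Path:
    """Write quantification results to CSV, ordered by (sample, tile_index).

    ``include_vessel=None`` keeps vessel columns unless every record's vessel
    fields are missing (single-channel mode).
    """
    df = records_to_frame(records)
    if include_vessel is None:
        include_vessel = len(df) > 0 and not df["vessel_length_um"].isna().all()
    if not include_vessel:
        df = df.drop(columns=_VESSEL_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
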