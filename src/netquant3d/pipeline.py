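"""End-to-end orchestration of the single- and two-channel workflows.

For every input stack: optional z-step correction -> per-channel
random-forest segmentation -> optional particle exclusion -> 3D
skeletonization -> network length -> lobe volume from the combined channel
masks -> density -> one results row (or one per tile when a tiling is
configured).  Outputs land in a fixed folder layout::

    output_dir/
      segmented_<channel>/   binary masks, 8-bit TIFF
      skeletons_<channel>/   centerlines, 8-bit TIFF
      montages/              QC montages (raw MIP | skeleton MIP | overlay)
      heatmaps/              per-tile density CSV + rendered image (if tiled)
      results.csv
      run_manifest.json

The whole run is deterministic given (inputs, config, seed); the
acceleration toggle changes scheduling only, never numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .density import (
    DensityRecord,
    compute_density,
    estimate_lobe_volume,
    make_qc_montage,
    measure_tiles,
    render_heatmap,
    save_montage,
    tile_density_map,
)
from .particles import ParticleFilterSpec, exclude_particles
from .segmentation import (
    FeatureBankSpec,
    PixelClassifier,
    TrainingAnnotation,
    apply_classifier,
    train_classifier,
)
from .skeleton import build_skeleton_graph, measure_length, skeletonize_3d
from .stacks import (
    CalibratedStack,
    RunConfig,
    apply_z_correction,
    read_stack,
    write_mask,
    write_results_csv,
)

logger = logging.getLogger(__name__)

_CHANNELS = {"single_channel": ("neuron",), "two_channel": ("neuron", "vessel")}


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stacks: dict = field(default_factory=dict)  # name -> {"status", "error"?}
    timings_s: dict = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return sum(1 for v in self.stacks.values() if v["status"] == "failed")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def _discover_stacks(input_dir: Path) -> list[Path]:
    paths = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    if not paths:
        raise FileNotFoundError(f"no TIFF stacks found in {input_dir}")
    return paths


def _load_classifiers(config: RunConfig) -> dict[str, PixelClassifier]:
    channels = _CHANNELS[config.mode]
    classifiers = {}
    for ch in channels:
        path = config.classifier_paths.get(ch)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                f"missing classifier for channel {ch!r}: {path!r} "
                "(train one with the 'train' command first)"
            )
        classifiers[ch] = PixelClassifier.load(path)
    return classifiers


def _quantify_stack(
    stack: CalibratedStack,
    config: RunConfig,
    classifiers: dict[str, PixelClassifier],
    out: Path,
) -> list[DensityRecord]:
    channels = _CHANNELS[config.mode]
    if config.z_correction_factor != 1.0:
        stack = apply_z_correction(stack, config.z_correction_factor)

    pf_spec = ParticleFilterSpec(
        max_size=config.particle_max_size,
        circularity_range=(config.particle_circ_lo, config.particle_circ_hi),
        enabled=config.exclude_particles,
    )

    masks, skeletons, lengths = {}, {}, {}
    for ch in channels:
        chan_stack = stack.channel(ch) if stack.voxels.ndim == 4 else stack
        mask = apply_classifier(chan_stack, classifiers[ch], acceleration=config.acceleration)
        if config.exclude_particles:
            mask, removed = exclude_particles(mask, pf_spec, return_counts=True)
            logger.info("%s/%s: particle exclusion removed %s components per slice",
                        stack.name, ch, removed)
        masks[ch] = mask
        write_mask(mask, out / f"segmented_{ch}" / f"{stack.name}.tif")
        skel = skeletonize_3d(mask)
        skeletons[ch] = skel
        write_mask(skel, out / f"skeletons_{ch}" / f"{stack.name}.tif")
        lengths[ch] = measure_length(build_skeleton_graph(skel)).total_length_um
        montage = make_qc_montage(chan_stack, skel)
        save_montage(montage, out / "montages" / f"{stack.name}_{ch}.png")

    lobe = estimate_lobe_volume(list(masks.values()), closing_radius_um=config.closing_radius_um)

    units = config.density_units
    records: list[DensityRecord] = []
    if config.tile_shape is None:
        vol = lobe.volume_um3
        flagged = vol <= 0
        records.append(
            DensityRecord(
                sample=stack.name,
                tile_index=0,
                tile_z=0.0,
                tile_y=0.0,
                tile_x=0.0,
                neuron_length_um=lengths["neuron"],
                vessel_length_um=lengths.get("vessel"),
                lobe_volume_um3=vol,
                neuron_density=compute_density(lengths["neuron"], vol, units) if not flagged else float("nan"),
                vessel_density=(
                    compute_density(lengths["vessel"], vol, units) if "vessel" in lengths and not flagged else
                    (float("nan") if "vessel" in lengths else None)
                ),
                density_units=units,
                flagged=flagged,
            )
        )
    else:
        ty, tx = config.tile_shape
        dz, dy, dx = stack.spacing
        nz = stack.grid_shape[0]
        tile_extent = nz * dz * ty * dy * tx * dx
        per_ch = {}
        for ch in channels:
            lg, vg = measure_tiles(skeletons[ch], lobe.lobe_mask, (ty, tx))
            grid, table = tile_density_map(
                lg, vg, (ty, tx), stack.spacing, units=units, tile_extent_um3=tile_extent
            )
            per_ch[ch] = (lg, vg, grid)
            (out / "heatmaps").mkdir(parents=True, exist_ok=True)
            table.to_csv(out / "heatmaps" / f"{stack.name}_{ch}.csv", index=False)
            render_heatmap(grid, out / "heatmaps" / f"{stack.name}_{ch}.png",
                           title=f"{stack.name} {ch} density")
        lg_n, vg, grid_n = per_ch["neuron"]
        n_ty, n_tx = lg_n.shape
        for i in range(n_ty):
            for j in range(n_tx):
                vol = vg[i, j]
                flagged = not np.isfinite(grid_n.values[i, j])
                rec = DensityRecord(
                    sample=stack.name,
                    tile_index=i * n_tx + j,
                    tile_z=0.0,
                    tile_y=i * ty * dy,
                    tile_x=j * tx * dx,
                    neuron_length_um=lg_n[i, j],
                    vessel_length_um=per_ch["vessel"][0][i, j] if "vessel" in per_ch else None,
                    lobe_volume_um3=vol,
                    neuron_density=grid_n.values[i, j],
                    vessel_density=per_ch["vessel"][2].values[i, j] if "vessel" in per_ch else None,
                    density_units=units,
                    flagged=flagged,
                )
                records.append(rec)
    return records


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the full quantification workflow over every stack in the input dir."""
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        version=__version__,
        seed=config.seed,
    )
    try:
        stack_paths = _discover_stacks(input_dir)
        classifiers = _load_classifiers(config)  # fail fast before any processing
    except Exception:
        manifest.save(out / "run_manifest.json")
        raise

    channels = _CHANNELS[config.mode]
    channel_names = channels if config.mode == "two_channel" else None
    all_records: list[DensityRecord] = []
    for path in stack_paths:
        t0 = time.perf_counter()
        try:
            stack = read_stack(path, spacing=config.spacing, channel_names=channel_names)
            if config.mode == "two_channel" and stack.voxels.ndim != 4:
                raise ValueError(f"{path.name}: two_channel mode needs a channel axis")
            if config.mode == "single_channel" and stack.voxels.ndim != 3:
                raise ValueError(f"{path.name}: single_channel mode needs a plain z-stack")
            records = _quantify_stack(stack, config, classifiers, out)
            all_records.extend(records)
            status = "flagged" if any(r.flagged for r in records) else "ok"
            manifest.stacks[stack.name] = {"status": status}
        except Exception as exc:
            logger.error("stack %s failed: %s", path.name, exc)
            manifest.stacks[path.stem] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
            }
            logger.debug("%s", traceback.format_exc())
        manifest.timings_s[path.stem] = round(time.perf_counter() - t0, 3)

    write_results_csv(
        all_records, out / "results.csv", include_vessel=(config.mode == "two_channel")
    )
    manifest.save(out / "run_manifest.json")
    return manifest


def train_command(
    stack_path: str | Path,
    labels_path: str | Path,
    out_path: str | Path,
    spacing,
    bank: FeatureBankSpec | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> Path:
    """Train a classifier from a stack plus a label file and archive it.

    Labels are either a CSV with columns ``z, y, x, label`` (label in
    {foreground, background} or {1, 0}) or a label TIFF where 1 marks
    foreground scribbles, 2 background, 0 unlabeled.
    """
    stack_path, labels_path = Path(stack_path), Path(labels_path)
    if not labels_path.exists():
        raise FileNotFoundError(f"label file not found: {labels_path}")
    stack = read_stack(stack_path, spacing=spacing)
    if stack.voxels.ndim == 4:
        raise ValueError("train on a single-channel stack (extract the channel first)")

    if labels_path.suffix.lower() == ".csv":
        import pandas as pd

        df = pd.read_csv(labels_path)
        coords = df[["z", "y", "x"]].to_numpy()
        labels = df["label"].to_numpy()
    else:
        import tifffile

        lab = tifffile.imread(labels_path)
        if lab.ndim == 2:
            lab = lab[None]
        fg = np.argwhere(lab == 1)
        bg = np.argwhere(lab == 2)
        coords = np.concatenate([fg, bg])
        labels = np.concatenate([np.ones(len(fg), dtype=int), np.zeros(len(bg), dtype=int)])

    annotation = TrainingAnnotation(coordinates=coords, labels=labels)
    clf = train_classifier(stack, annotation, bank=bank, n_trees=n_trees, seed=seed)
    logger.info(
        "training summary: %d foreground / %d background labels, training accuracy %.3f",
        int((annotation.labels == 1).sum()),
        int((annotation.labels == 0).sum()),
        clf.training_accuracy,
    )
    return clf.save(out_path)
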