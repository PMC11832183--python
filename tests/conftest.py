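"""Shared fixtures: phantom validation sets and trained classifiers.

The heavy end-to-end fixtures are session-scoped so the training-and-
quantification study runs once and is shared by the evaluation and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import netquant3d as nq
from netquant3d.phantoms import annotation_from_truth
from netquant3d.segmentation import train_classifier_multi

#: master seed of the phantom study used across the suite
STUDY_SEED = 29


@pytest.fixture(scope="session")
def validation_set():
    """10 phantom stacks, 2 train / 8 validation, exact truth lengths."""
    items, manifest = nq.make_validation_set(seed=STUDY_SEED)
    return items, manifest


@pytest.fixture(scope="session")
def phantom_classifier(validation_set):
    """Random forest trained on the two designated training phantoms."""
    items, _ = validation_set
    train_items = [it for it in items if it.role == "train"]
    anns = [
        annotation_from_truth(it.mask, it.spec.radius_um, seed=it.spec.seed)
        for it in train_items
    ]
    return train_classifier_multi(
        [it.stack for it in train_items], anns, seed=STUDY_SEED
    )


@pytest.fixture(scope="session")
def end_to_end_measurements(validation_set, phantom_classifier):
    """Automated vs true lengths on the 8 validation phantoms.

    Returns a dict with per-stack true lengths, lengths measured after
    classifier segmentation, lengths measured on the true rasterized masks,
    and Dice overlaps of the predicted masks.
    """
    items, _ = validation_set
    out = {"true": [], "measured": [], "true_mask_measured": [], "dice": []}
    for it in items:
        if it.role != "validation":
            continue
        res_true, _ = nq.skeleton_length(it.mask)
        pred = nq.apply_classifier(it.stack, phantom_classifier)
        inter = int((pred.binary & it.mask.binary).sum())
        dice = 2 * inter / (int(pred.binary.sum()) + int(it.mask.binary.sum()))
        res, _ = nq.skeleton_length(pred)
        out["true"].append(it.truth.total_length_um)
        out["measured"].append(res.total_length_um)
        out["true_mask_measured"].append(res_true.total_length_um)
        out["dice"].append(dice)
    return {k: np.asarray(v) for k, v in out.items()}


@pytest.fixture(scope="session")
def small_phantom():
    """A small phantom (quick to segment) with its stack, mask and truth."""
    spec = nq.PhantomSpec(shape=(24, 96, 96), n_tubes=3, n_steps=40, seed=11)
    truth = nq.grow_network(spec)
    stack, mask = nq.rasterize(truth, spec)
    return spec, truth, stack, mask


@pytest.fixture(scope="session")
def pipeline_env(tmp_path_factory):
    """A miniature two-channel study on disk: stacks, classifiers, config.

    Two small two-channel phantom stacks (neuron + vessel tubes drawn from
    different seeds) plus per-channel classifiers trained on an additional
    training stack, ready for run_pipeline.
    """
    root = tmp_path_factory.mktemp("pipeline")
    input_dir = root / "input"
    input_dir.mkdir()
    base = dict(shape=(16, 64, 64), n_tubes=2, n_steps=25)

    def channel_phantom(seed):
        spec = nq.PhantomSpec(**base, seed=seed)
        truth = nq.grow_network(spec)
        stack, mask = nq.rasterize(truth, spec)
        return spec, stack, mask

    # training stack + classifiers per channel
    classifiers = {}
    for ch, seed in (("neuron", 101), ("vessel", 202)):
        spec, stack, mask = channel_phantom(seed)
        ann = annotation_from_truth(mask, spec.radius_um, n_per_class=200, seed=seed)
        clf = nq.train_classifier(stack, ann, seed=5)
        classifiers[ch] = str(clf.save(root / f"{ch}.clf"))

    # two-channel input stacks
    for i, (s_n, s_v) in enumerate([(11, 12), (13, 14)]):
        _, neuron, _ = channel_phantom(s_n)
        _, vessel, _ = channel_phantom(s_v)
        two = nq.CalibratedStack(
            np.stack([neuron.voxels, vessel.voxels]),
            spacing=neuron.spacing,
            channel_names=("neuron", "vessel"),
        )
        nq.write_stack(two, input_dir / f"stack_{i:02d}.tif")

    spacing = nq.PhantomSpec(**base, seed=0).spacing
    config = nq.RunConfig(
        input_dir=str(input_dir),
        output_dir=str(root / "out"),
        classifier_paths=classifiers,
        mode="two_channel",
        spacing=spacing,
        closing_radius_um=10.0,
        seed=0,
    )
    return root, config


@pytest.fixture(scope="session")
def separable_fixture():
    """Two well-separated intensity populations with sparse labels.

    Background voxels ~ N(30, 5^2), tube voxels ~ N(200, 5^2) on an 8-bit
    grid; 200 labeled voxels per class plus a held-out labeled set.
    """
    rng = np.random.default_rng(42)
    shape = (16, 32, 32)
    tube = np.zeros(shape, dtype=bool)
    tube[:, 14:18, :] = True  # a slab of "structure"
    img = rng.normal(30, 5, size=shape)
    img[tube] = rng.normal(200, 5, size=int(tube.sum()))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    stack = nq.CalibratedStack(img, spacing=(2.0, 1.0, 1.0), name="separable")

    fg_pool = np.argwhere(tube)
    bg_pool = np.argwhere(~tube)
    fg = fg_pool[rng.choice(len(fg_pool), 400, replace=False)]
    bg = bg_pool[rng.choice(len(bg_pool), 400, replace=False)]

    def make_ann(fg_sel, bg_sel):
        coords = np.concatenate([fg_sel, bg_sel])
        labels = np.concatenate(
            [np.ones(len(fg_sel), dtype=int), np.zeros(len(bg_sel), dtype=int)]
        )
        return nq.TrainingAnnotation(coordinates=coords, labels=labels)

    train_ann = make_ann(fg[:200], bg[:200])
    held_out = make_ann(fg[200:], bg[200:])
    return stack, tube, train_ann, held_out
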