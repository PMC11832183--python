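"""Trainable per-voxel segmentation of curvilinear network structures.

A random forest is trained on a multiscale filter bank computed from the raw
intensity stack, from sparse foreground/background scribbles, and applied
voxel-wise to produce a binary network mask.  A fixed-intensity threshold
baseline is provided as a comparator.

Sigmas are expressed in micrometres and converted per axis to voxel units,
so the same bank is meaningful on anisotropic stacks.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from sklearn.ensemble import RandomForestClassifier

from .stacks import CalibratedStack, LabelMask

logger = logging.getLogger(__name__)

_CLASSIFIER_FORMAT_VERSION = 1

KNOWN_FEATURES = (
    "identity",
    "gaussian",
    "difference_of_gaussians",
    "gradient_magnitude",
    "laplacian",
    "hessian_eigenvalues",
    "local_min",
    "local_max",
    "local_mean",
)

DEFAULT_FEATURES = (
    "gaussian",
    "difference_of_gaussians",
    "gradient_magnitude",
    "laplacian",
    "hessian_eigenvalues",
)


@dataclass(frozen=True)
class FeatureBankSpec:
    """Multiscale filter bank: which features, at which physical scales.

    ``sigmas_um`` default to {1, 2, 4, 8} x dx of the stack they are applied
    to (resolved at feature-computation time when left as None).
    """

    sigmas_um: tuple[float, ...] | None = None
    features: tuple[str, ...] = DEFAULT_FEATURES
    use_3d: bool = True

    def __post_init__(self) -> None:
        if self.sigmas_um is not None:
            sig = tuple(float(s) for s in self.sigmas_um)
            if any(s <= 0 for s in sig):
                raise ValueError(f"sigmas must be strictly positive, got {sig}")
            if any(b <= a for a, b in zip(sig, sig[1:])):
                raise ValueError(f"sigmas must be strictly increasing, got {sig}")
            object.__setattr__(self, "sigmas_um", sig)
        feats = tuple(self.features)
        if not feats:
            raise ValueError("feature set must be non-empty")
        unknown = set(feats) - set(KNOWN_FEATURES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}; known: {KNOWN_FEATURES}")
        object.__setattr__(self, "features", feats)

    def resolve_sigmas(self, spacing: Sequence[float]) -> tuple[float, ...]:
        if self.sigmas_um is not None:
            return self.sigmas_um
        dx = float(spacing[2])
        return tuple(dx * m for m in (1.0, 2.0, 4.0, 8.0))


@dataclass
class TrainingAnnotation:
    """Sparse voxel scribbles: coordinates with foreground/background labels."""

    coordinates: np.ndarray  # (n, 3) int, (z, y, x)
    labels: np.ndarray  # (n,) int, 1 = foreground, 0 = background

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.intp)
        labels = np.asarray(self.labels)
        if labels.dtype.kind in "US":
            labels = np.asarray([1 if l == "foreground" else 0 for l in labels])
        self.labels = labels.astype(np.int8)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array of (z, y, x)")
        if len(self.coordinates) != len(self.labels):
            raise ValueError("coordinates and labels must be parallel")

    def validate_for(self, stack: CalibratedStack) -> None:
        shape = np.asarray(stack.grid_shape)
        if (self.coordinates < 0).any() or (self.coordinates >= shape).any():
            raise ValueError("annotation coordinates fall outside the stack")
        classes = np.unique(self.labels)
        if len(classes) < 2:
            raise ValueError("both classes required: annotate foreground and background")


def _sigma_vox(sigma_um: float, spacing: Sequence[float], use_3d: bool) -> tuple[float, ...]:
    if use_3d:
        return tuple(sigma_um / s for s in spacing)
    return tuple(sigma_um / s for s in spacing[1:])


def _check_sigma(sigma_um: float, spacing: Sequence[float], use_3d: bool) -> None:
    axes = ("z", "y", "x") if use_3d else ("y", "x")
    sp = spacing if use_3d else spacing[1:]
    for ax, s in zip(axes, sp):
        if sigma_um < s / 2:
            raise ValueError(
                f"sigma {sigma_um} um is below half a voxel ({s / 2} um) along axis {ax}"
            )


def _filter_volume(img: np.ndarray, func, sigma_vox, use_3d: bool) -> np.ndarray:
    """Apply a per-volume filter in 3D, or slice-by-slice in 2D mode."""
    if use_3d:
        return func(img, sigma_vox)
    out = np.empty_like(img)
    for z in range(img.shape[0]):
        out[z] = func(img[z], sigma_vox)
    return out


def _hessian_eigs(img: np.ndarray, sigma_vox, use_3d: bool) -> list[np.ndarray]:
    def eig2(sl, sv):
        H = hessian_matrix(sl, sigma=sv, use_gaussian_derivatives=True)
        return hessian_matrix_eigvals(H)

    if use_3d:
        return list(eig2(img, sigma_vox))
    n_eig = 2
    outs = [np.empty_like(img) for _ in range(n_eig)]
    for z in range(img.shape[0]):
        ev = eig2(img[z], sigma_vox)
        for k in range(n_eig):
            outs[k][z] = ev[k]
    return outs


def _rank_size(sigma_vox) -> tuple[int, ...]:
    return tuple(max(1, 2 * int(round(s)) + 1) for s in sigma_vox)


def compute_features(
    stack: CalibratedStack, bank: FeatureBankSpec
) -> tuple[np.ndarray, list[str]]:
    """Per-voxel feature matrix for a single-channel stack.

    Returns ``(features, names)`` where ``features`` has shape
    ``(n_voxels, n_features)`` in C (z, y, x) raveling order, and feature
    order is the fixed (feature, sigma) enumeration of the bank.
    """
    if stack.voxels.ndim != 3:
        raise ValueError("compute_features expects a single-channel stack")
    # filter in float64 (float32 derivative kernels leave a constant bias),
    # store features as float32
    img = stack.voxels.astype(np.float64)
    sigmas = bank.resolve_sigmas(stack.spacing)
    for s in sigmas:
        _check_sigma(s, stack.spacing, bank.use_3d)

    planes: list[np.ndarray] = []
    names: list[str] = []
    u3 = bank.use_3d
    for feat in bank.features:
        if feat == "identity":
            planes.append(img)
            names.append("identity")
            continue
        for s_um in sigmas:
            sv = _sigma_vox(s_um, stack.spacing, u3)
            tag = f"{feat}_s{s_um:g}"
            if feat == "gaussian":
                planes.append(_filter_volume(img, ndi.gaussian_filter, sv, u3))
                names.append(tag)
            elif feat == "difference_of_gaussians":
                g1 = _filter_volume(img, ndi.gaussian_filter, sv, u3)
                sv2 = tuple(1.6 * c for c in sv)
                g2 = _filter_volume(img, ndi.gaussian_filter, sv2, u3)
                planes.append(g1 - g2)
                names.append(tag)
            elif feat == "gradient_magnitude":
                planes.append(_filter_volume(img, ndi.gaussian_gradient_magnitude, sv, u3))
                names.append(tag)
            elif feat == "laplacian":
                # truncate=6: at the default 4 sigma the truncated derivative
                # kernel does not sum to zero and biases constant regions
                lap = lambda a, s_: ndi.gaussian_laplace(a, s_, truncate=6.0)
                planes.append(_filter_volume(img, lap, sv, u3))
                names.append(tag)
            elif feat == "hessian_eigenvalues":
                eigs = _hessian_eigs(img, sv, u3)
                for k, e in enumerate(eigs):
                    planes.append(e.astype(np.float32))
                    names.append(f"{tag}_e{k}")
            elif feat == "local_min":
                planes.append(_filter_volume(img, lambda a, s_: ndi.minimum_filter(a, size=_rank_size(s_)), sv, u3))
                names.append(tag)
            elif feat == "local_max":
                planes.append(_filter_volume(img, lambda a, s_: ndi.maximum_filter(a, size=_rank_size(s_)), sv, u3))
                names.append(tag)
            elif feat == "local_mean":
                planes.append(_filter_volume(img, lambda a, s_: ndi.uniform_filter(a, size=_rank_size(s_)), sv, u3))
                names.append(tag)
    feats = np.stack([p.ravel() for p in planes], axis=1).astype(np.float32)
    return feats, names


@dataclass
class PixelClassifier:
    """A trained random-forest voxel classifier bound to its filter bank."""

    model: RandomForestClassifier
    bank: FeatureBankSpec
    n_trees: int
    seed: int
    class_names: tuple[str, str] = ("background", "foreground")
    training_spacing: tuple[float, float, float] | None = None
    training_accuracy: float | None = None

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "format_version": _CLASSIFIER_FORMAT_VERSION,
            "bank": dataclasses.asdict(self.bank),
            "n_trees": self.n_trees,
            "seed": self.seed,
            "class_names": list(self.class_names),
            "training_spacing": self.training_spacing,
            "training_accuracy": self.training_accuracy,
            "model": self.model,
        }
        joblib.dump(payload, path)
        return path

    @classmethod
    def load(cls, path: str | Path, expected_bank: FeatureBankSpec | None = None) -> "PixelClassifier":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != _CLASSIFIER_FORMAT_VERSION:
            raise ValueError(f"unsupported classifier archive version {version!r}")
        bank_dict = dict(payload["bank"])
        if bank_dict.get("sigmas_um") is not None:
            bank_dict["sigmas_um"] = tuple(bank_dict["sigmas_um"])
        bank_dict["features"] = tuple(bank_dict["features"])
        bank = FeatureBankSpec(**bank_dict)
        if expected_bank is not None and bank != expected_bank:
            raise ValueError("classifier archive bank spec does not match the expected bank")
        return cls(
            model=payload["model"],
            bank=bank,
            n_trees=payload["n_trees"],
            seed=payload["seed"],
            class_names=tuple(payload["class_names"]),
            training_spacing=tuple(payload["training_spacing"]) if payload["training_spacing"] else None,
            training_accuracy=payload["training_accuracy"],
        )


def train_classifier(
    stack: CalibratedStack,
    annotation: TrainingAnnotation,
    bank: FeatureBankSpec | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> PixelClassifier:
    """Train a random forest on the feature vectors at annotated voxels."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    bank = bank or FeatureBankSpec()
    annotation.validate_for(stack)
    feats, _ = compute_features(stack, bank)
    nz, ny, nx = stack.grid_shape
    flat_idx = np.ravel_multi_index(tuple(annotation.coordinates.T), (nz, ny, nx))
    X = feats[flat_idx]
    y = annotation.labels
    model = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed), n_jobs=1
    )
    model.fit(X, y)
    acc = float(model.score(X, y))
    logger.info(
        "trained classifier: %d fg / %d bg labels, training accuracy %.3f",
        int((y == 1).sum()), int((y == 0).sum()), acc,
    )
    return PixelClassifier(
        model=model,
        bank=bank,
        n_trees=n_trees,
        seed=int(seed),
        training_spacing=stack.spacing,
        training_accuracy=acc,
    )


def train_classifier_multi(
    stacks: Sequence[CalibratedStack],
    annotations: Sequence[TrainingAnnotation],
    bank: FeatureBankSpec | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> PixelClassifier:
    """Train one random forest on annotations pooled from several stacks."""
    if len(stacks) != len(annotations) or not stacks:
        raise ValueError("stacks and annotations must be parallel and non-empty")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    bank = bank or FeatureBankSpec()
    X_parts, y_parts = [], []
    for stack, ann in zip(stacks, annotations):
        ann.validate_for(stack)
        feats, _ = compute_features(stack, bank)
        flat_idx = np.ravel_multi_index(tuple(ann.coordinates.T), stack.grid_shape)
        X_parts.append(feats[flat_idx])
        y_parts.append(ann.labels)
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=int(seed), n_jobs=1)
    model.fit(X, y)
    return PixelClassifier(
        model=model,
        bank=bank,
        n_trees=n_trees,
        seed=int(seed),
        training_spacing=stacks[0].spacing,
        training_accuracy=float(model.score(X, y)),
    )


def predict_proba(
    stack: CalibratedStack, clf: PixelClassifier, chunk_rows: int | None = None
) -> np.ndarray:
    """Foreground posterior per voxel.  ``chunk_rows`` splits prediction into
    batches (performance only; results are identical)."""
    feats, _ = compute_features(stack, clf.bank)
    fg_col = list(clf.model.classes_).index(1)
    if chunk_rows is None:
        proba = clf.model.predict_proba(feats)[:, fg_col]
    else:
        parts = []
        for start in range(0, feats.shape[0], chunk_rows):
            parts.append(clf.model.predict_proba(feats[start : start + chunk_rows])[:, fg_col])
        proba = np.concatenate(parts)
    return proba.reshape(stack.grid_shape)


def apply_classifier(
    stack: CalibratedStack, clf: PixelClassifier, acceleration: bool = False
) -> LabelMask:
    """Classify every voxel; foreground iff posterior >= 0.5 (ties favour
    foreground, preserving thin structures).

    ``acceleration`` enables chunked prediction; masks are numerically
    identical with it on or off.
    """
    if clf.training_spacing is not None:
        ratio = np.asarray(stack.spacing) / np.asarray(clf.training_spacing)
        if (ratio > 10).any() or (ratio < 0.1).any():
            warnings.warn(
                f"stack spacing {stack.spacing} differs >10x from training spacing "
                f"{clf.training_spacing}; proceeding",
                stacklevel=2,
            )
    chunk = 262144 if acceleration else None
    proba = predict_proba(stack, clf, chunk_rows=chunk)
    mask = (proba >= 0.5).astype(np.uint8)
    return LabelMask(voxels=mask, spacing=stack.spacing, class_names={1: "foreground"})


@dataclass(frozen=True)
class ThresholdResult:
    """Voxels strictly above a fixed gray value, in counts and physical units."""

    count: int
    area_um2: float
    volume_um3: float


def fixed_threshold_area(stack: CalibratedStack, threshold: float) -> ThresholdResult:
    """Count voxels with intensity strictly greater than ``threshold``.

    The comparison is strict (value == threshold is excluded).  Area is the
    per-slice thresholded pixel area summed over slices (count x dy*dx);
    volume is count x dz*dy*dx.
    """
    if stack.voxels.ndim != 3:
        raise ValueError("fixed_threshold_area expects a single-channel stack")
    maxval = 2 ** stack.bit_depth - 1
    if not (0 <= threshold <= maxval):
        raise ValueError(f"threshold {threshold} outside {stack.bit_depth}-bit range [0, {maxval}]")
    count = int(np.count_nonzero(stack.voxels > threshold))
    dz, dy, dx = stack.spacing
    return ThresholdResult(
        count=count,
        area_um2=count * dy * dx,
        volume_um3=count * dz * dy * dx,
    )
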