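"""Synthetic tubular-network phantoms with exact ground-truth length.

Each phantom emulates one field of view of an immunolabeled, cleared-tissue
z-stack: bright curvilinear tubes (nerve fibers / vessels) over a diffuse
background, with anisotropic z sampling, Gaussian blur standing in for the
point-spread function, and additive Gaussian noise.  Tube centerlines are
persistent random walks whose polylines are pure geometry, so the total
centerline length is known exactly and independently of rasterization —
the role manual annotation plays for real stacks.

Walks reflect specularly at the domain boundary (grid box, or an ellipsoid
envelope emulating a tissue lobe); the wall-intersection point is inserted
into the polyline, so every step contributes exactly ``step_um`` of length.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stacks import CalibratedStack, LabelMask, Spacing, write_stack, write_mask


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom stack.

    Geometry is physical (micrometres); the grid is ``shape`` voxels at
    ``spacing``.  ``persistence`` in [0, 1) sets the direction correlation
    of the walk (0 = diffusive, -> 1 = ballistic).  ``envelope`` confines
    tubes to an ellipsoid with the given semiaxes (um), centered in the
    grid, and provides an exact analytic lobe volume.
    """

    shape: tuple[int, int, int] = (44, 160, 160)
    spacing: Spacing = (1.25, 1.0, 1.0)
    n_tubes: int = 6
    n_steps: int = 80
    step_um: float = 4.0
    persistence: float = 0.95
    radius_um: float = 3.0
    envelope: tuple[float, float, float] | None = None  # ellipsoid semiaxes (z, y, x) um
    min_separation_factor: float = 3.0  # min tube-center clearance, x radius_um; 0 disables
    max_turn_deg: float = 20.0  # per-step curvature cap (reflection kinks included)
    tube_intensity: float = 200.0
    background_intensity: float = 30.0
    noise_sd: float = 15.0
    psf_sigma_um: float = 0.5
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 3 for d in self.shape):
            raise ValueError(f"degenerate grid: every axis needs >= 3 voxels, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must lie in [0, 1)")
        for name in ("step_um", "radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0 or self.psf_sigma_um < 0:
            raise ValueError("noise_sd and psf_sigma_um must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def extent_um(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    @property
    def envelope_volume_um3(self) -> float | None:
        if self.envelope is None:
            return None
        a, b, c = self.envelope
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass
class PhantomTruth:
    """Exact centerline geometry of a generated phantom."""

    polylines: list[np.ndarray]  # each (k, 3) float64, physical (z, y, x) um
    total_length_um: float
    envelope_volume_um3: float | None = None
    rasterized_mask: LabelMask | None = None

    def recompute_length(self) -> float:
        """Independent per-segment length sum (consistency handle)."""
        total = 0.0
        for poly in self.polylines:
            seg = np.diff(poly, axis=0)
            total += float(np.sqrt((seg**2).sum(axis=1)).sum())
        return total


class _BoxDomain:
    def __init__(self, lo: np.ndarray, hi: np.ndarray):
        self.lo, self.hi = lo, hi

    def contains(self, p: np.ndarray) -> bool:
        return bool(np.all(p >= self.lo) and np.all(p <= self.hi))

    def inward_bias(self, p: np.ndarray, reach: float) -> np.ndarray:
        """Unit-scaled push away from faces closer than ``reach``."""
        bias = np.zeros(3)
        for a in range(3):
            d_lo = p[a] - self.lo[a]
            d_hi = self.hi[a] - p[a]
            if d_lo < reach:
                bias[a] += 1.0 - d_lo / reach
            if d_hi < reach:
                bias[a] -= 1.0 - d_hi / reach
        return bias

    def first_exit(self, p: np.ndarray, d: np.ndarray, t_max: float):
        """Smallest t in (0, t_max] where p + t*d crosses a face, with the
        inward normal there; None if the segment stays inside."""
        best_t, best_n = None, None
        for a in range(3):
            if d[a] > 0:
                t = (self.hi[a] - p[a]) / d[a]
                normal_sign = -1.0
            elif d[a] < 0:
                t = (self.lo[a] - p[a]) / d[a]
                normal_sign = 1.0
            else:
                continue
            if 0 < t <= t_max and (best_t is None or t < best_t):
                n = np.zeros(3)
                n[a] = normal_sign
                best_t, best_n = t, n
        return (best_t, best_n) if best_t is not None else None


class _EllipsoidDomain:
    def __init__(self, center: np.ndarray, semiaxes: np.ndarray):
        self.center, self.semiaxes = center, semiaxes

    def contains(self, p: np.ndarray) -> bool:
        q = (p - self.center) / self.semiaxes
        return bool((q @ q) <= 1.0 + 1e-12)

    def inward_bias(self, p: np.ndarray, reach: float) -> np.ndarray:
        q = (p - self.center) / self.semiaxes
        r = np.sqrt(q @ q)
        if r < 1e-9:
            return np.zeros(3)
        # first-order distance to the surface: (1 - r) / |grad r|
        grad = q / (r * self.semiaxes)
        dist = (1.0 - r) / np.linalg.norm(grad)
        if dist >= reach:
            return np.zeros(3)
        inward = -grad / np.linalg.norm(grad)
        return inward * (1.0 - max(dist, 0.0) / reach)

    def first_exit(self, p: np.ndarray, d: np.ndarray, t_max: float):
        q = (p - self.center) / self.semiaxes
        w = d / self.semiaxes
        a = w @ w
        b = 2.0 * (q @ w)
        c = q @ q - 1.0
        disc = b * b - 4 * a * c
        if disc < 0 or a == 0:
            return None
        t = (-b + np.sqrt(disc)) / (2 * a)  # outgoing root (c <= 0 inside)
        if not (0 < t <= t_max):
            return None
        hit = p + t * d
        n = -(hit - self.center) / self.semiaxes**2  # inward normal direction
        n = n / np.linalg.norm(n)
        return t, n


def _unit_sphere(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            return v / norm


def _advance(p: np.ndarray, d: np.ndarray, step: float, domain) -> tuple[list[np.ndarray], np.ndarray]:
    """One step of length ``step`` with specular reflection at the boundary.

    Returns the polyline points appended (wall points included) and the
    outgoing direction.  Sub-segment lengths sum exactly to ``step``.
    """
    points: list[np.ndarray] = []
    remaining = step
    for _ in range(16):
        exit_ = domain.first_exit(p, d, remaining)
        if exit_ is None:
            p = p + remaining * d
            points.append(p.copy())
            return points, d
        t, n = exit_
        p = p + t * d
        points.append(p.copy())
        remaining -= t
        d = d - 2.0 * (d @ n) * n
        d = d / np.linalg.norm(d)
        if remaining <= 1e-12:
            return points, d
        # nudge direction inward if grazing
        if d @ n < 1e-9:
            d = d + 1e-6 * n
            d = d / np.linalg.norm(d)
    # pathological corner: stop the step at the boundary
    return points, d


def _make_domain(spec: PhantomSpec):
    extent = spec.extent_um
    margin = np.minimum(spec.radius_um, extent / 4)
    lo, hi = margin, extent - margin
    if spec.envelope is not None:
        return _EllipsoidDomain(extent / 2.0, np.asarray(spec.envelope, dtype=float))
    return _BoxDomain(lo, hi)


def grow_network(spec: PhantomSpec) -> PhantomTruth:
    """Grow persistent-random-walk tube centerlines, reproducibly from the seed.

    Two geometric guards keep the phantom valid for length validation:

    * a minimum center-to-center clearance of ``min_separation_factor x
      radius_um`` between tubes and against the tube's own earlier course
      (beyond a short trailing window) — fused tubes would make the mask
      under-count the exact polyline ground truth;
    * a per-step turn cap ``max_turn_deg`` that also applies to the kink a
      wall reflection realizes, so bends stay shallow relative to the tube
      radius (steep approaches to the boundary are re-drawn: the walk grazes
      the wall instead of folding back through itself).

    Steps violating either guard are re-drawn; a tube that runs out of
    admissible directions ends early, its exact polyline length still
    entering the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    domain = _make_domain(spec)
    extent = spec.extent_um
    clearance = spec.min_separation_factor * spec.radius_um
    cos_cap = np.cos(np.radians(spec.max_turn_deg))
    # points of the own tube closer along the course than the trailing
    # window are allowed nearby (consecutive steps are always "close")
    window = int(np.ceil(2.0 * clearance / spec.step_um)) + 1
    occupied: list[np.ndarray] = []  # step points of finished tubes
    polylines: list[np.ndarray] = []

    def clear_of(points: list[np.ndarray], own: list[np.ndarray]) -> bool:
        if clearance <= 0:
            return True
        for p in points:
            for arr in occupied:
                if np.min(np.sqrt(((arr - p) ** 2).sum(axis=1))) < clearance:
                    return False
            if len(own) > window:
                past = np.asarray(own[: len(own) - window])
                if np.min(np.sqrt(((past - p) ** 2).sum(axis=1))) < clearance:
                    return False
        return True

    def turns_ok(p0: np.ndarray, d_in: np.ndarray | None, new_pts: list[np.ndarray]) -> bool:
        segs = np.diff(np.asarray([p0] + new_pts), axis=0)
        lens = np.linalg.norm(segs, axis=1)
        keep = lens > 1e-9
        segs = segs[keep] / lens[keep][:, None]
        dirs = ([d_in] if d_in is not None else []) + list(segs)
        return all(a @ b >= cos_cap for a, b in zip(dirs, dirs[1:]))

    reach = 2.0 * spec.step_um  # boundary-avoidance horizon
    sin_cap = np.sqrt(1.0 - cos_cap**2)

    def start_point() -> np.ndarray | None:
        placed_inside = False
        for _ in range(10000):
            p = rng.uniform(0, 1, size=3) * extent
            if not domain.contains(p):
                continue
            placed_inside = True
            if clear_of([p], own=[p]):
                return p
        if not placed_inside:
            raise RuntimeError("could not place a tube start inside the domain")
        return None  # domain has no clear room left

    for _ in range(spec.n_tubes):
        budget = spec.n_steps
        while budget > 0:
            p = start_point()
            if p is None:
                break  # grid saturated: remaining budget is forfeited
            d = _unit_sphere(rng)
            d_in = None  # no turn constraint on the very first step
            pts = [p.copy()]
            step_pts = [p.copy()]  # one entry per step (wall points excluded)
            while budget > 0:
                accepted = None
                bias = domain.inward_bias(p, reach)
                for _attempt in range(60):
                    u = _unit_sphere(rng)
                    d_try = spec.persistence * d + (1.0 - spec.persistence) * u + bias
                    norm = np.linalg.norm(d_try)
                    d_try = d_try / norm if norm > 1e-12 else _unit_sphere(rng)
                    if d_in is not None and d_try @ d_in < cos_cap:
                        # project the candidate back onto the turn cone
                        perp = d_try - (d_try @ d_in) * d_in
                        n_perp = np.linalg.norm(perp)
                        if n_perp < 1e-12:
                            continue
                        d_try = cos_cap * d_in + sin_cap * perp / n_perp
                    new_pts, d_out = _advance(p, d_try, spec.step_um, domain)
                    if turns_ok(p, d_in, new_pts) and clear_of(new_pts, own=step_pts):
                        accepted = (new_pts, d_out)
                        break
                if accepted is None:
                    break  # fiber segment ends: boxed in; restart elsewhere
                new_pts, d = accepted
                seg_last = new_pts[-1] - (new_pts[-2] if len(new_pts) > 1 else p)
                nrm = np.linalg.norm(seg_last)
                d_in = seg_last / nrm if nrm > 1e-9 else d
                pts.extend(new_pts)
                p = pts[-1]
                step_pts.append(p.copy())
                budget -= 1
            if len(pts) > 1:
                polylines.append(np.asarray(pts))
                occupied.append(np.asarray(step_pts))
            else:
                budget -= 1  # isolated start with no room: spend a step, move on

    total = 0.0
    for poly in polylines:
        seg = np.diff(poly, axis=0)
        total += float(np.sqrt((seg**2).sum(axis=1)).sum())
    return PhantomTruth(
        polylines=polylines,
        total_length_um=total,
        envelope_volume_um3=spec.envelope_volume_um3,
    )


def rasterize(truth: PhantomTruth, spec: PhantomSpec) -> tuple[CalibratedStack, LabelMask]:
    """Render the centerlines as an intensity stack plus the true tube mask.

    The mask is every voxel whose center lies within ``radius_um`` of a
    centerline (anisotropy-aware Euclidean distance via a distance
    transform sampled at the voxel spacing).  The intensity stack is
    background + tube plateau, blurred at ``psf_sigma_um``, plus Gaussian
    noise, clipped to the bit depth.
    """
    spacing = np.asarray(spec.spacing)
    if spec.radius_um < max(spacing) / 2:
        import warnings

        warnings.warn(
            f"tube radius {spec.radius_um} um is below half the largest voxel "
            f"dimension ({max(spacing) / 2} um); tubes may disconnect across slices"
        )
    centerline = np.zeros(spec.shape, dtype=bool)
    ds = min(spec.spacing) / 3.0
    for poly in truth.polylines:
        seg = np.diff(poly, axis=0)
        seg_len = np.sqrt((seg**2).sum(axis=1))
        for k in range(len(seg)):
            n_samp = max(2, int(np.ceil(seg_len[k] / ds)) + 1)
            ts = np.linspace(0.0, 1.0, n_samp)
            pts = poly[k] + ts[:, None] * seg[k]
            idx = np.round(pts / spacing).astype(int)
            np.clip(idx, 0, np.asarray(spec.shape) - 1, out=idx)
            centerline[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    dist = ndi.distance_transform_edt(~centerline, sampling=spec.spacing)
    mask = dist <= spec.radius_um

    img = np.full(spec.shape, spec.background_intensity, dtype=np.float64)
    img[mask] = spec.tube_intensity
    if spec.psf_sigma_um > 0:
        img = ndi.gaussian_filter(img, sigma=spec.psf_sigma_um / spacing)
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng((spec.seed + 1) % 2**31)
        img = img + noise_rng.normal(0.0, spec.noise_sd, size=spec.shape)
    maxval = 2**spec.bit_depth - 1
    img = np.clip(np.round(img), 0, maxval)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    stack = CalibratedStack(
        voxels=img.astype(dtype),
        spacing=spec.spacing,
        bit_depth=spec.bit_depth,
        name=f"phantom_seed{spec.seed}",
    )
    mask_out = LabelMask(
        voxels=mask.astype(np.uint8), spacing=spec.spacing, class_names={1: "tube"}
    )
    truth.rasterized_mask = mask_out
    return stack, mask_out


def annotation_from_truth(
    mask: LabelMask,
    radius_um: float,
    n_per_class: int = 300,
    seed: int = 0,
):
    """Sparse training scribbles derived from the true tube mask.

    Emulates a user marking foreground strokes inside tubes (voxels well
    inside the tube: distance-from-background > 0.2 x radius) and background
    strokes both right next to the structures (annulus 0.5-1.5 x radius
    outside the surface) and in the far background, the way scribbles are
    placed in interactive training.
    """
    from .segmentation import TrainingAnnotation

    rng = np.random.default_rng(seed)
    inside = ndi.distance_transform_edt(mask.binary, sampling=mask.spacing)
    outside = ndi.distance_transform_edt(~mask.binary, sampling=mask.spacing)
    fg_pool = np.argwhere(inside > 0.2 * radius_um)
    near_pool = np.argwhere((outside > 0.5 * radius_um) & (outside <= 1.5 * radius_um))
    far_pool = np.argwhere(outside > 1.5 * radius_um)
    if len(fg_pool) == 0 or (len(near_pool) + len(far_pool)) == 0:
        raise ValueError("mask too sparse/dense to derive both annotation classes")
    fg = fg_pool[rng.choice(len(fg_pool), size=min(n_per_class, len(fg_pool)), replace=False)]
    n_near = min(n_per_class // 2, len(near_pool))
    n_far = min(n_per_class - n_near, len(far_pool))
    bg_parts = []
    if n_near:
        bg_parts.append(near_pool[rng.choice(len(near_pool), size=n_near, replace=False)])
    if n_far:
        bg_parts.append(far_pool[rng.choice(len(far_pool), size=n_far, replace=False)])
    bg = np.concatenate(bg_parts)
    coords = np.concatenate([fg, bg])
    labels = np.concatenate([np.ones(len(fg), dtype=np.int8), np.zeros(len(bg), dtype=np.int8)])
    return TrainingAnnotation(coordinates=coords, labels=labels)


@dataclass
class ValidationStack:
    name: str
    role: str  # "train" | "validation"
    spec: PhantomSpec
    stack: CalibratedStack
    mask: LabelMask
    truth: PhantomTruth


def _derive_seed(seed: int, i: int) -> int:
    return int((seed * 1000003 + 7919 * i + 1) % (2**31 - 1))


def make_validation_set(
    n_stacks: int = 10,
    template: PhantomSpec | None = None,
    seed: int = 0,
    n_train: int = 2,
    out_dir: str | Path | None = None,
) -> tuple[list[ValidationStack], pd.DataFrame]:
    """A reproducible phantom set with a designated train/validation split.

    Defaults mirror the evaluation design used on real tissue: 10 stacks,
    the first ``n_train`` = 2 reserved for classifier training and the
    remaining 8 for validation.  Tube count varies deterministically across
    validation stacks so that true lengths span a usable range for
    regression.
    """
    if n_stacks < 2:
        raise ValueError("need at least 2 stacks (one train, one validation)")
    if not (1 <= n_train < n_stacks):
        raise ValueError("n_train must be >= 1 and leave at least one validation stack")
    template = template or PhantomSpec()
    tube_cycle = (3, 9, 4, 8, 5, 10, 6, 7)
    items: list[ValidationStack] = []
    rows = []
    for i in range(n_stacks):
        role = "train" if i < n_train else "validation"
        n_tubes = template.n_tubes if role == "train" else tube_cycle[(i - n_train) % len(tube_cycle)]
        spec_i = PhantomSpec(
            **{
                **template.__dict__,
                "n_tubes": n_tubes,
                "seed": _derive_seed(seed, i),
            }
        )
        truth = grow_network(spec_i)
        stack, mask = rasterize(truth, spec_i)
        name = f"phantom_{i:02d}"
        stack.name = name
        items.append(
            ValidationStack(name=name, role=role, spec=spec_i, stack=stack, mask=mask, truth=truth)
        )
        rows.append(
            {
                "name": name,
                "role": role,
                "n_tubes": n_tubes,
                "seed": spec_i.seed,
                "total_length_um": truth.total_length_um,
                "envelope_volume_um3": truth.envelope_volume_um3,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for it in items:
            write_stack(it.stack, out_dir / f"{it.name}.tif")
            write_mask(it.mask, out_dir / f"{it.name}_truthmask.tif")
        manifest.to_csv(out_dir / "truth_manifest.csv", index=False)
    return items, manifest


def stack_digest(stack: CalibratedStack) -> str:
    """Content hash of the voxel grid (distinctness checks in tests)."""
    return hashlib.sha256(np.ascontiguousarray(stack.voxels).tobytes()).hexdigest()
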