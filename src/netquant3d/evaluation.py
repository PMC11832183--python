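"""Validation harness: automated vs reference length measurements.

Automated network lengths are compared against a reference (manual
annotation on real data; exact centerline geometry on phantoms) by ordinary
least squares of measured on reference, reporting slope, intercept, r^2
(squared Pearson correlation, which for OLS with intercept coincides with
the coefficient of determination), and the mean absolute error in the input
unit.  The intercept is never forced through zero, so additive bias remains
visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .segmentation import fixed_threshold_area
from .stacks import CalibratedStack


@dataclass
class PairedMeasurements:
    reference: np.ndarray
    measured: np.ndarray
    units: str = "um"

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.measured = np.asarray(self.measured, dtype=float)
        if self.reference.shape != self.measured.shape or self.reference.ndim != 1:
            raise ValueError("reference and measured must be parallel 1D lists")
        if len(self.reference) < 2:
            raise ValueError("need at least 2 paired measurements")
        if (self.reference < 0).any() or (self.measured < 0).any():
            raise ValueError("measurements must be non-negative")


@dataclass(frozen=True)
class RegressionReport:
    slope: float
    intercept: float
    r_squared: float
    mean_absolute_error: float
    n: int


def regress_paired(pm: PairedMeasurements) -> RegressionReport:
    """OLS of measured on reference, with r^2 and MAE."""
    if np.ptp(pm.reference) == 0:
        raise ValueError("degenerate regression: reference values are constant")
    res = stats.linregress(pm.reference, pm.measured)
    mae = float(np.mean(np.abs(pm.measured - pm.reference)))
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        mean_absolute_error=mae,
        n=len(pm.reference),
    )


@dataclass(frozen=True)
class SpreadResult:
    mean: float
    deviations: tuple[float, ...]
    mean_absolute_deviation: float


def annotator_spread(values: Sequence[float]) -> SpreadResult:
    """Per-annotator absolute error to the group mean, and its average.

    Quantifies how far independent measurements of one and the same stack
    scatter around their mean.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need at least 2 independent measurements")
    mean = float(values.mean())
    dev = np.abs(values - mean)
    return SpreadResult(
        mean=mean,
        deviations=tuple(float(d) for d in dev),
        mean_absolute_deviation=float(dev.mean()),
    )


def baseline_threshold_predictor(
    stacks: Sequence[CalibratedStack],
    reference_lengths: Sequence[float],
    threshold: float = 170,
) -> PairedMeasurements:
    """Fixed-threshold comparator: thresholded area as a length predictor.

    Pairs each stack's reference length with the area of voxels strictly
    above ``threshold``.  Reference and predictor carry different units
    (length vs area), so only r^2 of the subsequent regression is
    meaningful, not slope or MAE.
    """
    if len(stacks) != len(reference_lengths):
        raise ValueError("stacks and reference lengths must be parallel")
    areas = [fixed_threshold_area(s, threshold).area_um2 for s in stacks]
    return PairedMeasurements(
        reference=np.asarray(reference_lengths, dtype=float),
        measured=np.asarray(areas, dtype=float),
        units="um_vs_um2",
    )


def plot_regression(
    pm: PairedMeasurements, report: RegressionReport, path: str | Path, title: str | None = None
) -> Path:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pm.reference, pm.measured, color="tab:blue", zorder=3)
    xs = np.linspace(0, pm.reference.max() * 1.05, 50)
    ax.plot(xs, report.slope * xs + report.intercept, "k-", lw=1)
    ax.plot(xs, xs, "k--", lw=0.8, alpha=0.5, label="identity")
    ax.set_xlabel(f"reference [{pm.units}]")
    ax.set_ylabel(f"measured [{pm.units}]")
    ax.set_title(title or f"r² = {report.r_squared:.3f}, MAE = {report.mean_absolute_error:.3g}")
    ax.legend()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
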