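"""Population-level assay statistics for reporter screens.

Percent-positive cells against a control-derived cut-off, trapezoidal AUC of
summary time courses, signal-over-background, and the Z' screening-quality
factor Z' = 1 - 3 (sd_pos + sd_neg) / |avg_pos - avg_neg| (an excellent
assay has s/b > 2 and Z' > 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSeparationError


@dataclass(frozen=True)
class ScreenStats:
    """Positive/negative control moments and derived assay quality."""

    avg_pos: float
    avg_neg: float
    sd_pos: float
    sd_neg: float
    s_over_b: float
    z_prime: float

    def to_dict(self) -> dict:
        return {
            "avg_pos": self.avg_pos,
            "avg_neg": self.avg_neg,
            "sd_pos": self.sd_pos,
            "sd_neg": self.sd_neg,
            "s_over_b": self.s_over_b,
            "z_prime": self.z_prime,
        }


@dataclass(frozen=True)
class TimeCourse:
    """A per-timepoint summary statistic (times in hours)."""

    t: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("t and value must be 1-D vectors of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")


def positivity_cutoff(control_intensities, quantile: float = 0.995) -> float:
    """Empirical quantile of the unstimulated-control intensity distribution.

    Linear interpolation between order statistics; requires at least 20
    control values so the tail quantile is meaningful.
    """
    values = np.asarray(control_intensities, dtype=float)
    if values.size < 20:
        raise ValueError(f"need >= 20 control values, got {values.size}")
    if not (0.0 <= quantile <= 1.0):
        raise ValueError("quantile must lie in [0, 1]")
    return float(np.quantile(values, quantile))


def percent_positive(intensities, cutoff: float) -> float:
    """Percentage of intensities strictly above the cut-off."""
    values = np.asarray(intensities, dtype=float)
    if values.size == 0:
        raise ValueError("empty intensity list")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return 100.0 * float(np.count_nonzero(values > cutoff)) / values.size


def auc(tc: TimeCourse) -> float:
    """Trapezoidal area under the time course over its observed span."""
    if tc.t.size < 2:
        raise ValueError("need at least 2 time points")
    return float(np.trapezoid(tc.value, tc.t))


def signal_over_background(stim_mean: float, ctrl_mean: float) -> float:
    """Mean stimulated intensity divided by mean unstimulated intensity."""
    if ctrl_mean <= 0:
        raise ValueError("control mean must be > 0")
    return float(stim_mean) / float(ctrl_mean)


def z_prime(pos_values, neg_values) -> ScreenStats:
    """Z' factor of a screen from positive- and negative-control values.

    Uses sample standard deviations (n-1 denominator).  Z' is invariant
    under any positive affine rescaling applied to both groups.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 values per group")
    avg_pos, avg_neg = float(pos.mean()), float(neg.mean())
    if avg_pos == avg_neg:
        raise DegenerateSeparationError("positive and negative means coincide")
    sd_pos = float(pos.std(ddof=1))
    sd_neg = float(neg.std(ddof=1))
    z = 1.0 - 3.0 * (sd_pos + sd_neg) / abs(avg_pos - avg_neg)
    s_b = avg_pos / avg_neg if avg_neg > 0 else float("nan")
    return ScreenStats(avg_pos, avg_neg, sd_pos, sd_neg, s_b, z)


def confluency_corrected(total_intensity: float, cell_count: float) -> float:
    """Field fluorescence divided by simulated cell count.

    A stand-in for confluency normalization of plate-imager fluorescence:
    the simulator has no confluency readout, so the per-field cell count
    plays that role.
    """
    if cell_count <= 0:
        raise ValueError("cell_count must be > 0")
    return float(total_intensity) / float(cell_count)
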