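"""Osmotic-swelling quantification: diameter ratio d/d0, ratio at a
timepoint, and area under the curve over the first 20 minutes.

Cells under hypotonic shock swell; the per-cell readout is the diameter of
a manual circular ROI every 30 s.  All diameters are normalized by the
initial diameter d0, and the early response is summarized by the AUC over
the first 20 min — by default of (ratio − 1), so an isotonic control with a
flat ratio of 1 integrates to exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SwellingTrace", "SwellingSummary", "diameter_ratio", "auc_first_20min", "ratio_at", "summarize_swelling"]


@dataclass(frozen=True)
class SwellingTrace:
    times_min: np.ndarray
    diameter_um: np.ndarray
    condition: str = "HYPO"  # ISO / HYPO / EXTREME

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        d = np.asarray(self.diameter_um, dtype=float)
        if t.shape != d.shape or t.ndim != 1 or t.size < 1:
            raise ValueError("times and diameters must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(d <= 0):
            raise ValueError("diameters must be positive")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "diameter_um", d)

    @property
    def d0_um(self) -> float:
        return float(self.diameter_um[0])


@dataclass(frozen=True)
class SwellingSummary:
    condition: str
    d0_um: float
    ratio_at_15min: float
    auc_0_20min: float
    baseline_subtracted: bool


def diameter_ratio(trace: SwellingTrace) -> np.ndarray:
    """ratio[t] = d[t]/d0; the first sample is exactly 1."""
    return trace.diameter_um / trace.d0_um


def auc_first_20min(trace: SwellingTrace, baseline_subtracted: bool = True) -> float:
    """Trapezoidal AUC of the ratio over [0, 20] min.

    Default integrates (ratio − 1) in ratio·min so a constant trace gives 0;
    ``baseline_subtracted=False`` integrates the raw ratio.  The 20-min
    endpoint is linearly interpolated if it falls between samples.
    """
    t = trace.times_min
    if t[-1] < 20.0 - 1e-9:
        raise ValueError(f"trace spans only {t[-1]:.2f} min; need >= 20 min")
    ratio = diameter_ratio(trace)
    y = ratio - 1.0 if baseline_subtracted else ratio
    # resample onto [0, 20] with an interpolated endpoint
    inside = t <= 20.0 + 1e-12
    tt = t[inside]
    yy = y[inside]
    if tt[-1] < 20.0:
        tt = np.append(tt, 20.0)
        yy = np.append(yy, np.interp(20.0, t, y))
    return float(np.trapezoid(yy, tt))


def ratio_at(trace: SwellingTrace, t_min: float = 15.0) -> float:
    """Linearly interpolated d/d0 at ``t_min`` minutes (default 15)."""
    t = trace.times_min
    if not (t[0] - 1e-12 <= t_min <= t[-1] + 1e-12):
        raise ValueError(f"time {t_min} min outside trace span [{t[0]}, {t[-1]}]")
    return float(np.interp(t_min, t, diameter_ratio(trace)))


def summarize_swelling(trace: SwellingTrace, baseline_subtracted: bool = True) -> SwellingSummary:
    return SwellingSummary(
        condition=trace.condition,
        d0_um=trace.d0_um,
        ratio_at_15min=ratio_at(trace, 15.0),
        auc_0_20min=auc_first_20min(trace, baseline_subtracted),
        baseline_subtracted=baseline_subtracted,
    )
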