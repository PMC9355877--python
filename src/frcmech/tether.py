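"""Optical-tweezer tether mechanics: trap calibration and tether force.

The trap stiffness k is calibrated by equipartition from the positional
fluctuations of a stationary trapped bead: k = k_B·T / Var(x).  A membrane
tether pulled from the cell displaces the bead from the trap center by Δx,
and the tether force is F_T = k·Δx (pN = pN/nm × nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

K_B_PN_NM_PER_K = 0.0138065  # pN·nm/K

__all__ = [
    "BeadTrack",
    "TrapCalibration",
    "TetherForceResult",
    "calibrate_equipartition",
    "detect_tether_windows",
    "tether_force",
    "K_B_PN_NM_PER_K",
]


@dataclass(frozen=True)
class BeadTrack:
    """1-D bead position along the pull axis, sampled every 90 ms by default."""

    times_s: np.ndarray
    position_nm: np.ndarray
    temperature_K: float = 310.15

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        x = np.asarray(self.position_nm, dtype=float)
        if t.shape != x.shape or t.ndim != 1:
            raise ValueError("times and positions must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "position_nm", x)

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class TrapCalibration:
    k_pN_per_nm: float
    variance_nm2: float
    n_samples: int
    temperature_K: float
    method: str = "equipartition"


@dataclass(frozen=True)
class TetherForceResult:
    delta_x_nm: float
    force_pN: float
    k_pN_per_nm: float
    baseline_window: tuple[int, int]
    plateau_window: tuple[int, int]
    flags: tuple[str, ...] = ()


def calibrate_equipartition(
    track: BeadTrack, window: tuple[int, int] | None = None
) -> TrapCalibration:
    """Trap stiffness from equipartition: k = k_B·T / Var(position).

    ``window`` restricts calibration to a tether-free, stationary stretch
    (half-open frame range); the whole track is used by default.  Requires
    at least 100 samples; a zero-variance (constant) trace is degenerate.
    """
    x = track.position_nm if window is None else track.position_nm[window[0]:window[1]]
    if x.size < 100:
        raise ValueError(f"calibration needs >= 100 samples, got {x.size}")
    var = float(np.var(x, ddof=1))
    if var == 0.0:
        raise ValueError("positional variance is zero; trace is degenerate")
    k = K_B_PN_NM_PER_K * track.temperature_K / var
    return TrapCalibration(k_pN_per_nm=k, variance_nm2=var,
                           n_samples=int(x.size), temperature_K=track.temperature_K)


def detect_tether_windows(
    track: BeadTrack,
    guard_frames: int = 3,
    min_window: int = 10,
    min_effect_sd: float = 3.0,
) -> tuple[tuple[int, int], tuple[int, int], tuple[str, ...]]:
    """Locate the tether-pull step and return (baseline, plateau, flags).

    The change point maximizes the between-window mean separation relative
    to the pooled within-window standard deviation.  Windows exclude a guard
    band of ``guard_frames`` around the step.  If the best step is smaller
    than ``min_effect_sd`` pooled SDs the trace is flagged ``no_step``; a
    secondary step inside the plateau flags ``multi_step`` and truncates the
    plateau before it (the first step is kept).
    """
    x = track.position_nm
    n = x.size
    if n < 2 * min_window:
        raise ValueError("track too short for step detection")

    def best_split(seg: np.ndarray) -> tuple[int, float]:
        best_i, best_score = -1, -np.inf
        for i in range(min_window, seg.size - min_window + 1):
            left, right = seg[:i], seg[i:]
            pooled = np.sqrt((left.var(ddof=1) * (left.size - 1)
                              + right.var(ddof=1) * (right.size - 1))
                             / (left.size + right.size - 2))
            if pooled == 0:
                pooled = np.finfo(float).tiny
            score = abs(right.mean() - left.mean()) / pooled
            if score > best_score:
                best_i, best_score = i, score
        return best_i, best_score

    split, score = best_split(x)
    flags: list[str] = []
    if score < min_effect_sd:
        flags.append("no_step")
        return (0, n // 2), (n // 2, n), tuple(flags)
    # with multiple steps the global split can land on a later one; walk left
    # to the earliest significant step so the first step defines the plateau
    while split >= 2 * min_window:
        split2, score2 = best_split(x[:split])
        if score2 >= min_effect_sd:
            split = split2
            flags.append("multi_step")
        else:
            break
    baseline = (0, max(split - guard_frames, min_window))
    plateau_start = min(split + guard_frames, n - min_window)
    plateau_end = n
    # look for a second step inside the plateau
    plateau_seg = x[plateau_start:plateau_end]
    if plateau_seg.size >= 2 * min_window:
        split2, score2 = best_split(plateau_seg)
        if score2 >= min_effect_sd:
            flags.append("multi_step")
            plateau_end = plateau_start + max(split2 - guard_frames, min_window)
    return baseline, (plateau_start, plateau_end), tuple(dict.fromkeys(flags))


def tether_force(
    track: BeadTrack,
    calibration: TrapCalibration,
    windows: tuple[tuple[int, int], tuple[int, int]],
    flags: tuple[str, ...] = (),
) -> TetherForceResult:
    """F_T = k·Δx with Δx = |mean(plateau) − mean(baseline)| in nm."""
    (b0, b1), (p0, p1) = windows
    n = len(track)
    for lo, hi in ((b0, b1), (p0, p1)):
        if not (0 <= lo < hi <= n):
            raise ValueError(f"window ({lo}, {hi}) outside track of length {n}")
    if max(b0, p0) < min(b1, p1):
        raise ValueError("baseline and plateau windows overlap")
    delta_x = abs(float(track.position_nm[p0:p1].mean())
                  - float(track.position_nm[b0:b1].mean()))
    return TetherForceResult(
        delta_x_nm=delta_x,
        force_pN=calibration.k_pN_per_nm * delta_x,
        k_pN_per_nm=calibration.k_pN_per_nm,
        baseline_window=(b0, b1),
        plateau_window=(p0, p1),
        flags=tuple(flags),
    )
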