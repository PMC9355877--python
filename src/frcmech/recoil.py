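"""Laser-ablation recoil: landmark displacement, initial velocity, curve fits.

After a line cut through the network, tension is read out from how fast two
landmarks on either side of the cut separate.  The displacement trace is the
change in landmark separation relative to the pre-cut baseline; the initial
recoil velocity is the displacement one frame after the cut divided by the
frame interval (0.521 s per frame by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FRAME_INTERVAL_S = 0.521

__all__ = [
    "RecoilTrace",
    "RecoilSummary",
    "FRAME_INTERVAL_S",
    "displacement_from_landmarks",
    "initial_recoil_velocity",
    "fit_recoil",
    "mean_recoil_curve",
]


@dataclass(frozen=True)
class RecoilTrace:
    times_s: np.ndarray
    displacement_um: np.ndarray
    cut_index: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        d = np.asarray(self.displacement_um, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("times and displacement must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (0 <= self.cut_index < t.size):
            raise ValueError(f"cut_index {self.cut_index} out of range")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "displacement_um", d)

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.times_s)))

    @property
    def post_cut_times_s(self) -> np.ndarray:
        """Times relative to the cut for post-cut frames (cut frame = Δt)."""
        return self.times_s[self.cut_index:] - (
            self.times_s[self.cut_index] - self.frame_interval_s
        )


@dataclass(frozen=True)
class RecoilSummary:
    v0_um_per_s: float
    plateau_um: float
    A_um: float | None = None
    tau_s: float | None = None
    residual_rms_um: float | None = None
    fit_flag: str = "ok"


def displacement_from_landmarks(
    track_a: np.ndarray,
    track_b: np.ndarray,
    cut_index: int,
    times_s: np.ndarray | None = None,
    frame_interval_s: float = FRAME_INTERVAL_S,
    baseline: str = "mean",
) -> RecoilTrace:
    """Separation change between two landmark tracks, baseline-referenced.

    ``track_a``/``track_b`` are (n, 2) position arrays in µm.  The baseline
    is the mean pre-cut separation (``baseline="mean"``, default) or the
    separation at the last pre-cut frame (``baseline="last"``).
    """
    a = np.atleast_2d(np.asarray(track_a, dtype=float))
    b = np.atleast_2d(np.asarray(track_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"landmark tracks differ in shape: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if not (1 <= cut_index < n):
        raise ValueError(f"cut_index must be in [1, {n}), got {cut_index}")
    sep = np.linalg.norm(a - b, axis=1)
    if baseline == "mean":
        base = sep[:cut_index].mean()
    elif baseline == "last":
        base = sep[cut_index - 1]
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    if times_s is None:
        times_s = np.arange(n) * frame_interval_s
    return RecoilTrace(times_s=np.asarray(times_s, float),
                       displacement_um=sep - base, cut_index=cut_index)


def initial_recoil_velocity(trace: RecoilTrace) -> float:
    """v₀ = displacement at the first post-cut frame / frame interval (µm/s)."""
    if trace.cut_index >= trace.times_s.size:
        raise ValueError("trace has no post-cut frames")
    return float(trace.displacement_um[trace.cut_index] / trace.frame_interval_s)


def fit_recoil(trace: RecoilTrace) -> RecoilSummary:
    """Least-squares fit of d(t) = A·(1 − e^(−t/τ)) to the post-cut trace.

    Times are measured from the cut (the first post-cut frame sits at one
    frame interval).  Non-convergence or an unidentifiable τ (flat trace)
    is flagged; the raw trace remains usable either way.
    """
    from scipy.optimize import curve_fit

    d = trace.displacement_um[trace.cut_index:]
    t = trace.post_cut_times_s
    if d.size < 5:
        raise ValueError("need at least 5 post-cut frames to fit")
    v0 = initial_recoil_velocity(trace)
    plateau = float(d[-1])

    def model(t, A, tau):
        return A * (1.0 - np.exp(-t / tau))

    if np.allclose(d, 0.0):
        return RecoilSummary(v0, plateau, A_um=0.0, tau_s=None,
                             residual_rms_um=0.0, fit_flag="tau_unidentifiable")
    a0 = max(float(d.max()), 1e-6)
    tau0 = max(float(t[-1]) / 3.0, trace.frame_interval_s)
    try:
        popt, _ = curve_fit(model, t, d, p0=(a0, tau0),
                            bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=10_000)
    except RuntimeError:
        return RecoilSummary(v0, plateau, fit_flag="no_convergence")
    resid = d - model(t, *popt)
    return RecoilSummary(v0, plateau, A_um=float(popt[0]), tau_s=float(popt[1]),
                         residual_rms_um=float(np.sqrt(np.mean(resid**2))))


def mean_recoil_curve(traces: list[RecoilTrace]) -> dict:
    """Pointwise mean ± SEM of post-cut displacement on a common time grid."""
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    grids = [tr.post_cut_times_s for tr in traces]
    n_common = min(g.size for g in grids)
    ref = grids[0][:n_common]
    for g in grids[1:]:
        if not np.allclose(g[:n_common], ref, rtol=0, atol=1e-9):
            raise ValueError("traces are not on a common post-cut time grid")
    stackd = np.stack([tr.displacement_um[tr.cut_index:tr.cut_index + n_common]
                       for tr in traces])
    mean = stackd.mean(axis=0)
    sem = stackd.std(axis=0, ddof=1) / np.sqrt(stackd.shape[0])
    return {"times_s": ref, "mean_um": mean, "sem_um": sem, "n": stackd.shape[0]}
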