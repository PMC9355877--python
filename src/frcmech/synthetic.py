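"""Synthetic-data generators with exact ground truth for every pipeline stage.

Each generator is a pure function of its truth parameters and seed: identical
inputs give identical outputs, and the truth object retains everything needed
to score the downstream measurement exactly.  The generators emulate the
input classes the quantification stages consume:

* fibrous network images with controllable mesh size (gap analysis),
* nuclei fields with controllable density and spacing (packing density),
* two-landmark recoil displacement traces sampled at 0.521 s over 25 s,
* trapped-bead position traces sampled at 90 ms with a tether-pull step,
* cell-diameter swelling traces sampled every 30 s,
* nuclei time-lapse detections with division events at a controlled rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from frcmech.core import CalibratedImage2D

K_B_PN_NM_PER_K = 0.0138065  # Boltzmann constant in pN·nm/K

__all__ = [
    "NetworkImageTruth",
    "NucleiFieldTruth",
    "RecoilTruth",
    "BeadTraceTruth",
    "SwellingTruth",
    "DivisionMovieTruth",
    "make_network_image",
    "make_nuclei_image",
    "make_recoil_trace",
    "make_landmark_tracks",
    "make_bead_trace",
    "make_swelling_trace",
    "make_division_movie",
    "K_B_PN_NM_PER_K",
]


# ---------------------------------------------------------------------------
# network images (gap analysis input)


@dataclass(frozen=True)
class NetworkImageTruth:
    """Fibrous-network image parameters: jittered square-lattice edges.

    The rendered foreground is the dilation of the edge segments by the
    fiber width; the ground-truth free-space mask is its complement.
    """

    shape: tuple[int, int] = (256, 256)
    spacing_px: float = 20.0
    jitter_px: float = 3.0
    fiber_width_px: int = 3
    pixel_size_um: float = 0.5
    blur_sigma_px: float = 0.7
    photon_scale: float = 100.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fiber_width_px < 1:
            raise ValueError("fiber_width_px must be >= 1")
        if self.spacing_px <= 2:
            raise ValueError("spacing_px must exceed 2 px")


def _lattice_segments(truth: NetworkImageTruth, rng: np.random.Generator):
    """Jittered square-lattice node grid; edges join 4-neighbours."""
    h, w = truth.shape
    nr = int(math.floor(h / truth.spacing_px)) + 1
    nc = int(math.floor(w / truth.spacing_px)) + 1
    base_r = np.arange(nr)[:, None] * truth.spacing_px
    base_c = np.arange(nc)[None, :] * truth.spacing_px
    jr = rng.uniform(-truth.jitter_px, truth.jitter_px, size=(nr, nc))
    jc = rng.uniform(-truth.jitter_px, truth.jitter_px, size=(nr, nc))
    nodes_r = np.clip(base_r + jr, 0, h - 1)
    nodes_c = np.clip(base_c + jc, 0, w - 1)
    segments = []
    for i in range(nr):
        for j in range(nc):
            if j + 1 < nc:
                segments.append(((nodes_r[i, j], nodes_c[i, j]), (nodes_r[i, j + 1], nodes_c[i, j + 1])))
            if i + 1 < nr:
                segments.append(((nodes_r[i, j], nodes_c[i, j]), (nodes_r[i + 1, j], nodes_c[i + 1, j])))
    return segments


def render_segments(shape: tuple[int, int], segments, fiber_width_px: int) -> np.ndarray:
    """Rasterize segments and dilate to the fiber width; True = fiber."""
    from skimage.draw import line
    from skimage.morphology import dilation, disk

    canvas = np.zeros(shape, dtype=bool)
    h, w = shape
    for (r0, c0), (r1, c1) in segments:
        for p in ((r0, c0), (r1, c1)):
            if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
                raise ValueError(f"segment endpoint {p} outside image bounds {shape}")
        rr, cc = line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        canvas[rr, cc] = True
    if fiber_width_px > 1:
        canvas = dilation(canvas, disk(fiber_width_px // 2))
    return canvas


def make_network_image(truth: NetworkImageTruth) -> tuple[CalibratedImage2D, np.ndarray]:
    """Render a fluorescent-style network image plus its exact free-space mask.

    Fibers are drawn at high intensity, Gaussian-blurred, then corrupted with
    Poisson shot noise on a scaled intensity plus Gaussian read noise.
    """
    rng = np.random.default_rng(truth.seed)
    segments = _lattice_segments(truth, rng)
    if not segments:
        raise ValueError("network has no edge segments")
    fg = render_segments(truth.shape, segments, truth.fiber_width_px)
    clean = ndimage.gaussian_filter(fg.astype(float), truth.blur_sigma_px)
    photons = rng.poisson(clean * truth.photon_scale).astype(float)
    noisy = photons + rng.normal(0.0, truth.read_noise_sd, size=truth.shape)
    image = CalibratedImage2D(noisy, truth.pixel_size_um, channel="PDPN")
    free_space = ~fg
    return image, free_space


# ---------------------------------------------------------------------------
# nuclei fields (packing density input)


@dataclass(frozen=True)
class NucleiFieldTruth:
    """Field of Gaussian-profile nuclei with a minimum centroid separation."""

    centroids: tuple[tuple[float, float], ...]
    shape: tuple[int, int] = (256, 256)
    nucleus_radius_px: float = 4.0
    min_separation_px: float = 16.0
    amplitude: float = 100.0
    read_noise_sd: float = 2.0
    pixel_size_um: float = 0.5
    exclusion_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.centroids, dtype=float)
        if pts.size:
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            if d.min() < self.min_separation_px - 1e-9:
                raise ValueError(
                    f"centroid separation {d.min():.2f} px below minimum "
                    f"{self.min_separation_px} px"
                )

    @classmethod
    def random(
        cls,
        n: int,
        shape: tuple[int, int] = (256, 256),
        min_separation_px: float = 16.0,
        seed: int = 0,
        margin_px: float = 8.0,
        **kwargs,
    ) -> "NucleiFieldTruth":
        """Rejection-sample ``n`` centroids with the given minimum spacing."""
        rng = np.random.default_rng(seed)
        pts: list[tuple[float, float]] = []
        attempts = 0
        while len(pts) < n:
            attempts += 1
            if attempts > 100_000:
                raise ValueError("cannot place nuclei at requested density/spacing")
            r = rng.uniform(margin_px, shape[0] - 1 - margin_px)
            c = rng.uniform(margin_px, shape[1] - 1 - margin_px)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_separation_px**2 for pr, pc in pts):
                pts.append((r, c))
        return cls(centroids=tuple(pts), shape=shape,
                   min_separation_px=min_separation_px, seed=seed, **kwargs)


def make_nuclei_image(truth: NucleiFieldTruth) -> CalibratedImage2D:
    """Render Gaussian nuclei at the truth centroids plus read noise."""
    rng = np.random.default_rng(truth.seed)
    h, w = truth.shape
    clean = np.zeros((h, w), dtype=float)
    sigma = truth.nucleus_radius_px / 1.5  # FWHM-ish profile inside the radius
    rows, cols = np.indices((h, w))
    for r0, c0 in truth.centroids:
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        clean += truth.amplitude * np.exp(-d2 / (2 * sigma**2))
    noisy = clean + rng.normal(0.0, truth.read_noise_sd, size=(h, w))
    return CalibratedImage2D(noisy, truth.pixel_size_um, channel="DAPI")


# ---------------------------------------------------------------------------
# ablation recoil traces


@dataclass(frozen=True)
class RecoilTruth:
    """Saturating-exponential recoil: d(t) = A·(1 − e^(−(t−t_cut)/τ)) after the cut."""

    amplitude_A_um: float = 2.0
    tau_s: float = 4.0
    noise_sd_um: float = 0.0
    frame_interval_s: float = 0.521
    duration_s: float = 25.0
    cut_time_s: float = 2.0
    baseline_separation_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_A_um < 0:
            raise ValueError("amplitude must be >= 0")
        if self.tau_s <= 0:
            raise ValueError("tau must be > 0")

    def sampled(self, times_s: np.ndarray) -> tuple[np.ndarray, int]:
        """Noise-free displacement on a frame grid, plus the cut index.

        The cut is snapped to the frame grid: it happens at the frame just
        before ``cut_index`` (the first post-cut frame), so the first
        post-cut displacement is exactly ``A·(1 − e^(−Δt/τ))``.
        """
        t = np.asarray(times_s, dtype=float)
        cut_index = int(round(self.cut_time_s / self.frame_interval_s))
        cut_index = min(max(cut_index, 1), t.size - 1)
        t_cut = t[cut_index - 1]
        out = np.zeros_like(t)
        post = np.arange(t.size) >= cut_index
        out[post] = self.amplitude_A_um * (1.0 - np.exp(-(t[post] - t_cut) / self.tau_s))
        return out, cut_index


def make_recoil_trace(truth: RecoilTruth):
    """Sample the recoil model on the frame grid; returns a RecoilTrace.

    Displacement is exactly 0 before the cut; after the cut it follows
    ``A·(1 − e^(−Δt/τ))`` plus Gaussian noise of SD ``noise_sd_um``.
    """
    from frcmech.recoil import RecoilTrace

    rng = np.random.default_rng(truth.seed)
    times = np.arange(0.0, truth.duration_s + 1e-9, truth.frame_interval_s)
    disp, cut_index = truth.sampled(times)
    if truth.noise_sd_um > 0:
        noise = rng.normal(0.0, truth.noise_sd_um, size=times.size)
        noise[:cut_index] = 0.0  # baseline-referenced: pre-cut frames define zero
        disp = disp + noise
    return RecoilTrace(times_s=times, displacement_um=disp, cut_index=cut_index)


def make_landmark_tracks(truth: RecoilTruth):
    """Two landmark position tracks whose separation follows the recoil model.

    Landmark A stays fixed; landmark B moves away along the x axis.  Both
    carry isotropic positional noise of SD ``noise_sd_um / sqrt(2)`` per
    coordinate so the separation noise is comparable to the trace model.
    Returns ``(times_s, xy_a_um, xy_b_um, cut_index)``.
    """
    rng = np.random.default_rng(truth.seed)
    times = np.arange(0.0, truth.duration_s + 1e-9, truth.frame_interval_s)
    disp, cut_index = truth.sampled(times)
    sep = truth.baseline_separation_um + disp
    xy_a = np.zeros((times.size, 2))
    xy_b = np.column_stack([sep, np.zeros(times.size)])
    if truth.noise_sd_um > 0:
        xy_b[:, 0] += rng.normal(0.0, truth.noise_sd_um, size=times.size)
    return times, xy_a, xy_b, cut_index


# ---------------------------------------------------------------------------
# trapped-bead traces (tether mechanics)


@dataclass(frozen=True)
class BeadTraceTruth:
    """Ornstein–Uhlenbeck trapped bead with an optional tether-pull step.

    Stationary variance is k_B·T/k; the discrete-time update is exact, so
    the variance is analytic at any sampling interval.  After ``step_time_s``
    the mean position is shifted by ``tether_step_nm``.
    """

    k_pN_per_nm: float = 0.114
    temperature_K: float = 310.15
    relaxation_time_s: float = 0.01
    sample_interval_s: float = 0.090
    duration_s: float = 90.0
    tether_step_nm: float = 0.0
    step_time_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_pN_per_nm <= 0 or self.temperature_K <= 0:
            raise ValueError("stiffness and temperature must be positive")

    @property
    def variance_nm2(self) -> float:
        return K_B_PN_NM_PER_K * self.temperature_K / self.k_pN_per_nm


def make_bead_trace(truth: BeadTraceTruth):
    """Simulate the trapped-bead position trace; returns a BeadTrack.

    Exact OU update: x_{n+1} = φ·x_n + sqrt(σ²(1−φ²))·ξ with
    φ = exp(−Δt/τ_relax) and σ² = k_B·T/k; the process starts in its
    stationary distribution, so every sample has variance k_B·T/k.
    """
    from frcmech.tether import BeadTrack

    n = int(round(truth.duration_s / truth.sample_interval_s))
    if n < 100:
        raise ValueError("bead trace must contain >= 100 samples for calibration")
    rng = np.random.default_rng(truth.seed)
    phi = math.exp(-truth.sample_interval_s / truth.relaxation_time_s)
    sd = math.sqrt(truth.variance_nm2)
    innov_sd = sd * math.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + shocks[i - 1]
    times = np.arange(n) * truth.sample_interval_s
    x = x + np.where(times >= truth.step_time_s, truth.tether_step_nm, 0.0)
    return BeadTrack(times_s=times, position_nm=x, temperature_K=truth.temperature_K)


# ---------------------------------------------------------------------------
# osmotic swelling traces


@dataclass(frozen=True)
class SwellingTruth:
    """Exponential-plateau swelling of the cell diameter under hypotonic shock."""

    d0_um: float = 20.0
    plateau_ratio: float = 1.2
    rate_per_min: float = 0.2
    noise_sd_um: float = 0.0
    sample_interval_min: float = 0.5
    duration_min: float = 30.0
    condition: str = "HYPO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d0_um <= 0:
            raise ValueError("d0 must be positive")
        if self.plateau_ratio < 1 and self.condition != "ISO":
            raise ValueError("plateau_ratio must be >= 1 for hypotonic conditions")

    def ratio(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return 1.0 + (self.plateau_ratio - 1.0) * (1.0 - np.exp(-self.rate_per_min * t))

    def auc_0_20_baseline(self) -> float:
        """Closed-form ∫₀²⁰ (ratio − 1) dt in ratio·min."""
        a = self.plateau_ratio - 1.0
        r = self.rate_per_min
        if r == 0:
            return 0.0
        return a * (20.0 - (1.0 - math.exp(-r * 20.0)) / r)


def make_swelling_trace(truth: SwellingTruth):
    """Sample the diameter trace on the frame grid; returns a SwellingTrace.

    The first frame is noise-free so d0 anchors the ratio at exactly 1.
    """
    from frcmech.swelling import SwellingTrace

    rng = np.random.default_rng(truth.seed)
    times = np.arange(0.0, truth.duration_min + 1e-9, truth.sample_interval_min)
    d = truth.d0_um * truth.ratio(times)
    if truth.noise_sd_um > 0:
        noise = rng.normal(0.0, truth.noise_sd_um, size=times.size)
        noise[0] = 0.0
        d = d + noise
    return SwellingTrace(times_min=times, diameter_um=d, condition=truth.condition)


# ---------------------------------------------------------------------------
# division movies (proliferation tracking)


@dataclass(frozen=True)
class DivisionMovieTruth:
    """Nuclei time-lapse with exponential division times at a per-cell rate.

    Cells random-walk with Gaussian steps of SD ``motility_step_px``; at a
    division the parent disappears and two daughters appear at
    ``±daughter_offset_px`` along a random axis.  The offset exceeds typical
    frame-to-frame motion so a mitosis reads as one track ending and two
    starting — the signature the division detector keys on.
    """

    n0: int = 50
    division_rate_per_cell_per_h: float = 0.01
    frame_interval_h: float = 0.5
    duration_h: float = 72.0
    motility_step_px: float = 1.0
    daughter_offset_px: float = 6.0
    daughter_min_age_h: float = 2.0
    end_margin_frames: int = 3  # no divisions this close to the movie end
    shape: tuple[int, int] = (512, 512)
    min_separation_px: float = 30.0
    substrate: str = "glass"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.division_rate_per_cell_per_h < 0:
            raise ValueError("division rate must be >= 0")

    def expected_events(self) -> float:
        """Branching-process expectation: n0·(e^{rT} − 1) division events.

        Exact for ``daughter_min_age_h = 0`` (pure Yule process); with a
        refractory age the true expectation is slightly lower.
        """
        return self.n0 * (math.exp(self.division_rate_per_cell_per_h * self.duration_h) - 1.0)


@dataclass(frozen=True)
class PlantedDivision:
    parent_id: int
    frame: int
    daughter_ids: tuple[int, int]


def make_division_movie(truth: DivisionMovieTruth):
    """Simulate the movie; returns (detections DataFrame, truth events).

    The detections table has columns ``frame, row, col, truth_id`` (the
    truth_id column is ground truth for scoring and is not consumed by the
    tracker).  Division times are exponential with the per-cell rate;
    daughters inherit independent exponential clocks (Yule process), so the
    expected event count is ``n0·(e^{rT} − 1)``.
    """
    import pandas as pd

    rng = np.random.default_rng(truth.seed)
    n_frames = int(round(truth.duration_h / truth.frame_interval_h)) + 1
    h, w = truth.shape
    margin = 2 * truth.daughter_offset_px

    # initial well-separated placement
    pos: dict[int, np.ndarray] = {}
    attempts = 0
    while len(pos) < truth.n0:
        attempts += 1
        if attempts > 200_000:
            raise ValueError("cannot place starting nuclei at requested separation")
        cand = np.array([rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin)])
        if all(np.hypot(*(cand - p)) >= truth.min_separation_px for p in pos.values()):
            pos[len(pos)] = cand

    next_id = truth.n0
    rate = truth.division_rate_per_cell_per_h
    last_div_frame = n_frames - 1 - truth.end_margin_frames
    div_frame: dict[int, int] = {}
    if rate > 0:
        for cid in list(pos):
            t_div = rng.exponential(1.0 / rate)
            f = int(math.ceil(t_div / truth.frame_interval_h))
            if 1 <= f <= last_div_frame:
                div_frame[cid] = f

    rows: list[tuple[int, float, float, int]] = []
    events: list[PlantedDivision] = []
    for f in range(n_frames):
        # record detections for currently alive cells
        for cid, p in pos.items():
            rows.append((f, float(p[0]), float(p[1]), cid))
        if f == n_frames - 1:
            break
        # divisions scheduled for frame f+1: parent vanishes, daughters appear
        dividing = [cid for cid, df_ in div_frame.items() if df_ == f + 1 and cid in pos]
        survivors = [cid for cid in pos if cid not in dividing]
        for cid in dividing:
            parent_pos = pos.pop(cid)
            # clamp the division center away from the border so neither
            # daughter is clipped — clipping would distort the offset
            # geometry the division detector keys on
            center = np.clip(parent_pos, truth.daughter_offset_px,
                             [h - 1 - truth.daughter_offset_px, w - 1 - truth.daughter_offset_px])
            theta = rng.uniform(0, 2 * math.pi)
            off = truth.daughter_offset_px * np.array([math.sin(theta), math.cos(theta)])
            d1, d2 = next_id, next_id + 1
            next_id += 2
            for did, sign in ((d1, +1.0), (d2, -1.0)):
                pos[did] = center + sign * off
                if rate > 0:
                    # refractory age keeps daughters alive long enough to track
                    t_div = truth.daughter_min_age_h + rng.exponential(1.0 / rate)
                    fd = f + 1 + int(math.ceil(t_div / truth.frame_interval_h))
                    if fd <= last_div_frame:
                        div_frame[did] = fd
            events.append(PlantedDivision(cid, f + 1, (d1, d2)))
        # random-walk motility; newborn daughters keep their exact offset this frame
        for cid in survivors:
            step = rng.normal(0.0, truth.motility_step_px, size=2)
            pos[cid] = np.clip(pos[cid] + step, 0.0, [h - 1.0, w - 1.0])

    detections = pd.DataFrame(rows, columns=["frame", "row", "col", "truth_id"])
    return detections, events
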