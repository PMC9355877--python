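"""F-actin fiber scoring: pMLC positivity and matrix (perlecan) alignment.

Hand-drawn fiber ROIs (polylines) are first restricted to the PDPN⁺ FRC
network, then scored on the pMLC and perlecan channels.  A fiber is called
positive on a channel when its mean intensity exceeds the background mean by
z background SDs (background = in-network, non-fiber pixels); "aligned" for
the matrix channel additionally requires an overlap fraction of the fiber
over channel-positive pixels.  Percentages are reported over in-network
fibers only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from frcmech.core import CalibratedImage2D, RegionROI

__all__ = [
    "FiberROI",
    "FiberScore",
    "FiberSummary",
    "fiber_pixels",
    "fiber_in_network",
    "estimate_background",
    "score_channel",
    "score_fibers",
    "summarize_fibers",
]


@dataclass(frozen=True)
class FiberROI:
    """Polyline fiber trace with a sampling width (px)."""

    vertices: tuple[tuple[float, float], ...]
    width_px: int = 3
    id: int = 0

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("fiber ROI needs at least 2 vertices")
        object.__setattr__(self, "vertices",
                           tuple((float(r), float(c)) for r, c in self.vertices))

    def as_region(self) -> RegionROI:
        return RegionROI(self.vertices, closed=False)

    def length_um(self, pixel_size_um: float) -> float:
        v = np.asarray(self.vertices)
        return float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1))) * pixel_size_um


@dataclass(frozen=True)
class FiberScore:
    fiber_id: int
    in_network: bool
    network_fraction: float
    pmlc_positive: bool | None = None
    pmlc_mean: float | None = None
    matrix_aligned: bool | None = None
    matrix_mean: float | None = None
    matrix_overlap_fraction: float | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class FiberSummary:
    n_fibers_in_network: int
    n_pmlc_positive: int
    n_matrix_aligned: int
    pct_pmlc_positive: float
    pct_matrix_aligned: float
    z_threshold: float


def fiber_pixels(roi: FiberROI, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixels sampled by the widened polyline, clipped to shape."""
    from skimage.draw import line
    from skimage.morphology import dilation, disk

    canvas = np.zeros(shape, dtype=bool)
    v = np.asarray(roi.vertices)
    for (r0, c0), (r1, c1) in zip(v[:-1], v[1:]):
        rr, cc = line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[keep], cc[keep]] = True
    if roi.width_px > 1:
        canvas = dilation(canvas, disk(roi.width_px // 2))
    return np.nonzero(canvas)


def fiber_in_network(roi: FiberROI, pdpn_mask: np.ndarray, min_fraction: float = 0.5) -> tuple[bool, float]:
    """True iff >= ``min_fraction`` of the sampled fiber pixels lie in the mask."""
    mask = np.asarray(pdpn_mask).astype(bool)
    rr, cc = fiber_pixels(roi, mask.shape)
    if rr.size == 0:
        raise ValueError("fiber ROI samples no pixels inside the image")
    frac = float(mask[rr, cc].mean())
    return frac >= min_fraction, frac


def estimate_background(
    channel: CalibratedImage2D,
    pdpn_mask: np.ndarray,
    fiber_rois: list[FiberROI],
) -> tuple[float, float]:
    """(mean, SD) of the channel over in-network pixels not on any fiber."""
    mask = np.asarray(pdpn_mask).astype(bool)
    bg = mask.copy()
    for roi in fiber_rois:
        rr, cc = fiber_pixels(roi, mask.shape)
        bg[rr, cc] = False
    vals = np.asarray(channel.pixels, dtype=float)[bg]
    if vals.size == 0:
        raise ValueError("no background pixels available (mask fully covered by fibers)")
    return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0


def score_channel(
    roi: FiberROI,
    channel: CalibratedImage2D,
    background: tuple[float, float],
    z: float = 2.0,
) -> tuple[float, bool, tuple[str, ...]]:
    """Mean fiber intensity and the positivity call against the background.

    Positive iff mean > bg_mean + z·bg_SD.  A degenerate background
    (zero variance) falls back to the absolute rule mean > bg_mean and is
    flagged.
    """
    px = np.asarray(channel.pixels, dtype=float)
    rr, cc = fiber_pixels(roi, px.shape)
    mean = float(px[rr, cc].mean())
    bg_mean, bg_sd = background
    flags: tuple[str, ...] = ()
    if bg_sd == 0.0:
        flags = ("degenerate_background",)
        positive = mean > bg_mean
    else:
        positive = mean > bg_mean + z * bg_sd
    return mean, positive, flags


def _overlap_fraction(roi: FiberROI, positive_mask: np.ndarray) -> float:
    rr, cc = fiber_pixels(roi, positive_mask.shape)
    return float(positive_mask[rr, cc].mean())


def score_fibers(
    rois: list[FiberROI],
    pdpn_mask: np.ndarray,
    pmlc: CalibratedImage2D | None = None,
    matrix: CalibratedImage2D | None = None,
    z: float = 2.0,
    in_network_fraction: float = 0.5,
    matrix_overlap_min: float = 0.5,
) -> list[FiberScore]:
    """Score every fiber: network membership, then per-channel positivity.

    The matrix channel's "aligned" call combines the intensity rule with an
    overlap criterion: >= ``matrix_overlap_min`` of the fiber pixels must lie
    over matrix-positive pixels (channel > bg_mean + z·bg_SD pixelwise).
    """
    scores: list[FiberScore] = []
    bg_pmlc = estimate_background(pmlc, pdpn_mask, rois) if pmlc is not None else None
    bg_matrix = estimate_background(matrix, pdpn_mask, rois) if matrix is not None else None
    if matrix is not None:
        m_mean, m_sd = bg_matrix
        matrix_pos_mask = np.asarray(matrix.pixels, dtype=float) > m_mean + z * m_sd
    for roi in rois:
        in_net, frac = fiber_in_network(roi, pdpn_mask, in_network_fraction)
        if not in_net:
            scores.append(FiberScore(roi.id, False, frac))
            continue
        kwargs: dict = {}
        flags: tuple[str, ...] = ()
        if pmlc is not None:
            mean, pos, fl = score_channel(roi, pmlc, bg_pmlc, z)
            kwargs.update(pmlc_positive=pos, pmlc_mean=mean)
            flags += fl
        if matrix is not None:
            mean, pos, fl = score_channel(roi, matrix, bg_matrix, z)
            overlap = _overlap_fraction(roi, matrix_pos_mask)
            kwargs.update(matrix_aligned=pos and overlap >= matrix_overlap_min,
                          matrix_mean=mean, matrix_overlap_fraction=overlap)
            flags += fl
        scores.append(FiberScore(roi.id, True, frac, flags=flags, **kwargs))
    return scores


def summarize_fibers(scores: list[FiberScore], z: float = 2.0) -> FiberSummary:
    """Percent positive / aligned over in-network fibers only."""
    in_net = [s for s in scores if s.in_network]
    if not in_net:
        raise ValueError("no in-network fibers to summarize")
    n = len(in_net)
    n_pmlc = sum(1 for s in in_net if s.pmlc_positive)
    n_mat = sum(1 for s in in_net if s.matrix_aligned)
    return FiberSummary(
        n_fibers_in_network=n,
        n_pmlc_positive=n_pmlc,
        n_matrix_aligned=n_mat,
        pct_pmlc_positive=100.0 * n_pmlc / n,
        pct_matrix_aligned=100.0 * n_mat / n,
        z_threshold=z,
    )
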