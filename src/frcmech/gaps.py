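"""FRC-network gap analysis: greedy maximal-circle packing of free space.

The network image is binarized (foreground = network fibers), then circles
are fitted consecutively: at each step the largest circle, centered on a
pixel center, that contains no foreground pixel, lies within the image
bounds, and does not overlap any previously fitted circle.  Radii summarize
the mesh size of the network; the reported distribution keeps radii strictly
above a physical threshold (default 12 µm).

Geometry conventions
--------------------
* A circle of radius ``r`` centered at pixel ``c`` occupies the open disc:
  it contains every pixel whose center is at Euclidean distance < r.  The
  maximal foreground-free radius at ``c`` therefore equals the distance from
  ``c`` to the nearest obstacle pixel center, and is attained.
* Obstacles are the foreground pixels plus a virtual 1-px border ring just
  outside the image, so fitted circles never extend past the image bounds.
* Circle–circle overlap is continuous geometry: circles ``i`` and ``j``
  overlap iff ``dist(c_i, c_j) < r_i + r_j`` (touching is allowed).
* Ties among equally maximal radii break to the smallest ``(row, col)`` in
  lexicographic order, making the output fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from frcmech.core import CalibratedImage2D

__all__ = [
    "GapCircle",
    "GapAnalysisResult",
    "binarize_network",
    "fit_gap_circles",
    "radius_distribution",
]


@dataclass(frozen=True)
class GapCircle:
    """One fitted free-space circle."""

    row: int
    col: int
    radius_px: float
    radius_um: float
    rank: int


@dataclass(frozen=True)
class GapAnalysisResult:
    circles: tuple[GapCircle, ...]
    r_min_px: float
    pixel_size_um: float
    provenance: dict = field(default_factory=dict)

    @property
    def radii_um(self) -> np.ndarray:
        return np.array([c.radius_um for c in self.circles])


def binarize_network(
    image: CalibratedImage2D,
    method: str = "otsu",
    *,
    smooth_sigma_px: float = 0.5,
    invert: bool = False,
    threshold: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Binarize a network fluorescence image: True = network (foreground).

    Parameters
    ----------
    method
        ``"otsu"`` (default, data-derived) or ``"manual"`` (requires
        ``threshold``).
    smooth_sigma_px
        Gaussian pre-smoothing before thresholding; 0 disables.
    invert
        Set when the network is dark on a bright background.

    Returns the boolean mask and a provenance dict (method, threshold used,
    and a ``degenerate`` flag set for constant images, which binarize to
    all-background).
    """
    px = np.asarray(image.pixels, dtype=float)
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite values")
    if invert:
        px = px.max() - px
    if smooth_sigma_px > 0:
        px = ndimage.gaussian_filter(px, sigma=smooth_sigma_px)
    prov = {"method": method, "smooth_sigma_px": smooth_sigma_px,
            "invert": invert, "degenerate": False}
    if method == "manual":
        if threshold is None:
            raise ValueError("manual binarization requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(px) == 0:
            prov["degenerate"] = True
            prov["threshold"] = None
            return np.zeros(px.shape, dtype=bool), prov
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(px))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    prov["threshold"] = thr
    return px > thr, prov


def _obstacle_distance(mask: np.ndarray) -> np.ndarray:
    """Distance from each pixel center to the nearest obstacle pixel center.

    Obstacles = foreground pixels plus a virtual one-pixel foreground border
    around the image.  Exact Euclidean distances.
    """
    padded = np.pad(mask, 1, constant_values=True)
    dist = ndimage.distance_transform_edt(~padded)
    return dist[1:-1, 1:-1]


def fit_gap_circles(
    mask: np.ndarray,
    pixel_size_um: float,
    r_min_px: float = 2.0,
    *,
    max_circles: int | None = None,
    provenance: dict | None = None,
) -> GapAnalysisResult:
    """Greedily pack maximal non-overlapping circles into free space.

    Stops when the largest feasible radius drops below ``r_min_px``.  The
    fitted radii are non-increasing with rank, and the output is exactly
    reproducible: maximal radius first, ties to smallest (row, col).
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary (bool or {0,1})")
        mask = mask.astype(bool)
    if r_min_px < 1:
        raise ValueError(f"r_min_px must be >= 1, got {r_min_px}")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")

    # cap[p] = largest feasible radius for a circle centered at p given the
    # obstacles and all circles fitted so far.
    cap = _obstacle_distance(mask)
    rows, cols = np.indices(mask.shape)
    circles: list[GapCircle] = []
    while True:
        flat = np.argmax(cap)  # first (row-major) maximum = lexicographic tie-break
        r = float(cap.flat[flat])
        if r < r_min_px:
            break
        cr, cc = np.unravel_index(flat, cap.shape)
        circles.append(GapCircle(int(cr), int(cc), r, r * pixel_size_um, len(circles)))
        if max_circles is not None and len(circles) >= max_circles:
            break
        # non-overlap constraint against the new circle, touching allowed
        dist = np.sqrt((rows - cr) ** 2 + (cols - cc) ** 2)
        np.minimum(cap, dist - r, out=cap)
    return GapAnalysisResult(
        circles=tuple(circles),
        r_min_px=float(r_min_px),
        pixel_size_um=float(pixel_size_um),
        provenance=dict(provenance or {}),
    )


def radius_distribution(
    result: GapAnalysisResult, threshold_um: float = 12.0
) -> dict:
    """Radii strictly above ``threshold_um`` with count, median and IQR."""
    radii = result.radii_um
    kept = radii[radii > threshold_um]
    summary = {
        "threshold_um": float(threshold_um),
        "radii_um": kept,
        "count": int(kept.size),
        "median_um": float(np.median(kept)) if kept.size else float("nan"),
        "iqr_um": (
            float(np.percentile(kept, 75) - np.percentile(kept, 25)) if kept.size else float("nan")
        ),
    }
    return summary


def overlay_figure(image: CalibratedImage2D, result: GapAnalysisResult, path) -> None:
    """Save a PNG of the image with fitted circles drawn on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image.pixels, cmap="gray")
    for c in result.circles:
        ax.add_patch(plt.Circle((c.col, c.row), c.radius_px, fill=False, color="tab:orange", lw=0.8))
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
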