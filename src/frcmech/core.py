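"""Shared data model: calibrated images, stacks, ROIs, table I/O and seeding.

Every quantification in the package runs on pixel grids with an isotropic
physical calibration (µm per pixel).  The coordinate convention is 0-based
``(row, col)`` with pixel centers at integer coordinates; every physical
distance is the Euclidean pixel distance multiplied by ``pixel_size_um``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("frcmech")

__all__ = [
    "CalibratedImage2D",
    "ImageStack",
    "RegionROI",
    "RunConfig",
    "read_image",
    "max_project",
    "write_table",
    "read_table",
    "write_manifest",
]


@dataclass(frozen=True)
class CalibratedImage2D:
    """A single 2-D image plane with physical pixel calibration.

    Parameters
    ----------
    pixels
        2-D array of intensities (arbitrary units; treated as relative).
    pixel_size_um
        Isotropic pixel size in µm per pixel; must be positive.
    channel
        Free-text channel label (e.g. ``"PDPN"``, ``"DAPI"``).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def physical_size_um(self) -> tuple[float, float]:
        """(height, width) in µm."""
        return (self.shape[0] * self.pixel_size_um, self.shape[1] * self.pixel_size_um)

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage2D":
        return CalibratedImage2D(pixels, self.pixel_size_um, self.channel)


@dataclass(frozen=True)
class ImageStack:
    """Ordered planes sharing one calibration: a z-stack or a time-lapse.

    Exactly one of ``z_step_um`` (spatial stack) or ``frame_interval_s``
    (time-lapse) must be set, and must be strictly positive.
    """

    planes: tuple[CalibratedImage2D, ...]
    z_step_um: float | None = None
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        if len(self.planes) == 0:
            raise ValueError("stack must contain at least one plane")
        if (self.z_step_um is None) == (self.frame_interval_s is None):
            raise ValueError("exactly one of z_step_um / frame_interval_s must be set")
        interval = self.z_step_um if self.z_step_um is not None else self.frame_interval_s
        if not np.isfinite(interval) or interval <= 0:
            raise ValueError(f"stack interval must be strictly positive, got {interval}")
        shapes = {p.shape for p in self.planes}
        cals = {p.pixel_size_um for p in self.planes}
        if len(shapes) != 1 or len(cals) != 1:
            raise ValueError("all planes must share shape and calibration")
        object.__setattr__(self, "planes", tuple(self.planes))

    @property
    def is_timelapse(self) -> bool:
        return self.frame_interval_s is not None

    @property
    def pixel_size_um(self) -> float:
        return self.planes[0].pixel_size_um

    def __len__(self) -> int:
        return len(self.planes)

    def as_array(self) -> np.ndarray:
        return np.stack([p.pixels for p in self.planes])


@dataclass(frozen=True)
class RegionROI:
    """Polygonal (closed) or polyline (open) region in pixel coordinates."""

    vertices: tuple[tuple[float, float], ...]
    closed: bool = True

    def __post_init__(self) -> None:
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        if self.closed and len(verts) < 3:
            raise ValueError("closed ROI needs at least 3 vertices")
        if not self.closed and len(verts) < 2:
            raise ValueError("polyline ROI needs at least 2 vertices")
        object.__setattr__(self, "vertices", verts)

    def area_px2(self) -> float:
        """Shoelace polygon area in px² (closed ROIs only)."""
        if not self.closed:
            raise ValueError("area is defined for closed ROIs only")
        v = np.asarray(self.vertices)
        r, c = v[:, 0], v[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))

    def area_um2(self, pixel_size_um: float) -> float:
        return self.area_px2() * pixel_size_um**2

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of which (row, col) points fall inside the polygon."""
        from matplotlib.path import Path as MplPath

        if not self.closed:
            raise ValueError("containment is defined for closed ROIs only")
        path = MplPath(np.asarray(self.vertices))
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return path.contains_points(pts)


@dataclass
class RunConfig:
    """Per-stage parameter maps plus output/log/seed plumbing."""

    stages: dict = field(default_factory=dict)
    output_dir: Path = Path("results")
    log_level: str = "INFO"
    seed: int = 0

    def stage(self, name: str) -> dict:
        return dict(self.stages.get(name, {}))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {"output_dir", "log_level", "seed"}
        meta = {k: data.pop(k) for k in list(data) if k in known}
        if "output_dir" in meta:
            meta["output_dir"] = Path(meta["output_dir"])
        return cls(stages=data, **meta)


def read_image(
    path: str | Path,
    pixel_size_um: float,
    *,
    z_step_um: float | None = None,
    frame_interval_s: float | None = None,
    channel: str = "",
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into a calibrated stack.

    Calibration is taken from the caller, never from TIFF metadata (metadata
    dialects vary); if the file carries a resolution tag it is logged for
    comparison.  Defaults to a spatial stack with ``z_step_um=1`` when
    neither interval is given.
    """
    path = Path(path)
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be positive, got {pixel_size_um}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"unreadable TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected grayscale planes, got array of shape {arr.shape}")
    try:
        with tifffile.TiffFile(path) as tf:
            res = tf.pages[0].tags.get("XResolution")
            if res is not None:
                logger.info("TIFF %s carries XResolution=%s (caller calibration %g µm/px used)",
                            path.name, res.value, pixel_size_um)
    except Exception:
        pass
    planes = tuple(CalibratedImage2D(p, pixel_size_um, channel) for p in arr)
    if frame_interval_s is not None:
        return ImageStack(planes, frame_interval_s=frame_interval_s)
    return ImageStack(planes, z_step_um=z_step_um if z_step_um is not None else 1.0)


def write_image(stack: ImageStack | CalibratedImage2D, path: str | Path) -> Path:
    """Write a stack or plane as a (multi-page) TIFF, intensities as stored."""
    path = Path(path)
    if isinstance(stack, CalibratedImage2D):
        arr = stack.pixels
    else:
        arr = stack.as_array()
    tifffile.imwrite(path, arr)
    return path


def max_project(stack: ImageStack) -> CalibratedImage2D:
    """Per-pixel maximum over the planes of a spatial stack."""
    if stack.is_timelapse:
        raise ValueError("max_project is for spatial z-stacks, not time-lapses")
    proj = np.max(stack.as_array(), axis=0)
    first = stack.planes[0]
    return CalibratedImage2D(proj, first.pixel_size_um, first.channel)


def write_table(records: Iterable, path: str | Path, columns: Sequence[str] | None = None) -> Path:
    """Write records (dataclasses or dicts) to CSV with a header.

    Units are embedded in column names by the record schemas themselves
    (e.g. ``radius_um``).  Zero records yields a header-only CSV when the
    schema is known via ``columns`` or a dataclass sample.
    """
    path = Path(path)
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            rows.append(dataclasses.asdict(rec))
        else:
            rows.append(dict(rec))
    df = pd.DataFrame(rows, columns=columns if columns is not None else None)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, *, subcommand: str, params: dict,
                   inputs: Sequence[str | Path] = (), seed: int | None = None) -> Path:
    """Write a JSON run manifest: resolved parameters, input hashes, seed."""
    from frcmech import __version__

    import datetime

    manifest = {
        "subcommand": subcommand,
        "parameters": params,
        "input_hashes": {str(p): file_sha256(p) for p in inputs},
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
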