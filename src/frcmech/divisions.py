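"""Proliferation tracking: link nuclei detections, count division events.

Nuclei are linked frame-to-frame by greedy mutual-nearest-neighbour matching
within a maximum displacement (with one-frame gap closure).  A division is a
track that ends at frame f with at least two new tracks starting at f (±1)
within a search radius of its last position, each persisting a minimum
number of frames; the two nearest daughters are assigned.  New tracks that
cannot be paired to a terminating parent count as entering cells, never as
divisions — conservative counting.  Divisions over the imaging window are
normalized by the starting nucleus count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrackSet",
    "DivisionEvent",
    "ProliferationSummary",
    "link_detections",
    "detect_divisions",
    "divisions_per_cell",
]


@dataclass
class TrackSet:
    """id → ordered list of (frame, row, col); frames strictly increasing."""

    tracks: dict[int, list[tuple[int, float, float]]]
    frame_interval_h: float = 0.5
    substrate: str = ""

    def start_frame(self, tid: int) -> int:
        return self.tracks[tid][0][0]

    def end_frame(self, tid: int) -> int:
        return self.tracks[tid][-1][0]

    def length_frames(self, tid: int) -> int:
        return len(self.tracks[tid])

    def last_position(self, tid: int) -> np.ndarray:
        _, r, c = self.tracks[tid][-1]
        return np.array([r, c])

    def first_position(self, tid: int) -> np.ndarray:
        _, r, c = self.tracks[tid][0]
        return np.array([r, c])

    @property
    def n_frames(self) -> int:
        return 1 + max(t[-1][0] for t in self.tracks.values())


@dataclass(frozen=True)
class DivisionEvent:
    parent_id: int
    frame: int
    daughter_ids: tuple[int, int]


@dataclass(frozen=True)
class ProliferationSummary:
    n0: int
    n_events: int
    divisions_per_cell: float
    times_h: np.ndarray = field(repr=False)
    cumulative_per_cell: np.ndarray = field(repr=False)
    substrate: str = ""


def _match_frame(prev: np.ndarray, nxt: np.ndarray, max_disp: float) -> list[tuple[int, int]]:
    """Greedy mutual-nearest-neighbour pairs between two point sets."""
    if prev.size == 0 or nxt.size == 0:
        return []
    d = np.sqrt(((prev[:, None, :] - nxt[None, :, :]) ** 2).sum(-1))
    pairs = []
    d = d.copy()
    while True:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if not np.isfinite(d[i, j]) or d[i, j] > max_disp:
            break
        pairs.append((int(i), int(j)))
        d[i, :] = np.inf
        d[:, j] = np.inf
    return pairs


def link_detections(
    detections: pd.DataFrame,
    max_disp_px: float = 5.0,
    frame_interval_h: float = 0.5,
    substrate: str = "",
    gap_closing: bool = True,
) -> TrackSet:
    """Link per-frame centroids (columns frame, row, col) into tracks.

    Greedy mutual-nearest-neighbour within ``max_disp_px``; unmatched
    detections start new tracks.  With ``gap_closing`` a track that missed
    one frame may reconnect within ``max_disp_px`` two frames later.
    """
    frames = sorted(detections["frame"].unique())
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to link")
    by_frame = {
        f: detections.loc[detections["frame"] == f, ["row", "col"]].to_numpy(float)
        for f in frames
    }
    tracks: dict[int, list[tuple[int, float, float]]] = {}
    active: dict[int, np.ndarray] = {}  # tid -> last position
    lagged: dict[int, tuple[int, np.ndarray]] = {}  # tid -> (last frame, position)
    next_tid = 0

    f0 = frames[0]
    for p in by_frame[f0]:
        tracks[next_tid] = [(f0, float(p[0]), float(p[1]))]
        active[next_tid] = p
        next_tid += 1

    for f in frames[1:]:
        pts = by_frame[f]
        act_ids = list(active)
        prev = np.array([active[t] for t in act_ids]) if act_ids else np.empty((0, 2))
        pairs = _match_frame(prev, pts, max_disp_px)
        matched_next = set()
        matched_prev = set()
        for i, j in pairs:
            tid = act_ids[i]
            tracks[tid].append((f, float(pts[j][0]), float(pts[j][1])))
            active[tid] = pts[j]
            matched_prev.add(tid)
            matched_next.add(j)
        # unmatched active tracks fall into the one-frame gap pool
        new_lagged: dict[int, tuple[int, np.ndarray]] = {}
        for tid in act_ids:
            if tid not in matched_prev:
                new_lagged[tid] = (f - 1, active[tid])
                del active[tid]
        # try to close one-frame gaps with leftover detections
        leftover = [j for j in range(len(pts)) if j not in matched_next]
        if gap_closing and lagged and leftover:
            lag_ids = list(lagged)
            lag_pos = np.array([lagged[t][1] for t in lag_ids])
            left_pos = pts[leftover]
            pairs2 = _match_frame(lag_pos, left_pos, max_disp_px)
            for i, j in pairs2:
                tid = lag_ids[i]
                jj = leftover[j]
                tracks[tid].append((f, float(pts[jj][0]), float(pts[jj][1])))
                active[tid] = pts[jj]
                matched_next.add(jj)
                del lagged[tid]
        # remaining leftovers start new tracks
        for j in range(len(pts)):
            if j not in matched_next:
                tracks[next_tid] = [(f, float(pts[j][0]), float(pts[j][1]))]
                active[next_tid] = pts[j]
                next_tid += 1
        lagged = new_lagged  # tracks that just missed this frame get one more chance
    return TrackSet(tracks=tracks, frame_interval_h=frame_interval_h, substrate=substrate)


def detect_divisions(
    trackset: TrackSet,
    search_radius_px: float = 15.0,
    min_daughter_len_frames: int = 3,
) -> list[DivisionEvent]:
    """Pair terminating tracks with two nearby newborn tracks.

    An event requires a track ending at frame f and >= 2 tracks starting at
    f−1, f or f+1 relative to the first post-parent frame, within
    ``search_radius_px`` of the parent's last position, each persisting
    >= ``min_daughter_len_frames``.  Each daughter is assigned to at most one
    parent; the two nearest candidates win.
    """
    first_frame = min(trackset.start_frame(tid) for tid in trackset.tracks)
    last_frame = max(trackset.end_frame(tid) for tid in trackset.tracks)
    ends = [(tid, trackset.end_frame(tid)) for tid in trackset.tracks
            if trackset.end_frame(tid) < last_frame]
    starts_by_frame: dict[int, list[int]] = {}
    for tid in trackset.tracks:
        sf = trackset.start_frame(tid)
        if sf > first_frame and trackset.length_frames(tid) >= min_daughter_len_frames:
            starts_by_frame.setdefault(sf, []).append(tid)

    events: list[DivisionEvent] = []
    claimed: set[int] = set()
    for tid, ef in sorted(ends, key=lambda x: (x[1], x[0])):
        p = trackset.last_position(tid)
        event_frame = ef + 1  # first frame the parent is gone
        candidates: list[tuple[float, int]] = []
        for f in (event_frame - 1, event_frame, event_frame + 1):
            for did in starts_by_frame.get(f, []):
                if did in claimed or did == tid:
                    continue
                dist = float(np.linalg.norm(trackset.first_position(did) - p))
                if dist <= search_radius_px:
                    candidates.append((dist, did))
        if len(candidates) >= 2:
            candidates.sort()
            d1, d2 = candidates[0][1], candidates[1][1]
            claimed.update((d1, d2))
            events.append(DivisionEvent(parent_id=tid, frame=event_frame,
                                        daughter_ids=(d1, d2)))
    return events


def divisions_per_cell(
    events: list[DivisionEvent],
    n0: int,
    frame_interval_h: float,
    n_frames: int | None = None,
    substrate: str = "",
) -> ProliferationSummary:
    """Events normalized by the starting nucleus count, plus the cumulative curve.

    n0 is fixed at frame 0: cells leaving the field do not change the
    divisor.  The cumulative curve is non-decreasing and ends at
    divisions_per_cell.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if n_frames is None:
        n_frames = 1 + max((e.frame for e in events), default=0)
    times_h = np.arange(n_frames) * frame_interval_h
    counts = np.zeros(n_frames)
    for e in events:
        counts[min(e.frame, n_frames - 1)] += 1
    cumulative = np.cumsum(counts) / n0
    return ProliferationSummary(
        n0=int(n0),
        n_events=len(events),
        divisions_per_cell=len(events) / n0,
        times_h=times_h,
        cumulative_per_cell=cumulative,
        substrate=substrate,
    )
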