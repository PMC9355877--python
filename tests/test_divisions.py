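"""Tracking and division counting: linking, event detection, normalization."""

import numpy as np
import pandas as pd
import pytest

from frcmech.divisions import (
    DivisionEvent,
    detect_divisions,
    divisions_per_cell,
    link_detections,
)
from frcmech.synthetic import DivisionMovieTruth, make_division_movie


def sparse_truth(seed, rate=0.006, n0=12):
    """Fixture satisfying the detector's separation/persistence constraints."""
    return DivisionMovieTruth(n0=n0, division_rate_per_cell_per_h=rate,
                              min_separation_px=60, motility_step_px=0.5, seed=seed)


class TestLinking:
    def test_stationary_nuclei_full_tracks(self):
        rows = [(f, r, c) for f in range(10) for r, c in ((10.0, 10.0), (40.0, 40.0))]
        df = pd.DataFrame(rows, columns=["frame", "row", "col"])
        ts = link_detections(df, max_disp_px=5.0)
        assert len(ts.tracks) == 2
        assert all(len(t) == 10 for t in ts.tracks.values())

    def test_track_purity_on_random_walk(self):
        truth = DivisionMovieTruth(n0=20, division_rate_per_cell_per_h=0.0,
                                   min_separation_px=50, motility_step_px=0.5, seed=1)
        dets, _ = make_division_movie(truth)
        ts = link_detections(dets, max_disp_px=5.0)
        # every linked position must belong to a single ground-truth cell
        pure = 0
        for tid, pts in ts.tracks.items():
            ids = set()
            for f, r, c in pts:
                row = dets[(dets.frame == f) & (np.isclose(dets.row, r)) & (np.isclose(dets.col, c))]
                ids.add(int(row.iloc[0].truth_id))
            pure += len(ids) == 1
        assert pure / len(ts.tracks) >= 0.98

    def test_distant_jump_terminates_track(self):
        # two nuclei "swap" by jumping far beyond max_disp: tracks must break
        rows = []
        for f in range(5):
            rows += [(f, 10.0, 10.0), (f, 10.0, 60.0)]
        for f in range(5, 10):
            rows += [(f, 10.0, 60.0 - 0.01), (f, 10.0, 10.0 + 0.01)]
        df = pd.DataFrame(rows, columns=["frame", "row", "col"])
        ts = link_detections(df, max_disp_px=5.0, gap_closing=False)
        # positions coincide so linking keeps two continuous tracks;
        # the real check: no track contains a jump larger than max_disp
        for pts in ts.tracks.values():
            arr = np.array([(r, c) for _, r, c in pts])
            if len(arr) > 1:
                assert np.hypot(*np.diff(arr, axis=0).T).max() <= 5.0

    def test_gap_closure_bridges_one_missing_frame(self):
        rows = [(f, 10.0, 10.0 + f) for f in range(10) if f != 5]
        df = pd.DataFrame(rows, columns=["frame", "row", "col"])
        ts = link_detections(df, max_disp_px=5.0)
        assert len(ts.tracks) == 1
        frames = [f for f, _, _ in list(ts.tracks.values())[0]]
        assert frames == [f for f in range(10) if f != 5]


class TestDetectDivisions:
    def test_no_terminations_no_events(self):
        rows = [(f, 10.0, 10.0) for f in range(10)]
        df = pd.DataFrame(rows, columns=["frame", "row", "col"])
        df2 = pd.concat([df, pd.DataFrame([(f, 40.0, 40.0) for f in range(10)],
                                          columns=["frame", "row", "col"])])
        ts = link_detections(df2, max_disp_px=5.0)
        assert detect_divisions(ts) == []

    def test_planted_events_recovered_exactly(self):
        truth = sparse_truth(seed=0, rate=0.008)
        dets, events = make_division_movie(truth)
        ts = link_detections(dets, max_disp_px=5.0)
        recovered = detect_divisions(ts)
        assert len(recovered) == len(events)
        assert sorted(e.frame for e in recovered) == sorted(e.frame for e in events)

    def test_entering_cell_not_counted(self):
        # a track appearing far from any ending track is an entering cell
        rows = [(f, 10.0, 10.0) for f in range(20)]
        rows += [(f, 100.0, 100.0) for f in range(8, 20)]  # enters at frame 8
        df = pd.DataFrame(rows, columns=["frame", "row", "col"])
        ts = link_detections(df, max_disp_px=5.0)
        assert detect_divisions(ts) == []


class TestDivisionsPerCell:
    def test_arithmetic(self):
        events = [DivisionEvent(i, 5 + i, (100 + 2 * i, 101 + 2 * i)) for i in range(5)]
        s = divisions_per_cell(events, n0=10, frame_interval_h=0.5, n_frames=20)
        assert s.divisions_per_cell == 0.5

    def test_zero_events(self):
        s = divisions_per_cell([], n0=10, frame_interval_h=0.5, n_frames=20)
        assert s.divisions_per_cell == 0.0
        assert np.all(s.cumulative_per_cell == 0.0)

    def test_cumulative_curve_monotone_ends_at_total(self):
        truth = sparse_truth(seed=2, rate=0.01)
        dets, _ = make_division_movie(truth)
        ts = link_detections(dets, max_disp_px=5.0)
        events = detect_divisions(ts)
        n0 = sum(1 for t in ts.tracks.values() if t[0][0] == 0)
        s = divisions_per_cell(events, n0, 0.5, n_frames=ts.n_frames)
        assert np.all(np.diff(s.cumulative_per_cell) >= 0)
        assert s.cumulative_per_cell[-1] == pytest.approx(s.divisions_per_cell)

    def test_zero_n0_rejected(self):
        with pytest.raises(ValueError):
            divisions_per_cell([], n0=0, frame_interval_h=0.5)


class TestInvariances:
    def test_translation_invariance(self):
        truth = sparse_truth(seed=3, rate=0.008)
        dets, _ = make_division_movie(truth)
        shifted = dets.copy()
        shifted["row"] += 37.0
        shifted["col"] -= 11.0
        e1 = detect_divisions(link_detections(dets, max_disp_px=5.0))
        e2 = detect_divisions(link_detections(shifted, max_disp_px=5.0))
        assert len(e1) == len(e2)
        assert sorted(e.frame for e in e1) == sorted(e.frame for e in e2)

    def test_frame_reindexing_invariance(self):
        truth = sparse_truth(seed=4, rate=0.008)
        dets, _ = make_division_movie(truth)
        reindexed = dets.copy()
        reindexed["frame"] += 100
        e1 = detect_divisions(link_detections(dets, max_disp_px=5.0))
        e2 = detect_divisions(link_detections(reindexed, max_disp_px=5.0))
        assert len(e1) == len(e2)
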