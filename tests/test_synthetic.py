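"""Generators: determinism, ground-truth consistency, closed-form anchors."""

import math

import numpy as np
import pytest

from frcmech import synthetic as sx


class TestDeterminism:
    def test_network_image_reproducible(self):
        t = sx.NetworkImageTruth(seed=11)
        img1, free1 = sx.make_network_image(t)
        img2, free2 = sx.make_network_image(t)
        np.testing.assert_array_equal(img1.pixels, img2.pixels)
        np.testing.assert_array_equal(free1, free2)

    def test_nuclei_image_reproducible(self):
        t = sx.NucleiFieldTruth.random(10, seed=4)
        np.testing.assert_array_equal(
            sx.make_nuclei_image(t).pixels, sx.make_nuclei_image(t).pixels
        )

    def test_bead_trace_reproducible(self):
        t = sx.BeadTraceTruth(seed=2)
        a = sx.make_bead_trace(t)
        b = sx.make_bead_trace(t)
        np.testing.assert_array_equal(a.position_nm, b.position_nm)

    def test_division_movie_reproducible(self):
        t = sx.DivisionMovieTruth(n0=10, seed=3)
        d1, e1 = sx.make_division_movie(t)
        d2, e2 = sx.make_division_movie(t)
        assert d1.equals(d2) and e1 == e2


class TestNetworkImage:
    def test_foreground_is_dilated_segments(self):
        t = sx.NetworkImageTruth(seed=1)
        _, free = sx.make_network_image(t)
        # free space plus fibers tile the image; fibers occupy a plausible band
        assert 0.05 < (~free).mean() < 0.6

    def test_zero_fiber_width_rejected(self):
        with pytest.raises(ValueError):
            sx.NetworkImageTruth(fiber_width_px=0)

    def test_segment_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            sx.render_segments((32, 32), [((0, 0), (40, 40))], 3)


class TestNucleiField:
    def test_minimum_separation_enforced(self):
        with pytest.raises(ValueError):
            sx.NucleiFieldTruth(centroids=((10, 10), (12, 10)), min_separation_px=16)

    def test_zero_nuclei_blank_plus_noise(self):
        t = sx.NucleiFieldTruth(centroids=(), shape=(32, 32), read_noise_sd=1.0, seed=0)
        img = sx.make_nuclei_image(t)
        assert abs(img.pixels.mean()) < 0.5
        assert img.pixels.std() > 0

    def test_random_placement_respects_spacing(self):
        t = sx.NucleiFieldTruth.random(20, min_separation_px=20, seed=5)
        pts = np.asarray(t.centroids)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 20


class TestRecoilTrace:
    def test_closed_form_first_frame(self):
        t = sx.RecoilTruth(amplitude_A_um=2.0, tau_s=4.0, noise_sd_um=0.0, cut_time_s=0.521)
        trace = sx.make_recoil_trace(t)
        expected = 2.0 * (1 - math.exp(-0.521 / 4.0))
        assert trace.displacement_um[trace.cut_index] == pytest.approx(expected, rel=1e-12)

    def test_zero_amplitude_flat(self):
        trace = sx.make_recoil_trace(sx.RecoilTruth(amplitude_A_um=0.0))
        np.testing.assert_array_equal(trace.displacement_um, 0.0)

    def test_precut_displacement_zero(self):
        trace = sx.make_recoil_trace(sx.RecoilTruth(noise_sd_um=0.05, seed=1))
        np.testing.assert_array_equal(trace.displacement_um[: trace.cut_index], 0.0)

    def test_terminal_mean_near_amplitude(self):
        # Monte-Carlo: sample mean of d(25 s) within 3 SE of A
        vals = [
            sx.make_recoil_trace(sx.RecoilTruth(noise_sd_um=0.05, seed=s)).displacement_um[-1]
            for s in range(100)
        ]
        a_true = sx.RecoilTruth().amplitude_A_um * (
            1 - math.exp(-(sx.make_recoil_trace(sx.RecoilTruth()).post_cut_times_s[-1]) / 4.0)
        )
        se = np.std(vals, ddof=1) / 10
        assert abs(np.mean(vals) - a_true) < 3 * se


class TestBeadTrace:
    def test_stationary_variance_matches_equipartition(self):
        t = sx.BeadTraceTruth(k_pN_per_nm=0.114, temperature_K=310.15, duration_s=900, seed=0)
        assert t.variance_nm2 == pytest.approx(0.0138065 * 310.15 / 0.114)
        track = sx.make_bead_trace(t)
        assert np.var(track.position_nm, ddof=1) == pytest.approx(t.variance_nm2, rel=0.1)

    def test_zero_step_mean_constant(self):
        t = sx.BeadTraceTruth(tether_step_nm=0.0, duration_s=200, seed=1)
        track = sx.make_bead_trace(t)
        half = len(track) // 2
        sd = math.sqrt(t.variance_nm2)
        assert abs(track.position_nm[:half].mean() - track.position_nm[half:].mean()) < sd

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            sx.make_bead_trace(sx.BeadTraceTruth(duration_s=5.0))


class TestSwellingTrace:
    def test_isotonic_ratio_one(self):
        t = sx.SwellingTruth(plateau_ratio=1.0, condition="ISO", noise_sd_um=0.0)
        trace = sx.make_swelling_trace(t)
        np.testing.assert_allclose(trace.diameter_um / trace.d0_um, 1.0)

    def test_plateau_reached(self):
        t = sx.SwellingTruth(plateau_ratio=1.2, rate_per_min=0.3, noise_sd_um=0.0)
        trace = sx.make_swelling_trace(t)
        assert trace.diameter_um[-1] / trace.d0_um == pytest.approx(1.2, abs=0.005)


class TestDivisionMovie:
    def test_zero_rate_no_events(self):
        t = sx.DivisionMovieTruth(n0=10, division_rate_per_cell_per_h=0.0, seed=0)
        dets, events = sx.make_division_movie(t)
        assert events == []
        assert set(dets["truth_id"]) == set(range(10))

    def test_daughters_adjacent_and_parent_disappears(self):
        t = sx.DivisionMovieTruth(n0=10, division_rate_per_cell_per_h=0.02, seed=8)
        dets, events = sx.make_division_movie(t)
        assert events, "fixture should contain at least one division"
        for e in events[:5]:
            parent = dets[dets.truth_id == e.parent_id]
            assert parent.frame.max() == e.frame - 1
            p = parent.iloc[-1][["row", "col"]].to_numpy(float)
            for did in e.daughter_ids:
                d0 = dets[(dets.truth_id == did) & (dets.frame == e.frame)]
                assert len(d0) == 1
                dist = np.hypot(*(d0.iloc[0][["row", "col"]].to_numpy(float) - p))
                assert 1.0 <= dist <= 2 * t.daughter_offset_px + 1

    def test_event_count_matches_branching_expectation(self):
        # pure Yule process (no refractory age): E[events] = n0 (e^{rT} − 1)
        t0 = sx.DivisionMovieTruth(n0=50, division_rate_per_cell_per_h=0.01,
                                   daughter_min_age_h=0.0)
        counts = []
        for s in range(50):
            t = sx.DivisionMovieTruth(n0=50, division_rate_per_cell_per_h=0.01,
                                      daughter_min_age_h=0.0, seed=s)
            _, events = sx.make_division_movie(t)
            counts.append(len(events))
        expect = t0.expected_events()
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se
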