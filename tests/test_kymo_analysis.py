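"""Tests of thresholding, segmentation, classification and measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kymodwell as kd
from kymodwell.kymo_analysis import (
    AnalysisConfig,
    AnalysisError,
    DISCARDED,
    LATTICE,
    TRANSLOCATING,
    EventTrace,
    classify_event,
    detect_event_pixels,
    duration_from_frames,
    estimate_threshold,
    locate_microtubule,
    measure_end_residence,
    measure_run_length,
    measure_velocity,
    segment_events,
)
from conftest import flood_fill_components, make_gfp_kymograph


class TestEstimateThreshold:
    def test_constant_image_warns_and_returns_value(self):
        with pytest.warns(UserWarning, match="zero median absolute deviation"):
            assert estimate_threshold(np.full((10, 10), 100.0)) == 100.0

    def test_zero_image(self):
        with pytest.warns(UserWarning):
            assert estimate_threshold(np.zeros((5, 5))) == 0.0

    def test_separates_sparse_bright_pixels(self, rng):
        img = rng.normal(100.0, 10.0, (100, 100))
        bright = rng.choice(img.size, img.size // 100, replace=False)
        img.flat[bright] = 1000.0
        thr = estimate_threshold(img, k=3.0)
        # independent oracle: direct median/MAD computation
        med = np.median(img)
        expected = med + 3.0 * 1.4826 * np.median(np.abs(img - med))
        assert thr == pytest.approx(expected)
        assert 120.0 <= thr <= 145.0
        assert thr < 1000.0


class TestLocateMicrotubule:
    def test_noiseless_uniform_span(self):
        rho = np.zeros((20, 100))
        rho[:, 10:51] = 500.0
        kymo = kd.Kymograph(rho, np.zeros_like(rho), 1 / 2.7, 160.0)
        ext = locate_microtubule(kymo)
        assert (ext.left_end, ext.right_end) == (10, 50)

    def test_longest_run_wins(self):
        rho = np.zeros((10, 100))
        rho[:, 5:9] = 500.0
        rho[:, 20:61] = 500.0
        kymo = kd.Kymograph(rho, np.zeros_like(rho), 1 / 2.7, 160.0)
        ext = locate_microtubule(kymo)
        # brute-force run scan oracle on the thresholded profile
        assert (ext.left_end, ext.right_end) == (20, 60)

    def test_no_microtubule_raises(self, rng):
        rho = rng.normal(100.0, 1.0, (20, 50))
        kymo = kd.Kymograph(rho, np.zeros_like(rho), 1 / 2.7, 160.0)
        with pytest.raises(AnalysisError, match="no microtubule"):
            locate_microtubule(kymo)

    def test_simulated_ends_within_one_pixel(self, small_imaging):
        ds = kd.generate_dataset(kd.DEFAULT_PANEL["WT"], small_imaging, 3, seed=3)
        for mt, kymo in zip(ds.microtubules, ds.kymographs):
            ext = locate_microtubule(kymo)
            left_true = mt.position_to_column(mt.length, small_imaging.pixel_size)
            assert abs(ext.left_end - mt.start_pixel) <= 1
            assert abs(ext.right_end - left_true) <= 1

    def test_subpixel_tip_estimate(self, small_imaging):
        ds = kd.generate_dataset(kd.DEFAULT_PANEL["WT"], small_imaging, 3, seed=4)
        for mt, kymo in zip(ds.microtubules, ds.kymographs):
            ext = locate_microtubule(kymo)
            tip_true = mt.position_to_column(mt.length, small_imaging.pixel_size)
            assert ext.right_tip == pytest.approx(tip_true, abs=0.15)


class TestDetectEventPixels:
    def test_zero_noise_footprint(self, extent_10_50):
        gfp = np.full((20, 60), 50.0)
        gfp[5, 20] += 300.0
        gfp[5, 21] += 150.0
        kymo = make_gfp_kymograph(gfp)
        with pytest.warns(UserWarning):
            mask = detect_event_pixels(kymo, extent_10_50)
        assert set(zip(*np.nonzero(mask))) == {(5, 20), (5, 21)}

    def test_signal_outside_microtubule_is_removed(self, extent_10_50):
        gfp = np.full((20, 60), 50.0)
        gfp[3, 55] += 400.0  # beyond right_end = 50
        kymo = make_gfp_kymograph(gfp)
        with pytest.warns(UserWarning):
            mask = detect_event_pixels(kymo, extent_10_50)
        assert not mask.any()

    def test_pixel_recall_on_simulated_data(self, small_imaging):
        from kymodwell import benchmark

        ds = kd.generate_dataset(kd.DEFAULT_PANEL["WT"], small_imaging, 4, seed=6)
        recalls = []
        for mt, kymo, events in zip(ds.microtubules, ds.kymographs, ds.events):
            res = kd.analyse_kymograph(kymo)
            m = benchmark.match_events(events, res, mt, small_imaging)
            if np.isfinite(m["mean_pixel_recall"]):
                recalls.append(m["mean_pixel_recall"])
        assert np.mean(recalls) >= 0.9


class TestSegmentEvents:
    def test_empty_mask(self):
        assert segment_events(np.zeros((5, 5), bool)) == []

    def test_diagonal_contact_is_one_component(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = mask[3, 3] = True
        comps = segment_events(mask)
        assert len(comps) == 1
        assert set(map(tuple, comps[0].tolist())) == {(2, 2), (3, 3)}

    def test_blank_row_separates(self):
        mask = np.zeros((7, 4), bool)
        mask[0:2, 1:3] = True
        mask[3:5, 1:3] = True
        assert len(segment_events(mask)) == 2

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        st.integers(2, 12),
        st.integers(2, 12),
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 0.9),
    )
    def test_matches_brute_force_flood_fill(self, nr, nc, seed, density):
        mask = np.random.default_rng(seed).random((nr, nc)) < density
        got = {frozenset(map(tuple, c.tolist())) for c in segment_events(mask)}
        want = {frozenset(c) for c in flood_fill_components(mask)}
        assert got == want


def diagonal_trace_kymo(n_frames=12, width=60, start_col=45, right_end=50):
    """1-px-wide diagonal trace advancing one column per frame to the end."""
    gfp = np.zeros((n_frames, width))
    pixels = []
    for i in range(6):
        gfp[2 + i, start_col + i] = 100.0
        pixels.append((2 + i, start_col + i))
    return make_gfp_kymograph(gfp), np.array(pixels), kd.MicrotubuleExtent(10, right_end, 1.0)


class TestClassifyEvent:
    def test_single_pixel_is_lattice(self, extent_10_50):
        gfp = np.zeros((10, 60))
        gfp[4, 30] = 100.0
        kymo = make_gfp_kymograph(gfp)
        tr = classify_event(np.array([[4, 30]]), extent_10_50, kymo)
        assert tr.cls == LATTICE
        assert tr.end_residence is None
        assert not tr.is_end_resident

    def test_diagonal_to_end_is_translocating_and_end_resident(self):
        kymo, pixels, extent = diagonal_trace_kymo()
        tr = classify_event(pixels, extent, kymo)
        assert tr.cls == TRANSLOCATING
        assert tr.is_end_resident
        assert tr.end_side == "right"

    def test_x_shaped_component_is_discarded(self, extent_10_50):
        gfp = np.zeros((10, 60))
        pix = []
        for i in range(5):
            gfp[2 + i, 20 + i] = 100.0
            gfp[2 + i, 24 - i] = 100.0
            pix += [(2 + i, 20 + i), (2 + i, 24 - i)]
        kymo = make_gfp_kymograph(gfp)
        tr = classify_event(np.array(sorted(set(pix))), extent_10_50, kymo)
        assert tr.cls == DISCARDED
        assert tr.discard_reason == "crossing"
        assert tr.end_residence is None and tr.velocity is None

    def test_empty_pixel_set_raises(self, extent_10_50):
        kymo = make_gfp_kymograph(np.zeros((5, 60)))
        with pytest.raises(ValueError, match="empty"):
            classify_event(np.empty((0, 2)), extent_10_50, kymo)

    def test_every_component_gets_exactly_one_class(self, small_imaging):
        ds = kd.generate_dataset(kd.DEFAULT_PANEL["WT"], small_imaging, 2, seed=8)
        for kymo in ds.kymographs:
            for tr in kd.analyse_kymograph(kymo).traces:
                assert tr.cls in (DISCARDED, LATTICE, TRANSLOCATING)


class TestMeasurements:
    def test_end_residence_frame_conventions(self):
        tr = EventTrace(np.array([[0, 50]]), LATTICE, 0, 0, end_frames=1,
                        end_side="right")
        assert measure_end_residence(tr, 1 / 2.7, "k") == pytest.approx(0.370, abs=5e-4)
        tr5 = EventTrace(np.array([[0, 50]]), LATTICE, 0, 4, end_frames=5,
                         end_side="right")
        assert measure_end_residence(tr5, 1 / 2.7, "k") == pytest.approx(1.852, abs=5e-4)
        assert measure_end_residence(tr5, 1 / 2.7, "k_minus_1") == pytest.approx(4 / 2.7)
        assert measure_end_residence(tr5, 1 / 2.7, "k_minus_half") == pytest.approx(4.5 / 2.7)

    def test_end_residence_requires_end_occupancy(self):
        tr = EventTrace(np.array([[0, 30]]), LATTICE, 0, 0, end_frames=0)
        with pytest.raises(ValueError):
            measure_end_residence(tr, 1 / 2.7)

    def test_velocity_two_pixels_per_frame(self):
        frames = np.arange(6)
        tr = EventTrace(
            np.array([[f, 2 * f] for f in frames]), TRANSLOCATING, 0, 5,
            frames=frames, centroids=2.0 * frames,
        )
        v = measure_velocity(tr, pixel_size=160.0, frame_interval=1 / 2.7)
        assert v == pytest.approx(864.0)

    def test_velocity_of_stationary_trace_is_zero(self):
        frames = np.arange(4)
        tr = EventTrace(
            np.array([[f, 30] for f in frames]), TRANSLOCATING, 0, 3,
            frames=frames, centroids=np.full(4, 30.0),
        )
        assert measure_velocity(tr, 160.0, 1 / 2.7) == pytest.approx(0.0, abs=1e-9)

    def test_run_length_arithmetic(self):
        frames = np.arange(11)
        tr = EventTrace(
            np.array([[f, 20 + f] for f in frames]), TRANSLOCATING, 0, 10,
            frames=frames, centroids=20.0 + frames,
        )
        assert measure_run_length(tr, 160.0) == pytest.approx(1.6)
        tr0 = EventTrace(
            np.array([[f, 20] for f in frames]), TRANSLOCATING, 0, 10,
            frames=frames, centroids=np.full(11, 20.0),
        )
        assert measure_run_length(tr0, 160.0) == 0.0

    def test_duration_never_negative_and_quantised(self):
        for k in range(1, 8):
            for conv in ("k", "k_minus_1", "k_minus_half"):
                d = duration_from_frames(k, 1 / 2.7, conv)
                assert d >= 0.0


class TestAnalyseKymograph:
    def test_blank_gfp_channel_gives_no_events(self):
        rho = np.zeros((30, 80))
        rho[:, 10:40] = 500.0
        kymo = kd.Kymograph(rho, np.zeros((30, 80)), 1 / 2.7, 160.0)
        with pytest.warns(UserWarning):
            res = kd.analyse_kymograph(kymo)
        assert res.traces == []

    def test_deterministic(self, small_imaging):
        from kymodwell.kymo_analysis import traces_to_records

        ds = kd.generate_dataset(kd.DEFAULT_PANEL["WT"], small_imaging, 1, seed=13)
        r1 = traces_to_records(kd.analyse_kymograph(ds.kymographs[0]).traces)
        r2 = traces_to_records(kd.analyse_kymograph(ds.kymographs[0]).traces)
        assert r1 == r2

    def test_ground_truth_recovery_rate(self):
        from kymodwell import benchmark

        imaging = kd.ImagingParams(n_frames=1000, seed=2)
        ds = kd.generate_dataset(kd.DEFAULT_PANEL["WT"], imaging, 4, seed=17)
        n_rec = n_det = 0
        for mt, kymo, events in zip(ds.microtubules, ds.kymographs, ds.events):
            res = kd.analyse_kymograph(kymo)
            m = benchmark.match_events(events, res, mt, imaging)
            n_rec += m["n_recovered"]
            n_det += m["n_detectable"]
        assert n_det > 30
        assert n_rec / n_det >= 0.8

    def test_mirror_invariance(self, small_imaging):
        ds = kd.generate_dataset(kd.DEFAULT_PANEL["WT"], small_imaging, 2, seed=19)
        for kymo in ds.kymographs:
            res = kd.analyse_kymograph(kymo)
            res_m = kd.analyse_kymograph(kymo.mirrored())

            def summary(r):
                ends = sorted(
                    round(t.end_residence, 6) for t in r.traces
                    if t.end_residence is not None
                )
                vels = sorted(
                    round(t.velocity, 3) for t in r.traces if t.velocity is not None
                )
                return ends, vels

            e1, v1 = summary(res)
            e2, v2 = summary(res_m)
            assert e1 == e2
            assert v1 == pytest.approx(v2, rel=1e-6)

    def test_end_dwell_recovery_is_monotonic(self):
        imaging = kd.ImagingParams(n_frames=1200, seed=3)
        from kymodwell import benchmark

        means = []
        for tau in (0.5, 1.0, 2.0):
            motor = kd.DEFAULT_PANEL["WT"].with_(mean_end_dwell=tau)
            ds = kd.generate_dataset(motor, imaging, 12, seed=23)
            res = [kd.analyse_kymograph(k) for k in ds.kymographs]
            dur, _ = benchmark.collect_end_residences(res, ds.microtubules)
            assert dur.size > 20
            means.append(dur.mean())
        assert means[0] < means[1] < means[2]
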