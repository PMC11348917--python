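"""Circular-variance selectivity, permutation significance and categorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geniculate import tuning as tu
from geniculate.protocol import StimulusProtocol

DIRS = np.arange(0, 360, 45.0)


def _resp(P, N=None, speeds=(400.0,), baseline_sd=0.01):
    """Minimal ResponseMatrix around given amplitude rows."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    N = np.zeros_like(P) if N is None else np.atleast_2d(np.asarray(N, dtype=float))
    return tu.ResponseMatrix(
        speeds=tuple(speeds[: P.shape[0]]),
        directions=tuple(DIRS),
        P=P,
        N=N,
        mean_resp=P.copy(),
        baselines=np.zeros_like(P),
        F0=0.0,
        baseline_sd=baseline_sd,
        frame_rate=4.0,
        filter_samples=1,
    )


class TestProtocol:
    def test_slowest_speed_duration_is_12s(self):
        prot = StimulusProtocol()
        assert prot.stim_duration(400.0) == pytest.approx(12.0)
        assert prot.stim_duration(1200.0) == pytest.approx(4.0)
        assert prot.stim_duration(2400.0) == pytest.approx(2.0)

    def test_temporal_frequencies(self):
        prot = StimulusProtocol()
        assert [prot.temporal_freq(s) for s in prot.speeds_um_s] == pytest.approx(
            [1 / 3, 1.0, 2.0]
        )

    def test_duration_times_freq_is_four_cycles(self):
        prot = StimulusProtocol()
        for s in prot.speeds_um_s:
            assert prot.stim_duration(s) * prot.temporal_freq(s) == pytest.approx(4.0)

    def test_schedule_covers_all_stimuli(self):
        prot = StimulusProtocol(n_trials=3)
        sched = prot.schedule()
        assert len(sched) == 3 * 24
        assert sched.groupby(["speed", "direction"]).size().eq(3).all()

    def test_schedule_deterministic(self):
        a = StimulusProtocol(order_seed=9).schedule()
        b = StimulusProtocol(order_seed=9).schedule()
        assert a.equals(b)


class TestSelectivityIndices:
    def test_single_direction_responder(self):
        P = np.zeros(8)
        P[0] = 1.0
        res = tu.selectivity_indices(_resp(P), 400.0, eye_axis_offset_deg=0.0)
        assert res.dsi == pytest.approx(1.0)
        assert res.osi == pytest.approx(1.0)
        assert res.preferred_direction == pytest.approx(0.0)

    def test_symmetric_responder(self):
        P = np.zeros(8)
        P[0] = P[4] = 1.0  # 0° and 180°
        res = tu.selectivity_indices(_resp(P), 400.0, eye_axis_offset_deg=0.0)
        assert res.dsi == 0.0  # exact cancellation
        assert res.osi == pytest.approx(1.0)

    def test_direction_symmetric_response_has_exactly_zero_dsi(self):
        rng = np.random.default_rng(1)
        half = rng.uniform(0.5, 2.0, 4)
        P = np.concatenate([half, half])  # P(θ) = P(θ+180°)
        res = tu.selectivity_indices(_resp(P), 400.0)
        assert res.dsi == pytest.approx(0.0, abs=1e-14)

    def test_printed_formula_on_2_1s(self):
        P = np.array([2.0, 1, 1, 1, 1, 1, 1, 1])
        res = tu.selectivity_indices(_resp(P), 400.0, eye_axis_offset_deg=0.0)
        assert res.dsi == pytest.approx(1 / 9)
        assert res.preferred_direction == pytest.approx(0.0)

    def test_negative_amplitudes_clipped_before_formula(self):
        P = np.array([1.0, -5, 0, 0, 0, 0, 0, 0])
        res = tu.selectivity_indices(_resp(P), 400.0)
        assert res.dsi == pytest.approx(1.0)

    def test_scale_invariance(self):
        P = np.abs(np.sin(np.deg2rad(DIRS))) + 0.2
        a = tu.selectivity_indices(_resp(P), 400.0)
        b = tu.selectivity_indices(_resp(3.7 * P), 400.0)
        assert a.dsi == pytest.approx(b.dsi)
        assert a.osi == pytest.approx(b.osi)

    def test_rotation_covariance(self):
        P = np.exp(2 * (np.cos(np.deg2rad(DIRS - 90)) - 1))
        res0 = tu.selectivity_indices(_resp(P), 400.0, eye_axis_offset_deg=0.0)
        res1 = tu.selectivity_indices(_resp(np.roll(P, 1)), 400.0, eye_axis_offset_deg=0.0)
        assert (res1.preferred_direction - res0.preferred_direction) % 360 == pytest.approx(45.0)

    def test_eye_axis_correction_subtracts_20(self):
        P = np.zeros(8)
        P[2] = 1.0  # 90°
        res = tu.selectivity_indices(_resp(P), 400.0)
        assert res.preferred_direction == pytest.approx(70.0)

    def test_snr_gate_forces_zero_dsi(self):
        P = np.zeros(8)
        P[0] = 1.0
        res = tu.selectivity_indices(_resp(P, baseline_sd=10.0), 400.0)
        assert res.dsi == 0.0 and res.osi == 0.0

    def test_zero_sum_flags_undefined_preference(self):
        res = tu.selectivity_indices(_resp(np.zeros(8)), 400.0)
        assert res.dsi == 0.0
        assert np.isnan(res.preferred_direction)

    @given(st.lists(st.floats(0.0, 10.0), min_size=8, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_indices_bounded_unit_interval(self, amps):
        res = tu.selectivity_indices(_resp(np.array(amps)), 400.0)
        assert 0.0 <= res.dsi <= 1.0 + 1e-12
        assert 0.0 <= res.osi <= 1.0 + 1e-12


class TestSbC:
    def _resp_with_means(self, n_negative):
        means = np.ones(24)
        means[:n_negative] = -1.0
        r = _resp(np.zeros(8))
        r.mean_resp = means.reshape(1, 24)[:, :8]  # placeholder, replaced below
        r.mean_resp = means.reshape(3, 8)
        return r

    def test_13_of_24_is_sbc(self):
        sbc, pct = tu.classify_sbc(self._resp_with_means(13))
        assert sbc and pct == pytest.approx(13 / 24)

    def test_12_of_24_is_not_sbc(self):
        sbc, pct = tu.classify_sbc(self._resp_with_means(12))
        assert not sbc and pct == pytest.approx(0.5)

    def test_all_positive_not_sbc(self):
        sbc, pct = tu.classify_sbc(self._resp_with_means(0))
        assert not sbc and pct == 0.0


class TestCategorize:
    def test_hierarchy_ds_wins_over_os(self):
        cat = tu.categorize(0.5, 0.9, 0, 0, 0.01, 0.01, 1, 1, sbc=False)
        assert cat == "DS"

    def test_broad_when_weakly_tuned(self):
        cat = tu.categorize(0.1, 0.1, 0.1, 0.1, 0.5, 0.5, 0.5, 0.5, sbc=False)
        assert cat == "broad"

    def test_none_when_moderately_tuned_but_not_significant(self):
        cat = tu.categorize(0.2, 0.2, 0, 0, 0.5, 0.5, 1, 1, sbc=False)
        assert cat == "none"

    def test_sbc_beats_broad(self):
        cat = tu.categorize(0.1, 0.1, 0, 0, 0.5, 0.5, 1, 1, sbc=True)
        assert cat == "SbC"

    def test_negative_indices_rank_below_positive(self):
        cat = tu.categorize(0.5, 0, 0.5, 0, 0.01, 1, 0.01, 1, sbc=False)
        assert cat == "DS"
        cat = tu.categorize(0.1, 0, 0.5, 0, 0.5, 1, 0.01, 1, sbc=False)
        assert cat == "DS_neg"


class TestPreprocess:
    def test_constant_movie_unchanged(self):
        movie = np.full((20, 8, 8), 3.0)
        out = tu.preprocess_movie(movie, 4.0)
        assert np.allclose(out, 3.0)

    def test_zero_motion_recovers_zero_shifts(self):
        rng = np.random.default_rng(0)
        frame = rng.random((16, 16))
        movie = np.repeat(frame[None], 10, axis=0)
        out = tu.preprocess_movie(movie, 4.0, correct_bidirectional=False, filter_ms=0.0)
        assert np.allclose(out, movie)

    def test_injected_jitter_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.random((24, 24))
        base[8:16, 8:16] += 3.0  # structure to register on
        shifts = [(0, 0), (2, -1), (-2, 2), (1, 1), (0, -2)] * 4
        movie = np.stack([np.roll(np.roll(base, dy, 0), dx, 1) for dy, dx in shifts])
        out = tu.preprocess_movie(movie, 4.0, correct_bidirectional=False, filter_ms=0.0)
        # after registration all frames match the reference frame
        ref = np.median(out, axis=0)
        frac_aligned = np.mean([np.allclose(f, ref) for f in out])
        assert frac_aligned >= 0.95

    def test_bad_frame_rate_rejected(self):
        with pytest.raises(ValueError):
            tu.preprocess_movie(np.zeros((5, 4, 4)), 0.0)


class TestLocalCorrelation:
    def test_iid_noise_near_zero(self):
        rng = np.random.default_rng(2)
        corr = tu.local_correlation_image(rng.normal(size=(300, 12, 12)))
        assert abs(corr.mean()) < 0.05

    def test_shared_signal_high_interior(self):
        rng = np.random.default_rng(3)
        sig = np.sin(np.linspace(0, 20, 400))
        movie = rng.normal(0, 0.05, (400, 12, 12))
        movie[:, 4:9, 4:9] += sig[:, None, None]
        corr = tu.local_correlation_image(movie)
        assert corr[5:8, 5:8].min() > 0.8

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            tu.local_correlation_image(np.zeros((1, 4, 4)))

    def test_constant_pixels_give_zero(self):
        movie = np.zeros((50, 6, 6))
        movie[:, 0, 0] = np.sin(np.arange(50))
        corr = tu.local_correlation_image(movie)
        assert corr[3, 3] == 0.0


class TestSegmentation:
    def _movie_with_somata(self, centers, seed=4):
        rng = np.random.default_rng(seed)
        sig = {c: np.cumsum(rng.normal(size=300)) for c in centers}
        movie = rng.normal(0, 0.1, (300, 24, 24))
        yy, xx = np.mgrid[0:24, 0:24]
        for c, s in sig.items():
            mask = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= 4
            movie[:, mask] += (s / np.abs(s).max())[:, None] + 1.0
        return movie

    def test_two_somata_two_disjoint_rois(self):
        movie = self._movie_with_somata([(6, 6), (17, 17)])
        corr = tu.local_correlation_image(movie)
        rois = tu.segment_rois(movie, corr)
        assert len(rois) == 2
        a = {tuple(p) for p in rois[0].pixels}
        b = {tuple(p) for p in rois[1].pixels}
        assert not a & b

    def test_single_soma_jaccard(self):
        movie = self._movie_with_somata([(12, 12)])
        corr = tu.local_correlation_image(movie)
        rois = tu.segment_rois(movie, corr)
        assert len(rois) == 1
        yy, xx = np.mgrid[0:24, 0:24]
        truth = {(y, x) for y, x in zip(*np.nonzero((yy - 12) ** 2 + (xx - 12) ** 2 <= 4))}
        got = {tuple(p) for p in rois[0].pixels}
        assert len(got & truth) / len(got | truth) >= 0.6

    def test_pure_noise_rarely_segments(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            movie = rng.normal(size=(200, 16, 16))
            corr = tu.local_correlation_image(movie)
            hits += len(tu.segment_rois(movie, corr)) > 0
        assert hits <= 1  # >=95% of seeds yield no ROI

    def test_background_disjoint_from_roi(self):
        movie = self._movie_with_somata([(12, 12)])
        corr = tu.local_correlation_image(movie)
        roi = tu.segment_rois(movie, corr)[0]
        a = {tuple(p) for p in roi.pixels}
        b = {tuple(p) for p in roi.background_pixels}
        assert not a & b and len(b) == 5


class TestExtractResponses:
    def test_flat_trace_all_zero(self, protocol):
        n = int(protocol.total_duration_s * 4.0) + 10
        resp = tu.extract_responses(np.ones(n) * 2.0, protocol, 4.0)
        assert np.allclose(resp.P, 0) and np.allclose(resp.N, 0)
        assert np.allclose(resp.mean_resp, 0)

    def test_boxcar_during_one_stimulus(self, protocol):
        fs = 4.0
        sched = protocol.schedule()
        row = sched[(sched["speed"] == 400.0) & (sched["direction"] == 90.0)]
        n = int(protocol.total_duration_s * fs) + 10
        trace = np.zeros(n)
        for _, r in row.iterrows():
            trace[int(r["onset_s"] * fs) : int(r["offset_s"] * fs)] = 1.0
        resp = tu.extract_responses(trace, protocol, fs, filter_ms=0.0)
        i, j = resp.speeds.index(400.0), resp.directions.index(90.0)
        assert resp.P[i, j] == pytest.approx(1.0)
        assert resp.N[i, j] == pytest.approx(0.0)
        assert resp.mean_resp[i, j] > 0.9

    def test_short_trace_rejected(self, protocol):
        with pytest.raises(ValueError, match="shorter"):
            tu.extract_responses(np.zeros(10), protocol, 4.0)


class TestPermutation:
    def _segments(self, rng, tuned=False, n_trials=4, n_samp=20):
        segs = rng.normal(0, 0.3, (8, n_trials, n_samp))
        if tuned:
            # graded von-Mises drive peaking at 90°
            amps = 2.0 * np.exp(2.0 * (np.cos(np.deg2rad(DIRS - 90.0)) - 1))
            segs += amps[:, None, None]
        return segs

    def test_identical_responses_not_significant(self):
        segs = np.ones((8, 4, 20))
        p = tu.permutation_significance(segs, DIRS, n_perm=200, seed=0)
        assert p > 0.5

    def test_tuned_cell_significant(self):
        hits = 0
        for seed in range(10):
            segs = self._segments(np.random.default_rng(seed), tuned=True, n_trials=6)
            p = tu.permutation_significance(segs, DIRS, n_perm=400, seed=seed)
            hits += p < 0.05
        assert hits >= 10 * 0.95

    def test_null_calibration(self):
        """Exchangeable-null rejection rate is 5% ± 2% over 500 sessions."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sessions = 500
        for _ in range(n_sessions):
            segs = self._segments(rng)
            p = tu.permutation_significance(segs, DIRS, n_perm=200, seed=rng)
            rejections += p < 0.05
        assert abs(rejections / n_sessions - 0.05) <= 0.02

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            tu.permutation_significance(np.zeros((8, 1, 10)), DIRS, n_perm=100, seed=0)

    def test_low_permutation_count_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            tu.permutation_significance(np.zeros((8, 2, 5)), DIRS, n_perm=99, seed=0)


class TestEndToEnd:
    def test_six_categories_recovered(self, six_kind_session, protocol):
        cfg, movie, roi_truth, tuning_truth = six_kind_session
        for ci, truth in enumerate(tuning_truth):
            mask = roi_truth[ci]["compartments"][0]["mask"]
            trace = movie[:, mask].mean(axis=1)
            resp = tu.extract_responses(trace, protocol, cfg.frame_rate, filter_ms=0.0)
            res = tu.analyze_tuning(resp, n_perm=300, seed=ci)
            want = {"DS": "DS", "OS": "OS", "DS_neg": "DS_neg", "OS_neg": "OS_neg",
                    "SbC": "SbC", "broad": "broad"}[truth["kind"]]
            assert res.category == want, f"cell {ci}: {truth['kind']} -> {res.category}"

    def test_ds_preferred_direction_within_15_deg(self, six_kind_session, protocol):
        cfg, movie, roi_truth, tuning_truth = six_kind_session
        mask = roi_truth[0]["compartments"][0]["mask"]
        trace = movie[:, mask].mean(axis=1)
        resp = tu.extract_responses(trace, protocol, cfg.frame_rate, filter_ms=0.0)
        res = tu.analyze_tuning(resp, n_perm=200, seed=0)
        corrected_truth = (tuning_truth[0]["preferred_deg"] - 20.0) % 360
        diff = abs((res.preferred_direction - corrected_truth + 180) % 360 - 180)
        assert res.dsi > 0.3
        assert diff <= 15.0

    def test_segmentation_finds_true_cells(self, six_kind_session):
        cfg, movie, roi_truth, _ = six_kind_session
        pre = tu.preprocess_movie(movie, cfg.frame_rate)
        corr = tu.local_correlation_image(pre)
        rois = tu.segment_rois(pre, corr)
        true_centroids = [r["compartments"][0]["centroid"] for r in roi_truth]
        matched = 0
        for tc in true_centroids:
            d = [np.hypot(r.centroid[0] - tc[0], r.centroid[1] - tc[1]) for r in rois]
            matched += min(d) < 3.0 if d else 0
        assert matched >= 5  # at least 5 of 6 ground-truth cells found


class TestMatchRois:
    def _session(self, centers, shift=(0, 0), seed=0):
        rng = np.random.default_rng(seed)
        img = rng.random((32, 32))
        for c in centers:
            img[c[0] - 1 : c[0] + 2, c[1] - 1 : c[1] + 2] += 2.0
        img = np.roll(np.roll(img, shift[0], 0), shift[1], 1)
        rois = [
            tu.Roi(np.array([[c[0] + shift[0], c[1] + shift[1]]]),
                   (c[0] + shift[0], c[1] + shift[1]))
            for c in centers
        ]
        return {"image": img, "rois": rois, "snr": [5.0] * len(rois)}

    def test_duplicated_session_matches_every_roi(self):
        s = self._session([(8, 8), (20, 20)])
        groups = tu.match_rois([s, s])
        assert len(groups) == 2
        assert all(len(g) == 2 for g in groups)

    def test_shifted_session_matches_recovered(self):
        a = self._session([(8, 8), (20, 20)])
        b = self._session([(8, 8), (20, 20)], shift=(3, -2))
        groups = tu.match_rois([a, b], max_shift=6)
        assert len(groups) == 2

    def test_disjoint_roi_sets_no_matches(self):
        a = self._session([(6, 6)])
        b = self._session([(24, 24)])
        groups = tu.match_rois([a, b])
        assert groups == []
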