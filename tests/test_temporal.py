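"""Tests of SSIM scheduling, ROI building, histogram peaks and the driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midirseg import (
    GaussianComponent,
    GmmParams,
    InvalidArgumentError,
    ItfGmmConfig,
    PeakRule,
    PixelMixture,
    SsimParams,
    TemporalHistogram,
    adapt_component_count,
    build_roi,
    count_histogram_peaks,
    global_ssim,
    init_model,
    itf_gmm_run,
    learning_rate_from_ssim,
    step_frame,
)


class TestGlobalSsim:
    def test_identical_images_give_one(self):
        img = np.random.default_rng(0).integers(0, 256, (8, 8)).astype(float)
        assert global_ssim(img, img) == pytest.approx(1.0)

    def test_constant_black_vs_white(self):
        a = np.zeros((6, 6))
        b = np.full((6, 6), 255.0)
        c1 = (0.01 * 255) ** 2
        expected = c1 / (255.0**2 + c1)
        assert global_ssim(a, b) == pytest.approx(expected)
        assert expected == pytest.approx(1.0e-4, rel=0.02)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 256, (10, 12)).astype(float)
        b = rng.integers(0, 256, (10, 12)).astype(float)
        assert global_ssim(a, b) == pytest.approx(global_ssim(b, a))

    def test_range_and_shape_check(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.integers(0, 256, (6, 6)).astype(float)
            b = rng.integers(0, 256, (6, 6)).astype(float)
            assert -1.0 <= global_ssim(a, b) <= 1.0
        with pytest.raises(InvalidArgumentError):
            global_ssim(np.zeros((3, 3)), np.zeros((4, 3)))


class TestLearningRateSchedule:
    @pytest.mark.parametrize("ssim,expected", [(1.0, 0.0), (0.0, 0.0125), (0.2, 0.01)])
    def test_closed_form_values(self, ssim, expected):
        assert learning_rate_from_ssim(ssim) == pytest.approx(expected)

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_and_bounded(self, s1, s2):
        a1, a2 = learning_rate_from_ssim(s1), learning_rate_from_ssim(s2)
        assert 0.0 <= a1 <= 1.0 / 40.0
        if s1 <= s2:
            assert a1 >= a2

    def test_out_of_range_input_clamped(self):
        assert learning_rate_from_ssim(5.0) == 0.0
        assert learning_rate_from_ssim(-5.0) == pytest.approx(2.0 / 80.0)


class TestBuildRoi:
    def test_tight_bounding_box(self):
        mask = np.zeros((50, 60), dtype=bool)
        mask[10:21, 30:41] = True
        roi = build_roi([mask], margin=0)
        assert (roi.row_start, roi.row_stop, roi.col_start, roi.col_stop) == (10, 21, 30, 41)

    def test_union_covers_separated_blobs(self):
        a = np.zeros((40, 40), dtype=bool)
        b = np.zeros((40, 40), dtype=bool)
        a[5, 5] = True
        b[30, 35] = True
        roi = build_roi([a, b], margin=0)
        assert roi.row_start == 5 and roi.row_stop == 31
        assert roi.col_start == 5 and roi.col_stop == 36

    def test_margin_clipped_to_frame(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1, 18] = True
        roi = build_roi([mask], margin=5)
        assert roi.row_start == 0 and roi.col_stop == 20

    def test_empty_union_falls_back_to_whole_frame(self):
        roi = build_roi([np.zeros((12, 15), dtype=bool)], margin=3)
        assert roi.shape == (12, 15)


class TestTemporalHistogram:
    def test_counts_sum_to_window_minimum(self):
        hist = TemporalHistogram((2, 2), window=5)
        rng = np.random.default_rng(0)
        for t in range(8):
            hist.push(rng.integers(0, 256, (2, 2)))
            assert hist.counts.sum(axis=1).tolist() == [min(t + 1, 5)] * 4

    def test_rolling_eviction(self):
        hist = TemporalHistogram((1, 1), window=3)
        for v in (10, 10, 20, 30):
            hist.push(np.array([[v]]))
        px = hist.pixel(0, 0)
        assert px[10] == 1 and px[20] == 1 and px[30] == 1


class TestPeakCounting:
    def test_single_unimodal_bump(self):
        h = np.zeros(256)
        h[95:106] = [1, 3, 7, 12, 18, 22, 18, 12, 7, 3, 1]
        assert count_histogram_peaks(h) == 1

    def test_distant_maxima_kept(self):
        h = np.zeros(256)
        h[50] = 10
        h[200] = 8
        assert count_histogram_peaks(h) == 2

    def test_close_maxima_merged(self):
        h = np.zeros(256)
        h[100] = 10
        h[120] = 8
        assert count_histogram_peaks(h, PeakRule(merge_distance=30)) == 1
        assert count_histogram_peaks(h, PeakRule(merge_distance=15)) == 2

    def test_merge_keeps_taller_peak_for_chain_decisions(self):
        # peaks at 100 (tall), 125, 160: 125 merges into 100, 160 survives
        h = np.zeros(256)
        h[100] = 20
        h[125] = 5
        h[160] = 7
        assert count_histogram_peaks(h, PeakRule(merge_distance=30)) == 2

    def test_plateau_counts_once(self):
        h = np.zeros(256)
        h[80:85] = 9   # flat-topped bump
        assert count_histogram_peaks(h) == 1

    def test_all_zero_returns_k_min(self):
        assert count_histogram_peaks(np.zeros(256), PeakRule(k_min=1)) == 1
        assert count_histogram_peaks(np.zeros(256), PeakRule(k_min=2)) == 2

    def test_clamped_to_k_max(self):
        h = np.zeros(256)
        h[::40] = 5
        assert count_histogram_peaks(h, PeakRule(k_max=3)) == 3

    @given(st.integers(2, 50))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_uniform_scaling(self, c):
        rng = np.random.default_rng(42)
        h = rng.integers(0, 30, 256)
        assert count_histogram_peaks(h) == count_histogram_peaks(h * c)


class TestAdaptComponentCount:
    def mixture(self, *weights):
        return PixelMixture(
            [GaussianComponent(w, 100.0 + 10 * i, 25.0) for i, w in enumerate(weights)]
        )

    def test_grow_renormalises(self):
        m = self.mixture(0.6, 0.4)
        adapt_component_count(m, 3)
        assert len(m) == 3
        assert sum(c.weight for c in m.components) == pytest.approx(1.0)

    def test_grow_seeds_least_covered_peak(self):
        m = self.mixture(0.6, 0.4)          # means 100, 110
        adapt_component_count(m, 3, peak_intensities=[105.0, 200.0])
        assert any(c.mean == 200.0 for c in m.components)

    def test_shrink_drops_lowest_ranked(self):
        m = self.mixture(0.5, 0.3, 0.2)
        adapt_component_count(m, 2)
        assert len(m) == 2
        assert sum(c.weight for c in m.components) == pytest.approx(1.0)
        assert {round(c.mean) for c in m.components} == {100, 110}

    def test_zero_target_clamped_to_one(self):
        m = self.mixture(0.5, 0.5)
        adapt_component_count(m, 0)
        assert len(m) == 1
        assert m.components[0].weight == pytest.approx(1.0)


def make_constant_sequence(n, shape=(12, 16), value=90.0):
    return [np.full(shape, value) for _ in range(n)]


class TestDriver:
    def small_config(self, **kw):
        defaults = dict(warmup_frames=8, roi_margin=2, hist_window=10)
        defaults.update(kw)
        return ItfGmmConfig(**defaults)

    def test_constant_sequence_all_background_after_warmup(self):
        result = itf_gmm_run(make_constant_sequence(25), self.small_config())
        for mask in result.post_warmup_masks():
            assert not mask.any()

    def test_identical_crops_freeze_in_roi_learning_rate(self):
        result = itf_gmm_run(make_constant_sequence(20), self.small_config())
        assert all(a == 0.0 for a in result.alpha_history)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidArgumentError):
            itf_gmm_run(make_constant_sequence(5), self.small_config())

    def test_component_counts_stay_in_clamp_range(self):
        rng = np.random.default_rng(9)
        frames = [np.clip(rng.normal(100, 5, (10, 12)), 0, 255) for _ in range(30)]
        cfg = self.small_config()
        result = itf_gmm_run(frames, cfg)
        k = result.state.n_active
        assert k.min() >= cfg.peak_rule.k_min
        assert k.max() <= cfg.peak_rule.k_max
        act = result.state.active_mask()
        sums = np.where(act, result.state.weight, 0.0).sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_disabled_features_equal_plain_model_bitwise(self):
        rng = np.random.default_rng(17)
        frames = [np.clip(rng.normal(100, 6, (9, 9)), 0, 255) for _ in range(20)]
        cfg = self.small_config(adapt_lr=False, adapt_k=False)
        result = itf_gmm_run(frames, cfg)
        state = init_model(frames[0], cfg.k_init, cfg.params,
                           capacity=max(cfg.peak_rule.k_max, cfg.k_init))
        plain = [np.zeros((9, 9), dtype=bool)]
        for f in frames[1:]:
            mask, state = step_frame(f, state)
            plain.append(mask)
        for a, b in zip(result.masks, plain):
            assert np.array_equal(a, b)

    def test_moving_bright_target_detected_in_phase_two(self):
        rng = np.random.default_rng(23)
        frames = []
        for t in range(30):
            f = np.clip(rng.normal(100, 2, (16, 20)), 0, 255)
            r = 4 + (t // 3) % 8
            f[r:r + 3, 9:12] += 60
            frames.append(np.clip(f, 0, 255))
        result = itf_gmm_run(frames, self.small_config())
        hits = sum(m.any() for m in result.post_warmup_masks())
        assert hits >= len(result.post_warmup_masks()) // 2
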