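"""Unit and property tests of the mixture background model."""

import numpy as np
import pytest

from midirseg import (
    GaussianComponent,
    GmmParams,
    InvalidArgumentError,
    InvalidStateError,
    NO_MATCH,
    PixelMixture,
    init_model,
    match_component,
    select_background,
    step_frame,
    update_mixture,
)
from reference_gmm import reference_masks


def mixture(*comps):
    return PixelMixture([GaussianComponent(w, mu, var) for w, mu, var in comps])


class TestInit:
    @pytest.mark.parametrize("k,expected", [(2, [0.5, 0.5]), (1, [1.0]), (4, [0.25] * 4)])
    def test_equal_initial_weights(self, k, expected):
        state = init_model(np.full((3, 3), 100.0), k, GmmParams())
        assert np.allclose(state.weight[1, 1, :k], expected)
        assert state.n_active[0, 0] == k

    def test_first_component_centred_on_pixel_and_initial_variance(self):
        frame = np.arange(12, dtype=float).reshape(3, 4)
        state = init_model(frame, 3, GmmParams(init_variance=225.0))
        assert np.allclose(state.mean[:, :, 0], frame)
        assert np.all(state.variance[:, :, :3] == 225.0)

    def test_rejects_bad_arguments(self):
        with pytest.raises(InvalidArgumentError):
            init_model(np.full((3, 3), 100.0), 0, GmmParams())
        with pytest.raises(InvalidArgumentError):
            init_model(np.full((3, 3), 300.0), 2, GmmParams())
        with pytest.raises(InvalidArgumentError):
            init_model(np.zeros((3, 3, 2)), 2, GmmParams())


class TestMatch:
    def test_within_two_point_five_sigma(self):
        m = mixture((1.0, 100.0, 100.0))  # sigma = 10
        assert match_component(120.0, m, 2.5) == 0

    def test_just_outside_bound(self):
        m = mixture((1.0, 100.0, 100.0))
        assert match_component(126.0, m, 2.5) == NO_MATCH

    def test_first_ranked_match_wins(self):
        m = mixture((0.5, 50.0, 25.0), (0.5, 200.0, 25.0))
        assert match_component(52.0, m, 2.5) == 0

    def test_multiplier_must_be_positive(self):
        with pytest.raises(InvalidArgumentError):
            match_component(1.0, mixture((1.0, 0.0, 1.0)), 0.0)


class TestUpdate:
    def test_matched_weight_gain(self):
        m = mixture((0.4, 100.0, 25.0), (0.6, 200.0, 25.0))
        update_mixture(m, 0, 100.0, alpha=0.1)
        by_mean = {round(c.mean): c.weight for c in m.components}
        assert by_mean[100] == pytest.approx(0.46)   # (1-a) w + a
        assert by_mean[200] == pytest.approx(0.54)   # (1-a) w

    def test_unmatched_weight_decay(self):
        m = mixture((0.5, 100.0, 25.0), (0.5, 200.0, 25.0))
        update_mixture(m, 0, 100.0, alpha=0.02)
        by_mean = {round(c.mean): c.weight for c in m.components}
        assert by_mean[200] == pytest.approx(0.49)

    def test_matched_mean_moves_by_rho(self):
        m = mixture((1.0, 100.0, 400.0))
        update_mixture(m, 0, 120.0, alpha=0.5)       # rho = alpha
        assert m.components[0].mean == pytest.approx(110.0)

    def test_no_match_replaces_weakest(self):
        p = GmmParams(init_variance=225.0, replacement_weight=0.05)
        m = mixture((0.7, 100.0, 4.0), (0.3, 150.0, 4.0))
        update_mixture(m, NO_MATCH, 250.0, alpha=0.01, params=p)
        means = [c.mean for c in m.components]
        assert 250.0 in means
        assert 150.0 not in means                    # lowest-ranked was evicted
        new = m.components[means.index(250.0)]
        assert new.variance == 225.0

    def test_alpha_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            update_mixture(mixture((1.0, 0.0, 1.0)), 0, 0.0, alpha=1.5)

    def test_weights_renormalised_and_sorted(self):
        rng = np.random.default_rng(3)
        m = mixture((0.2, 10.0, 9.0), (0.5, 90.0, 25.0), (0.3, 180.0, 100.0))
        for _ in range(30):
            x = float(rng.integers(0, 256))
            update_mixture(m, match_component(x, m, 2.5), x, alpha=0.05)
            assert sum(c.weight for c in m.components) == pytest.approx(1.0, abs=1e-9)
            assert m.is_sorted()


class TestSelectBackground:
    @pytest.mark.parametrize(
        "weights,T,expected",
        [([0.6, 0.3, 0.1], 0.5, 1), ([0.5, 0.3, 0.2], 0.7, 2), ([0.4, 0.3, 0.3], 1.0, 3)],
    )
    def test_prefix_selection(self, weights, T, expected):
        m = mixture(*[(w, 0.0, 1.0) for w in weights])
        assert select_background(m, T) == expected

    def test_unsorted_mixture_rejected(self):
        m = PixelMixture([GaussianComponent(0.1, 0.0, 1.0), GaussianComponent(0.9, 0.0, 1.0)])
        with pytest.raises(InvalidStateError):
            select_background(m, 0.7)


class TestStepFrame:
    def test_stationary_background_absorbed(self):
        frame = np.full((4, 4), 80.0)
        state = init_model(frame, 3, GmmParams())
        for _ in range(12):
            mask, state = step_frame(frame, state)
        assert not mask.any()

    def test_intensity_jump_is_foreground(self):
        frame = np.full((4, 4), 50.0)
        state = init_model(frame, 3, GmmParams(init_variance=100.0))
        for _ in range(10):
            mask, state = step_frame(frame, state)
        jumped = frame.copy()
        jumped[2, 1] = 250.0
        mask, state = step_frame(jumped, state)
        assert mask[2, 1]
        assert mask.sum() == 1

    def test_shape_mismatch_rejected(self):
        state = init_model(np.zeros((4, 4)), 2, GmmParams())
        with pytest.raises(InvalidArgumentError):
            step_frame(np.zeros((5, 4)), state)

    def test_alpha_zero_freezes_model(self):
        rng = np.random.default_rng(0)
        state = init_model(rng.integers(0, 256, (5, 5)).astype(float), 3, GmmParams())
        for _ in range(5):
            _, state = step_frame(rng.integers(0, 256, (5, 5)).astype(float), state)
        before = state.copy()
        _, state = step_frame(rng.integers(0, 256, (5, 5)).astype(float), state, alpha=0.0)
        assert np.array_equal(before.weight, state.weight)
        assert np.array_equal(before.mean, state.mean)
        assert np.array_equal(before.variance, state.variance)
        assert state.frame_count == before.frame_count + 1

    def test_weight_normalisation_and_order_invariant(self):
        rng = np.random.default_rng(1)
        state = init_model(rng.integers(0, 256, (6, 6)).astype(float), 3, GmmParams())
        for _ in range(25):
            _, state = step_frame(rng.integers(0, 256, (6, 6)).astype(float), state)
            act = state.active_mask()
            sums = np.where(act, state.weight, 0.0).sum(axis=2)
            assert np.allclose(sums, 1.0, atol=1e-9)
            key = np.where(act, state.weight / state.variance, -np.inf)
            assert np.all(np.diff(key, axis=2) <= 1e-12)

    def test_monotone_absorption_on_constant_video(self):
        frame = np.full((2, 2), 120.0)
        state = init_model(frame, 3, GmmParams(alpha=0.05))
        prev_top = state.weight[0, 0, 0]
        for _ in range(20):
            _, state = step_frame(frame, state)
            top = state.weight[0, 0, 0]
            assert top >= prev_top - 1e-12
            prev_top = top

    def test_scripted_grid_matches_scalar_reference(self):
        rng = np.random.default_rng(11)
        frames = rng.integers(0, 256, (10, 4, 4)).astype(float)
        params = GmmParams()
        state = init_model(frames[0], 3, params, capacity=3)
        impl = []
        for f in frames[1:]:
            mask, state = step_frame(f, state)
            impl.append(mask)
        for r in range(4):
            for c in range(4):
                expected = reference_masks(frames[:, r, c], 3, params)
                got = [bool(m[r, c]) for m in impl]
                assert got == expected, f"pixel ({r}, {c})"

    def test_single_pixel_histories_match_scalar_reference(self):
        rng = np.random.default_rng(2024)
        params = GmmParams()
        for _ in range(25):
            n = int(rng.integers(5, 51))
            history = rng.integers(0, 256, n).astype(float)
            state = init_model(history[:1].reshape(1, 1), 3, params, capacity=3)
            got = []
            for x in history[1:]:
                mask, state = step_frame(np.array([[x]]), state)
                got.append(bool(mask[0, 0]))
            assert got == reference_masks(history, 3, params)


class TestStatePersistence:
    def test_npz_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        state = init_model(rng.integers(0, 256, (4, 4)).astype(float), 3, GmmParams())
        for _ in range(7):
            _, state = step_frame(rng.integers(0, 256, (4, 4)).astype(float), state)
        path = tmp_path / "model.npz"
        state.save(path)
        loaded = state.load(path)
        assert np.array_equal(loaded.weight, state.weight)
        assert np.array_equal(loaded.mean, state.mean)
        assert np.array_equal(loaded.variance, state.variance)
        assert loaded.frame_count == state.frame_count
        assert loaded.params == state.params

    def test_mixture_at_reflects_arrays(self):
        state = init_model(np.full((2, 2), 42.0), 2, GmmParams())
        m = state.mixture_at(0, 0)
        assert len(m) == 2
        assert m.components[0].mean == 42.0
        assert sum(c.weight for c in m.components) == pytest.approx(1.0)


class TestGmmParams:
    def test_background_ratio_range_enforced(self):
        with pytest.raises(InvalidArgumentError):
            GmmParams(background_ratio=0.4)
        with pytest.raises(InvalidArgumentError):
            GmmParams(background_ratio=1.2)

    def test_auto_learning_rate_flag_maps_to_default(self):
        assert GmmParams(alpha=-1).alpha == 0.005
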