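"""Smoother, feature extraction, priors and Winsorization caps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethosim.kinematics import (
    KinematicPriors,
    build_priors,
    cap_increment,
    compute_residuals,
    extract_features,
    smooth_reference,
    wrap_angle,
)


# -- smoother ---------------------------------------------------------------

def brute_force_smooth(x, w):
    """Independent O(T*w) oracle: centered median then centered mean with
    symmetric window shrink at the boundaries."""
    h = w // 2

    def stage(v, stat):
        out = np.empty_like(v, dtype=float)
        for t in range(len(v)):
            hh = min(h, t, len(v) - 1 - t)
            out[t] = stat(v[t - hh : t + hh + 1])
        return out

    return stage(stage(np.asarray(x, float), np.median), np.mean)


def test_smoother_constant_signal_unchanged():
    x = np.full(100, 3.7)
    assert np.allclose(smooth_reference(x, 21), x)


def test_smoother_removes_single_spike():
    x = np.full(200, 1.0)
    x[100] = 51.0
    out = smooth_reference(x, 21)
    assert np.allclose(out, 1.0)


@pytest.mark.parametrize("w,T", [(5, 3), (5, 50), (21, 200), (41, 100)])
def test_smoother_matches_brute_force_oracle(w, T):
    rng = np.random.default_rng(w * 1000 + T)
    x = rng.normal(size=T)
    assert np.allclose(smooth_reference(x, w), brute_force_smooth(x, w))


def test_smoother_shift_equivariant():
    rng = np.random.default_rng(2)
    x = rng.normal(size=300)
    assert np.allclose(smooth_reference(x + 5.5, 21), smooth_reference(x, 21) + 5.5)


def test_smoother_rejects_even_window():
    with pytest.raises(ValueError):
        smooth_reference(np.zeros(10), 4)


# -- residuals --------------------------------------------------------------

def test_residuals_identity_and_offset():
    rng = np.random.default_rng(0)
    ref = rng.normal(size=(50, 2))
    assert np.allclose(compute_residuals(ref, ref), 0.0)
    b = np.array([0.3, -0.1])
    e = compute_residuals(ref + b, ref)
    assert np.allclose(e, b)
    # algebraic identity: reference + residual reconstructs observed
    obs = rng.normal(size=(50, 2))
    assert np.allclose(ref + compute_residuals(obs, ref), obs)


# -- features ---------------------------------------------------------------

def test_features_straight_line():
    xy = np.column_stack([np.arange(10.0), np.zeros(10)])
    f = extract_features(xy)
    assert np.allclose(f.step_lengths, 1.0)
    assert np.allclose(f.headings, 0.0)
    assert np.allclose(f.turning_angles, 0.0)


def test_features_right_angle_turn():
    xy = np.array([[0, 0], [1, 0], [1, 1]], dtype=float)
    f = extract_features(xy)
    assert np.isclose(f.turning_angles[0], np.pi / 2)


def test_turn_wrap_convention():
    # heading difference of 3*pi/2 wraps to -pi/2
    assert np.isclose(wrap_angle(3 * np.pi / 2), -np.pi / 2)


@settings(max_examples=100, deadline=None)
@given(
    st.floats(-20.0, 20.0, allow_nan=False),
    st.integers(min_value=-5, max_value=5),
)
def test_wrap_is_2pi_periodic_and_in_range(theta, k):
    w0 = wrap_angle(theta)
    wk = wrap_angle(theta + 2 * np.pi * k)
    assert -np.pi < w0 <= np.pi + 1e-12
    assert np.isclose(w0, wk, atol=1e-9)


# -- priors -----------------------------------------------------------------

def _priors_from_random(seed=4, T=500):
    rng = np.random.default_rng(seed)
    xy = np.cumsum(rng.normal(scale=0.01, size=(T, 2)), axis=0)
    labels = rng.integers(1, 4, T)
    return extract_features(xy), labels


def test_priors_partition_all_steps():
    feats, labels = _priors_from_random()
    pr = build_priors(feats, labels)
    total = sum(v.size for v in pr.step_samples_by_state.values())
    assert total == feats.step_lengths.size
    total_t = sum(v.size for v in pr.turn_samples_by_state.values())
    assert total_t == feats.turning_angles.size


def test_priors_single_state_flags_absent():
    feats, _ = _priors_from_random()
    pr = build_priors(feats, np.ones(feats.n_frames, int))
    assert set(pr.absent_states) == {2, 3}
    with pytest.raises(ValueError):
        pr.require_complete()


def test_caps_match_sort_based_quantile_oracle():
    feats, labels = _priors_from_random(seed=9)
    p = 0.9
    pr = build_priors(feats, labels, p_step=p, p_turn=p)
    for s in (1, 2, 3):
        v = np.sort(pr.step_samples_by_state[s])
        # type-7: linear interpolation between order statistics
        h = (v.size - 1) * p
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        expected = v[lo] + (h - lo) * (v[hi] - v[lo])
        assert np.isclose(pr.step_cap_by_state[s], expected)


def test_caps_at_p1_are_maxima():
    feats, labels = _priors_from_random(seed=10)
    pr = build_priors(feats, labels, p_step=1.0, p_turn=1.0)
    for s in (1, 2, 3):
        assert np.isclose(
            pr.step_cap_by_state[s], pr.step_samples_by_state[s].max()
        )
        assert np.isclose(
            pr.turn_cap_by_state[s], np.abs(pr.turn_samples_by_state[s]).max()
        )


@settings(max_examples=100, deadline=None)
@given(
    st.floats(0.0, 2.0, allow_nan=False),
    st.floats(-4.0, 4.0, allow_nan=False),
)
def test_cap_increment_winsorizes_and_is_idempotent(step, turn):
    pr = KinematicPriors(
        step_samples_by_state={1: np.array([0.1])},
        turn_samples_by_state={1: np.array([0.5])},
        step_cap_by_state={1: 0.5},
        turn_cap_by_state={1: 2.0},
        percentiles=(0.995, 0.995),
    )
    s1, t1 = cap_increment(step, turn, pr, 1)
    assert s1 <= 0.5 and s1 <= step + 1e-15
    assert abs(t1) <= 2.0 and abs(t1) <= abs(turn) + 1e-15
    assert np.sign(t1) == np.sign(turn) or t1 == 0
    s2, t2 = cap_increment(s1, t1, pr, 1)
    assert s2 == s1 and t2 == t1


def test_cap_increment_sign_preservation():
    pr = KinematicPriors(
        step_samples_by_state={1: np.array([0.1])},
        turn_samples_by_state={1: np.array([0.5])},
        step_cap_by_state={1: 1.0},
        turn_cap_by_state={1: 2.0},
        percentiles=(0.995, 0.995),
    )
    _, t = cap_increment(0.0, -3.0, pr, 1)
    assert t == -2.0
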