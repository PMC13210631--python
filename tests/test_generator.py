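"""State-sequence generation, feeding smoothing, and session synthesis."""

import numpy as np
import pytest

from ethosim.channel import ChannelParams, ObservationChannel
from ethosim.dynamics import (
    CalibratedChain,
    DwellModel,
    TransitionMatrix,
    empirical_occupancy,
    stationary_distribution,
    induced_occupancy,
)
from ethosim.generator import (
    GeneratorConfig,
    generate_state_sequence,
    smooth_feeding,
    synthesize_session,
)
from ethosim.kinematics import KinematicPriors, extract_features


def _chain(P=None, dwell_samples=None):
    P = np.asarray(
        P if P is not None else [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]],
        dtype=float,
    )
    tm = TransitionMatrix(P=P, counts=np.zeros((3, 3), int))
    mu = stationary_distribution(P)
    dwell = DwellModel(
        samples_by_state=dwell_samples
        or {1: [3, 5], 2: [1, 2], 3: [2, 4]}
    )
    occ = induced_occupancy(mu, dwell.means_vector())
    return (
        CalibratedChain(
            alpha=P[0, 1:].copy(),
            transition_matrix=tm,
            stationary=mu,
            occupancy=occ,
            objective=0.0,
            grid_step=0.001,
        ),
        dwell,
    )


def test_single_frame_truncation():
    chain, dwell = _chain()
    labels = generate_state_sequence(chain, dwell, 1, np.random.default_rng(0))
    assert labels.shape == (1,) and labels[0] in (1, 2, 3)


def test_unit_dwell_never_repeats():
    chain, dwell = _chain(dwell_samples={1: [1], 2: [1], 3: [1]})
    labels = generate_state_sequence(chain, dwell, 500, np.random.default_rng(1))
    assert (labels[1:] != labels[:-1]).all()


@pytest.mark.parametrize(
    "pattern,expected_join",
    [
        # preceding run strictly longer -> joins exploring
        ([1] * 5 + [2] + [3] * 3, 1),
        # tie -> preceding run wins
        ([1] * 3 + [2] + [3] * 3, 1),
        # following run longer -> joins the following state
        ([1] * 2 + [2] + [3] * 3, 3),
    ],
)
def test_smooth_feeding_singleton_assignment(pattern, expected_join):
    out = smooth_feeding(pattern)
    idx = pattern.index(2)
    assert out[idx] == expected_join
    # all other frames unchanged
    mask = np.ones(len(pattern), bool)
    mask[idx] = False
    assert np.array_equal(out[mask], np.asarray(pattern)[mask])


def test_smooth_feeding_fixed_point_without_singletons():
    seq = [1] * 4 + [2, 2] + [3] * 3 + [1] * 2
    assert np.array_equal(smooth_feeding(seq), seq)
    # longer feeding runs survive untouched
    assert (smooth_feeding(seq) == 2).sum() == 2


def test_smooth_feeding_removes_all_interior_singletons():
    rng = np.random.default_rng(3)
    seq = rng.integers(1, 4, 2000)
    out = smooth_feeding(seq)
    from ethosim.dynamics import segment_runs

    rs = segment_runs(out)
    interior = np.arange(1, len(rs) - 1)
    assert not any(
        rs.states[k] == 2 and rs.durations[k] == 1 for k in interior
    )


# -- full synthesis ---------------------------------------------------------

def _point_channel(scale=1e-12, bias=(0.0, 0.0), cap=1.0):
    params = {}
    caps = {}
    for s in (1, 2, 3):
        for c in ("LoS", "NLoS"):
            params[(s, c)] = ChannelParams(
                bias=np.asarray(bias),
                gauss_cov=scale * np.eye(2),
                outlier_prob=0.0,
                t_scale=scale * np.eye(2),
                t_dof=4.0,
            )
            caps[(s, c)] = cap
    return ObservationChannel(
        params_by_bin=params, distortion_cap_by_bin=caps,
        cap_percentile=0.999, n_min=5,
    )


def _point_priors(step=0.01, turn=0.0):
    return KinematicPriors(
        step_samples_by_state={s: np.array([step]) for s in (1, 2, 3)},
        turn_samples_by_state={s: np.array([turn]) for s in (1, 2, 3)},
        step_cap_by_state={s: step for s in (1, 2, 3)},
        turn_cap_by_state={s: max(abs(turn), 1e-9) for s in (1, 2, 3)},
        percentiles=(0.995, 0.995),
    )


def test_zero_distortion_channel_observed_equals_latent():
    chain, dwell = _chain()
    sess = synthesize_session(
        chain, dwell, _point_priors(), _point_channel(),
        GeneratorConfig(length=200, regime="LoS", seed=0),
    )
    assert np.allclose(sess.observed_xy, sess.latent_xy, atol=1e-5)


def test_point_mass_priors_straight_line():
    chain, dwell = _chain()
    T = 300
    sess = synthesize_session(
        chain, dwell, _point_priors(step=0.01, turn=0.0), _point_channel(),
        GeneratorConfig(length=T, regime="LoS", seed=4),
    )
    steps = np.diff(sess.latent_xy, axis=0)
    assert np.allclose(np.hypot(steps[:, 0], steps[:, 1]), 0.01)
    total = np.linalg.norm(sess.latent_xy[-1] - sess.latent_xy[0])
    assert np.isclose(total, (T - 1) * 0.01, rtol=1e-9)


def test_synthesis_bitwise_deterministic(fitted):
    a = fitted.simulate("NLoS", n_sessions=1, length=500, seed=42)[0]
    b = fitted.simulate("NLoS", n_sessions=1, length=500, seed=42)[0]
    assert np.array_equal(a.observed_xy, b.observed_xy)
    assert np.array_equal(a.latent_xy, b.latent_xy)
    assert np.array_equal(a.labels, b.labels)
    c = fitted.simulate("NLoS", n_sessions=1, length=500, seed=43)[0]
    assert not np.array_equal(a.observed_xy, c.observed_xy)


def test_cap_compliance_over_seeded_sessions(fitted):
    """Latent steps never exceed the largest step cap and observed-minus-
    latent magnitudes never exceed the largest distortion cap (scan of 100
    seeded sessions)."""
    max_step = max(fitted.priors.step_cap_by_state.values())
    for regime in ("LoS", "NLoS"):
        max_cap = max(
            fitted.channel.cap_for(s, regime) for s in (1, 2, 3)
        )
        for sess in fitted.simulate(regime, n_sessions=50, length=300, seed=7):
            f = extract_features(sess.latent_xy)
            assert f.step_lengths.max() <= max_step + 1e-12
            e = sess.observed_xy - sess.latent_xy
            assert np.hypot(e[:, 0], e[:, 1]).max() <= max_cap + 1e-12


def test_synthetic_occupancy_matches_calibration(fitted):
    """Mean occupancy over 50 seeded T=3000 sessions stays within 0.03 per
    state of the real occupancy used for calibration (feeding smoothing only
    slightly shifts the feeding share)."""
    synth = fitted.simulate("LoS", n_sessions=50, length=3000, seed=900)
    occ = np.mean([empirical_occupancy(s.labels) for s in synth], axis=0)
    assert np.abs(occ - fitted.pi_real).max() < 0.03


def test_latent_steps_match_prior_distribution(fitted):
    """State-conditioned latent step lengths reproduce the (capped) prior
    sample sets: two-sample KS < 0.02 at ~1e5 pooled samples per state."""
    from scipy.stats import ks_2samp

    sessions = fitted.simulate("LoS", n_sessions=40, length=3000, seed=50)
    for s in (1, 2, 3):
        synth = np.concatenate(
            [
                extract_features(sess.latent_xy).step_lengths[sess.labels[1:] == s]
                for sess in sessions
            ]
        )
        prior = fitted.priors.step_samples_by_state[s]
        cap = fitted.priors.step_cap_by_state[s]
        stat = ks_2samp(synth, np.minimum(prior, cap)).statistic
        assert stat < 0.02, (s, stat, synth.size)
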