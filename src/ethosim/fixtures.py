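"""Ground-truth session generator standing in for the real UWB recordings.

The real dataset (two LoS and two NLoS sessions of ~3000 frames at 10 Hz) is
not bundled; this module generates *real-like* sessions from a fully known
parametric ground truth so that calibration, parameter recovery and the whole
pipeline are testable offline. The generating mechanism mirrors the model's
assumptions — a zero-diagonal run-level chain with parametric dwell laws,
state-conditioned step/turn laws, and an additive state- and regime-
conditioned Gaussian/Student-t observation channel — so closure tests can
compare recovered parameters against the truth.

Default magnitudes emulate a mouse in an open arena at 10 Hz: exploring
dominates with long bouts and the longest steps (~0.2 m/s), feeding bouts are
short and nearly stationary, burrowing is intermediate; the NLoS channel has
a larger bias, wider covariance and a higher outlier probability than LoS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .config import DT, LOS, NLOS, REGIMES, STATES
from .channel import ChannelParams, sample_mixture
from .dynamics import induced_occupancy, stationary_distribution
from .kinematics import wrap_angle
from .session import Session, default_frame_times

__all__ = ["GroundTruth", "default_ground_truth", "make_real_like_sessions"]


@dataclass(frozen=True)
class DwellLaw:
    """Shifted negative-binomial run-duration law: d = 1 + NB(r, p), frames."""

    r: float
    p: float

    @property
    def mean(self) -> float:
        return 1.0 + self.r * (1.0 - self.p) / self.p

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        return 1 + rng.negative_binomial(self.r, self.p, size)


@dataclass(frozen=True)
class StepLaw:
    """Gamma step-length law (meters per frame)."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size)


@dataclass(frozen=True)
class TurnLaw:
    """Wrapped zero-mean normal turning-angle law (radians)."""

    sigma: float

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        return wrap_angle(rng.normal(0.0, self.sigma, size))


@dataclass
class GroundTruth:
    """Fully known generative parameters for real-like fixture sessions."""

    chain: np.ndarray  # (3, 3) zero-diagonal row-stochastic
    dwell_laws: Dict[int, DwellLaw]
    step_laws: Dict[int, StepLaw]
    turn_laws: Dict[int, TurnLaw]
    channel_truth: Dict[Tuple[int, str], ChannelParams]

    @property
    def dwell_means(self) -> np.ndarray:
        return np.array([self.dwell_laws[s].mean for s in STATES])

    @property
    def occupancy_truth(self) -> np.ndarray:
        """Frame occupancy implied by the chain and the mean dwell times."""
        mu = stationary_distribution(self.chain)
        return induced_occupancy(mu, self.dwell_means)


def _iso(v: float) -> np.ndarray:
    return v * np.eye(2)


def default_ground_truth() -> GroundTruth:
    """Documented default truth.

    Exploring-dominant chain; dwell means ordered exploring >> burrowing >
    feeding (15 s, 5 s, 2.5 s bouts); exploring steps longest. The NLoS
    channel has a larger bias norm, larger covariance and a higher outlier
    probability than LoS, emulating NLoS-induced multipath distortion.
    """
    chain = np.array(
        [
            [0.0, 0.60, 0.40],
            [0.85, 0.0, 0.15],
            [0.90, 0.10, 0.0],
        ]
    )
    dwell_laws = {
        1: DwellLaw(r=2.0, p=2.0 / 151.0),  # mean 150 frames = 15 s
        2: DwellLaw(r=2.0, p=2.0 / 26.0),  # mean 25 frames = 2.5 s
        3: DwellLaw(r=2.0, p=2.0 / 51.0),  # mean 50 frames = 5 s
    }
    step_laws = {
        1: StepLaw(shape=2.5, scale=0.008),  # mean 0.020 m/frame ~ 0.20 m/s
        2: StepLaw(shape=2.0, scale=0.002),  # mean 0.004 m/frame ~ 0.04 m/s
        3: StepLaw(shape=2.0, scale=0.004),  # mean 0.008 m/frame ~ 0.08 m/s
    }
    turn_laws = {
        1: TurnLaw(sigma=0.35),  # persistent exploratory headings
        2: TurnLaw(sigma=1.20),  # near-stationary jittery heading
        3: TurnLaw(sigma=0.80),
    }
    channel: Dict[Tuple[int, str], ChannelParams] = {}
    los_bias = {1: (0.008, -0.004), 2: (0.012, 0.004), 3: (0.010, -0.006)}
    los_rho = {1: 0.02, 2: 0.04, 3: 0.03}
    nlos_bias = {1: (0.050, 0.025), 2: (0.060, 0.030), 3: (0.055, 0.020)}
    nlos_rho = {1: 0.12, 2: 0.18, 3: 0.15}
    for s in STATES:
        channel[(s, LOS)] = ChannelParams(
            bias=np.array(los_bias[s]),
            gauss_cov=_iso(4e-4),  # 2 cm nominal sd
            outlier_prob=los_rho[s],
            t_scale=_iso(2e-3),
            t_dof=4.0,
        )
        channel[(s, NLOS)] = ChannelParams(
            bias=np.array(nlos_bias[s]),
            gauss_cov=_iso(1.6e-3),  # 4 cm nominal sd
            outlier_prob=nlos_rho[s],
            t_scale=_iso(1e-2),
            t_dof=4.0,
        )
    return GroundTruth(
        chain=chain,
        dwell_laws=dwell_laws,
        step_laws=step_laws,
        turn_laws=turn_laws,
        channel_truth=channel,
    )


def _truth_state_sequence(
    truth: GroundTruth, T: int, rng: np.random.Generator
) -> np.ndarray:
    mu = stationary_distribution(truth.chain)
    labels = np.empty(T, dtype=int)
    idx = int(rng.choice(len(STATES), p=mu))
    filled = 0
    while filled < T:
        dur = int(truth.dwell_laws[STATES[idx]].sample(rng, 1)[0])
        dur = min(dur, T - filled)
        labels[filled : filled + dur] = STATES[idx]
        filled += dur
        if filled < T:
            idx = int(rng.choice(len(STATES), p=truth.chain[idx]))
    return labels


def make_real_like_session(
    truth: GroundTruth, regime: str, T: int, rng: np.random.Generator
) -> Session:
    """One real-like session with all latent quantities retained."""
    labels = _truth_state_sequence(truth, T, rng)
    heading = float(rng.uniform(-np.pi, np.pi))
    latent = np.zeros((T, 2))
    steps = np.zeros(T - 1)
    turns = np.zeros(T - 1)
    arrival = labels[1:]
    for s in STATES:
        mask = arrival == s
        n_s = int(mask.sum())
        if n_s:
            steps[mask] = truth.step_laws[s].sample(rng, n_s)
            turns[mask] = truth.turn_laws[s].sample(rng, n_s)
    headings = heading + np.cumsum(turns)
    latent[1:, 0] = np.cumsum(steps * np.cos(headings))
    latent[1:, 1] = np.cumsum(steps * np.sin(headings))
    distortion = np.empty((T, 2))
    for s in STATES:
        mask = labels == s
        n_s = int(mask.sum())
        if n_s:
            params = truth.channel_truth[(s, regime)]
            distortion[mask] = sample_mixture(params, rng, size=n_s)
    return Session(
        frame_times=default_frame_times(T),
        observed_xy=latent + distortion,
        labels=labels,
        regime=regime,
        latent_xy=latent,
    )


def make_real_like_sessions(
    truth: GroundTruth,
    n_los: int = 2,
    n_nlos: int = 2,
    T: int = 3000,
    seed: int = 0,
) -> List[Session]:
    """Generate the stand-in "real" dataset (default: 2 LoS + 2 NLoS, T=3000).

    All randomness flows through one seeded stream; identical seeds give
    identical session sets.
    """
    rng = np.random.default_rng(seed)
    sessions = []
    for _ in range(n_los):
        sessions.append(make_real_like_session(truth, LOS, T, rng))
    for _ in range(n_nlos):
        sessions.append(make_real_like_session(truth, NLOS, T, rng))
    return sessions
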