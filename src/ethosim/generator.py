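"""End-to-end synthesis of sensor-observed sessions.

A session is generated in four stages:

1. a run-based state sequence: the first run state drawn from the calibrated
   chain's stationary run distribution, successors from the calibrated
   transition matrix, durations bootstrapped from the empirical dwell
   multisets, the final run truncated to land exactly on T frames;
2. feeding smoothing: isolated single-frame feeding runs are reassigned to
   the longer neighboring run (preceding run on ties) before any kinematics
   are drawn;
3. latent propagation: per-frame step lengths and turning angles are
   bootstrapped from the arrival-state priors, Winsorized at the prior caps,
   and integrated into a heading/position track;
4. observation: a distortion is drawn from the (state, regime) channel bin at
   every frame (including the first), radially capped, and added to the
   latent position.

All randomness flows through one numpy Generator per session in a fixed call
order (states, heading, steps, turns, distortions), so a fixed seed
reproduces a session bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import DT, LOS, STATES
from .dynamics import CalibratedChain, DwellModel, segment_runs
from .kinematics import KinematicPriors
from .channel import ObservationChannel, sample_mixture, cap_distortion
from .session import Session, default_frame_times

__all__ = [
    "GeneratorConfig",
    "generate_state_sequence",
    "smooth_feeding",
    "synthesize_session",
]

FEEDING = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Per-session synthesis settings (defaults: 3000 frames = 300 s)."""

    length: int = 3000
    dt: float = DT
    regime: str = LOS
    seed: int = 0
    init_position: tuple = (0.0, 0.0)
    init_heading: Optional[float] = None  # None: uniform on (-pi, pi]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1 frame")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def generate_state_sequence(
    chain: CalibratedChain,
    dwell: DwellModel,
    T: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Run-based state sequence of exactly T frames.

    The initial run state is drawn from the stationary run distribution
    mu(alpha); successors follow P(alpha); durations are bootstrapped from the
    empirical dwell multisets; the final run is truncated at T.
    """
    for s in STATES:
        d = dwell.samples_by_state.get(s)
        if d is None or d.size == 0:
            raise ValueError(f"no dwell samples for state {s}")
    P = chain.transition_matrix.P
    labels = np.empty(T, dtype=int)
    state_idx = int(rng.choice(len(STATES), p=chain.stationary))
    filled = 0
    while filled < T:
        state = STATES[state_idx]
        dur = min(dwell.sample(state, rng), T - filled)
        labels[filled : filled + dur] = state
        filled += dur
        if filled < T:
            state_idx = int(rng.choice(len(STATES), p=P[state_idx]))
    return labels


def smooth_feeding(labels: Sequence[int]) -> np.ndarray:
    """Remove interior singleton feeding runs for temporal coherence.

    A feeding frame whose neighbors are both non-feeding is reassigned to the
    neighboring state whose run is longer, ties resolved in favor of the
    preceding run. Boundary frames (no two-sided neighborhood) are untouched;
    all other frames are unchanged.
    """
    labels = np.asarray(labels, dtype=int)
    runs = segment_runs(labels)
    states = runs.states.copy()
    durations = runs.durations
    K = len(states)
    # decisions taken on the original run structure, then rebuilt
    for k in range(1, K - 1):
        if states[k] == FEEDING and durations[k] == 1:
            if runs.durations[k - 1] >= runs.durations[k + 1]:
                states[k] = runs.states[k - 1]
            else:
                states[k] = runs.states[k + 1]
    return np.repeat(states, durations)


def synthesize_session(
    chain: CalibratedChain,
    dwell: DwellModel,
    priors: KinematicPriors,
    channel: ObservationChannel,
    cfg: GeneratorConfig,
) -> Session:
    """Generate one sensor-observed synthetic session.

    Returns a :class:`Session` carrying the latent trajectory, the observed
    trajectory (latent + capped distortion) and the smoothed state labels.
    """
    priors.require_complete()
    rng = np.random.default_rng(cfg.seed)
    T = cfg.length

    labels = smooth_feeding(generate_state_sequence(chain, dwell, T, rng))

    if cfg.init_heading is None:
        heading0 = float(rng.uniform(-np.pi, np.pi))
    else:
        heading0 = float(cfg.init_heading)

    # bootstrap state-conditioned increments for t = 2..T (arrival states)
    steps = np.zeros(max(T - 1, 0))
    turns = np.zeros(max(T - 1, 0))
    arrival = labels[1:]
    for s in STATES:  # fixed state order keeps the rng stream reproducible
        mask = arrival == s
        n_s = int(mask.sum())
        if n_s == 0:
            continue
        L = priors.step_samples_by_state[s]
        Th = priors.turn_samples_by_state[s]
        steps[mask] = L[rng.integers(0, L.size, n_s)]
        turns[mask] = Th[rng.integers(0, Th.size, n_s)]
        q_l = priors.step_cap_by_state[s]
        q_t = priors.turn_cap_by_state[s]
        steps[mask] = np.minimum(steps[mask], q_l)
        turns[mask] = np.sign(turns[mask]) * np.minimum(np.abs(turns[mask]), q_t)

    # phi_t = phi_{t-1} + theta_t for t = 2..T (a turn is applied before the
    # first step too, as in the propagation recursion)
    headings = heading0 + np.cumsum(turns)
    latent = np.empty((T, 2))
    latent[0] = cfg.init_position
    if T > 1:
        dx = steps * np.cos(headings)
        dy = steps * np.sin(headings)
        latent[1:, 0] = latent[0, 0] + np.cumsum(dx)
        latent[1:, 1] = latent[0, 1] + np.cumsum(dy)

    # distortion at every frame, grouped per state in fixed order
    distortion = np.empty((T, 2))
    for s in STATES:
        mask = labels == s
        n_s = int(mask.sum())
        if n_s == 0:
            continue
        params = channel.resolve(s, cfg.regime)
        e = sample_mixture(params, rng, size=n_s)
        distortion[mask] = cap_distortion(e, channel.cap_for(s, cfg.regime))

    observed = latent + distortion
    return Session(
        frame_times=default_frame_times(T, cfg.dt),
        observed_xy=observed,
        labels=labels,
        regime=cfg.regime,
        latent_xy=latent,
    )
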