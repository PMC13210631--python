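"""Reference smoothing, kinematic features, and state-conditioned priors.

The reference trajectory is a denoised proxy for the animal's true motion,
obtained coordinate-wise by a centered rolling median followed by a centered
rolling mean (median first to reject outliers, mean to restore smoothness).
From the reference we extract per-frame step lengths, headings and turning
angles; these are pooled per *arrival* state into empirical priors from which
the generator later bootstraps, with high-percentile Winsorization caps to
keep long-horizon synthesis stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .config import LOS, NLOS, STATES, validate_labels

__all__ = [
    "SmootherSpec",
    "KinematicFeatures",
    "KinematicPriors",
    "smooth_reference",
    "compute_residuals",
    "extract_features",
    "build_priors",
    "cap_increment",
    "wrap_angle",
]


@dataclass(frozen=True)
class SmootherSpec:
    """Two-stage smoother window per regime, in samples (odd, centered)."""

    window_by_regime: Mapping[str, int] = field(
        default_factory=lambda: {LOS: 21, NLOS: 41}
    )

    def __post_init__(self) -> None:
        for regime, w in self.window_by_regime.items():
            if w < 1 or w % 2 == 0:
                raise ValueError(f"window for {regime} must be odd and >= 1, got {w}")

    def window_for(self, regime: str) -> int:
        return int(self.window_by_regime[regime])


def _rolling_center(values: np.ndarray, w: int, stat) -> np.ndarray:
    """Centered rolling statistic with symmetric window shrink at boundaries.

    At index t the window is ``[t-h, t+h]`` with ``h = min(w//2, t, T-1-t)``
    so the window stays centered on t and shrinks to a single sample at the
    edges. Interior frames (full windows) are vectorized via a stride view.
    """
    T = values.shape[0]
    h = w // 2
    out = np.empty_like(values, dtype=float)
    if T >= w:
        windows = np.lib.stride_tricks.sliding_window_view(values, w)
        out[h : T - h] = stat(windows, axis=1)
    for t in range(min(h, T)):
        hh = min(h, t, T - 1 - t)
        out[t] = stat(values[t - hh : t + hh + 1])
    for t in range(max(T - h, 0), T):
        hh = min(h, t, T - 1 - t)
        out[t] = stat(values[t - hh : t + hh + 1])
    if T < w:  # no full windows at all: every frame is a boundary frame
        for t in range(T):
            hh = min(h, t, T - 1 - t)
            out[t] = stat(values[t - hh : t + hh + 1])
    return out


def smooth_reference(xy: np.ndarray, w: int) -> np.ndarray:
    """Two-stage reference smoother: rolling median then rolling mean.

    Applied coordinate-wise with centered windows of ``w`` samples; output has
    the same length as the input (boundary windows shrink symmetrically down
    to one sample, so no frame is lost).
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {w}")
    xy = np.asarray(xy, dtype=float)
    squeeze = xy.ndim == 1
    if squeeze:
        xy = xy[:, None]
    out = np.empty_like(xy)
    for j in range(xy.shape[1]):
        med = _rolling_center(xy[:, j], w, np.median)
        out[:, j] = _rolling_center(med, w, np.mean)
    return out[:, 0] if squeeze else out


def compute_residuals(observed: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Residual distortion e_t = observed_t - reference_t (meters)."""
    observed = np.asarray(observed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if observed.shape != reference.shape:
        raise ValueError("observed and reference must have equal shapes")
    return observed - reference


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]; invariant under adding 2*pi*k."""
    wrapped = -(np.mod(-np.asarray(theta, dtype=float) + np.pi, 2 * np.pi) - np.pi)
    return wrapped


@dataclass
class KinematicFeatures:
    """Per-frame step lengths, headings and turning angles of one trajectory.

    ``step_lengths[i]`` and ``headings[i]`` describe the displacement *into*
    frame ``i + 1`` (0-based); ``turning_angles[i]`` is the wrapped heading
    change into frame ``i + 2``. Features are thus defined from the second
    frame on, turns from the third.
    """

    step_lengths: np.ndarray  # (T-1,), meters
    headings: np.ndarray  # (T-1,), radians
    turning_angles: np.ndarray  # (T-2,), radians in (-pi, pi]

    @property
    def n_frames(self) -> int:
        return self.step_lengths.size + 1


def extract_features(xy: np.ndarray) -> KinematicFeatures:
    """Step length, heading and turning angle of a planar trajectory."""
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValueError("need a (T, 2) array with T >= 2")
    d = np.diff(xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    headings = np.arctan2(d[:, 1], d[:, 0])
    turns = wrap_angle(np.diff(headings))
    return KinematicFeatures(step_lengths=steps, headings=headings, turning_angles=turns)


@dataclass
class KinematicPriors:
    """State-conditioned empirical increment priors with Winsorization caps.

    Step-length samples L_i and turning-angle samples T_i are assigned to the
    *arrival* state of the displacement; A_i = |T_i|. Caps are the p_step /
    p_turn quantiles (type-7, linear interpolation) of L_i and A_i.
    """

    step_samples_by_state: Dict[int, np.ndarray]
    turn_samples_by_state: Dict[int, np.ndarray]
    step_cap_by_state: Dict[int, float]
    turn_cap_by_state: Dict[int, float]
    percentiles: tuple  # (p_step, p_turn)
    absent_states: tuple = ()

    @property
    def abs_turn_samples_by_state(self) -> Dict[int, np.ndarray]:
        return {s: np.abs(t) for s, t in self.turn_samples_by_state.items()}

    def require_complete(self) -> None:
        if self.absent_states:
            raise ValueError(
                f"states {self.absent_states} have no kinematic samples; "
                "priors cannot drive synthesis"
            )


def build_priors(
    features: KinematicFeatures,
    labels: Sequence[int],
    p_step: float = 0.995,
    p_turn: float = 0.995,
) -> KinematicPriors:
    """Assemble state-conditioned priors from one trajectory's features.

    ``labels`` are the frame-level states aligned with the trajectory the
    features came from; sample (l_t, theta_t) joins the sample set of the
    arrival-state label z_t.
    """
    labels = np.asarray(labels, dtype=int)
    validate_labels(labels)
    if labels.size != features.n_frames:
        raise ValueError("labels must align with the feature source frames")
    step_states = labels[1:]  # arrival state of each step
    turn_states = labels[2:]  # arrival state of each turn
    return pool_priors(
        [(features.step_lengths, step_states)],
        [(features.turning_angles, turn_states)],
        p_step=p_step,
        p_turn=p_turn,
    )


def pool_priors(
    step_chunks: Sequence[tuple],
    turn_chunks: Sequence[tuple],
    p_step: float = 0.995,
    p_turn: float = 0.995,
) -> KinematicPriors:
    """Build priors from (samples, arrival-states) chunks pooled over sessions."""
    steps: Dict[int, list] = {s: [] for s in STATES}
    turns: Dict[int, list] = {s: [] for s in STATES}
    for values, states in step_chunks:
        for s in STATES:
            steps[s].append(np.asarray(values)[np.asarray(states) == s])
    for values, states in turn_chunks:
        for s in STATES:
            turns[s].append(np.asarray(values)[np.asarray(states) == s])
    step_samples = {s: np.concatenate(v) if v else np.empty(0) for s, v in steps.items()}
    turn_samples = {s: np.concatenate(v) if v else np.empty(0) for s, v in turns.items()}
    absent = tuple(
        s for s in STATES if step_samples[s].size == 0 or turn_samples[s].size == 0
    )
    step_caps = {
        s: float(np.quantile(v, p_step)) if v.size else float("nan")
        for s, v in step_samples.items()
    }
    turn_caps = {
        s: float(np.quantile(np.abs(v), p_turn)) if v.size else float("nan")
        for s, v in turn_samples.items()
    }
    return KinematicPriors(
        step_samples_by_state=step_samples,
        turn_samples_by_state=turn_samples,
        step_cap_by_state=step_caps,
        turn_cap_by_state=turn_caps,
        percentiles=(p_step, p_turn),
        absent_states=absent,
    )


def cap_increment(
    step: float | np.ndarray,
    turn: float | np.ndarray,
    priors: KinematicPriors,
    state: int,
) -> tuple:
    """Winsorize one state's sampled increments against the prior caps.

    The step is clipped from above; the turning angle is clipped in magnitude
    with its sign preserved. Idempotent by construction.
    """
    q_l = priors.step_cap_by_state.get(int(state))
    q_t = priors.turn_cap_by_state.get(int(state))
    if q_l is None or q_t is None or np.isnan(q_l) or np.isnan(q_t):
        raise ValueError(f"no caps available for state {state}")
    step_c = np.minimum(step, q_l)
    turn_c = np.sign(turn) * np.minimum(np.abs(turn), q_t)
    return step_c, turn_c
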