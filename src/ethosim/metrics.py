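"""Statistical Turing test and MSD-based temporal realism.

Real and synthetic sessions are compared along (i) behavioral-state occupancy,
(ii) state-conditioned histogram KL divergences of step length and turning
angle (natural log, additive-epsilon smoothing, shared bin edges from the
pooled sample range so binning never confounds the comparison),
(iii) occupancy-weighted KL summaries, (iv) pooled residual-magnitude KL and
two-sample KS within a sensing regime, and (v) mean-squared displacement
across lags with an RMSE summary between group-mean curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import ks_2samp

from .config import DT, STATES
from .dynamics import empirical_occupancy, pooled_empirical_occupancy
from .kinematics import SmootherSpec, compute_residuals, extract_features, smooth_reference
from .session import Session

__all__ = [
    "HistogramSpec",
    "TuringReport",
    "MsdCurve",
    "histogram_pmf",
    "kl_divergence",
    "turing_report",
    "msd",
    "mean_msd_curve",
    "rmse_msd",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Histogram settings for divergence metrics (B bins over [lo, hi])."""

    n_bins: int = 50
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def histogram_pmf(
    samples: np.ndarray,
    edges: np.ndarray,
    epsilon: float = 1e-12,
) -> np.ndarray:
    """Additively smoothed, normalized histogram PMF on fixed bin edges.

    Out-of-range samples are clipped to the edge bins; an empty sample set
    yields the uniform epsilon-only PMF.
    """
    edges = np.asarray(edges, dtype=float)
    samples = np.asarray(samples, dtype=float)
    if samples.size:
        clipped = np.clip(samples, edges[0], edges[-1])
        counts, _ = np.histogram(clipped, bins=edges)
    else:
        counts = np.zeros(edges.size - 1)
    smoothed = counts + epsilon
    return smoothed / smoothed.sum()


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL divergence (nats) between strictly positive PMFs of equal length."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("pmf length mismatch")
    if (p <= 0).any() or (q <= 0).any():
        raise ValueError("pmfs must be strictly positive (use epsilon smoothing)")
    return float(np.sum(p * np.log(p / q)))


@dataclass
class TuringReport:
    """Realism metric bundle for one regime comparison (all KL in nats)."""

    regime: str
    occupancy_real: np.ndarray
    occupancy_synth: np.ndarray
    occupancy_error: np.ndarray  # synth - real, per state
    kl_step_by_state: Dict[int, float]
    kl_turn_by_state: Dict[int, float]
    weighted_kl_step: float
    weighted_kl_turn: float
    residual_kl: float
    residual_ks: float

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "occupancy_real": self.occupancy_real.tolist(),
            "occupancy_synth": self.occupancy_synth.tolist(),
            "occupancy_error": self.occupancy_error.tolist(),
            "kl_step_by_state": {str(k): v for k, v in self.kl_step_by_state.items()},
            "kl_turn_by_state": {str(k): v for k, v in self.kl_turn_by_state.items()},
            "weighted_kl_step": self.weighted_kl_step,
            "weighted_kl_turn": self.weighted_kl_turn,
            "residual_kl": self.residual_kl,
            "residual_ks": self.residual_ks,
        }


def _state_samples(sessions: Sequence[Session]) -> Tuple[Dict[int, np.ndarray], Dict[int, np.ndarray]]:
    """Pooled per-arrival-state observed-domain step and turn samples."""
    steps: Dict[int, list] = {s: [] for s in STATES}
    turns: Dict[int, list] = {s: [] for s in STATES}
    for sess in sessions:
        feats = extract_features(sess.observed_xy)
        arr_step = sess.labels[1:]
        arr_turn = sess.labels[2:]
        for s in STATES:
            steps[s].append(feats.step_lengths[arr_step == s])
            turns[s].append(feats.turning_angles[arr_turn == s])
    return (
        {s: np.concatenate(v) for s, v in steps.items()},
        {s: np.concatenate(v) for s, v in turns.items()},
    )


def _residual_magnitudes(
    sessions: Sequence[Session], smoother: SmootherSpec
) -> np.ndarray:
    """Pooled proxy-referenced residual magnitudes across sessions."""
    mags = []
    for sess in sessions:
        ref = sess.reference_xy
        if ref is None:
            ref = smooth_reference(sess.observed_xy, smoother.window_for(sess.regime))
        e = compute_residuals(sess.observed_xy, ref)
        mags.append(np.hypot(e[:, 0], e[:, 1]))
    return np.concatenate(mags)


def _shared_edges(a: np.ndarray, b: np.ndarray, n_bins: int) -> np.ndarray:
    pooled = np.concatenate([a, b])
    if pooled.size == 0:
        return np.linspace(0.0, 1.0, n_bins + 1)
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        hi = lo + 1e-12
    return np.linspace(lo, hi, n_bins + 1)


def turing_report(
    real: Sequence[Session],
    synth: Sequence[Session],
    spec: HistogramSpec = HistogramSpec(),
    pi_real: Optional[np.ndarray] = None,
    smoother: SmootherSpec = SmootherSpec(),
) -> TuringReport:
    """Full statistical Turing comparison of one regime's real vs synthetic sets.

    Features are extracted from *observed* trajectories; bin edges are shared
    between real and synthetic samples (pooled range per feature and state);
    the weighted KL uses the real-data occupancy as weights; residual metrics
    pool magnitudes across states within the regime.
    """
    if not real or not synth:
        raise ValueError("both session sets must be non-empty")
    regimes = {s.regime for s in real} | {s.regime for s in synth}
    if len(regimes) != 1:
        raise ValueError(f"sessions must share one regime, got {sorted(regimes)}")
    regime = regimes.pop()

    occ_real = pooled_empirical_occupancy([s.labels for s in real])
    occ_synth = pooled_empirical_occupancy([s.labels for s in synth])
    if pi_real is None:
        pi_real = occ_real

    real_steps, real_turns = _state_samples(real)
    synth_steps, synth_turns = _state_samples(synth)

    kl_step, kl_turn = {}, {}
    for s in STATES:
        edges = _shared_edges(real_steps[s], synth_steps[s], spec.n_bins)
        p = histogram_pmf(real_steps[s], edges, spec.epsilon)
        q = histogram_pmf(synth_steps[s], edges, spec.epsilon)
        kl_step[s] = kl_divergence(p, q)
        edges = _shared_edges(real_turns[s], synth_turns[s], spec.n_bins)
        p = histogram_pmf(real_turns[s], edges, spec.epsilon)
        q = histogram_pmf(synth_turns[s], edges, spec.epsilon)
        kl_turn[s] = kl_divergence(p, q)

    w = np.asarray(pi_real, dtype=float)
    weighted_step = float(sum(w[i] * kl_step[s] for i, s in enumerate(STATES)))
    weighted_turn = float(sum(w[i] * kl_turn[s] for i, s in enumerate(STATES)))

    r_mag = _residual_magnitudes(real, smoother)
    s_mag = _residual_magnitudes(synth, smoother)
    edges = _shared_edges(r_mag, s_mag, spec.n_bins)
    residual_kl = kl_divergence(
        histogram_pmf(r_mag, edges, spec.epsilon),
        histogram_pmf(s_mag, edges, spec.epsilon),
    )
    residual_ks = float(ks_2samp(r_mag, s_mag, method="asymp").statistic)

    return TuringReport(
        regime=regime,
        occupancy_real=occ_real,
        occupancy_synth=occ_synth,
        occupancy_error=occ_synth - np.asarray(pi_real, float),
        kl_step_by_state=kl_step,
        kl_turn_by_state=kl_turn,
        weighted_kl_step=weighted_step,
        weighted_kl_turn=weighted_turn,
        residual_kl=residual_kl,
        residual_ks=residual_ks,
    )


# ---------------------------------------------------------------------------
# mean-squared displacement
# ---------------------------------------------------------------------------

@dataclass
class MsdCurve:
    """MSD(k) over lags k = 1..K frames; n_pairs(k) = T - k."""

    lags: np.ndarray  # frames
    msd: np.ndarray  # m^2
    n_pairs: np.ndarray
    dt: float = DT

    @property
    def lag_seconds(self) -> np.ndarray:
        return self.lags * self.dt


def msd(xy: np.ndarray, K: int, dt: float = DT) -> MsdCurve:
    """Mean-squared displacement MSD(k) = mean_t ||x_{t+k} - x_t||^2, k=1..K."""
    xy = np.asarray(xy, dtype=float)
    T = xy.shape[0]
    if K < 1 or K >= T:
        raise ValueError(f"need 1 <= K < T, got K={K}, T={T}")
    lags = np.arange(1, K + 1)
    out = np.empty(K)
    for i, k in enumerate(lags):
        d = xy[k:] - xy[:-k]
        out[i] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
    return MsdCurve(lags=lags, msd=out, n_pairs=T - lags, dt=dt)


def mean_msd_curve(
    trajectories: Iterable[np.ndarray], K: int, dt: float = DT
) -> Tuple[MsdCurve, np.ndarray]:
    """Group mean MSD curve and per-lag standard deviation across trajectories.

    Trajectories shorter than K + 1 frames are excluded (with no resampling of
    the lag grid), so all averaged curves share identical lags.
    """
    curves = []
    for xy in trajectories:
        if np.asarray(xy).shape[0] <= K:
            import warnings

            warnings.warn("trajectory shorter than K+1 frames excluded from MSD mean")
            continue
        curves.append(msd(xy, K, dt).msd)
    if not curves:
        raise ValueError("no trajectory long enough for the requested lag grid")
    stack = np.vstack(curves)
    lags = np.arange(1, K + 1)
    mean_curve = MsdCurve(lags=lags, msd=stack.mean(axis=0), n_pairs=np.full(K, len(curves)), dt=dt)
    return mean_curve, stack.std(axis=0)


def rmse_msd(curve_real: MsdCurve, curve_synth: MsdCurve) -> float:
    """RMSE between two mean MSD curves on an identical lag grid (m^2)."""
    if not np.array_equal(curve_real.lags, curve_synth.lags):
        raise ValueError("lag grids differ")
    diff = curve_synth.msd - curve_real.msd
    return float(np.sqrt(np.mean(diff**2)))
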