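"""Run-level semi-Markov dynamics and occupancy calibration.

The frame-level label sequence is collapsed into *runs* (maximal blocks of a
single state). Run succession is modeled as a first-order Markov chain with a
structurally zero diagonal — persistence lives entirely in the state-specific
dwell-time distributions, which are kept empirical (the multiset of observed
run durations). Frame-level occupancy is induced by weighting the chain's
stationary run frequencies with mean dwell times:

    pi_i = mu_i * m_i / sum_l mu_l * m_l

Because the dominant state (exploring) exits rarely, its outgoing transition
row is poorly estimated from run counts alone; `calibrate_occupancy` replaces
that single row with the point alpha = (alpha_2, alpha_3) on the simplex that
makes the induced occupancy best match the empirically observed occupancy,
leaving the rare-state rows at their (renormalized) empirical values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence

import numpy as np

from .config import STATES, validate_labels

__all__ = [
    "RunSequence",
    "TransitionMatrix",
    "DwellModel",
    "CalibratedChain",
    "segment_runs",
    "estimate_transition_matrix",
    "fit_dwell_model",
    "stationary_distribution",
    "induced_occupancy",
    "empirical_occupancy",
    "calibrate_occupancy",
]

N_STATES = len(STATES)


class EstimationError(RuntimeError):
    """Raised when a quantity cannot be estimated from the data provided."""


@dataclass
class RunSequence:
    """Run-length encoding of a label sequence: ordered (state, duration) pairs.

    Durations are frames and sum to ``total_frames``; adjacent runs always
    carry different states.
    """

    states: np.ndarray  # (K,) int
    durations: np.ndarray  # (K,) int, frames
    total_frames: int

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.durations = np.asarray(self.durations, dtype=int)
        if (self.durations < 1).any():
            raise ValueError("run durations must be >= 1 frame")
        if (self.states[1:] == self.states[:-1]).any():
            raise ValueError("adjacent runs must differ in state")
        if int(self.durations.sum()) != self.total_frames:
            raise ValueError("run durations do not sum to total_frames")

    def __len__(self) -> int:
        return len(self.states)

    def expand(self) -> np.ndarray:
        """Frame-level labels reproducing the original sequence exactly."""
        return np.repeat(self.states, self.durations)


@dataclass
class TransitionMatrix:
    """Zero-diagonal run-level transition matrix with its count table.

    Rows with no observed outgoing transition are undefined under maximum
    likelihood; they are filled uniformly over the other states and flagged in
    ``degenerate_rows`` (the fill only matters for synthesis, never for the
    reported counts).
    """

    P: np.ndarray  # (3, 3), zero diagonal, rows sum to 1
    counts: np.ndarray  # (3, 3) nonnegative ints, zero diagonal
    degenerate_rows: tuple = ()

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.P.shape != (N_STATES, N_STATES):
            raise ValueError("P must be 3x3")
        if not np.allclose(np.diag(self.P), 0.0):
            raise ValueError("P must have a zero diagonal")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("P rows must sum to 1")


@dataclass
class DwellModel:
    """Empirical dwell-time distributions: per-state duration multisets (frames)."""

    samples_by_state: Dict[int, np.ndarray]
    absent_states: tuple = ()

    def __post_init__(self) -> None:
        self.samples_by_state = {
            int(s): np.asarray(d, dtype=int) for s, d in self.samples_by_state.items()
        }

    @property
    def mean_by_state(self) -> Dict[int, float]:
        return {s: float(d.mean()) for s, d in self.samples_by_state.items() if d.size}

    def means_vector(self) -> np.ndarray:
        """Mean dwell (frames) ordered by state id; raises if a state is absent."""
        out = np.empty(N_STATES)
        for i, s in enumerate(STATES):
            d = self.samples_by_state.get(s)
            if d is None or d.size == 0:
                raise EstimationError(f"no dwell samples for state {s}")
            out[i] = d.mean()
        return out

    def sample(self, state: int, rng: np.random.Generator) -> int:
        """Bootstrap one dwell time (with replacement) from the state's multiset."""
        d = self.samples_by_state.get(int(state))
        if d is None or d.size == 0:
            raise EstimationError(f"no dwell samples for state {state}")
        return int(d[rng.integers(0, d.size)])


@dataclass
class CalibratedChain:
    """Outcome of occupancy calibration of the exploring-exit row.

    ``alpha`` is (alpha_2, alpha_3) on the simplex; rows 2 and 3 of
    ``transition_matrix`` are the renormalized empirical rows (betas); the
    stationary run distribution and induced occupancy are evaluated at alpha.
    """

    alpha: np.ndarray  # (2,), sums to 1
    transition_matrix: TransitionMatrix
    stationary: np.ndarray  # mu(alpha)
    occupancy: np.ndarray  # pi(alpha)
    objective: float  # ||pi(alpha) - pi_real||^2 at the optimum
    grid_step: float

    @property
    def betas(self) -> np.ndarray:
        return self.transition_matrix.P[1:, :].copy()


# ---------------------------------------------------------------------------
# segmentation and estimation
# ---------------------------------------------------------------------------

def segment_runs(labels: Sequence[int]) -> RunSequence:
    """Collapse consecutive identical labels into (state, duration) runs."""
    labels = np.asarray(labels, dtype=int)
    validate_labels(labels)
    boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [labels.size]))
    return RunSequence(
        states=labels[starts],
        durations=ends - starts,
        total_frames=int(labels.size),
    )


def _as_run_list(runs: RunSequence | Iterable[RunSequence]) -> list[RunSequence]:
    if isinstance(runs, RunSequence):
        return [runs]
    return list(runs)


def count_transitions(runs: RunSequence | Iterable[RunSequence]) -> np.ndarray:
    """Run-level transition count table N_ij pooled across sequences."""
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    for rs in _as_run_list(runs):
        a = rs.states[:-1] - 1
        b = rs.states[1:] - 1
        np.add.at(counts, (a, b), 1)
    return counts


def estimate_transition_matrix(
    runs: RunSequence | Iterable[RunSequence],
) -> TransitionMatrix:
    """Maximum-likelihood zero-diagonal transition matrix from run counts.

    Rows without outgoing transitions are filled uniformly over the other two
    states and flagged degenerate.
    """
    counts = count_transitions(runs)
    if counts.sum() == 0:
        raise EstimationError("no run-level transitions observed")
    P = np.zeros((N_STATES, N_STATES))
    degenerate = []
    for i in range(N_STATES):
        row_sum = counts[i].sum()
        if row_sum == 0:
            P[i] = 1.0 / (N_STATES - 1)
            P[i, i] = 0.0
            degenerate.append(STATES[i])
        else:
            P[i] = counts[i] / row_sum
    return TransitionMatrix(P=P, counts=counts, degenerate_rows=tuple(degenerate))


def fit_dwell_model(runs: RunSequence | Iterable[RunSequence]) -> DwellModel:
    """Per-state empirical run-duration multisets pooled across sequences."""
    pooled: Dict[int, list] = {s: [] for s in STATES}
    for rs in _as_run_list(runs):
        for s, d in zip(rs.states, rs.durations):
            pooled[int(s)].append(int(d))
    absent = tuple(s for s in STATES if not pooled[s])
    return DwellModel(
        samples_by_state={s: np.asarray(v, dtype=int) for s, v in pooled.items()},
        absent_states=absent,
    )


# ---------------------------------------------------------------------------
# stationary distribution and occupancy
# ---------------------------------------------------------------------------

def stationary_distribution(P: np.ndarray | TransitionMatrix) -> np.ndarray:
    """Unique stationary distribution mu of a row-stochastic matrix.

    Solved exactly as the left null space of (P - I) with the normalization
    1' mu = 1 (3x3 problem, no iteration). Raises when the chain has no
    unique stationary law (reducible / multiple closed classes).
    """
    if isinstance(P, TransitionMatrix):
        P = P.P
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    # eigen-decomposition of P', eigenvalue 1 must be simple
    w, v = np.linalg.eig(P.T)
    close = np.isclose(w, 1.0, atol=1e-8)
    if close.sum() != 1:
        raise EstimationError(
            "chain has no unique stationary distribution (reducible or periodic)"
        )
    mu = np.real(v[:, close.argmax()])
    mu = mu / mu.sum()
    if (mu < -1e-10).any():
        raise EstimationError("stationary solve produced negative mass")
    mu = np.clip(mu, 0.0, None)
    mu /= mu.sum()
    resid = np.abs(mu @ P - mu).max()
    if resid > 1e-10:
        raise EstimationError(f"stationary residual too large: {resid:g}")
    return mu


def induced_occupancy(mu: np.ndarray, dwell_means: np.ndarray | DwellModel) -> np.ndarray:
    """Frame-level occupancy induced by run frequencies and mean dwell times."""
    if isinstance(dwell_means, DwellModel):
        dwell_means = dwell_means.means_vector()
    mu = np.asarray(mu, dtype=float)
    m = np.asarray(dwell_means, dtype=float)
    if (m <= 0).any():
        raise ValueError("mean dwell times must be positive")
    pi = mu * m
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate occupancy normalization")
    return pi / total


def empirical_occupancy(labels: Sequence[int]) -> np.ndarray:
    """Fraction of frames per state, ordered by state id."""
    labels = np.asarray(labels, dtype=int)
    validate_labels(labels)
    return np.array([(labels == s).mean() for s in STATES])


def pooled_empirical_occupancy(label_seqs: Iterable[Sequence[int]]) -> np.ndarray:
    """Occupancy over the concatenation of several label sequences."""
    return empirical_occupancy(np.concatenate([np.asarray(x) for x in label_seqs]))


# ---------------------------------------------------------------------------
# occupancy calibration
# ---------------------------------------------------------------------------

def _chain_template(alpha2: float, betas: np.ndarray) -> np.ndarray:
    P = np.zeros((N_STATES, N_STATES))
    P[0, 1] = alpha2
    P[0, 2] = 1.0 - alpha2
    P[1:, :] = betas
    return P


def renormalized_betas(P_hat: TransitionMatrix) -> np.ndarray:
    """Rows 2..3 of the empirical matrix renormalized over off-diagonals."""
    betas = P_hat.P[1:, :].copy()
    for r in range(betas.shape[0]):
        betas[r, r + 1] = 0.0
        s = betas[r].sum()
        if s <= 0:
            raise EstimationError(
                f"state {STATES[r + 1]} has no off-diagonal transition mass"
            )
        betas[r] /= s
    return betas


def calibrate_occupancy(
    P_hat: TransitionMatrix,
    dwell: DwellModel,
    pi_real: np.ndarray,
    grid_step: float = 0.001,
) -> CalibratedChain:
    """Grid-search the exploring-exit row to match empirical occupancy.

    Minimizes ``||pi(alpha) - pi_real||_2^2`` over alpha_2 in {0, grid_step,
    ..., 1} with alpha_3 = 1 - alpha_2; rows 2 and 3 stay at their empirical
    (renormalized) values. Exhaustive search guarantees the reported minimum is
    global on the grid; grid points yielding a reducible chain are skipped.
    """
    pi_real = np.asarray(pi_real, dtype=float)
    if pi_real.shape != (N_STATES,) or abs(pi_real.sum() - 1.0) > 1e-9:
        raise ValueError("pi_real must be a valid occupancy vector")
    m = dwell.means_vector()
    betas = renormalized_betas(P_hat)
    n_pts = int(round(1.0 / grid_step)) + 1
    grid = np.linspace(0.0, 1.0, n_pts)
    best = None
    for a2 in grid:
        P = _chain_template(a2, betas)
        try:
            mu = stationary_distribution(P)
        except EstimationError:
            continue
        pi = induced_occupancy(mu, m)
        obj = float(((pi - pi_real) ** 2).sum())
        if best is None or obj < best[0]:
            best = (obj, a2, P, mu, pi)
    if best is None:
        raise EstimationError("all candidate chains reducible; cannot calibrate")
    obj, a2, P, mu, pi = best
    tm = TransitionMatrix(P=P, counts=P_hat.counts, degenerate_rows=P_hat.degenerate_rows)
    return CalibratedChain(
        alpha=np.array([a2, 1.0 - a2]),
        transition_matrix=tm,
        stationary=mu,
        occupancy=pi,
        objective=obj,
        grid_step=grid_step,
    )
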