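"""Statsmodels-style model front-end: calibrate once, then simulate.

:class:`TrajectoryModel` holds the labeled sessions and the run configuration;
``fit()`` performs the full calibration — run segmentation, run-level chain
estimation, dwell modeling, occupancy calibration, reference smoothing,
kinematic prior construction with caps, and the EM fit of the observation
channel with hierarchical pooling — and returns a :class:`TrajectoryResults`
carrying the calibrated parameter bundle, diagnostics and a ``summary()``
table. Synthesis (`simulate`) and serialization (`save`/`load`) hang off the
results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import dynamics, kinematics
from .channel import (
    ChannelParams,
    ObservationChannel,
    ResidualSet,
    fit_channel,
)
from .config import LOS, NLOS, REGIMES, STATES, STATE_NAMES, RunConfig
from .dynamics import (
    CalibratedChain,
    DwellModel,
    TransitionMatrix,
    calibrate_occupancy,
    estimate_transition_matrix,
    fit_dwell_model,
    pooled_empirical_occupancy,
    segment_runs,
)
from .generator import GeneratorConfig, synthesize_session
from .kinematics import KinematicPriors, compute_residuals, extract_features, smooth_reference
from .session import Session, read_session

__all__ = ["TrajectoryModel", "TrajectoryResults", "load_results"]

_SCHEMA_VERSION = 1


class BundleLoadError(RuntimeError):
    pass


class TrajectoryModel:
    """Sensor-aware generative trajectory model built from labeled sessions.

    Parameters
    ----------
    sessions : sequence of Session
        Labeled planar trajectories; both regimes should be represented for
        the channel fit (sparser regimes fall back to pooling).
    config : RunConfig
        Resolved tunables (smoother windows, percentiles, EM settings, ...).
    """

    def __init__(self, sessions: Sequence[Session], config: RunConfig = RunConfig()):
        if not sessions:
            raise ValueError("need at least one session")
        self.sessions = list(sessions)
        self.config = config

    @classmethod
    def from_csv(
        cls, paths: Sequence[str | Path], config: RunConfig = RunConfig()
    ) -> "TrajectoryModel":
        return cls([read_session(p) for p in paths], config)

    # -- calibration -----------------------------------------------------
    def fit(self) -> "TrajectoryResults | PerRegimeResults":
        cfg = self.config

        if not cfg.pool_regimes:
            # per-regime estimation: each regime's sessions calibrate their
            # own chain, priors and channel
            import dataclasses

            pooled_cfg = dataclasses.replace(cfg, pool_regimes=True)
            by_regime = {}
            for regime in REGIMES:
                sess = [s for s in self.sessions if s.regime == regime]
                if sess:
                    by_regime[regime] = TrajectoryModel(sess, pooled_cfg).fit()
            return PerRegimeResults(config=cfg, by_regime=by_regime)

        # run-level dynamics pooled across sessions (both regimes)
        run_seqs = [segment_runs(s.labels) for s in self.sessions]
        P_hat = estimate_transition_matrix(run_seqs)
        dwell = fit_dwell_model(run_seqs)
        pi_real = pooled_empirical_occupancy([s.labels for s in self.sessions])
        chain = calibrate_occupancy(P_hat, dwell, pi_real, grid_step=cfg.grid_step)

        # reference smoothing with the regime-specific window, then priors
        # and residuals from the reference proxy
        step_chunks, turn_chunks = [], []
        resid, resid_states, resid_regimes = [], [], []
        fitted_sessions = []
        for sess in self.sessions:
            ref = smooth_reference(sess.observed_xy, cfg.window_for(sess.regime))
            fitted_sessions.append(sess.with_reference(ref))
            feats = extract_features(ref)
            step_chunks.append((feats.step_lengths, sess.labels[1:]))
            turn_chunks.append((feats.turning_angles, sess.labels[2:]))
            e = compute_residuals(sess.observed_xy, ref)
            resid.append(e)
            resid_states.append(sess.labels)
            resid_regimes.append(np.full(sess.n_frames, sess.regime, dtype=object))
        priors = kinematics.pool_priors(
            step_chunks, turn_chunks, p_step=cfg.p_step, p_turn=cfg.p_turn
        )
        priors.require_complete()

        residual_set = ResidualSet(
            residuals=np.vstack(resid),
            states=np.concatenate(resid_states),
            regimes=np.concatenate(resid_regimes),
        )
        channel = fit_channel(
            residual_set,
            nu=cfg.nu,
            n_min=cfg.n_min,
            reg=cfg.em_reg,
            p_resid=cfg.p_resid,
            tol=cfg.em_tol,
            max_iter=cfg.em_max_iter,
        )

        return TrajectoryResults(
            config=cfg,
            chain=chain,
            dwell=dwell,
            priors=priors,
            channel=channel,
            pi_real=pi_real,
            sessions=fitted_sessions,
        )


@dataclass
class TrajectoryResults:
    """Calibrated parameter bundle with diagnostics and synthesis methods."""

    config: RunConfig
    chain: CalibratedChain
    dwell: DwellModel
    priors: KinematicPriors
    channel: ObservationChannel
    pi_real: np.ndarray
    sessions: Optional[List[Session]] = None  # calibration sessions w/ references

    # -- synthesis -------------------------------------------------------
    def simulate(
        self,
        regime: str,
        n_sessions: int = 1,
        length: Optional[int] = None,
        seed: int = 0,
    ) -> List[Session]:
        """Generate synthetic observed-domain sessions under one regime.

        Session ``i`` uses seed ``seed + i`` so cohorts are reproducible and
        individual sessions can be regenerated in isolation.
        """
        length = length or self.config.n_frames
        out = []
        for i in range(n_sessions):
            cfg = GeneratorConfig(
                length=length, dt=self.config.dt, regime=regime, seed=seed + i
            )
            out.append(
                synthesize_session(self.chain, self.dwell, self.priors, self.channel, cfg)
            )
        return out

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Human-readable calibration summary table."""
        cfg = self.config
        lines = []
        add = lines.append
        add("Sensor-aware trajectory model — calibration summary")
        add("=" * 64)
        add("Run-level transition counts N_ij (rows: from, cols: to):")
        for i, s in enumerate(STATES):
            row = "  ".join(f"{c:6d}" for c in self.chain.transition_matrix.counts[i])
            add(f"  {STATE_NAMES[s]:<10s} {row}")
        if self.chain.transition_matrix.degenerate_rows:
            add(f"  degenerate rows: {self.chain.transition_matrix.degenerate_rows}")
        add("")
        a2, a3 = self.chain.alpha
        add(f"Calibrated exploring exits: alpha = ({a2:.3f}, {a3:.3f}), "
            f"objective = {self.chain.objective:.3e} (grid step {self.chain.grid_step})")
        add("Occupancy (real vs calibrated model):")
        for i, s in enumerate(STATES):
            add(
                f"  {STATE_NAMES[s]:<10s} real {self.pi_real[i]:.4f}   "
                f"model {self.chain.occupancy[i]:.4f}"
            )
        add("")
        add("Dwell means (frames) and prior caps:")
        means = self.dwell.mean_by_state
        for s in STATES:
            add(
                f"  {STATE_NAMES[s]:<10s} m={means.get(s, float('nan')):8.2f}   "
                f"q_step={self.priors.step_cap_by_state[s]:.4f} m   "
                f"q_turn={self.priors.turn_cap_by_state[s]:.3f} rad"
            )
        add("")
        add(f"Observation channel (nu={cfg.nu:g}, Nmin={cfg.n_min}):")
        for (s, c), p in sorted(self.channel.params_by_bin.items(), key=str):
            cap = self.channel.cap_for(s, c)
            add(
                f"  ({STATE_NAMES[s]:<9s},{c:>5s}) rho={p.outlier_prob:.3f} "
                f"|bias|={np.linalg.norm(p.bias):.4f} m  cap={cap:.4f} m  "
                f"pooling={p.pooling_level} (n={p.n_samples})"
            )
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def mat(a):
            return np.asarray(a).tolist()

        return {
            "schema_version": _SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "chain": {
                "alpha": mat(self.chain.alpha),
                "P": mat(self.chain.transition_matrix.P),
                "counts": mat(self.chain.transition_matrix.counts),
                "degenerate_rows": list(self.chain.transition_matrix.degenerate_rows),
                "stationary": mat(self.chain.stationary),
                "occupancy": mat(self.chain.occupancy),
                "objective": self.chain.objective,
                "grid_step": self.chain.grid_step,
            },
            "dwell": {
                str(s): mat(d)
                for s, d in sorted(self.dwell.samples_by_state.items())
            },
            "priors": {
                "steps": {
                    str(s): mat(v)
                    for s, v in sorted(self.priors.step_samples_by_state.items())
                },
                "turns": {
                    str(s): mat(v)
                    for s, v in sorted(self.priors.turn_samples_by_state.items())
                },
                "step_caps": {
                    str(s): (None if np.isnan(v) else v)
                    for s, v in sorted(self.priors.step_cap_by_state.items())
                },
                "turn_caps": {
                    str(s): (None if np.isnan(v) else v)
                    for s, v in sorted(self.priors.turn_cap_by_state.items())
                },
                "percentiles": list(self.priors.percentiles),
                "absent_states": list(self.priors.absent_states),
            },
            "channel": {
                "cap_percentile": self.channel.cap_percentile,
                "n_min": self.channel.n_min,
                "bins": [
                    {
                        "state": s,
                        "regime": c,
                        "bias": mat(p.bias),
                        "gauss_cov": mat(p.gauss_cov),
                        "outlier_prob": p.outlier_prob,
                        "t_scale": mat(p.t_scale),
                        "t_dof": p.t_dof,
                        "pooling_level": p.pooling_level,
                        "n_samples": p.n_samples,
                        "cap": self.channel.cap_for(s, c),
                    }
                    for (s, c) in sorted(self.channel.params_by_bin, key=str)
                    for p in [self.channel.params_by_bin[(s, c)]]
                ],
            },
            "pi_real": mat(self.pi_real),
        }

    def save(self, path: str | Path) -> None:
        """Serialize the bundle as JSON (deterministic key order)."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryResults":
        if d.get("schema_version") != _SCHEMA_VERSION:
            raise BundleLoadError(
                f"schema version {d.get('schema_version')!r} != {_SCHEMA_VERSION}"
            )
        config = RunConfig.from_dict(d["config"])
        ch = d["chain"]
        tm = TransitionMatrix(
            P=np.asarray(ch["P"]),
            counts=np.asarray(ch["counts"]),
            degenerate_rows=tuple(ch["degenerate_rows"]),
        )
        chain = CalibratedChain(
            alpha=np.asarray(ch["alpha"]),
            transition_matrix=tm,
            stationary=np.asarray(ch["stationary"]),
            occupancy=np.asarray(ch["occupancy"]),
            objective=float(ch["objective"]),
            grid_step=float(ch["grid_step"]),
        )
        dwell = DwellModel(
            samples_by_state={int(s): np.asarray(v) for s, v in d["dwell"].items()}
        )
        pr = d["priors"]
        priors = KinematicPriors(
            step_samples_by_state={
                int(s): np.asarray(v, dtype=float) for s, v in pr["steps"].items()
            },
            turn_samples_by_state={
                int(s): np.asarray(v, dtype=float) for s, v in pr["turns"].items()
            },
            step_cap_by_state={
                int(s): (float("nan") if v is None else float(v))
                for s, v in pr["step_caps"].items()
            },
            turn_cap_by_state={
                int(s): (float("nan") if v is None else float(v))
                for s, v in pr["turn_caps"].items()
            },
            percentiles=tuple(pr["percentiles"]),
            absent_states=tuple(pr["absent_states"]),
        )
        chd = d["channel"]
        params, caps = {}, {}
        for b in chd["bins"]:
            key = (int(b["state"]), b["regime"])
            params[key] = ChannelParams(
                bias=np.asarray(b["bias"]),
                gauss_cov=np.asarray(b["gauss_cov"]),
                outlier_prob=float(b["outlier_prob"]),
                t_scale=np.asarray(b["t_scale"]),
                t_dof=float(b["t_dof"]),
                pooling_level=b["pooling_level"],
                n_samples=int(b["n_samples"]),
            )
            caps[key] = float(b["cap"])
        channel = ObservationChannel(
            params_by_bin=params,
            distortion_cap_by_bin=caps,
            cap_percentile=float(chd["cap_percentile"]),
            n_min=int(chd["n_min"]),
        )
        return cls(
            config=config,
            chain=chain,
            dwell=dwell,
            priors=priors,
            channel=channel,
            pi_real=np.asarray(d["pi_real"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrajectoryResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PerRegimeResults:
    """Per-regime calibration (``RunConfig(pool_regimes=False)``): one fully
    independent results bundle per sensing regime present in the data."""

    config: RunConfig
    by_regime: Dict[str, TrajectoryResults]

    def __post_init__(self) -> None:
        if not self.by_regime:
            raise ValueError("no regime had any session to calibrate on")

    def simulate(self, regime: str, **kw) -> List[Session]:
        if regime not in self.by_regime:
            raise KeyError(f"no calibration for regime {regime!r}")
        return self.by_regime[regime].simulate(regime, **kw)

    def summary(self) -> str:
        parts = []
        for regime, res in sorted(self.by_regime.items()):
            parts.append(f"--- regime {regime} ---\n{res.summary()}")
        return "\n\n".join(parts)


def load_results(path: str | Path) -> TrajectoryResults:
    return TrajectoryResults.load(path)
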