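"""Run-wide configuration with the defaults used throughout the framework.

All tunables that the calibration/synthesis pipeline depends on are collected
in one frozen dataclass so that every report can echo the resolved
configuration and no stage carries hidden constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

#: Sampling interval of every session, seconds per frame.
DT = 0.1

#: Behavioral state alphabet: 1=exploring, 2=feeding, 3=burrowing.
STATES = (1, 2, 3)
STATE_NAMES = {1: "exploring", 2: "feeding", 3: "burrowing"}

#: Sensing regimes.
LOS = "LoS"
NLOS = "NLoS"
REGIMES = (LOS, NLOS)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for one calibrate/generate/evaluate run.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds (0.1 s; 10 Hz UWB frames).
    smoother_window : mapping
        Centered two-stage (median then mean) smoothing window per sensing
        regime, in samples. NLoS uses a wider window because NLoS propagation
        produces larger and more frequent outliers.
    p_step, p_turn : float
        Percentiles of the state-conditioned step-length and |turning-angle|
        samples used as Winsorization caps on latent increments.
    p_resid : float
        Percentile of per-bin residual magnitudes used as the distortion cap.
    nu : float
        Degrees of freedom of the Student-t outlier component (fixed, not
        estimated).
    n_min : int
        Minimum residual sample count for a (state, regime) bin before the
        channel fit falls back to hierarchical pooling.
    em_reg : float
        Diagonal regularization (m^2) added to covariance/scale updates.
    em_tol : float
        Relative log-likelihood change below which EM stops.
    em_max_iter : int
        Hard EM iteration cap.
    n_bins : int
        Histogram bin count for divergence metrics.
    hist_eps : float
        Additive smoothing constant for histogram PMFs.
    grid_step : float
        Grid resolution for the 1-D occupancy-calibration search over the
        exploring-exit simplex.
    n_frames : int
        Default synthetic session length in frames (3000 frames = 300 s).
    max_lag_s : float
        Largest MSD lag in seconds.
    pool_regimes : bool
        Whether run dynamics, occupancy calibration and kinematic priors pool
        LoS and NLoS sessions (default) or are estimated per regime.
    """

    dt: float = DT
    smoother_window: Mapping[str, int] = field(
        default_factory=lambda: {LOS: 21, NLOS: 41}
    )
    p_step: float = 0.995
    p_turn: float = 0.995
    p_resid: float = 0.999
    nu: float = 4.0
    n_min: int = 5
    em_reg: float = 1e-9
    em_tol: float = 1e-8
    em_max_iter: int = 200
    n_bins: int = 50
    hist_eps: float = 1e-12
    grid_step: float = 0.001
    n_frames: int = 3000
    max_lag_s: float = 30.0
    pool_regimes: bool = True

    def window_for(self, regime: str) -> int:
        return int(self.smoother_window[regime])

    @property
    def max_lag_frames(self) -> int:
        return int(round(self.max_lag_s / self.dt))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["smoother_window"] = dict(d["smoother_window"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def validate_labels(labels) -> None:
    """Raise if any label falls outside the 3-state alphabet."""
    import numpy as np

    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("empty label sequence")
    if not np.isin(arr, STATES).all():
        bad = sorted(set(arr.tolist()) - set(STATES))
        raise ValueError(f"labels outside state alphabet {STATES}: {bad}")
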