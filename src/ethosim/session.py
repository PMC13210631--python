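"""Session container and plain-CSV readers/writers.

A *session* is one labeled planar trajectory recorded (or synthesized) under a
single sensing regime: per frame a time stamp, an observed x/y position in
meters, and a behavioral state label from the three-state alphabet
{exploring, feeding, burrowing}. Synthetic sessions additionally carry the
latent (distortion-free) trajectory; calibrated sessions may carry the smoothed
reference trajectory.

The on-disk format is a diffable CSV with header ``t,x,y,state,regime`` plus
optional ``x_lat,y_lat`` and ``x_ref,y_ref`` columns. Time is the frame index
times the global sampling interval; positions are meters in the arena frame
whose origin is (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DT, REGIMES, validate_labels

__all__ = ["Session", "ArenaFrame", "read_session", "write_session"]

# >= 9 significant digits so that write -> read -> write is byte-stable.
_FLOAT_FMT = "%.12g"


class SessionFormatError(ValueError):
    """Malformed session file (missing columns, bad schema)."""


class SessionValidationError(ValueError):
    """Well-formed file whose contents violate a session invariant."""


@dataclass(frozen=True)
class ArenaFrame:
    """Rigid translation mapping raw coordinates into the arena frame.

    The arena origin is (0, 0) by convention; ``apply`` subtracts the origin
    offset and ``invert`` adds it back, so ``invert(apply(x)) == x``.
    """

    origin_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(2, dtype=float)
    )

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) - np.asarray(self.origin_offset, float)

    def invert(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) + np.asarray(self.origin_offset, float)


@dataclass
class Session:
    """One labeled planar trajectory under a constant sensing regime.

    Attributes
    ----------
    frame_times : (T,) float array, seconds (frame index * dt).
    observed_xy : (T, 2) float array, meters — the sensor-observed track.
    labels : (T,) int array over {1, 2, 3}.
    regime : "LoS" or "NLoS" (constant within the session).
    reference_xy : optional (T, 2) float array — smoothed reference proxy.
    latent_xy : optional (T, 2) float array — true latent track
        (synthetic sessions only).
    """

    frame_times: np.ndarray
    observed_xy: np.ndarray
    labels: np.ndarray
    regime: str
    reference_xy: Optional[np.ndarray] = None
    latent_xy: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.observed_xy = np.asarray(self.observed_xy, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.reference_xy is not None:
            self.reference_xy = np.asarray(self.reference_xy, dtype=float)
        if self.latent_xy is not None:
            self.latent_xy = np.asarray(self.latent_xy, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        T = len(self.frame_times)
        if T < 2:
            raise SessionValidationError(f"session needs T >= 2 frames, got {T}")
        for name in ("observed_xy", "reference_xy", "latent_xy"):
            arr = getattr(self, name)
            if arr is None:
                continue
            if arr.shape != (T, 2):
                raise SessionValidationError(
                    f"{name} shape {arr.shape} != ({T}, 2)"
                )
            if not np.isfinite(arr).all():
                raise SessionValidationError(f"non-finite values in {name}")
        if self.labels.shape != (T,):
            raise SessionValidationError("labels length mismatch")
        validate_labels(self.labels)
        if self.regime not in REGIMES:
            raise SessionValidationError(
                f"regime must be one of {REGIMES}, got {self.regime!r}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def with_reference(self, reference_xy: np.ndarray) -> "Session":
        return replace(self, reference_xy=reference_xy)

    def copy(self) -> "Session":
        return Session(
            frame_times=self.frame_times.copy(),
            observed_xy=self.observed_xy.copy(),
            labels=self.labels.copy(),
            regime=self.regime,
            reference_xy=None if self.reference_xy is None else self.reference_xy.copy(),
            latent_xy=None if self.latent_xy is None else self.latent_xy.copy(),
        )


def read_session(
    path: str | Path,
    arena: ArenaFrame | None = None,
) -> Session:
    """Read one session from CSV.

    Required columns: ``t, x, y, state, regime``; optional ``x_lat, y_lat``
    (latent track) and ``x_ref, y_ref`` (reference track). Coordinates are
    translated into the arena frame when ``arena`` is given.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["t", "x", "y", "state", "regime"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing columns {missing}")
    regimes = df["regime"].unique()
    if len(regimes) != 1:
        raise SessionValidationError(
            f"{path}: regime must be constant within a session, got {list(regimes)}"
        )
    arena = arena or ArenaFrame()
    xy = arena.apply(df[["x", "y"]].to_numpy(dtype=float))
    latent = None
    if {"x_lat", "y_lat"}.issubset(df.columns):
        latent = arena.apply(df[["x_lat", "y_lat"]].to_numpy(dtype=float))
    reference = None
    if {"x_ref", "y_ref"}.issubset(df.columns):
        reference = arena.apply(df[["x_ref", "y_ref"]].to_numpy(dtype=float))
    return Session(
        frame_times=df["t"].to_numpy(dtype=float),
        observed_xy=xy,
        labels=df["state"].to_numpy(dtype=int),
        regime=str(regimes[0]),
        reference_xy=reference,
        latent_xy=latent,
    )


def write_session(session: Session, path: str | Path) -> None:
    """Write a session as CSV; emits latent/reference columns when present."""
    session.validate()
    data = {
        "t": session.frame_times,
        "x": session.observed_xy[:, 0],
        "y": session.observed_xy[:, 1],
        "state": session.labels,
        "regime": [session.regime] * session.n_frames,
    }
    if session.latent_xy is not None:
        data["x_lat"] = session.latent_xy[:, 0]
        data["y_lat"] = session.latent_xy[:, 1]
    if session.reference_xy is not None:
        data["x_ref"] = session.reference_xy[:, 0]
        data["y_ref"] = session.reference_xy[:, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def default_frame_times(n_frames: int, dt: float = DT) -> np.ndarray:
    return np.arange(n_frames, dtype=float) * dt
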