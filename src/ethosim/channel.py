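"""State- and regime-conditioned UWB observation channel.

The observed position is the latent position plus an additive distortion

    e | (state i, regime c) = mu_ic + u,
    u ~ (1 - rho_ic) N(0, Sigma_ic) + rho_ic T_nu(0, Lambda_ic),

a shared-location two-component mixture in which the Gaussian captures nominal
localization noise and the Student-t (nu fixed at 4) captures heavy-tailed
outliers, with rho the outlier probability. Parameters are fitted per
(state, regime) bin by EM with the Student-t handled through its Gamma
scale-mixture augmentation; bins with fewer than ``n_min`` residuals fall back
hierarchically to a regime-pooled fit, then to a single global fit.
Sampled distortions are magnitude-capped at a high percentile of the bin's
residual magnitudes (Winsorization in the radial direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.special import gammaln

from .config import REGIMES, STATES

__all__ = [
    "ChannelParams",
    "ObservationChannel",
    "ResidualSet",
    "fit_channel",
    "fit_mixture",
    "sample_distortion",
    "compute_distortion_caps",
    "cap_distortion",
]

_DIM = 2

POOL_STATE_REGIME = "state_regime"
POOL_REGIME = "regime"
POOL_GLOBAL = "global"


class ChannelEstimationError(RuntimeError):
    pass


@dataclass
class ChannelParams:
    """Fitted distortion parameters for one (state, regime) bin."""

    bias: np.ndarray  # (2,), meters
    gauss_cov: np.ndarray  # (2, 2), m^2, SPD
    outlier_prob: float  # rho in [0, 1]
    t_scale: np.ndarray  # (2, 2), m^2, SPD
    t_dof: float  # nu (fixed)
    pooling_level: str = POOL_STATE_REGIME
    n_samples: int = 0
    loglik_trace: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=float)
        self.gauss_cov = np.asarray(self.gauss_cov, dtype=float)
        self.t_scale = np.asarray(self.t_scale, dtype=float)
        for name in ("gauss_cov", "t_scale"):
            M = getattr(self, name)
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob must lie in [0, 1]")


@dataclass
class ResidualSet:
    """Residual vectors with their frame-level state and session regime."""

    residuals: np.ndarray  # (N, 2), meters
    states: np.ndarray  # (N,)
    regimes: np.ndarray  # (N,) of "LoS"/"NLoS"

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        self.regimes = np.asarray(self.regimes)
        n = self.residuals.shape[0]
        if self.residuals.ndim != 2 or self.residuals.shape[1] != _DIM:
            raise ValueError("residuals must be (N, 2)")
        if self.states.shape != (n,) or self.regimes.shape != (n,):
            raise ValueError("states/regimes must align with residuals")
        if not np.isfinite(self.residuals).all():
            raise ValueError("non-finite residuals")

    @property
    def magnitudes(self) -> np.ndarray:
        return np.hypot(self.residuals[:, 0], self.residuals[:, 1])

    def subset(self, state: int | None = None, regime: str | None = None) -> np.ndarray:
        mask = np.ones(len(self.states), dtype=bool)
        if state is not None:
            mask &= self.states == state
        if regime is not None:
            mask &= self.regimes == regime
        return self.residuals[mask]

    def magnitudes_subset(self, state: int | None = None, regime: str | None = None):
        mask = np.ones(len(self.states), dtype=bool)
        if state is not None:
            mask &= self.states == state
        if regime is not None:
            mask &= self.regimes == regime
        return self.magnitudes[mask]


@dataclass
class ObservationChannel:
    """Resolved channel: per-bin parameters, caps, and pooling provenance."""

    params_by_bin: Dict[Tuple[int, str], ChannelParams]
    distortion_cap_by_bin: Dict[Tuple[int, str], float]
    cap_percentile: float
    n_min: int

    def resolve(self, state: int, regime: str) -> ChannelParams:
        try:
            return self.params_by_bin[(int(state), regime)]
        except KeyError:
            raise ChannelEstimationError(f"unresolvable bin ({state}, {regime})")

    def cap_for(self, state: int, regime: str) -> float:
        try:
            return self.distortion_cap_by_bin[(int(state), regime)]
        except KeyError:
            raise ChannelEstimationError(f"no distortion cap for ({state}, {regime})")

    @property
    def pooling_report(self) -> Dict[Tuple[int, str], str]:
        return {k: p.pooling_level for k, p in self.params_by_bin.items()}


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _logdet_and_inv(M: np.ndarray) -> tuple:
    L = np.linalg.cholesky(M)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    inv = np.linalg.inv(M)
    return logdet, inv


def _gauss_logpdf(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    logdet, inv = _logdet_and_inv(cov)
    d = x - mu
    maha = np.einsum("ni,ij,nj->n", d, inv, d)
    return -0.5 * (_DIM * np.log(2 * np.pi) + logdet + maha)


def _student_logpdf(x: np.ndarray, mu: np.ndarray, scale: np.ndarray, nu: float) -> np.ndarray:
    logdet, inv = _logdet_and_inv(scale)
    d = x - mu
    maha = np.einsum("ni,ij,nj->n", d, inv, d)
    return (
        gammaln((nu + _DIM) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * (_DIM * np.log(nu * np.pi) + logdet)
        - 0.5 * (nu + _DIM) * np.log1p(maha / nu)
    )


def _mix_loglik(x, mu, cov, rho, scale, nu) -> tuple:
    """Observed-data log-likelihood and per-point component log densities."""
    lg = np.log1p(-rho) + _gauss_logpdf(x, mu, cov)
    lt = np.log(rho) + _student_logpdf(x, mu, scale, nu)
    m = np.maximum(lg, lt)
    ll = m + np.log(np.exp(lg - m) + np.exp(lt - m))
    return float(ll.sum()), lg, lt


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------

def fit_mixture(
    residuals: np.ndarray,
    nu: float = 4.0,
    reg: float = 1e-9,
    tol: float = 1e-8,
    max_iter: int = 200,
    rho_init: float = 0.05,
) -> ChannelParams:
    """EM fit of the shared-location Gaussian + Student-t mixture.

    The t component is handled through its Gamma scale-mixture augmentation:
    conditional on membership, the latent precision weight has expectation
    ``(nu + d) / (nu + maha)``. Updates follow the ECM pattern (location given
    old shapes, then shapes given the new location), which preserves the EM
    monotonicity guarantee; ``rho`` is kept inside [1e-4, 1 - 1e-4] to avoid
    component death. Covariance and scale updates add ``reg`` to the diagonal.
    """
    x = np.asarray(residuals, dtype=float)
    if x.ndim != 2 or x.shape[1] != _DIM:
        raise ValueError("residuals must be (N, 2)")
    if not np.isfinite(x).all():
        raise ValueError("non-finite residuals")
    n = x.shape[0]
    if n < 2:
        raise ChannelEstimationError("need at least 2 residuals to fit")

    mu = x.mean(axis=0)
    cov = np.cov(x.T) + reg * np.eye(_DIM)
    scale = cov.copy()
    rho = float(np.clip(rho_init, 1e-4, 1 - 1e-4))

    trace = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        ll, lg, lt = _mix_loglik(x, mu, cov, rho, scale, nu)
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1.0):
            break
        ll_prev = ll

        # E-step: component responsibilities and t-precision weights
        r = 1.0 / (1.0 + np.exp(np.clip(lg - lt, -700, 700)))  # P(t-component)
        _, scale_inv = _logdet_and_inv(scale)
        d_old = x - mu
        maha_t = np.einsum("ni,ij,nj->n", d_old, scale_inv, d_old)
        w = (nu + _DIM) / (nu + maha_t)

        # CM-step 1: shared location given current shapes
        _, cov_inv = _logdet_and_inv(cov)
        wg = 1.0 - r
        wt = r * w
        A = wg.sum() * cov_inv + wt.sum() * scale_inv
        b = cov_inv @ (wg @ x) + scale_inv @ (wt @ x)
        mu = np.linalg.solve(A, b)

        # CM-step 2: shapes and mixing weight given the new location
        d = x - mu
        cov = (d.T * wg) @ d / max(wg.sum(), 1e-12) + reg * np.eye(_DIM)
        denom = max(r.sum(), 1e-12)
        scale = (d.T * wt) @ d / denom + reg * np.eye(_DIM)
        rho = float(np.clip(r.mean(), 1e-4, 1 - 1e-4))

    ll_final, _, _ = _mix_loglik(x, mu, cov, rho, scale, nu)
    trace.append(ll_final)
    cov = 0.5 * (cov + cov.T)
    scale = 0.5 * (scale + scale.T)
    return ChannelParams(
        bias=mu,
        gauss_cov=cov,
        outlier_prob=rho,
        t_scale=scale,
        t_dof=float(nu),
        n_samples=n,
        loglik_trace=np.asarray(trace),
    )


def fit_channel(
    residual_set: ResidualSet,
    nu: float = 4.0,
    n_min: int = 5,
    reg: float = 1e-9,
    p_resid: float = 0.999,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ObservationChannel:
    """Fit the full channel with hierarchical pooling and distortion caps.

    Each (state, regime) bin with at least ``n_min`` residuals gets its own
    mixture fit; sparser bins inherit the regime-pooled fit, and if the regime
    pool is itself below ``n_min`` they inherit a single global fit. Distortion
    caps (the ``p_resid`` quantile of residual magnitudes) follow the same
    pooling chain.
    """
    n_total = len(residual_set.states)
    if n_total < n_min:
        raise ChannelEstimationError(
            f"{n_total} residuals < n_min={n_min}; cannot fit channel"
        )

    em_kw = dict(nu=nu, reg=reg, tol=tol, max_iter=max_iter)
    global_params: Optional[ChannelParams] = None
    regime_params: Dict[str, Optional[ChannelParams]] = {}

    def get_global() -> ChannelParams:
        nonlocal global_params
        if global_params is None:
            p = fit_mixture(residual_set.residuals, **em_kw)
            p.pooling_level = POOL_GLOBAL
            global_params = p
        return global_params

    def get_regime(regime: str) -> ChannelParams:
        if regime not in regime_params:
            res = residual_set.subset(regime=regime)
            if res.shape[0] >= n_min:
                p = fit_mixture(res, **em_kw)
                p.pooling_level = POOL_REGIME
                regime_params[regime] = p
            else:
                regime_params[regime] = None
        p = regime_params[regime]
        return p if p is not None else get_global()

    params: Dict[Tuple[int, str], ChannelParams] = {}
    caps: Dict[Tuple[int, str], float] = {}
    for regime in REGIMES:
        for state in STATES:
            res = residual_set.subset(state=state, regime=regime)
            if res.shape[0] >= n_min:
                p = fit_mixture(res, **em_kw)
                p.pooling_level = POOL_STATE_REGIME
                params[(state, regime)] = p
                caps[(state, regime)] = float(
                    np.quantile(np.hypot(res[:, 0], res[:, 1]), p_resid)
                )
            else:
                p = get_regime(regime)
                params[(state, regime)] = p
                pooled_mag = residual_set.magnitudes_subset(
                    regime=regime if p.pooling_level == POOL_REGIME else None
                )
                if pooled_mag.size == 0:
                    pooled_mag = residual_set.magnitudes
                caps[(state, regime)] = float(np.quantile(pooled_mag, p_resid))
    return ObservationChannel(
        params_by_bin=params,
        distortion_cap_by_bin=caps,
        cap_percentile=p_resid,
        n_min=n_min,
    )


def compute_distortion_caps(
    residual_set: ResidualSet, p_resid: float = 0.999
) -> Dict[Tuple[int, str], float]:
    """Per-bin high-percentile residual-magnitude caps (no pooling)."""
    if len(residual_set.states) == 0:
        raise ChannelEstimationError("empty residual set")
    caps = {}
    for regime in REGIMES:
        for state in STATES:
            mags = residual_set.magnitudes_subset(state=state, regime=regime)
            if mags.size:
                caps[(state, regime)] = float(np.quantile(mags, p_resid))
    return caps


# ---------------------------------------------------------------------------
# sampling and capping
# ---------------------------------------------------------------------------

def sample_mixture(
    params: ChannelParams, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw distortion vectors; the Student-t via its Gaussian scale mixture."""
    n = int(size)
    is_outlier = rng.random(n) < params.outlier_prob
    z = rng.standard_normal((n, _DIM))
    Lg = np.linalg.cholesky(params.gauss_cov)
    Lt = np.linalg.cholesky(params.t_scale)
    out = np.empty((n, _DIM))
    out[~is_outlier] = z[~is_outlier] @ Lg.T
    # t_nu = N(0, Lambda) / sqrt(Gamma(nu/2, 2/nu)); draw for all n to keep
    # the consumed stream length independent of the outlier pattern
    g = rng.chisquare(params.t_dof, n) / params.t_dof
    out[is_outlier] = (z[is_outlier] @ Lt.T) / np.sqrt(g[is_outlier])[:, None]
    return out + params.bias


def sample_distortion(
    channel: ObservationChannel,
    state: int,
    regime: str,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Sample (uncapped) distortions for one (state, regime) bin."""
    return sample_mixture(channel.resolve(state, regime), rng, size=size)


def cap_distortion(e: np.ndarray, cap: float) -> np.ndarray:
    """Radially Winsorize distortion vectors to magnitude <= cap.

    Direction is preserved; the zero vector maps to itself. Idempotent.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    e = np.asarray(e, dtype=float)
    single = e.ndim == 1
    e2 = e[None, :] if single else e
    mag = np.hypot(e2[:, 0], e2[:, 1])
    factor = np.ones_like(mag)
    over = mag > cap
    factor[over] = cap / mag[over]
    out = e2 * factor[:, None]
    return out[0] if single else out
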