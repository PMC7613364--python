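"""Exact Gaussian-process regression on 1-D (time) inputs.

A zero-mean GP with a squared-exponential (SE) covariance is used to model a
single pixel's vegetation-descriptor time series y(t) under an additive
Gaussian noise model y_i = f(t_i) + e_i, e_i ~ N(0, sigma_n^2).

The kernel itself is noise-free,

    k(t_i, t_j) = sigma_f^2 * exp(-(t_i - t_j)^2 / (2 l^2)),

and the noise variance sigma_n^2 is added exactly once, on the diagonal of
the training covariance K + sigma_n^2 I.  Hyperparameters are carried on the
log scale (log(1/l), log sigma_f, log sigma_n), which both enforces
positivity during optimization and matches the convention in which pooled
crop hyperparameters are usually reported.

All heavy paths share one Cholesky factorization of K + sigma_n^2 I: the
predictive distribution, the log marginal likelihood and its analytic
gradient never form an explicit inverse or determinant.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    NumericalError,
    TrainingFailureError,
)

logger = logging.getLogger(__name__)

#: Minimum number of valid observations required to fit a pixel.
MIN_OBS = 4

#: Default uniform restart prior, wide enough to bracket hyperparameters
#: reported for agricultural LAI series by a comfortable margin.
DEFAULT_PRIOR_BOX = {
    "log_inv_l": (-6.0, -1.0),
    "log_sigma_f": (-2.5, 1.0),
    "log_sigma_n": (-3.5, 0.0),
}

_JITTER_START_FRAC = 1e-10  # of trace/n
_JITTER_MAX_FRAC = 1e-4
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Hyperparameters:
    """SE-kernel hyperparameters stored on the log scale.

    Attributes
    ----------
    log_inv_l : float
        log(1/l) with the length-scale l in days.
    log_sigma_f : float
        log of the signal standard deviation sigma_f.
    log_sigma_n : float
        log of the noise standard deviation sigma_n.
    """

    log_inv_l: float
    log_sigma_f: float
    log_sigma_n: float

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"non-finite hyperparameters: {arr}")

    @property
    def lengthscale(self) -> float:
        """Length-scale l in days."""
        return math.exp(-self.log_inv_l)

    @property
    def sigma_f2(self) -> float:
        """Signal variance sigma_f^2."""
        return math.exp(2.0 * self.log_sigma_f)

    @property
    def sigma_n2(self) -> float:
        """Noise variance sigma_n^2."""
        return math.exp(2.0 * self.log_sigma_n)

    def as_array(self) -> np.ndarray:
        return np.array([self.log_inv_l, self.log_sigma_f, self.log_sigma_n], float)

    @classmethod
    def from_array(cls, arr) -> "Hyperparameters":
        a = np.asarray(arr, float)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    @classmethod
    def from_linear(cls, lengthscale: float, sigma_f: float, sigma_n: float) -> "Hyperparameters":
        """Build from linear-scale l [days], sigma_f, sigma_n (standard deviations)."""
        if lengthscale <= 0 or sigma_f <= 0 or sigma_n <= 0:
            raise InvalidInputError("lengthscale, sigma_f and sigma_n must be positive")
        return cls(-math.log(lengthscale), math.log(sigma_f), math.log(sigma_n))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        return cls(float(d["log_inv_l"]), float(d["log_sigma_f"]), float(d["log_sigma_n"]))


@dataclass
class TimeSeries:
    """One pixel's irregularly sampled observations.

    times are float days since a configurable epoch; values carry the
    descriptor's units (e.g. LAI in m2/m2).  ``valid`` masks out cloudy or
    otherwise unusable acquisitions.
    """

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, bool)
        if not (len(self.times) == len(self.values) == len(self.valid)):
            raise InvalidInputError("times, values and valid must have equal length")
        t = self.times[self.valid]
        if t.size and not np.all(np.diff(t) > 0):
            raise InvalidInputError("valid times must be strictly increasing")
        if not np.all(np.isfinite(self.times)):
            raise InvalidInputError("times contain non-finite entries")
        if t.size and not np.all(np.isfinite(self.values[self.valid])):
            raise InvalidInputError("valid values contain non-finite entries")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) restricted to valid observations."""
        return self.times[self.valid], self.values[self.valid]


@dataclass
class GPRFit:
    """A conditioned GP for one pixel: factorized covariance and weights.

    ``chol_factor`` is the lower Cholesky factor L of K + sigma_n^2 I (plus
    any jitter recorded in ``jitter_used``); ``alpha`` solves
    (K + sigma_n^2 I) alpha = y.
    """

    theta: Hyperparameters
    train_times: np.ndarray
    train_values: np.ndarray
    alpha: np.ndarray
    chol_factor: np.ndarray
    jitter_used: float
    mean_offset: float = 0.0  # nonzero only when fitted with subtract_mean


@dataclass
class PredictiveSeries:
    """Posterior predictive mean and standard deviation on a time grid."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.mean = np.asarray(self.mean, float)
        self.sd = np.asarray(self.sd, float)


def se_kernel(t_a, t_b, theta: Hyperparameters, include_noise: bool = False) -> np.ndarray:
    """Squared-exponential covariance between two time vectors.

    Returns sigma_f^2 exp(-(t_a_i - t_b_j)^2 / (2 l^2)).  With
    ``include_noise`` and identical input grids, sigma_n^2 is added on the
    diagonal (the Kronecker-delta noise term); the noise is never baked into
    off-diagonal entries.
    """
    t_a = np.atleast_1d(np.asarray(t_a, float))
    t_b = np.atleast_1d(np.asarray(t_b, float))
    if not (np.all(np.isfinite(t_a)) and np.all(np.isfinite(t_b))):
        raise InvalidInputError("kernel inputs must be finite")
    d = t_a[:, None] - t_b[None, :]
    k = theta.sigma_f2 * np.exp(-0.5 * (d / theta.lengthscale) ** 2)
    if include_noise:
        if t_a.shape == t_b.shape and np.array_equal(t_a, t_b):
            k[np.diag_indices_from(k)] += theta.sigma_n2
        else:
            raise InvalidInputError("include_noise requires identical input grids")
    return k


def _chol_with_jitter(k_noisy: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor with escalating diagonal jitter on failure."""
    n = k_noisy.shape[0]
    scale = max(np.trace(k_noisy) / n, np.finfo(float).tiny)
    jitter = 0.0
    while True:
        try:
            L = cholesky(k_noisy + jitter * np.eye(n), lower=True)
            if jitter > 0:
                logger.debug("cholesky required jitter %.3e", jitter)
            return L, jitter
        except np.linalg.LinAlgError:
            pass
        except Exception as exc:  # scipy raises LinAlgError too, keep broad guard
            if "positive definite" not in str(exc).lower():
                raise
        jitter = _JITTER_START_FRAC * scale if jitter == 0.0 else jitter * 10.0
        if jitter > _JITTER_MAX_FRAC * scale:
            raise NumericalError(
                f"Cholesky factorization failed even with jitter {jitter:.3e}"
            )


def _training_cov(t: np.ndarray, theta: Hyperparameters) -> np.ndarray:
    k = se_kernel(t, t, theta)
    k[np.diag_indices_from(k)] += theta.sigma_n2
    return k


def fit_gpr(ts: TimeSeries, theta: Hyperparameters, min_obs: int = MIN_OBS,
            subtract_mean: bool = False) -> GPRFit:
    """Condition a GP on a pixel's valid observations.

    Factorizes K + sigma_n^2 I once; the factor is shared by prediction,
    likelihood and gradient evaluation. Deterministic for fixed inputs.
    With ``subtract_mean`` the sample mean is removed before conditioning
    and added back at prediction (off by default: the model is zero-mean).
    """
    if ts.n_valid < min_obs:
        raise InsufficientDataError(
            f"{ts.n_valid} valid observations < min_obs={min_obs}"
        )
    t, y = ts.masked()
    offset = float(y.mean()) if subtract_mean else 0.0
    L, jitter = _chol_with_jitter(_training_cov(t, theta))
    alpha = cho_solve((L, True), y - offset)
    return GPRFit(theta, t, y, alpha, L, jitter, mean_offset=offset)


def predict(fit: GPRFit, ts_values, t_star) -> PredictiveSeries:
    """Posterior predictive distribution at new times.

    mean(t*) = k*^T (K + sigma_n^2 I)^-1 y
    var(t*)  = c* - k*^T (K + sigma_n^2 I)^-1 k*,  c* = k(t*, t*) + sigma_n^2

    The predictive variance includes the observation-noise term, so far from
    the data it reverts to sigma_f^2 + sigma_n^2. ``ts_values`` may differ
    from the values the fit was built on, which lets one factorization serve
    many pixels that share an acquisition pattern.
    """
    t_star = np.atleast_1d(np.asarray(t_star, float))
    y = np.asarray(ts_values, float)
    if y.shape != fit.train_times.shape:
        raise InvalidInputError("ts_values length must match the training times")
    if not np.all(np.isfinite(t_star)):
        raise InvalidInputError("prediction times must be finite")
    theta = fit.theta
    k_star = se_kernel(fit.train_times, t_star, theta)  # n x m
    alpha = cho_solve((fit.chol_factor, True), y - fit.mean_offset)
    mean = k_star.T @ alpha + fit.mean_offset
    v = solve_triangular(fit.chol_factor, k_star, lower=True)  # n x m
    c_star = theta.sigma_f2 + theta.sigma_n2
    var = c_star - np.einsum("ij,ij->j", v, v)
    neg = var < 0
    if np.any(neg):
        logger.debug("clipping %d negative predictive variances (min %.3e)",
                     int(neg.sum()), float(var.min()))
        var = np.clip(var, 0.0, None)
    return PredictiveSeries(t_star, mean, np.sqrt(var))


def log_marginal_likelihood(ts: TimeSeries, theta: Hyperparameters) -> float:
    """Log marginal likelihood log p(y | t, theta).

    -1/2 y^T (K+sigma_n^2 I)^-1 y - 1/2 log|K+sigma_n^2 I| - n/2 log 2pi,
    evaluated through the Cholesky factor (no explicit inverse/determinant).
    """
    if ts.n_valid < 1:
        raise InsufficientDataError("need at least one valid observation")
    t, y = ts.masked()
    L, _ = _chol_with_jitter(_training_cov(t, theta))
    alpha = cho_solve((L, True), y)
    n = t.size
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * _LOG_2PI
    )


def lml_gradient(ts: TimeSeries, theta: Hyperparameters) -> np.ndarray:
    """Analytic gradient of the log marginal likelihood.

    Components are with respect to (log(1/l), log sigma_f, log sigma_n),
    via the trace identity d/dtheta_j = 1/2 tr((alpha alpha^T - Kn^-1)
    dKn/dtheta_j) with Kn = K + sigma_n^2 I, chained to the log scale:

      dKn/d log(1/l)   = -K * D^2 / l^2       (elementwise, D = time diffs)
      dKn/d log sigma_f = 2 K
      dKn/d log sigma_n = 2 sigma_n^2 I
    """
    if ts.n_valid < 1:
        raise InsufficientDataError("need at least one valid observation")
    t, y = ts.masked()
    n = t.size
    K = se_kernel(t, t, theta)
    Kn = K.copy()
    Kn[np.diag_indices_from(Kn)] += theta.sigma_n2
    L, _ = _chol_with_jitter(Kn)
    alpha = cho_solve((L, True), y)
    K_inv = cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - K_inv
    d2 = (t[:, None] - t[None, :]) ** 2
    g_linvl = 0.5 * np.sum(A * (K * (-d2 / theta.lengthscale**2)))
    g_lsf = np.sum(A * K)  # 0.5 * tr(A * 2K)
    g_lsn = theta.sigma_n2 * np.trace(A)
    return np.array([g_linvl, g_lsf, g_lsn])


def _neg_lml_and_grad(x: np.ndarray, t: np.ndarray, y: np.ndarray, d2: np.ndarray):
    """Objective for the optimizer: shares one factorization for value+grad."""
    theta = Hyperparameters.from_array(x)
    n = t.size
    K = theta.sigma_f2 * np.exp(-0.5 * d2 / theta.lengthscale**2)
    Kn = K.copy()
    Kn[np.diag_indices_from(Kn)] += theta.sigma_n2
    L, _ = _chol_with_jitter(Kn)
    alpha = cho_solve((L, True), y)
    lml = -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * _LOG_2PI
    K_inv = cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - K_inv
    g = np.array([
        0.5 * np.sum(A * (K * (-d2 / theta.lengthscale**2))),
        np.sum(A * K),
        theta.sigma_n2 * np.trace(A),
    ])
    return -lml, -g


def train_hyperparameters(
    ts: TimeSeries,
    n_restarts: int = 5,
    prior_box: dict | None = None,
    seed: int = 0,
    min_obs: int = MIN_OBS,
    maxiter: int = 200,
    ftol: float = 1e-6,
) -> tuple[Hyperparameters, float]:
    """Maximize the marginal likelihood by multi-restart quasi-Newton search.

    Starting points are drawn uniformly from ``prior_box`` (log-scale ranges);
    the restart with the highest converged log marginal likelihood wins.
    Deterministic for a fixed seed.

    Returns
    -------
    (Hyperparameters, float)
        Best hyperparameters and their log marginal likelihood.
    """
    if ts.n_valid < min_obs:
        raise InsufficientDataError(
            f"{ts.n_valid} valid observations < min_obs={min_obs}"
        )
    box = prior_box or DEFAULT_PRIOR_BOX
    lows = np.array([box["log_inv_l"][0], box["log_sigma_f"][0], box["log_sigma_n"][0]])
    highs = np.array([box["log_inv_l"][1], box["log_sigma_f"][1], box["log_sigma_n"][1]])
    rng = np.random.default_rng(seed)
    t, y = ts.masked()
    d2 = (t[:, None] - t[None, :]) ** 2

    best_x, best_lml = None, -np.inf
    diagnostics = []
    for _ in range(n_restarts):
        x0 = rng.uniform(lows, highs)
        try:
            res = optimize.minimize(
                _neg_lml_and_grad,
                x0,
                args=(t, y, d2),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": ftol},
            )
        except NumericalError as exc:
            diagnostics.append({"x0": x0.tolist(), "error": str(exc)})
            continue
        diagnostics.append({"x0": x0.tolist(), "success": bool(res.success),
                            "lml": float(-res.fun)})
        if np.isfinite(res.fun) and -res.fun > best_lml:
            best_lml, best_x = float(-res.fun), res.x
    if best_x is None:
        raise TrainingFailureError("all optimizer restarts failed", diagnostics)
    return Hyperparameters.from_array(best_x), best_lml
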