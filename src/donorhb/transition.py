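"""Covariate-adjusted autoregressive (transition) panel model of order q.

The model for donor i at visit t is

    y_it = alpha + beta'x_it + sum_r gamma_r (y_{i,t-r} - beta'x_{i,t-r}) + eps_it

with x = (age, warm-season, DPV) and eps_it ~ iid N(0, sigma2_eps).  Writing
w_it = y_it - beta'x_it, the adjusted series w is a stationary AR(q) with mean
mu_w = alpha / (1 - sum_r gamma_r); the centered series z = w - mu_w is a
zero-mean AR(q).

Estimation maximises the *exact* Gaussian likelihood: the latent AR(q) is put
in companion-form state space and a Kalman filter with the stationary initial
covariance delivers the prediction-error decomposition.  Because the first
q observations of each donor enter through the stationary marginal, donors
with fewer visits than the model order still contribute information.

The filter's gain/variance sequence does not depend on the data, so it is
precomputed once per series length and applied to all donors of that length
at once; fitting a cohort of several thousand donors takes seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .panel import Cohort
from .results import FitResult, PredictionSet
from .util import numeric_hessian

__all__ = [
    "TransitionParams",
    "NonStationaryError",
    "stationary_covariance",
    "exact_loglik",
    "fit_transition",
    "predict_dynamic_ar",
]

_COVARIATES = ["age", "season", "dpv"]
_LOG2PI = math.log(2.0 * math.pi)


class NonStationaryError(ValueError):
    """Raised when the AR lag polynomial has a root on or inside the unit circle."""


@dataclass(frozen=True)
class TransitionParams:
    """Parameters of the order-q transition model.

    ``beta`` is the coefficient triple (age per-year, warm-season, DPV) in
    mmol/l; ``gamma`` holds the lag coefficients gamma_1..gamma_q.
    """

    alpha: float
    beta: tuple[float, float, float]
    gamma: tuple[float, ...]
    sigma2_eps: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))
        if len(self.beta) != 3:
            raise ValueError("beta must be the (age, season, dpv) triple")
        if self.sigma2_eps <= 0:
            raise ValueError("sigma2_eps must be positive")
        _check_stationary(self.gamma)

    @property
    def q(self) -> int:
        return len(self.gamma)

    @property
    def stationary_mean(self) -> float:
        """mu_w = alpha / (1 - sum gamma_r), the mean of the adjusted series."""
        return self.alpha / (1.0 - sum(self.gamma))


def _companion(gamma: Sequence[float]) -> np.ndarray:
    q = len(gamma)
    F = np.zeros((q, q))
    F[0, :] = gamma
    if q > 1:
        F[np.arange(1, q), np.arange(0, q - 1)] = 1.0
    return F


def _check_stationary(gamma: Sequence[float], limit: float = 1.0) -> float:
    """Return the companion spectral radius; raise if >= limit."""
    if len(gamma) == 0:
        return 0.0
    rho = np.max(np.abs(np.linalg.eigvals(_companion(gamma))))
    if rho >= limit:
        raise NonStationaryError(
            f"AR coefficients are non-stationary: companion root modulus {rho:.4f} >= 1"
        )
    return float(rho)


def stationary_covariance(gamma: Sequence[float], sigma2: float) -> np.ndarray:
    """Covariance matrix of q consecutive values of a zero-mean AR(q).

    Solves the discrete Lyapunov equation P = F P F' + Q for the companion
    matrix F and innovation covariance Q = sigma2 * e1 e1'.  The result is the
    symmetric positive-definite Toeplitz matrix of autocovariances
    g_0 .. g_{q-1} that makes the Kalman likelihood exact from the first
    observation.
    """
    gamma = np.asarray(gamma, dtype=float)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    q = len(gamma)
    if q == 0:
        return np.zeros((0, 0))
    _check_stationary(gamma)
    F = _companion(gamma)
    Q = np.zeros((q, q))
    Q[0, 0] = sigma2
    P = scipy.linalg.solve_discrete_lyapunov(F, Q)
    return 0.5 * (P + P.T)


def autocovariances(gamma: Sequence[float], sigma2: float, n_lags: int) -> np.ndarray:
    """Autocovariances g_0..g_{n_lags} of the stationary AR(q).

    The first q values come from the Lyapunov solution; later lags follow the
    Yule-Walker recursion g_k = sum_r gamma_r g_{k-r}.
    """
    gamma = np.asarray(gamma, dtype=float)
    q = len(gamma)
    g = np.zeros(max(n_lags + 1, q))
    if q == 0:
        g[0] = sigma2
        return g[: n_lags + 1]
    P = stationary_covariance(gamma, sigma2)
    g[:q] = P[0, :q]
    for k in range(q, n_lags + 1):
        g[k] = gamma @ g[k - q : k][::-1]
    return g[: n_lags + 1]


# ---------------------------------------------------------------------------
# Kalman machinery


def _filter_schedule(gamma: np.ndarray, sigma2: float, t_max: int):
    """Precompute the data-independent filter sequence for t = 1..t_max.

    Returns (Fv, G, F): innovation variances Fv[t], update gains G[t] (such
    that the filtered state is a + G[t] * v), and the companion matrix.  The
    sequence is shared by every donor because the model is time-invariant.
    """
    q = len(gamma)
    F = _companion(gamma)
    P = stationary_covariance(gamma, sigma2)
    Q = np.zeros((q, q))
    Q[0, 0] = sigma2
    Fv = np.empty(t_max)
    G = np.empty((t_max, q))
    for t in range(t_max):
        f = P[0, 0]
        Fv[t] = f
        g = P[:, 0] / f
        G[t] = g
        P_upd = P - np.outer(g, P[0, :])
        P = F @ P_upd @ F.T + Q
        P = 0.5 * (P + P.T)
    return Fv, G, F


class _CohortView:
    """Design arrays and length-grouped index blocks, built once per cohort."""

    def __init__(self, cohort: Cohort):
        self.X = cohort.data[_COVARIATES].to_numpy(dtype=float)
        self.y = cohort.data["hb"].to_numpy(dtype=float)
        counts = cohort.data.groupby("donor_id", sort=True).size().to_numpy()
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        by_len: dict[int, list[int]] = {}
        for s, c in zip(starts, counts):
            by_len.setdefault(int(c), []).append(int(s))
        self.blocks = [
            (T, np.asarray(ss)[:, None] + np.arange(T)[None, :])
            for T, ss in sorted(by_len.items())
        ]
        self.t_max = int(counts.max())


def _loglik_view(params: TransitionParams, view: _CohortView) -> float:
    z_all = view.y - view.X @ np.asarray(params.beta) - params.stationary_mean
    q = params.q
    if q == 0:
        s2 = params.sigma2_eps
        return float(-0.5 * np.sum(_LOG2PI + math.log(s2) + z_all**2 / s2))
    gamma = np.asarray(params.gamma)
    Fv, G, F = _filter_schedule(gamma, params.sigma2_eps, view.t_max)
    log_fv = np.log(Fv)
    ll = 0.0
    for T, idx in view.blocks:
        Z = z_all[idx]
        A = np.zeros((Z.shape[0], q))
        for t in range(T):
            v = Z[:, t] - A[:, 0]
            ll += -0.5 * (Z.shape[0] * (_LOG2PI + log_fv[t]) + np.sum(v * v) / Fv[t])
            A = (A + v[:, None] * G[t][None, :]) @ F.T
    return float(ll)


def exact_loglik(params: TransitionParams, cohort: Cohort) -> float:
    """Exact Gaussian log-likelihood of the cohort under the transition model.

    Sum over donors of the joint log-density of (y_i1..y_iT) with the latent
    AR started from its stationary distribution (prediction-error
    decomposition).  Donors with fewer than q+1 visits contribute through the
    stationary marginal of their first observations.
    """
    return _loglik_view(params, _CohortView(cohort))


def predict_dynamic_ar(params: TransitionParams, cohort: Cohort) -> PredictionSet:
    """One-step-ahead dynamic predictions of Hb for every visit of every donor.

    For visit t the prediction is beta'x_it + mu_w + E[z_it | z_i1..z_i,t-1],
    the conditional expectation coming from the Kalman filter run on that
    donor's history.  At t = 1 there is no history, so the prediction uses
    covariates only.  The observed y_it is never used in its own prediction.
    """
    view = _CohortView(cohort)
    y = view.y
    mean_part = view.X @ np.asarray(params.beta) + params.stationary_mean
    z_all = y - mean_part
    pred = np.empty_like(y)
    q = params.q
    if q == 0:
        pred[:] = mean_part
    else:
        gamma = np.asarray(params.gamma)
        Fv, G, F = _filter_schedule(gamma, params.sigma2_eps, view.t_max)
        for T, idx in view.blocks:
            Z = z_all[idx]
            A = np.zeros((Z.shape[0], q))
            for t in range(T):
                pred[idx[:, t]] = mean_part[idx[:, t]] + A[:, 0]
                v = Z[:, t] - A[:, 0]
                A = (A + v[:, None] * G[t][None, :]) @ F.T
    out = cohort.data[["donor_id", "visit"]].copy()
    out["y_pred"] = pred
    out["y_obs"] = y
    return PredictionSet(out, gender=cohort.gender, model=f"AR({q})")


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


def _design(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    X = cohort.data[_COVARIATES].to_numpy(dtype=float)
    y = cohort.data["hb"].to_numpy(dtype=float)
    return X, y


def _ols_start(cohort: Cohort, q: int) -> np.ndarray:
    """Starting values: (alpha, beta) from OLS, gamma from lagged OLS residuals."""
    X, y = _design(cohort)
    D = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("singular design: a covariate is constant in this cohort")
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    # within-donor lag regression of residuals
    df = cohort.data[["donor_id"]].copy()
    df["resid"] = resid
    lags = []
    g = df.groupby("donor_id")["resid"]
    for r in range(1, q + 1):
        lags.append(g.shift(r).to_numpy())
    L = np.column_stack(lags)
    ok = ~np.isnan(L).any(axis=1)
    if ok.sum() > 5 * q:
        gam, *_ = np.linalg.lstsq(L[ok], resid[ok], rcond=None)
        e = resid[ok] - L[ok] @ gam
        s2 = max(float(np.var(e)), 1e-4)
        try:
            _check_stationary(gam, limit=0.98)
        except NonStationaryError:
            gam = np.full(q, 0.1)
    else:
        gam = np.full(q, 0.1)
        s2 = max(float(np.var(resid)), 1e-4)
    mu_w = coef[0]
    alpha0 = mu_w * (1.0 - gam.sum())
    return np.concatenate([[alpha0], coef[1:], gam, [0.5 * math.log(s2)]])


def _unpack(theta: np.ndarray, q: int) -> TransitionParams:
    return TransitionParams(
        alpha=float(theta[0]),
        beta=tuple(theta[1:4]),
        gamma=tuple(theta[4 : 4 + q]),
        sigma2_eps=float(math.exp(2.0 * theta[4 + q])),
    )


def fit_transition(
    cohort: Cohort,
    q: int,
    options: Optional[dict] = None,
) -> FitResult:
    """Fit the order-q transition model by exact maximum likelihood.

    The optimizer works on (alpha, beta, gamma, log sigma_eps); candidate
    gamma with companion spectral radius >= 0.999 are rejected by returning a
    large objective value, which makes the quasi-Newton line search backtrack
    into the stationary region.  Standard errors come from the inverse
    numerical Hessian at the optimum (delta method for sigma2_eps).
    """
    if q < 1:
        raise ValueError("transition model order must be >= 1")
    opts = {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7}
    if options:
        opts.update(options)
    theta0 = _ols_start(cohort, q)
    view = _CohortView(cohort)
    penalty = 1e10

    def nll(theta: np.ndarray) -> float:
        gamma = theta[4 : 4 + q]
        if len(gamma) and np.max(np.abs(np.linalg.eigvals(_companion(gamma)))) >= 0.999:
            return penalty
        if abs(theta[4 + q]) > 20:  # keep exp(2*logsig) in floating range
            return penalty
        return -_loglik_view(_unpack(theta, q), view)

    res = scipy.optimize.minimize(
        nll, theta0, method="L-BFGS-B", options=opts,
    )
    theta = res.x
    params = _unpack(theta, q)
    loglik = -float(res.fun)

    H = numeric_hessian(nll, theta)
    se = _se_from_hessian(H, q)
    names = ["alpha", "beta_age", "beta_season", "beta_dpv"]
    names += [f"gamma_{r}" for r in range(1, q + 1)] + ["sigma2_eps"]
    # delta method: sigma2 = exp(2 * logsig)
    se[-1] = 2.0 * params.sigma2_eps * se[-1]
    return FitResult(
        params=params,
        se=dict(zip(names, se)),
        loglik=loglik,
        n_obs=cohort.n_obs,
        n_params=5 + q,
        converged=bool(res.success),
        n_iter=int(res.nit),
        model=f"AR({q})",
    )


def _se_from_hessian(H: np.ndarray, q: int) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        se = np.full(H.shape[0], np.nan)
    return se
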