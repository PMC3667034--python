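"""Linear mixed models for donor Hb series, plus the multiple-regression benchmark.

Two random-effect structures are offered:

* ``RI`` — random intercept: y_it = alpha + b_0i + beta'x_it + eps_it.  The
  within-donor correlation is then constant: the intra-class correlation
  rho = sigma2_b0 / (sigma2_b0 + sigma2_eps).
* ``RIRS`` — random intercept and random age slope:
  y_it = alpha + b_0i + (beta_age + b_1i) age_it + beta_s season_it
         + beta_d dpv_it + eps_it,
  with (b_0i, b_1i) ~ N(0, D), D diagonal, independent of the iid
  N(0, sigma2_eps) residuals.

Variance components are estimated by restricted maximum likelihood (REML)
with the fixed effects profiled out by generalized least squares; dynamic
prediction uses empirical-Bayes (BLUP) estimates of a donor's random effects
computed from that donor's previous visits only.  ``structure="LR"`` encodes
the zero-variance benchmark so that ordinary least squares fits share the
same parameter container and prediction path.

All per-donor linear algebra is reduced to k x k (k <= 2) cross-products via
the Woodbury identity, so a REML evaluation on ten thousand donors is a few
batched matrix operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.optimize
import statsmodels.api as sm
from scipy.stats import chi2

from .panel import Cohort
from .results import FitResult, PredictionSet
from .util import numeric_hessian

__all__ = [
    "LMEParams",
    "RandomEffectEstimate",
    "fit_ols",
    "reml_criterion",
    "fit_lme",
    "empirical_bayes",
    "predict_dynamic_lme",
    "icc",
    "lrt_random_slope",
]

_COVARIATES = ["age", "season", "dpv"]
_LOG2PI = math.log(2.0 * math.pi)
_BOUNDARY_TOL = 1e-10


@dataclass(frozen=True)
class LMEParams:
    """Parameters of the mixed model (or the LR benchmark when variances are 0)."""

    alpha: float
    beta: tuple[float, float, float]
    sigma2_b0: float
    sigma2_b1: Optional[float]
    sigma2_eps: float
    structure: str  # "LR", "RI" or "RIRS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        if self.structure not in ("LR", "RI", "RIRS"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.sigma2_eps <= 0:
            raise ValueError("sigma2_eps must be positive")
        if self.sigma2_b0 < 0:
            raise ValueError("sigma2_b0 must be non-negative")
        if self.structure == "RIRS":
            if self.sigma2_b1 is None or self.sigma2_b1 < 0:
                raise ValueError("RIRS requires a non-negative sigma2_b1")

    @property
    def k(self) -> int:
        """Number of random effects per donor (0 for the LR benchmark)."""
        return {"LR": 0, "RI": 1, "RIRS": 2}[self.structure]

    def d_diag(self) -> np.ndarray:
        """Diagonal of the random-effects covariance D."""
        if self.structure == "RIRS":
            return np.array([self.sigma2_b0, self.sigma2_b1])
        if self.structure == "RI":
            return np.array([self.sigma2_b0])
        return np.zeros(0)


@dataclass(frozen=True)
class RandomEffectEstimate:
    """Empirical-Bayes estimate of one donor's random effects."""

    donor_id: str
    b0_hat: float
    b1_hat: float
    n_used: int


# ---------------------------------------------------------------------------
# per-cohort sufficient statistics


class _Suffstats:
    """Per-donor cross-products that make V-weighted sums O(k^3) per donor."""

    def __init__(self, cohort: Cohort, k: int):
        df = cohort.data
        self.y = df["hb"].to_numpy(dtype=float)
        n = len(self.y)
        self.X = np.column_stack([np.ones(n), df[_COVARIATES].to_numpy(dtype=float)])
        self.Z = _random_design(self.X, k)
        counts = df.groupby("donor_id", sort=True).size().to_numpy()
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.T = counts
        self.n, self.p, self.m = n, self.X.shape[1], len(counts)
        red = lambda a: np.add.reduceat(a, starts, axis=0)
        Z, X, y = self.Z, self.X, self.y
        self.ZtZ = np.stack(
            [red(Z[:, [a]] * Z) for a in range(k)], axis=1
        ) if k else np.zeros((self.m, 0, 0))
        self.ZtX = np.stack(
            [red(Z[:, [a]] * X) for a in range(k)], axis=1
        ) if k else np.zeros((self.m, 0, self.p))
        self.Zty = red(Z * y[:, None]).reshape(self.m, k) if k else np.zeros((self.m, 0))
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)


def _random_design(X: np.ndarray, k: int) -> np.ndarray:
    # columns of X are (1, age, season, dpv); random effects load on (1, age)
    return X[:, :k].copy()


def _gls_pieces(ss: _Suffstats, d_diag: np.ndarray, s2e: float):
    """GLS building blocks under V_i = Z_i D Z_i' + s2e I via Woodbury."""
    k = len(d_diag)
    if k == 0:
        XtVX = ss.XtX / s2e
        XtVy = ss.Xty / s2e
        ytVy = ss.yty / s2e
        sumlogdetV = ss.n * math.log(s2e)
        return XtVX, XtVy, ytVy, sumlogdetV
    dh = np.sqrt(d_diag)
    ZtZt = dh[:, None] * ss.ZtZ * dh[None, :]
    M = s2e * np.eye(k)[None] + ZtZt
    Minv = np.linalg.inv(M)
    logdetM = np.linalg.slogdet(M)[1]
    ZtXt = dh[None, :, None] * ss.ZtX
    Ztyt = dh[None, :] * ss.Zty
    XtVX = (ss.XtX - np.einsum("mki,mkl,mlj->ij", ZtXt, Minv, ZtXt)) / s2e
    XtVy = (ss.Xty - np.einsum("mki,mkl,ml->i", ZtXt, Minv, Ztyt)) / s2e
    ytVy = (ss.yty - np.einsum("mk,mkl,ml->", Ztyt, Minv, Ztyt)) / s2e
    sumlogdetV = ss.n * math.log(s2e) + float(np.sum(logdetM)) - ss.m * k * math.log(s2e)
    return XtVX, XtVy, ytVy, sumlogdetV


def _profiled_objectives(ss: _Suffstats, d_diag: np.ndarray, s2e: float):
    """(restricted loglik, profile ML loglik, beta_hat, XtVX) at the GLS beta."""
    XtVX, XtVy, ytVy, sumlogdetV = _gls_pieces(ss, d_diag, s2e)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    sign, logdet_xtvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    reml = -0.5 * (sumlogdetV + logdet_xtvx + rss + (ss.n - ss.p) * _LOG2PI)
    ml = -0.5 * (sumlogdetV + rss + ss.n * _LOG2PI)
    return reml, ml, beta, XtVX


def reml_criterion(params: LMEParams, cohort: Cohort) -> float:
    """Restricted log-likelihood at the given variance components.

    The fixed effects are profiled out by generalized least squares, so the
    value depends on params only through (sigma2_b0, sigma2_b1, sigma2_eps).
    With all random-effect variances at zero this reduces to the restricted
    likelihood of the error-only (OLS) model.
    """
    ss = _Suffstats(cohort, params.k)
    reml, _, _, _ = _profiled_objectives(ss, params.d_diag(), params.sigma2_eps)
    return float(reml)


# ---------------------------------------------------------------------------
# fitting


def fit_ols(cohort: Cohort) -> FitResult:
    """Multiple linear regression of Hb on age, season and DPV.

    Ignores the within-donor correlation by design; serves as the benchmark
    against which the transition and mixed models are judged.
    """
    ss = _Suffstats(cohort, 0)
    if np.linalg.matrix_rank(ss.X) < ss.X.shape[1]:
        raise ValueError("rank-deficient design: a covariate is constant")
    res = sm.OLS(ss.y, ss.X).fit()
    sigma2_ml = float(res.ssr / ss.n)
    params = LMEParams(
        alpha=float(res.params[0]),
        beta=tuple(res.params[1:4]),
        sigma2_b0=0.0,
        sigma2_b1=None,
        sigma2_eps=sigma2_ml,
        structure="LR",
    )
    names = ["alpha", "beta_age", "beta_season", "beta_dpv"]
    se = dict(zip(names, res.bse))
    se["sigma2_eps"] = sigma2_ml * math.sqrt(2.0 / ss.n)
    return FitResult(
        params=params,
        se=se,
        loglik=float(res.llf),
        n_obs=ss.n,
        n_params=5,
        converged=True,
        n_iter=0,
        model="LR",
    )


def _start_values(ss: _Suffstats, k: int) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(ss.X, ss.y, rcond=None)
    resid = ss.y - ss.X @ beta
    v = float(np.var(resid))
    # moment split: variance of donor mean residuals exceeds s2e/T by sigma2_b0
    starts = np.concatenate([[0], np.cumsum(ss.T)[:-1]])
    means = np.add.reduceat(resid, starts) / ss.T
    between = float(np.var(means))
    s2b0 = min(max(between - v * float(np.mean(1.0 / ss.T)), 0.05 * v), 0.9 * v)
    s2e = max(v - s2b0, 0.1 * v)
    if k == 1:
        return np.log([s2b0, s2e])
    return np.log([s2b0, 1e-5, s2e])


def fit_lme(
    cohort: Cohort,
    structure: str = "RI",
    options: Optional[dict] = None,
) -> FitResult:
    """REML fit of the random-intercept (RI) or intercept+slope (RIRS) model.

    Variance components are optimized on the log scale; the fixed effects are
    the GLS solution at the REML optimum, with standard errors from
    (X'V^-1X)^-1.  A variance whose estimate collapses below 1e-10 is
    reported as exactly 0 and flagged as a boundary solution.  The model is
    then re-maximized under ML (starting from the REML solution) and the ML
    log-likelihood is stored for information criteria.
    """
    if structure not in ("RI", "RIRS"):
        raise ValueError("structure must be 'RI' or 'RIRS'")
    k = 1 if structure == "RI" else 2
    ss = _Suffstats(cohort, k)
    if np.linalg.matrix_rank(ss.X) < ss.X.shape[1]:
        raise ValueError("rank-deficient design: a covariate is constant")
    opts = {"maxiter": 200}
    if options:
        opts.update(options)
    phi0 = _start_values(ss, k)
    # keep every variance within a wide but conditioned window around var(y)
    log_vy = math.log(float(np.var(ss.y)) + 1e-12)
    bounds = [(log_vy - 28.0, log_vy + 5.0)] * (k + 1)

    def neg_reml(phi: np.ndarray) -> float:
        v = np.exp(phi)
        try:
            reml, _, _, _ = _profiled_objectives(ss, v[:k], v[k])
        except np.linalg.LinAlgError:
            return 1e10
        return -reml

    res = _minimize_variances(neg_reml, phi0, bounds, opts["maxiter"])
    phi = res.x
    v = np.exp(phi)
    reml_val, _, beta, XtVX = _profiled_objectives(ss, v[:k], v[k])

    # ML refit for information criteria (same parameterization, warm start)
    def neg_ml(phi_ml: np.ndarray) -> float:
        vv = np.exp(phi_ml)
        try:
            _, ml, _, _ = _profiled_objectives(ss, vv[:k], vv[k])
        except np.linalg.LinAlgError:
            return 1e10
        return -ml

    res_ml = _minimize_variances(neg_ml, phi, bounds, opts["maxiter"])
    ml_val = -float(res_ml.fun)

    variances = v.copy()
    boundary = variances[:k] < _BOUNDARY_TOL
    variances[:k] = np.where(boundary, 0.0, variances[:k])
    params = LMEParams(
        alpha=float(beta[0]),
        beta=tuple(beta[1:4]),
        sigma2_b0=float(variances[0]),
        sigma2_b1=float(variances[1]) if k == 2 else None,
        sigma2_eps=float(variances[k]),
        structure=structure,
    )
    cov_beta = np.linalg.inv(XtVX)
    names = ["alpha", "beta_age", "beta_season", "beta_dpv"]
    se = dict(zip(names, np.sqrt(np.diag(cov_beta))))
    vc_names = ["sigma2_b0", "sigma2_b1", "sigma2_eps"] if k == 2 else [
        "sigma2_b0", "sigma2_eps"]
    se_phi = _phi_se(neg_reml, phi)
    for nm, vv, sp in zip(vc_names, v, se_phi):
        se[nm] = vv * sp  # delta method from the log scale
    return FitResult(
        params=params,
        se=se,
        loglik=ml_val,
        n_obs=ss.n,
        n_params=ss.p + k + 1,
        converged=bool(res.success and res_ml.success),
        n_iter=int(res.nit),
        model=f"LME-{structure}",
        extras={"reml": float(reml_val),
                "boundary": [bool(b) for b in boundary]},
    )


def _minimize_variances(fun, phi0: np.ndarray, bounds, maxiter: int):
    """Quasi-Newton on the log-variance scale with a simplex polish fallback.

    Central-difference gradients keep L-BFGS-B honest; if its line search
    still stalls (the objective is ~1e4, so gradient noise is real),
    Nelder-Mead finishes the job on this 2-3 dimensional problem.
    """
    res = scipy.optimize.minimize(
        fun, phi0, method="L-BFGS-B", bounds=bounds, jac="3-point",
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-7},
    )
    # the quasi-Newton step can stall on a flat coordinate (a variance whose
    # gradient vanishes on the log scale); a simplex polish is cheap in 2-3 dims
    res2 = scipy.optimize.minimize(
        fun, res.x, method="Nelder-Mead",
        options={"maxfev": 400, "xatol": 1e-7, "fatol": 1e-8},
    )
    if res2.fun <= res.fun:
        res2.nit = res.nit + res2.nit
        return res2
    return res


def _phi_se(neg_reml, phi: np.ndarray) -> np.ndarray:
    try:
        H = numeric_hessian(neg_reml, phi)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        return np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        return np.full(len(phi), np.nan)


# ---------------------------------------------------------------------------
# empirical Bayes and dynamic prediction


def _eb_solve(
    d_diag: np.ndarray, s2e: float, SZZ: np.ndarray, SZr: np.ndarray
) -> np.ndarray:
    """Batched BLUP: b_hat = D^(1/2) (s2e I + D^(1/2) S_zz D^(1/2))^-1 D^(1/2) S_zr.

    SZZ has shape (..., k, k); SZr shape (..., k).  Valid for singular D.
    """
    k = len(d_diag)
    dh = np.sqrt(d_diag)
    M = s2e * np.eye(k) + dh[:, None] * SZZ * dh[None, :]
    rhs = dh * SZr
    sol = np.linalg.solve(M, rhs[..., None])[..., 0]
    return dh * sol


def empirical_bayes(params: LMEParams, donor_prefix) -> RandomEffectEstimate:
    """Empirical-Bayes (BLUP) estimate of a donor's random effects.

    ``donor_prefix`` is a DataFrame of that donor's previous visits with the
    cohort columns; only those rows inform the estimate.  An empty prefix
    returns the prior mean (0, 0).
    """
    if params.structure == "LR":
        did = str(donor_prefix["donor_id"].iloc[0]) if len(donor_prefix) else ""
        return RandomEffectEstimate(did, 0.0, 0.0, len(donor_prefix))
    n = len(donor_prefix)
    donor_id = str(donor_prefix["donor_id"].iloc[0]) if n else ""
    if n == 0:
        return RandomEffectEstimate(donor_id, 0.0, 0.0, 0)
    X = np.column_stack(
        [np.ones(n), donor_prefix[_COVARIATES].to_numpy(dtype=float)]
    )
    y = donor_prefix["hb"].to_numpy(dtype=float)
    r = y - X @ np.concatenate([[params.alpha], params.beta])
    Z = _random_design(X, params.k)
    b = _eb_solve(params.d_diag(), params.sigma2_eps, Z.T @ Z, Z.T @ r)
    b0 = float(b[0])
    b1 = float(b[1]) if params.k == 2 else 0.0
    return RandomEffectEstimate(donor_id, b0, b1, n)


def predict_dynamic_lme(params: LMEParams, cohort: Cohort) -> PredictionSet:
    """Dynamic one-step-ahead predictions from the mixed model.

    For each visit t the donor's random effects are re-estimated by empirical
    Bayes from visits 1..t-1 and the prediction is x_it'beta + z_it'b_hat.
    At t = 1 the random effects are at their prior mean, so the prediction
    uses covariates only.  With all random-effect variances zero this
    reproduces the OLS predictions.
    """
    df = cohort.data
    n = len(df)
    X = np.column_stack([np.ones(n), df[_COVARIATES].to_numpy(dtype=float)])
    y = df["hb"].to_numpy(dtype=float)
    fixed = X @ np.concatenate([[params.alpha], params.beta])
    k = params.k
    if k == 0:
        pred = fixed
    else:
        Z = _random_design(X, k)
        r = y - fixed
        codes = df["donor_id"].astype("category").cat.codes.to_numpy()
        # prefix (exclusive) cumulative cross-products within donor
        prods = np.concatenate(
            [
                (Z[:, :, None] * Z[:, None, :]).reshape(n, k * k),
                Z * r[:, None],
            ],
            axis=1,
        )
        csum = _grouped_exclusive_cumsum(prods, codes)
        SZZ = csum[:, : k * k].reshape(n, k, k)
        SZr = csum[:, k * k :]
        b = _eb_solve(params.d_diag(), params.sigma2_eps, SZZ, SZr)
        pred = fixed + np.sum(Z * b, axis=1)
    out = df[["donor_id", "visit"]].copy()
    out["y_pred"] = pred
    out["y_obs"] = y
    label = "LR" if params.structure == "LR" else f"LME-{params.structure}"
    return PredictionSet(out, gender=cohort.gender, model=label)


def _grouped_exclusive_cumsum(a: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Cumulative sum within consecutive groups, excluding the current row."""
    total = np.cumsum(a, axis=0)
    shifted = np.zeros_like(total)
    shifted[1:] = total[:-1]
    first = np.ones(len(codes), dtype=bool)
    first[1:] = codes[1:] != codes[:-1]
    idx_first = np.nonzero(first)[0]
    grp_offs = np.zeros((len(idx_first), a.shape[1]))
    grp_offs[1:] = total[idx_first[1:] - 1]
    grp_ord = np.cumsum(first) - 1
    return shifted - grp_offs[grp_ord]


def icc(params: LMEParams) -> float:
    """Intra-class correlation sigma2_b0 / (sigma2_b0 + sigma2_eps).

    Only defined for the random-intercept structure, where the within-donor
    correlation is constant across visit pairs.
    """
    if params.structure != "RI":
        raise ValueError(
            "ICC is constant only under the random-intercept structure"
        )
    return params.sigma2_b0 / (params.sigma2_b0 + params.sigma2_eps)


def lrt_random_slope(fit_ri: FitResult, fit_rirs: FitResult) -> tuple[float, float]:
    """Likelihood-ratio test for the random age slope.

    The null (sigma2_b1 = 0) lies on the boundary of the parameter space, so
    the statistic L = 2(l_RIRS - l_RI), clipped at 0, is referred to an equal
    mixture of chi-squared distributions with 1 and 2 degrees of freedom.
    """
    if fit_ri.model != "LME-RI" or fit_rirs.model != "LME-RIRS":
        raise ValueError("expected an RI fit and an RIRS fit, in that order")
    if fit_ri.n_obs != fit_rirs.n_obs:
        raise ValueError("fits come from different cohorts (n_obs mismatch)")
    L = max(0.0, 2.0 * (fit_rirs.loglik - fit_ri.loglik))
    p = 0.5 * (float(chi2.sf(L, 1)) + float(chi2.sf(L, 2)))
    return L, p
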