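"""Aggregated multilevel models of daily steps with AR(1) residuals.

The aggregated analysis pools all participants' person-day rows and fits
a ladder of six nested linear mixed models by marginal maximum
likelihood (ML, not REML, because the ladder compares deviances of
models that differ in fixed effects):

1. random-intercept null model,
2. + fixed linear time,
3. + random time slope (unstructured 2x2 covariance),
4. + weekday dummies (Sunday reference) and within/between-person
   perceived barriers and pain/illness,
5. + the two intervention-availability indicators (intervention mode) or
   the within/between decomposition of one EMA predictor (predictor
   mode),
6. + AR(1) within-person residual correlation.

For participant i with model rows y_i, the marginal model is
y_i ~ N(X_i beta, Z_i G Z_i' + sigma2 * R_i) where G is the random
intercept(/slope) covariance and R_i has entries rho**|t_j - t_k| with t
the day index, so days removed from the frame (wash-out exclusion,
missing values) widen the correlation gap rather than re-indexing.

Fitting profiles beta and sigma2 out of the likelihood and optimizes the
remaining ratio parameters (G/sigma2 via its Cholesky factor, rho via
tanh) with quasi-Newton iterations; all participants are evaluated in
one batched, zero-padded pass per objective call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "MlmSpec",
    "MlmFit",
    "FixedEffect",
    "DevianceTest",
    "LadderResult",
    "center_covariates",
    "mlm_loglik",
    "fit_mlm",
    "run_ladder",
    "deviance_test",
    "compute_icc",
    "variance_explained",
]

LADDER_MODES = ("intervention", "predictor:self_efficacy", "predictor:motivation")


@dataclass(frozen=True)
class MlmSpec:
    """Specification of one mixed model.

    ``fixed_terms`` are design-matrix columns in order; ``"intercept"``
    denotes the constant column, every other entry names a column of the
    data frame.  ``random_slope`` upgrades the random part from a scalar
    intercept variance to an unstructured 2x2 intercept/slope covariance
    on the ``time_col`` covariate.  ``ar1`` switches the residual
    correlation from independence to gap-aware AR(1); ``fix_rho`` pins
    rho instead of estimating it (used for nesting checks).
    """

    fixed_terms: tuple[str, ...] = ("intercept",)
    random_slope: bool = False
    ar1: bool = False
    fix_rho: float | None = None
    time_col: str = "time"
    day_col: str = "day_index"
    group_col: str = "participant_id"
    response: str = "steps"

    @property
    def n_variance_params(self) -> int:
        k = 2 if not self.random_slope else 4  # (tau00, sigma2) or (+tau11, tau01)
        if self.ar1 and self.fix_rho is None:
            k += 1
        return k

    @property
    def n_params(self) -> int:
        return len(self.fixed_terms) + self.n_variance_params


@dataclass(frozen=True)
class FixedEffect:
    B: float
    SE: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    P: float


@dataclass
class MlmFit:
    """A fitted mixed model: estimates, variance components, fit indices.

    Point estimates of the fixed effects, the deviance (``minus2ll``) and
    BIC come from the ML fit (the model ladder compares ML deviances);
    the variance components and all fixed-effect uncertainty (SE, t, P,
    CI) come from a restricted-likelihood (REML) refit, whose level-2
    variance estimates are first-order unbiased in small cohorts.  The
    raw ML variance components are kept in ``ml_variance``.
    """

    spec: MlmSpec = None
    fixed: dict[str, FixedEffect] = field(default_factory=dict)
    tau00: float = 0.0
    tau11: float = 0.0
    tau01: float = 0.0
    sigma2: float = 1.0
    rho: float = 0.0
    minus2ll: float = np.nan
    n_obs: int = 0
    n_participants: int = 0
    n_params: int = 0
    converged: bool = True
    boundary: bool = False
    theta: np.ndarray | None = None
    ml_variance: dict | None = None

    @property
    def bic(self) -> float:
        return self.minus2ll + self.n_params * np.log(self.n_obs)

    def beta(self) -> np.ndarray:
        return np.array([fe.B for fe in self.fixed.values()])


@dataclass(frozen=True)
class DevianceTest:
    chi2: float
    df: int
    P: float


@dataclass
class LadderResult:
    """The six nested fits with step-wise deviance tests and summaries."""

    mode: str
    fits: list[MlmFit]
    tests: list[DevianceTest | None]
    labels: list[str]
    icc: float
    n_possible: int
    n_used: int
    variance_explained: dict[str, float]

    @property
    def final(self) -> MlmFit:
        return self.fits[-1]

    def table(self) -> pd.DataFrame:
        rows = []
        for label, fit, test in zip(self.labels, self.fits, self.tests):
            rows.append({
                "model": label,
                "n_params": fit.n_params,
                "minus2ll": fit.minus2ll,
                "chi2": test.chi2 if test else np.nan,
                "df": test.df if test else np.nan,
                "P": test.P if test else np.nan,
                "BIC": fit.bic,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# centering

def center_covariates(data: pd.DataFrame, variables: list[str],
                      group_col: str = "participant_id") -> pd.DataFrame:
    """Add person-mean, within-person and between-person columns.

    For each variable x: ``x_pmean`` is participant i's mean over
    non-missing days, ``x_within`` = x_it − x_pmean_i (missing where x
    is missing), and ``x_between`` = x_pmean_i centered at the grand
    mean of the person means (each participant weighted equally).
    """
    out = data.copy()
    for var in variables:
        if var not in out.columns:
            raise KeyError(f"variable {var!r} not in data")
        pmeans = out.groupby(group_col)[var].transform("mean")
        per_person = out.groupby(group_col)[var].mean()
        if per_person.isna().any():
            bad = per_person[per_person.isna()].index.tolist()
            raise ValueError(f"{var!r} entirely missing for participants {bad}")
        grand = per_person.mean()
        out[f"{var}_pmean"] = pmeans
        out[f"{var}_within"] = out[var] - pmeans
        out[f"{var}_between"] = pmeans - grand
    return out


# ---------------------------------------------------------------------------
# likelihood machinery

class _Batched:
    """Zero-padded per-participant arrays for one model frame."""

    def __init__(self, data: pd.DataFrame, spec: MlmSpec):
        cols = [c for c in spec.fixed_terms if c != "intercept"]
        needed = [spec.response] + cols + [spec.day_col]
        if spec.random_slope and spec.time_col not in needed:
            needed.append(spec.time_col)
        frame = data[[spec.group_col] + needed].dropna()
        if frame.empty:
            raise ValueError("no complete rows for the model frame")
        groups = [g for _, g in frame.groupby(spec.group_col, sort=False)]
        self.m = len(groups)
        self.n_obs = len(frame)
        self.p = len(spec.fixed_terms)
        nmax = max(len(g) for g in groups)
        self.X = np.zeros((self.m, nmax, self.p))
        self.y = np.zeros((self.m, nmax))
        self.mask = np.zeros((self.m, nmax), dtype=bool)
        self.D = np.zeros((self.m, nmax, nmax))
        self.T = np.zeros((self.m, nmax))   # time covariate for random slope
        for i, g in enumerate(groups):
            n = len(g)
            self.mask[i, :n] = True
            self.y[i, :n] = g[spec.response].to_numpy(dtype=float)
            for j, term in enumerate(spec.fixed_terms):
                self.X[i, :n, j] = (1.0 if term == "intercept"
                                    else g[term].to_numpy(dtype=float))
            days = g[spec.day_col].to_numpy(dtype=float)
            self.D[i, :n, :n] = np.abs(days[:, None] - days[None, :])
            if spec.random_slope:
                self.T[i, :n] = g[spec.time_col].to_numpy(dtype=float)
        self.pairmask = self.mask[:, :, None] & self.mask[:, None, :]
        self.ones = self.mask.astype(float)
        self.eye = np.eye(nmax)
        # between/within classification for df rule
        self.is_between = np.array([
            all(np.ptp(self.X[i][self.mask[i], j]) == 0 for i in range(self.m))
            for j in range(self.p)
        ])

    def corr(self, rho: float) -> np.ndarray:
        if rho == 0.0:
            return np.broadcast_to(self.eye, self.D.shape)
        R = np.power(rho, self.D) * self.pairmask
        idx = np.arange(self.D.shape[1])
        R[:, idx, idx] = 1.0
        return R

    def w_matrix(self, gtilde: np.ndarray, rho: float) -> np.ndarray:
        """W_i = Z_i (G/sigma2) Z_i' + R_i(rho), identity-padded."""
        o, t = self.ones, self.T
        ZGZ = (
            gtilde[0, 0] * (o[:, :, None] * o[:, None, :])
            + gtilde[0, 1] * (o[:, :, None] * t[:, None, :]
                              + t[:, :, None] * o[:, None, :])
            + gtilde[1, 1] * (t[:, :, None] * t[:, None, :])
        )
        return ZGZ + self.corr(rho)


def _unpack_theta(theta: np.ndarray, spec: MlmSpec) -> tuple[np.ndarray, float]:
    """theta -> (relative covariance G/sigma2, rho)."""
    if spec.random_slope:
        l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
        L = np.array([[l11, 0.0], [l21, l22]])
        k = 3
    else:
        l11 = np.exp(theta[0])
        L = np.array([[l11, 0.0], [0.0, 0.0]])
        k = 1
    gtilde = L @ L.T
    if spec.ar1:
        rho = spec.fix_rho if spec.fix_rho is not None else float(np.tanh(theta[k]))
    else:
        rho = 0.0
    return gtilde, rho


def _profiled_m2ll(theta: np.ndarray, b: _Batched, spec: MlmSpec,
                   reml: bool = False):
    """Profiled -2 log (restricted) likelihood and the profiled (beta, sigma2).

    With ``reml=True`` the residual variance is profiled on N − p degrees
    of freedom and the criterion gains the log|X'W⁻¹X| penalty; this
    restricted criterion is used only for inference (standard errors and
    reported variance components), never for the deviance ladder.
    """
    gtilde, rho = _unpack_theta(theta, spec)
    W = b.w_matrix(gtilde, rho)
    try:
        L = np.linalg.cholesky(W)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    logdet = 2.0 * np.log(np.einsum("mii->mi", L)).sum()
    rhs = np.concatenate([b.X, b.y[:, :, None]], axis=2)
    sol = np.linalg.solve(W, rhs)
    xtwx = np.einsum("mij,mik->jk", b.X, sol[:, :, : b.p])
    xtwy = np.einsum("mij,mi->j", b.X, sol[:, :, b.p])
    ytwy = float(np.einsum("mi,mi->", b.y, sol[:, :, b.p]))
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    quad = ytwy - 2 * beta @ xtwy + beta @ xtwx @ beta
    n = b.n_obs
    if reml:
        dof = max(n - b.p, 1)
        sigma2 = max(quad / dof, 1e-12)
        sign, logdet_info = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf, None, None, None
        m2ll = dof * (np.log(2 * np.pi * sigma2) + 1.0) + logdet + logdet_info
    else:
        sigma2 = max(quad / n, 1e-12)
        m2ll = n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
    return float(m2ll), beta, sigma2, xtwx


def mlm_loglik(params: dict, data: pd.DataFrame, spec: MlmSpec) -> float:
    """Marginal Gaussian log-likelihood at explicit parameter values.

    ``params`` holds ``beta`` (in ``spec.fixed_terms`` order), ``tau00``,
    ``sigma2`` and optionally ``tau11``, ``tau01``, ``rho``.  Rows with
    missing model variables are excluded.  Evaluates
    sum_i log N(y_i | X_i beta, Z_i G Z_i' + sigma2 R_i).
    """
    b = _Batched(data, spec)
    beta = np.asarray(params["beta"], dtype=float)
    if beta.shape != (b.p,):
        raise ValueError(f"beta must have length {b.p}")
    sigma2 = float(params["sigma2"])
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    G = np.array([
        [params.get("tau00", 0.0), params.get("tau01", 0.0)],
        [params.get("tau01", 0.0), params.get("tau11", 0.0)],
    ], dtype=float)
    rho = float(params.get("rho", 0.0))
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    W = b.w_matrix(G / sigma2, rho)
    L = np.linalg.cholesky(W)  # raises LinAlgError if not PD
    logdet_v = 2.0 * np.log(np.einsum("mii->mi", L)).sum() + b.n_obs * np.log(sigma2)
    r = (b.y - np.einsum("mij,j->mi", b.X, beta)) * b.ones
    winv_r = np.linalg.solve(W, r[:, :, None])[:, :, 0]
    quad = float(np.einsum("mi,mi->", r, winv_r)) / sigma2
    return -0.5 * (b.n_obs * np.log(2 * np.pi) + logdet_v + quad)


def _initial_theta(data: pd.DataFrame, spec: MlmSpec, b: _Batched) -> np.ndarray:
    """Moment-based start: split pooled-OLS residual variance between levels."""
    X = np.concatenate([b.X[i][b.mask[i]] for i in range(b.m)])
    y = np.concatenate([b.y[i][b.mask[i]] for i in range(b.m)])
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    counts = b.mask.sum(axis=1)
    splits = np.split(resid, np.cumsum(counts)[:-1])
    pmeans = np.array([s.mean() for s in splits])
    within = np.concatenate([s - s.mean() for s in splits])
    var_w = max(float(within.var(ddof=1)), 1e-8)
    var_b = max(float(pmeans.var(ddof=1)) - var_w / counts.mean(), 1e-4 * var_w)
    psi00 = var_b / var_w
    theta = [0.5 * np.log(max(psi00, 1e-6))]
    if spec.random_slope:
        theta += [0.0, np.log(1e-2)]
    if spec.ar1 and spec.fix_rho is None:
        theta += [np.arctanh(0.05)]
    return np.array(theta)


def _theta_bounds(spec: MlmSpec) -> list[tuple[float, float]]:
    bounds = [(-12.0, 8.0)]
    if spec.random_slope:
        bounds += [(-60.0, 60.0), (-14.0, 4.0)]
    if spec.ar1 and spec.fix_rho is None:
        bounds += [(-5.0, 5.0)]
    return bounds


def fit_mlm(
    data: pd.DataFrame,
    spec: MlmSpec,
    warm_start: MlmFit | None = None,
    max_restarts: int = 3,
) -> MlmFit:
    """Fit one mixed model by profiled marginal maximum likelihood.

    Fixed effects and the residual variance have closed forms given the
    relative covariance parameters, which are optimized numerically
    (L-BFGS-B on log/tanh transforms, safeguarded restarts from
    perturbed starts).  Fixed-effect standard errors come from the
    inverse expected information sigma2*(sum_i X_i' W_i^-1 X_i)^-1;
    denominator degrees of freedom follow the between/within rule:
    person-constant columns get n_participants − q (q = number of
    person-constant columns), day-varying columns get n_obs − p.
    """
    uniq = data[spec.group_col].nunique()
    if uniq < 2:
        raise ValueError("need at least 2 participants")
    b = _Batched(data, spec)

    starts = []
    if warm_start is not None and warm_start.theta is not None:
        t0 = _extend_theta(warm_start, spec)
        if t0 is not None:
            starts.append(t0)
    starts.append(_initial_theta(data, spec, b))
    starts.append(np.zeros_like(starts[-1]))

    bounds = _theta_bounds(spec)
    best = None
    rng = np.random.default_rng(0)
    attempts = 0
    for theta0 in starts:
        if attempts >= len(starts) + max_restarts:
            break
        attempts += 1
        res = optimize.minimize(
            lambda th: _profiled_m2ll(th, b, spec)[0],
            theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-11},
        )
        if not res.success:
            # L-BFGS-B line searches occasionally stall on these profiled
            # surfaces; a derivative-free polish from its best point is cheap
            polish = optimize.minimize(
                lambda th: _profiled_m2ll(th, b, spec)[0],
                res.x, method="Nelder-Mead",
                options={"maxiter": 400, "fatol": 1e-9, "xatol": 1e-7},
            )
            if polish.fun <= res.fun:
                res = polish
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success and np.isfinite(res.fun):
            if best.fun >= res.fun - 1e-6:
                break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("mixed-model optimization failed to produce a finite fit")
    if not best.success:
        logger.warning("mixed-model optimizer did not report convergence: %s",
                       best.message)

    theta = best.x
    m2ll, beta, sigma2, xtwx = _profiled_m2ll(theta, b, spec)
    gtilde, rho = _unpack_theta(theta, spec)

    # inference step: re-estimate the variance parameters under the
    # restricted (REML) criterion, warm-started at the ML optimum; ML's
    # level-2 variance estimates are biased low by roughly (m - q)/m with
    # only 15 participants, which would shrink every person-level CI
    res_r = optimize.minimize(
        lambda th: _profiled_m2ll(th, b, spec, reml=True)[0],
        theta, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-10},
    )
    if not res_r.success:
        polish = optimize.minimize(
            lambda th: _profiled_m2ll(th, b, spec, reml=True)[0],
            res_r.x, method="Nelder-Mead",
            options={"maxiter": 300, "fatol": 1e-8, "xatol": 1e-6},
        )
        if polish.fun <= res_r.fun:
            res_r = polish
    theta_r = res_r.x if np.isfinite(res_r.fun) else theta
    _, _, sigma2_r, xtwx_r = _profiled_m2ll(theta_r, b, spec, reml=True)
    gtilde_r, rho_r = _unpack_theta(theta_r, spec)
    cov_beta = sigma2_r * np.linalg.inv(xtwx_r)
    cov_beta = cov_beta + _kackar_harville_term(theta_r, b, spec)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))

    q_between = int(b.is_between.sum())
    df_between = max(b.m - q_between, 1)
    df_within = max(b.n_obs - b.p, 1)

    fixed: dict[str, FixedEffect] = {}
    for j, term in enumerate(spec.fixed_terms):
        df = df_between if b.is_between[j] else df_within
        tval = beta[j] / se[j] if se[j] > 0 else np.inf
        crit = stats.t.ppf(0.975, df)
        fixed[term] = FixedEffect(
            B=float(beta[j]), SE=float(se[j]),
            ci_low=float(beta[j] - crit * se[j]),
            ci_high=float(beta[j] + crit * se[j]),
            t=float(tval), df=float(df),
            P=float(2 * stats.t.sf(abs(tval), df)),
        )

    boundary = bool(theta[0] <= _theta_bounds(spec)[0][0] + 1e-6
                    or sigma2 <= 1e-10)
    fit = MlmFit(
        spec=spec, fixed=fixed,
        tau00=float(sigma2_r * gtilde_r[0, 0]),
        tau11=float(sigma2_r * gtilde_r[1, 1]),
        tau01=float(sigma2_r * gtilde_r[0, 1]),
        sigma2=float(sigma2_r), rho=float(rho_r),
        minus2ll=float(m2ll),
        n_obs=b.n_obs, n_participants=b.m,
        n_params=spec.n_params,
        converged=bool(best.success), boundary=boundary,
        theta=np.array(theta),
        ml_variance={
            "tau00": float(sigma2 * gtilde[0, 0]),
            "tau11": float(sigma2 * gtilde[1, 1]),
            "tau01": float(sigma2 * gtilde[0, 1]),
            "sigma2": float(sigma2), "rho": float(rho),
        },
    )
    return fit


def _kackar_harville_term(theta_r: np.ndarray, b: _Batched,
                          spec: MlmSpec) -> np.ndarray:
    """First-order correction for variance-parameter uncertainty.

    The plug-in GLS covariance sigma2*(X'W^-1 X)^-1 treats the estimated
    covariance parameters as known; the Kackar-Harville term adds
    D Cov(theta) D' where D = d beta(theta)/d theta, restoring the extra
    spread of estimated-GLS coefficients in small cohorts.  Cov(theta)
    comes from the numerical Hessian of the restricted criterion.
    """
    k = len(theta_r)
    p = b.p

    def beta_at(th):
        _, beta, _, _ = _profiled_m2ll(th, b, spec, reml=True)
        return beta

    def obj(th):
        return _profiled_m2ll(th, b, spec, reml=True)[0]

    h = 1e-4
    D = np.zeros((p, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        hi, lo = beta_at(theta_r + e), beta_at(theta_r - e)
        if hi is None or lo is None:
            return np.zeros((p, p))
        D[:, i] = (hi - lo) / (2 * h)
    # Hessian of -2 restricted LL by central differences
    H = np.zeros((k, k))
    f0 = obj(theta_r)
    hh = 1e-3
    for i in range(k):
        for j in range(i, k):
            ei, ej = np.zeros(k), np.zeros(k)
            ei[i], ej[j] = hh, hh
            fpp = obj(theta_r + ei + ej)
            fpm = obj(theta_r + ei - ej)
            fmp = obj(theta_r - ei + ej)
            fmm = obj(theta_r - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hh * hh)
    if not np.all(np.isfinite(H)):
        return np.zeros((p, p))
    try:
        cov_theta = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.zeros((p, p))
    # guard against an indefinite numerical Hessian near boundaries
    w, V = np.linalg.eigh(cov_theta)
    cov_theta = V @ np.diag(np.clip(w, 0.0, None)) @ V.T
    return D @ cov_theta @ D.T


def _extend_theta(prev: MlmFit, spec: MlmSpec) -> np.ndarray | None:
    """Map a previous (nested) fit's theta onto a larger spec's layout."""
    if prev.theta is None:
        return None
    theta = []
    pspec = prev.spec
    if spec.random_slope:
        if pspec.random_slope:
            theta += list(prev.theta[:3])
            k = 3
        else:
            theta += [prev.theta[0], 0.0, np.log(1e-2)]
            k = 1
    else:
        if pspec.random_slope:
            return None
        theta += [prev.theta[0]]
        k = 1
    if spec.ar1 and spec.fix_rho is None:
        if pspec.ar1 and pspec.fix_rho is None:
            theta += [prev.theta[-1]]
        else:
            theta += [np.arctanh(0.05)]
    return np.array(theta)


# ---------------------------------------------------------------------------
# ladder

def deviance_test(fit_smaller: MlmFit, fit_larger: MlmFit) -> DevianceTest:
    """Chi-square test of the deviance drop between nested ML fits."""
    df = fit_larger.n_params - fit_smaller.n_params
    if df <= 0:
        raise ValueError("larger model must add parameters")
    if fit_smaller.n_obs and fit_larger.n_obs and fit_smaller.n_obs != fit_larger.n_obs:
        raise ValueError("fits use different row counts; deviances not comparable")
    chi2 = max(0.0, fit_smaller.minus2ll - fit_larger.minus2ll)
    return DevianceTest(chi2=float(chi2), df=int(df),
                        P=float(stats.chi2.sf(chi2, df)))


def compute_icc(null_fit: MlmFit) -> float:
    """Intraclass correlation tau00/(tau00 + sigma2) from a null fit."""
    total = null_fit.tau00 + null_fit.sigma2
    if total <= 0:
        raise ValueError("both variance components are zero")
    return null_fit.tau00 / total


def variance_explained(reference_fit: MlmFit, fit: MlmFit,
                       component: str = "within") -> float:
    """Proportional reduction in a variance component between nested fits."""
    if component not in ("within", "between"):
        raise ValueError("component must be 'within' or 'between'")
    attr = "sigma2" if component == "within" else "tau00"
    ref = getattr(reference_fit, attr)
    if ref == 0:
        raise ValueError(f"reference {component} component is zero")
    return (ref - getattr(fit, attr)) / ref


WEEKDAY_DUMMIES = ("wd_mon", "wd_tue", "wd_wed", "wd_thu", "wd_fri", "wd_sat")


def prepare_frame(data: pd.DataFrame, mode: str) -> tuple[pd.DataFrame, int, list[str]]:
    """Build the model frame for one ladder mode.

    Intervention mode drops wash-out days (no component is delivered on
    them and their carryover status is ambiguous); predictor modes keep
    them.  Adds ``time`` (= day index), Sunday-referenced weekday
    dummies, and within/between-centered covariates.  Returns the frame,
    the possible-day count (before missingness), and the mode's model-5
    predictor column names.
    """
    if mode not in LADDER_MODES:
        raise ValueError(f"mode must be one of {LADDER_MODES}")
    df = data.copy()
    if mode == "intervention":
        df = df[df["washout"] == 0].copy()
    n_possible = len(df)
    df["time"] = df["day_index"].astype(float)
    for j, name in enumerate(WEEKDAY_DUMMIES, start=1):
        df[name] = (df["weekday"] == j).astype(float)
    center_vars = ["barriers", "pain"]
    if mode == "intervention":
        df["dmi"] = df["dmi_available"].astype(float)
        df["bf"] = df["bf_suggested"].astype(float)
        predictors = ["dmi", "bf"]
    else:
        var = "se_morning" if mode.endswith("self_efficacy") else "mot_morning"
        center_vars.append(var)
        predictors = [f"{var}_within", f"{var}_between"]
    df = center_covariates(df, center_vars)
    return df, n_possible, predictors


def ladder_specs(predictors: list[str]) -> tuple[list[str], list[MlmSpec]]:
    base = ("intercept",)
    m2 = base + ("time",)
    m4 = m2 + WEEKDAY_DUMMIES + (
        "barriers_within", "barriers_between", "pain_within", "pain_between")
    m5 = m4 + tuple(predictors)
    labels = [
        "1: fixed and random intercepts",
        "2: model 1 + fixed time",
        "3: model 2 + random time (UN)",
        "4: model 3 + day of week + barriers + pain (within/between)",
        "5: model 4 + " + " + ".join(predictors),
        "6: model 5 + AR1 residual autocorrelation",
    ]
    specs = [
        MlmSpec(fixed_terms=base),
        MlmSpec(fixed_terms=m2),
        MlmSpec(fixed_terms=m2, random_slope=True),
        MlmSpec(fixed_terms=m4, random_slope=True),
        MlmSpec(fixed_terms=m5, random_slope=True),
        MlmSpec(fixed_terms=m5, random_slope=True, ar1=True),
    ]
    return labels, specs


def run_ladder(data, mode: str = "intervention") -> LadderResult:
    """Fit the six-model ladder on one dataset.

    ``data`` is a long person-day table (or LongDataset).  All six models
    are fitted on the same complete-case rows (rows complete for the
    largest model's variables), so the successive deviance tests compare
    identical data.  Returns fits, step-wise chi-square tests, the
    null-model ICC and variance-explained summaries.
    """
    if hasattr(data, "data"):
        data = data.data
    df, n_possible, predictors = prepare_frame(data, mode)
    labels, specs = ladder_specs(predictors)
    frame_cols = ["participant_id", "day_index", "steps"] + [
        c for c in specs[-1].fixed_terms if c != "intercept"]
    frame = df[frame_cols].dropna()

    fits: list[MlmFit] = []
    tests: list[DevianceTest | None] = [None]
    prev: MlmFit | None = None
    for idx, spec in enumerate(specs):
        try:
            fit = fit_mlm(frame, spec, warm_start=prev)
        except Exception as exc:  # propagate with the failing model index
            raise RuntimeError(f"ladder model {idx + 1} failed: {exc}") from exc
        if prev is not None:
            tests.append(deviance_test(prev, fit))
        fits.append(fit)
        prev = fit

    ve = {
        "within_time_m2_vs_m1": variance_explained(fits[0], fits[1], "within"),
        "between_slope_m3_vs_m2": variance_explained(fits[1], fits[2], "between"),
        "within_controls_m4_vs_m3": variance_explained(fits[2], fits[3], "within"),
        "between_controls_m4_vs_m3": variance_explained(fits[2], fits[3], "between"),
        "within_predictors_m5_vs_m4": variance_explained(fits[3], fits[4], "within"),
    }
    return LadderResult(
        mode=mode, fits=fits, tests=tests, labels=labels,
        icc=compute_icc(fits[0]),
        n_possible=n_possible, n_used=len(frame),
        variance_explained=ve,
    )


def fit_table(fit: MlmFit) -> pd.DataFrame:
    """Tabulate one fit in the published layout (B, SE, CI, t, df, P)."""
    rows = [
        {"effect": "fixed", "term": term, "B": fe.B, "SE": fe.SE,
         "ci_low": fe.ci_low, "ci_high": fe.ci_high, "t": fe.t,
         "df": fe.df, "P": fe.P}
        for term, fe in fit.fixed.items()
    ]
    rows += [
        {"effect": "random", "term": "UN(1,1) intercept variance", "B": fit.tau00},
        {"effect": "random", "term": "UN(2,2) slope variance", "B": fit.tau11},
        {"effect": "random", "term": "UN(2,1) covariance", "B": fit.tau01},
        {"effect": "random", "term": "residual variance", "B": fit.sigma2},
        {"effect": "random", "term": "AR1 rho", "B": fit.rho},
    ]
    return pd.DataFrame(rows)
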