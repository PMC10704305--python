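"""Within-person (N-of-1) dynamic regression of daily steps.

Each participant's 40-day series is analyzed on its own with a multistep
procedure: (1) screen for linear/quadratic time trends; (2) screen for a
weekday cycle; (3) screen the autocorrelation function for candidate
lags and confirm each with a lagged-steps regression; then (4) fit the
final ordinary-least-squares model with the retained controls plus
either the two intervention-availability indicators (intention-to-treat
coding) or one morning EMA predictor (self-efficacy or motivation —
never both, they are strongly correlated), always controlling for
perceived barriers and pain/illness.  Wash-out days stay in the data and
act as control days, since nothing is delivered on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Nof1Spec",
    "Nof1Fit",
    "TermEstimate",
    "fit_ols",
    "detect_time_trend",
    "detect_weekday_effect",
    "detect_autocorrelation_lags",
    "fit_nof1_model",
    "summarize_cohort_nof1",
]

MODES = ("intervention", "predictor:self_efficacy", "predictor:motivation")


@dataclass(frozen=True)
class Nof1Spec:
    """Retained terms for a participant's final dynamic regression."""

    trend_terms: frozenset = frozenset()          # subset of {"linear", "quadratic"}
    include_weekday: bool = False
    lag_set: tuple[int, ...] = ()
    covariates: tuple[str, ...] = ("barriers", "pain")
    alpha: float = 0.05


@dataclass(frozen=True)
class TermEstimate:
    B: float
    SE: float
    ci_low: float
    ci_high: float
    P: float


@dataclass
class Nof1Fit:
    """OLS result: per-term estimates, fit statistics, dropped terms."""

    terms: dict[str, TermEstimate]
    r_squared: float
    n_used: int
    dropped_terms: list[tuple[str, str]] = field(default_factory=list)
    sse: float = np.nan

    def p_value(self, term: str) -> float | None:
        est = self.terms.get(term)
        return est.P if est is not None else None


def fit_ols(y, X: pd.DataFrame, add_intercept: bool = True) -> Nof1Fit:
    """Least squares with t-based inference for small daily series.

    Rows with any missing value are removed; covariates that are constant
    over the remaining rows are dropped (recorded in ``dropped_terms``)
    rather than raising, because participant-specific data routinely
    degenerate (e.g. a participant who never reports pain).  A perfectly
    fitting model (zero residual variance) reports P=0 for non-zero
    coefficients and P=1 otherwise instead of dividing by zero.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    frame = pd.concat([y, X.astype(float)], axis=1).dropna()
    yv = frame["y"].to_numpy()
    Xf = frame.drop(columns="y")

    dropped: list[tuple[str, str]] = []
    for col in list(Xf.columns):
        if np.ptp(Xf[col].to_numpy()) == 0:
            dropped.append((col, "constant over usable rows"))
            Xf = Xf.drop(columns=col)
    names = list(Xf.columns)
    M = Xf.to_numpy()
    if add_intercept:
        M = np.column_stack([np.ones(len(M)), M])
        names = ["intercept"] + names

    n, p = M.shape
    if n < p + 1:
        raise ValueError(f"only {n} usable rows for {p} coefficients")
    if np.linalg.matrix_rank(M) < p:
        raise ValueError("design matrix is singular after dropping constants")

    beta, _, _, _ = np.linalg.lstsq(M, yv, rcond=None)
    resid = yv - M @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    dof = n - p
    sigma2 = sse / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(M.T @ M)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    tcrit = stats.t.ppf(0.975, dof)
    terms: dict[str, TermEstimate] = {}
    perfect = sst > 0 and sse <= 1e-10 * sst or (sst == 0 and sse == 0)
    for j, name in enumerate(names):
        if perfect or se[j] == 0:
            pval = 0.0 if abs(beta[j]) > 1e-10 else 1.0
            tstat_se = 0.0
        else:
            tstat = beta[j] / se[j]
            pval = 2 * stats.t.sf(abs(tstat), dof)
            tstat_se = se[j]
        terms[name] = TermEstimate(
            B=float(beta[j]),
            SE=float(tstat_se),
            ci_low=float(beta[j] - tcrit * tstat_se),
            ci_high=float(beta[j] + tcrit * tstat_se),
            P=float(pval),
        )
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return Nof1Fit(terms=terms, r_squared=float(r2), n_used=n,
                   dropped_terms=dropped, sse=sse)


def detect_time_trend(steps, day_index, alpha: float = 0.05) -> frozenset:
    """Curve estimation: retain significant linear/quadratic trend terms.

    Fits steps ~ t (linear screen) and steps ~ t + t² (quadratic screen)
    and keeps each term whose coefficient has a two-sided P < alpha.
    """
    s = pd.Series(np.asarray(steps, dtype=float))
    t = pd.Series(np.asarray(day_index, dtype=float))
    usable = s.notna() & t.notna()
    if usable.sum() < 10:
        raise ValueError("need at least 10 non-missing observations")
    if np.ptp(s[usable].to_numpy()) == 0:
        raise ValueError("constant step series")
    retained = set()
    lin = fit_ols(s, pd.DataFrame({"t": t}))
    if lin.p_value("t") is not None and lin.p_value("t") < alpha:
        retained.add("linear")
    quad = fit_ols(s, pd.DataFrame({"t": t, "t2": t**2}))
    if quad.p_value("t2") is not None and quad.p_value("t2") < alpha:
        retained.add("quadratic")
    return frozenset(retained)


def detect_weekday_effect(steps, weekday, alpha: float = 0.05) -> bool:
    """True if a single numeric weekday covariate (1=Mon..7=Sun) predicts steps."""
    s = pd.Series(np.asarray(steps, dtype=float))
    w = pd.Series(np.asarray(weekday, dtype=float))
    usable = s.notna() & w.notna()
    if w[usable].nunique() < 2:
        raise ValueError("all usable observations share one weekday")
    fit = fit_ols(s, pd.DataFrame({"weekday": w}))
    p = fit.p_value("weekday")
    return p is not None and p < alpha


def _pairwise_acf(x: np.ndarray, lag: int) -> tuple[float, int]:
    """Lag-k autocorrelation over pairwise-complete observations."""
    a, b = x[lag:], x[:-lag]
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        return 0.0, int(ok.sum())
    return float(np.corrcoef(a[ok], b[ok])[0, 1]), int(ok.sum())


def detect_autocorrelation_lags(steps, max_lag: int = 7,
                                alpha: float = 0.05) -> tuple[int, ...]:
    """Screen the ACF for candidate lags and confirm each by regression.

    Candidates are lags whose sample autocorrelation falls outside the
    ±1.96/√n white-noise band (n = non-missing series length); each
    candidate is confirmed only if the lagged-steps coefficient in a
    regression of steps on that single lag has P < alpha.
    """
    x = np.asarray(steps, dtype=float)
    n_obs = int(np.sum(~np.isnan(x)))
    if len(x) < max_lag + 5:
        raise ValueError(f"series length {len(x)} < max_lag + 5")
    if n_obs < max_lag + 5:
        raise ValueError("too few non-missing observations")
    if np.ptp(x[~np.isnan(x)]) == 0:
        raise ValueError("constant step series")
    band = 1.96 / np.sqrt(n_obs)
    confirmed = []
    for lag in range(1, max_lag + 1):
        r, _ = _pairwise_acf(x, lag)
        if abs(r) <= band:
            continue
        lagged = pd.Series(x).shift(lag)
        fit = fit_ols(pd.Series(x), pd.DataFrame({f"lag{lag}": lagged}))
        p = fit.p_value(f"lag{lag}")
        if p is not None and p < alpha:
            confirmed.append(lag)
    return tuple(confirmed)


def build_spec(data: pd.DataFrame, alpha: float = 0.05,
               max_lag: int = 7) -> Nof1Spec:
    """Run the three screening steps on one participant's series."""
    steps = data["steps"]
    trend = frozenset()
    weekday = False
    lags: tuple[int, ...] = ()
    try:
        trend = detect_time_trend(steps, data["day_index"], alpha=alpha)
    except ValueError:
        pass
    try:
        weekday = detect_weekday_effect(steps, data["weekday"], alpha=alpha)
    except ValueError:
        pass
    try:
        lags = detect_autocorrelation_lags(steps, max_lag=max_lag, alpha=alpha)
    except ValueError:
        pass
    return Nof1Spec(trend_terms=trend, include_weekday=weekday,
                    lag_set=lags, alpha=alpha)


def fit_nof1_model(
    data: pd.DataFrame,
    mode: str = "intervention",
    spec: Nof1Spec | None = None,
) -> Nof1Fit:
    """Final dynamic regression for one participant.

    ``data`` is one participant's person-day rows (wash-out days
    included; their availability flags are 0, so they act as control
    days).  ``mode`` selects the primary predictors: the two intervention
    indicators, or morning self-efficacy, or morning motivation.  When
    ``spec`` is omitted the trend/weekday/lag screens are run first.
    Constant covariates (e.g. pain for a participant who reported none)
    are dropped and recorded.  Days missing any model variable are
    removed listwise.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    data = data.sort_values("day_index").reset_index(drop=True)
    if data["steps"].notna().sum() < 15:
        raise ValueError("fewer than 15 usable days")
    if spec is None:
        spec = build_spec(data)

    X = pd.DataFrame(index=data.index)
    if mode == "intervention":
        X["dmi"] = data["dmi_available"].astype(float)
        X["bf"] = data["bf_suggested"].astype(float)
    elif mode == "predictor:self_efficacy":
        X["self_efficacy"] = data["se_morning"].astype(float)
    else:
        X["motivation"] = data["mot_morning"].astype(float)
    for cov in spec.covariates:
        X[cov] = data[cov].astype(float)
    if "linear" in spec.trend_terms or "quadratic" in spec.trend_terms:
        X["time"] = data["day_index"].astype(float)
    if "quadratic" in spec.trend_terms:
        X["time_sq"] = data["day_index"].astype(float) ** 2
    if spec.include_weekday:
        X["weekday"] = data["weekday"].astype(float)
    steps = data["steps"].astype(float)
    for lag in spec.lag_set:
        X[f"steps_lag{lag}"] = steps.shift(lag)

    for col in X.columns:
        if X[col].notna().sum() == 0:
            raise ValueError(f"predictor {col} is entirely missing")
    return fit_ols(steps, X)


@dataclass(frozen=True)
class CohortNof1Summary:
    term: str
    n_total: int
    n_significant: int
    n_positive: int
    n_negative: int

    @property
    def percent(self) -> int:
        return int(np.floor(100 * self.n_significant / self.n_total + 0.5))

    @property
    def percent_positive(self) -> int:
        return int(np.floor(100 * self.n_positive / self.n_total + 0.5))

    def format(self, sign: str = "positive") -> str:
        k = {"any": self.n_significant, "positive": self.n_positive,
             "negative": self.n_negative}[sign]
        pct = int(np.floor(100 * k / self.n_total + 0.5))
        return f"{k}/{self.n_total} ({pct}%)"


def summarize_cohort_nof1(
    fits: dict[str, Nof1Fit],
    term: str,
    alpha: float = 0.05,
) -> CohortNof1Summary:
    """How many participants' fits found ``term`` significant, by sign.

    Participants whose model dropped the term count toward the
    denominator but cannot be significant.
    """
    if not fits:
        raise ValueError("no fits supplied")
    present = [f for f in fits.values() if term in f.terms]
    if not present:
        raise ValueError(f"term {term!r} absent from every fit")
    sig = [f.terms[term] for f in present if f.terms[term].P < alpha]
    return CohortNof1Summary(
        term=term,
        n_total=len(fits),
        n_significant=len(sig),
        n_positive=sum(est.B > 0 for est in sig),
        n_negative=sum(est.B < 0 for est in sig),
    )
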