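"""Monte-Carlo evaluation: parameter recovery, type-I error and power.

Every experiment regenerates full studies (schedule randomization,
cohort generation, missingness) from per-replicate seeds derived from a
master seed with ``numpy.random.SeedSequence(master, spawn_key=(stream,
rep))`` — a counter scheme that makes replicates independent and
individually re-runnable.  Fit failures are counted and reported, never
silently swallowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortConfig, simulate_study
from .design import DesignParams
from .mlm import LADDER_MODES, fit_mlm, ladder_specs, prepare_frame, run_ladder
from .nof1 import fit_nof1_model

logger = logging.getLogger(__name__)

__all__ = [
    "RecoveryReport",
    "replicate_seed",
    "recovery_experiment",
    "type1_error_experiment",
    "power_curve",
]


def replicate_seed(master_seed: int, rep: int, stream: int = 0) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stream, rep))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RecoveryReport:
    """Per-parameter recovery table plus bookkeeping."""

    table: pd.DataFrame
    n_reps: int
    n_failures: int
    master_seed: int
    mode: str
    estimates: pd.DataFrame = field(repr=False, default=None)

    def coverage(self, parameter: str) -> float:
        row = self.table.set_index("parameter").loc[parameter]
        return float(row["coverage"])


def _truth_map(config: CohortConfig, mode: str) -> dict[str, float]:
    """Generating values of every fixed effect estimable by model 6."""
    wd = config.weekday_effects
    truths = {
        "intercept": config.fixed_intercept,
        "time": config.time_slope,
        "wd_mon": wd[0], "wd_tue": wd[1], "wd_wed": wd[2],
        "wd_thu": wd[3], "wd_fri": wd[4], "wd_sat": wd[5],
        "barriers_within": config.within_barriers,
        "barriers_between": config.between_barriers,
        "pain_within": config.within_pain,
        "pain_between": config.between_pain,
    }
    if mode == "intervention":
        truths["dmi"] = config.effect_dmi
        truths["bf"] = config.effect_bf
    elif mode == "predictor:self_efficacy":
        truths["se_morning_within"] = (
            config.within_se if config.driver == "self_efficacy" else 0.0)
        truths["se_morning_between"] = (
            config.between_se if config.driver == "self_efficacy" else 0.0)
    else:
        truths["mot_morning_within"] = (
            config.within_mot if config.driver == "motivation" else 0.0)
        truths["mot_morning_between"] = (
            config.between_mot if config.driver == "motivation" else 0.0)
    return truths


def recovery_experiment(
    config: CohortConfig,
    n_reps: int,
    seed: int,
    mode: str = "predictor:self_efficacy",
    design: DesignParams | None = None,
    min_reps: int = 50,
) -> RecoveryReport:
    """Recover generating parameters from replicate synthetic studies.

    Each replicate simulates a full study and runs the chosen model
    ladder; the report tabulates, per fixed effect of the final model
    and per variance component, the truth, mean estimate, bias, RMSE and
    95% CI coverage (fixed effects only) with Monte-Carlo standard
    errors.
    """
    if n_reps < min_reps:
        raise ValueError(f"n_reps must be >= {min_reps}")
    if mode not in LADDER_MODES:
        raise ValueError(f"mode must be one of {LADDER_MODES}")
    truths = _truth_map(config, mode)
    records = []
    failures = 0
    for rep in range(n_reps):
        rep_seed = replicate_seed(seed, rep, stream=0)
        try:
            ds = simulate_study(config, rep_seed, design=design)
            ladder = run_ladder(ds, mode=mode)
        except Exception as exc:
            failures += 1
            logger.warning("replicate %d failed: %s", rep, exc)
            continue
        final = ladder.final
        rec = {"rep": rep, "seed": rep_seed}
        for term, fe in final.fixed.items():
            rec[term] = fe.B
            if term in truths:
                rec[f"{term}__covered"] = fe.ci_low <= truths[term] <= fe.ci_high
        rec["tau00"] = final.tau00
        rec["sigma2"] = final.sigma2
        rec["rho"] = final.rho
        records.append(rec)
    if not records:
        raise RuntimeError("all replicates failed")
    est = pd.DataFrame(records)

    var_truths = {"tau00": config.var_intercept, "sigma2": config.resid_var,
                  "rho": config.ar1_rho}
    rows = []
    for par, truth in {**truths, **var_truths}.items():
        if par not in est.columns:
            continue
        vals = est[par].to_numpy()
        bias = float(vals.mean() - truth)
        rmse = float(np.sqrt(np.mean((vals - truth) ** 2)))
        mc_se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        cov_col = f"{par}__covered"
        rows.append({
            "parameter": par,
            "truth": truth,
            "mean_estimate": float(vals.mean()),
            "bias": bias,
            "rmse": rmse,
            "mc_se": mc_se,
            "coverage": float(est[cov_col].mean()) if cov_col in est else np.nan,
        })
    return RecoveryReport(
        table=pd.DataFrame(rows), n_reps=n_reps, n_failures=failures,
        master_seed=seed, mode=mode, estimates=est,
    )


def fit_final_model(ds, mode: str):
    """Fit only the last ladder model (AR1, full fixed effects) on a dataset."""
    data = ds.data if hasattr(ds, "data") else ds
    frame, _, predictors = prepare_frame(data, mode)
    _, specs = ladder_specs(predictors)
    spec = specs[-1]
    cols = ["participant_id", "day_index", "steps"] + [
        c for c in spec.fixed_terms if c != "intercept"]
    return fit_mlm(frame[cols].dropna(), spec)


def _nof1_dmi_pvalues(ds, alpha: float) -> list[float]:
    pvals = []
    for pid, grp in ds.data.groupby("participant_id", sort=False):
        try:
            fit = fit_nof1_model(grp, mode="intervention")
        except ValueError:
            continue
        p = fit.p_value("dmi")
        if p is not None:
            pvals.append(p)
    return pvals


def type1_error_experiment(
    null_config: CohortConfig,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
    design: DesignParams | None = None,
    analyses: tuple[str, ...] = ("aggregated", "nof1"),
) -> pd.DataFrame:
    """Empirical false-positive rates for the dMI tests under the null.

    ``null_config`` must specify zero intervention effects.  For each
    replicate the aggregated analysis fits the final intervention model
    (model 6 of the ladder, AR1 residuals) and records the dMI p-value;
    the N-of-1 analysis records every participant's dynamic-regression
    dMI p-value.  Returns rejection proportions with binomial
    Monte-Carlo 95% intervals.
    """
    if null_config.effect_dmi != 0 or null_config.effect_bf != 0:
        raise ValueError("null_config must have zero intervention effects")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    agg_reject: list[bool] = []
    nof1_reject: list[bool] = []
    failures = 0
    for rep in range(n_reps):
        rep_seed = replicate_seed(seed, rep, stream=1)
        try:
            ds = simulate_study(null_config, rep_seed, design=design)
            if "aggregated" in analyses:
                final = fit_final_model(ds, "intervention")
                agg_reject.append(final.fixed["dmi"].P < alpha)
            if "nof1" in analyses:
                nof1_reject.extend(
                    p < alpha for p in _nof1_dmi_pvalues(ds, alpha))
        except Exception as exc:
            failures += 1
            logger.warning("replicate %d failed: %s", rep, exc)
    rows = []
    for name, rejects in (("aggregated_dmi", agg_reject), ("nof1_dmi", nof1_reject)):
        if not rejects:
            continue
        n = len(rejects)
        rate = float(np.mean(rejects))
        half = 1.96 * np.sqrt(max(rate * (1 - rate), 1e-12) / n)
        rows.append({"analysis": name, "n_tests": n, "rejection_rate": rate,
                     "ci_low": rate - half, "ci_high": rate + half,
                     "alpha": alpha, "n_failures": failures})
    return pd.DataFrame(rows)


def power_curve(
    grid: list[dict],
    n_reps: int,
    seed: int = 0,
    alpha: float = 0.05,
    base_config: CohortConfig | None = None,
    analyses: tuple[str, ...] = ("aggregated", "nof1"),
) -> pd.DataFrame:
    """Power of the dMI tests over a grid of design/effect configurations.

    Each grid point is a dict of CohortConfig overrides (e.g.
    ``effect_dmi``, ``n_participants``) optionally plus ``n_periods`` to
    lengthen/shorten the schedule.  Returns one row per grid point with
    empirical power for the aggregated and the within-person tests.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    from .cohort import default_config

    base = base_config or default_config()
    rows = []
    for g, point in enumerate(grid):
        point = dict(point)
        n_periods = point.pop("n_periods", None)
        design = DesignParams(n_periods=n_periods) if n_periods else None
        cfg = base.replace(**point)
        agg: list[bool] = []
        nof1: list[bool] = []
        failures = 0
        for rep in range(n_reps):
            rep_seed = replicate_seed(seed, rep, stream=10 + g)
            try:
                ds = simulate_study(cfg, rep_seed, design=design)
                if "aggregated" in analyses:
                    final = fit_final_model(ds, "intervention")
                    agg.append(final.fixed["dmi"].P < alpha)
                if "nof1" in analyses:
                    nof1.extend(p < alpha for p in _nof1_dmi_pvalues(ds, alpha))
            except Exception as exc:
                failures += 1
                logger.warning("grid %d replicate %d failed: %s", g, rep, exc)
        row = {**point, "n_periods": n_periods, "n_reps": n_reps,
               "n_failures": failures}
        if agg:
            row["power_aggregated_dmi"] = float(np.mean(agg))
        if nof1:
            row["power_nof1_dmi"] = float(np.mean(nof1))
        rows.append(row)
    return pd.DataFrame(rows)
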