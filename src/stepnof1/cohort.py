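"""Synthetic person-day cohorts for the factorial N-of-1 step trial.

Generates long-format person-day data with the statistical structure the
analyses assume: daily step counts with a large stable between-person
component (ICC ≈ 0.57), a random linear time trend, weekday periodicity,
AR(1) serially correlated residuals, intervention-availability effects,
and morning ecological momentary assessment (EMA) items — self-efficacy
and motivation on 1–9 visual-analog scales correlated at r ≈ 0.6,
perceived barriers on 1–9, and a 0–2 ordinal pain/illness scale — that
act on steps through separate within-person and between-person channels.

The default configuration is calibrated to the published quantities of
the 15-participant, 40-day pilot trial this package models: grand mean
11,137 steps, ICC 0.571, within-person self-efficacy effect 462
steps/point (motivation variant: 390), within-person pain effect −1524
steps/point, AR(1) ρ = 0.15, self-efficacy–motivation correlation 0.597,
no intervention effects, and step missingness resembling one participant
with no step data plus one with roughly half missing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CANONICAL_DESIGN, DesignParams, TrialSchedule, randomize_schedule

__all__ = [
    "CohortConfig",
    "LongDataset",
    "default_config",
    "simulate_ar1",
    "generate_cohort",
    "apply_missingness",
    "summarize_adherence",
    "simulate_study",
]

#: Theoretical mean of a 1..9 EMA item discretized into equal-probability bins.
EMA_GRAND_MEAN = 5.0

#: Squared correlation between a standard-normal latent and its 9-bin
#: equal-probability discretization; dividing the target correlation by this
#: factor makes the *observed* (discretized) scales correlate as configured.
_DISCRETIZATION_ATTENUATION = 0.9312

#: Column order of the long person-day table (the interchange schema).
DATA_COLUMNS = [
    "participant_id", "day_index", "weekday", "period_index", "condition",
    "dmi_available", "bf_suggested", "washout", "control", "leadout",
    "dmi_used", "bf_used", "steps",
    "se_morning", "mot_morning", "mot_evening", "barriers", "pain",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic cohort.

    Step-scale parameters are in steps (or steps per covariate point);
    variance components in steps²; ``ar1_rho`` is the lag-1 residual
    autocorrelation.  ``weekday_effects`` holds Monday..Sunday offsets
    with the reference day (Sunday) fixed at 0.  ``driver`` selects which
    EMA channel causally moves steps — ``"self_efficacy"`` or
    ``"motivation"`` — while the other item is generated merely
    correlated at ``se_mot_correlation`` (two collinear causal channels
    would not be separately identifiable, and the analyses model them
    separately for the same reason).
    """

    n_participants: int = 15
    fixed_intercept: float = 11137.0
    time_slope: float = -23.0
    weekday_effects: tuple[float, ...] = (2303.0, 0.0, 1609.0, 0.0, 0.0, 0.0, 0.0)
    effect_dmi: float = 0.0
    effect_bf: float = 0.0
    within_se: float = 462.0
    between_se: float = 263.0
    within_mot: float = 390.0
    between_mot: float = 1756.0
    within_barriers: float = -48.0
    between_barriers: float = 926.0
    within_pain: float = -1524.0
    between_pain: float = -4059.0
    var_intercept: float = 7_994_000.0
    var_slope: float = 1158.0
    cov_int_slope: float = 703.0
    resid_var: float = 6_006_000.0
    ar1_rho: float = 0.15
    se_mot_correlation: float = 0.597
    ema_person_share: float = 0.32
    pain_person_share: float = 0.45
    pain_probs: tuple[float, float, float] = (0.85, 0.11, 0.04)
    p_day_missing_steps: float = 30.0 / 560.0
    p_participant_total_dropout: float = 1.0 / 15.0
    p_ema_missing: float = 0.10
    p_dmi_use: float = 0.73
    p_bf_on_time: float = 0.75
    p_bf_one_day_late: float = 0.06
    p_bf_never: float = 0.19
    driver: str = "self_efficacy"

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        for name in ("var_intercept", "var_slope", "resid_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if not abs(self.se_mot_correlation) <= 1:
            raise ValueError("|se_mot_correlation| must be <= 1")
        if self.cov_int_slope**2 > self.var_intercept * self.var_slope + 1e-9:
            raise ValueError("random-effect covariance matrix is not PSD")
        if not 0 <= self.ema_person_share <= 1:
            raise ValueError("ema_person_share must be in [0, 1]")
        if not 0 <= self.pain_person_share <= 1:
            raise ValueError("pain_person_share must be in [0, 1]")
        if len(self.weekday_effects) != 7:
            raise ValueError("weekday_effects needs 7 values (Mon..Sun)")
        if len(self.pain_probs) != 3 or abs(sum(self.pain_probs) - 1) > 1e-9 or min(
            self.pain_probs
        ) < 0:
            raise ValueError("pain_probs must be 3 probabilities summing to 1")
        for name in (
            "p_day_missing_steps", "p_participant_total_dropout", "p_ema_missing",
            "p_dmi_use", "p_bf_on_time", "p_bf_one_day_late", "p_bf_never",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_bf_on_time + self.p_bf_one_day_late + self.p_bf_never > 1 + 1e-9:
            raise ValueError("biofeedback engagement probabilities exceed 1")
        if self.driver not in ("self_efficacy", "motivation", "none"):
            raise ValueError(f"unknown driver {self.driver!r}")

    @property
    def icc(self) -> float:
        """Intraclass correlation implied by the variance components."""
        return self.var_intercept / (self.var_intercept + self.resid_var)

    @property
    def random_effects_cov(self) -> np.ndarray:
        return np.array(
            [[self.var_intercept, self.cov_int_slope],
             [self.cov_int_slope, self.var_slope]]
        )

    def replace(self, **changes) -> "CohortConfig":
        cfg = dataclasses.replace(self, **changes)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=repr)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_config(driver: str = "self_efficacy") -> CohortConfig:
    """The calibrated default cohort configuration.

    ``driver`` chooses the causally active EMA channel: the default
    self-efficacy variant moves steps by 462 per within-person point; the
    motivation variant by 390.
    """
    cfg = CohortConfig(driver=driver)
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class LongDataset:
    """A long-format person-day table with provenance metadata."""

    data: pd.DataFrame
    seed: int
    config_hash: str

    def validate(self) -> None:
        df = self.data
        missing = [c for c in DATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if df.duplicated(["participant_id", "day_index"]).any():
            raise ValueError("duplicate (participant_id, day_index) rows")
        for pid, grp in df.groupby("participant_id", sort=False):
            days = grp["day_index"].to_numpy()
            if not np.array_equal(days, np.arange(1, len(days) + 1)):
                raise ValueError(f"participant {pid}: day indices not contiguous from 1")
        steps = df["steps"].dropna()
        if (steps < 0).any():
            raise ValueError("negative step counts present")

    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.data["participant_id"]))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_ar1(n: int, rho: float, sigma2: float, seed) -> np.ndarray:
    """Stationary AR(1) series with marginal variance ``sigma2``.

    The series starts from the stationary distribution N(0, sigma2) and
    evolves as x_t = rho·x_{t-1} + e_t with e_t ~ N(0, sigma2·(1−rho²)),
    so every margin has variance ``sigma2`` and lag-1 correlation ``rho``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1 for stationarity")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = _as_rng(seed)
    if sigma2 == 0:
        return np.zeros(n)
    x = np.empty(n)
    innovations = rng.standard_normal(n)
    x[0] = np.sqrt(sigma2) * innovations[0]
    scale = np.sqrt(sigma2 * (1 - rho**2))
    for t in range(1, n):
        x[t] = rho * x[t - 1] + scale * innovations[t]
    return x


def _discretize_ema(z: np.ndarray) -> np.ndarray:
    """Map standard-normal latents to 1..9 via equal-probability bins."""
    cuts = stats.norm.ppf(np.arange(1, 9) / 9.0)
    return (np.searchsorted(cuts, z) + 1).astype(float)


def _correlated_pair(rng: np.random.Generator, n: int, r: float,
                     person_share: float) -> tuple[np.ndarray, np.ndarray]:
    """Two length-n standard-normal latents with correlation ``r``.

    Each latent splits into a person-constant component (variance
    ``person_share``) and a daily component; both components share the
    correlation, so day-to-day values within a person are themselves
    correlated across the pair as in repeated EMA data.
    """
    corr = np.array([[1.0, r], [r, 1.0]])
    chol = np.linalg.cholesky(corr)
    a = chol @ rng.standard_normal(2) * np.sqrt(person_share)
    e = (chol @ rng.standard_normal((2, n))) * np.sqrt(1 - person_share)
    return a[0] + e[0], a[1] + e[1]


def _person_latent(rng: np.random.Generator, n: int, person_share: float) -> np.ndarray:
    a = rng.standard_normal() * np.sqrt(person_share)
    return a + rng.standard_normal(n) * np.sqrt(1 - person_share)


def _engagement(rng: np.random.Generator, schedule: TrialSchedule,
                cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-window use of the two components.

    dMI: each availability window is used (a single touch on a uniformly
    chosen window day) with probability ``p_dmi_use``.  Biofeedback: each
    suggested window ends with an on-time upload (last window day), a
    one-day-late upload (the following day, typically the wash-out day),
    or no upload.
    """
    n = len(schedule.days)
    dmi_used = np.zeros(n, dtype=bool)
    bf_used = np.zeros(n, dtype=bool)

    def windows(flag: str) -> list[list[int]]:
        runs, current = [], []
        for i, d in enumerate(schedule.days):
            if getattr(d, flag):
                current.append(i)
            elif current:
                runs.append(current)
                current = []
        if current:
            runs.append(current)
        return runs

    for win in windows("dmi_available"):
        if rng.random() < cfg.p_dmi_use:
            dmi_used[win[rng.integers(len(win))]] = True
    p_norm = cfg.p_bf_on_time + cfg.p_bf_one_day_late + cfg.p_bf_never
    probs = (
        np.array([cfg.p_bf_on_time, cfg.p_bf_one_day_late, cfg.p_bf_never]) / p_norm
        if p_norm > 0 else np.array([1.0, 0.0, 0.0])
    )
    for win in windows("bf_suggested"):
        outcome = rng.choice(3, p=probs)
        if outcome == 0:
            bf_used[win[-1]] = True
        elif outcome == 1 and win[-1] + 1 < n:
            bf_used[win[-1] + 1] = True
    return dmi_used, bf_used


def generate_cohort(
    config: CohortConfig,
    schedules: list[TrialSchedule],
    seed: int,
) -> LongDataset:
    """Generate a complete (no missingness) person-day cohort.

    For each participant, random intercept/slope deviations are drawn
    from the configured bivariate normal, EMA items from correlated
    latent-normal processes discretized onto their scales, and daily
    steps from the linear within/between-person model plus a stationary
    AR(1) residual; steps are floored at 0 and rounded to integers.
    """
    config.validate()
    if len(schedules) < config.n_participants:
        raise ValueError(
            f"need {config.n_participants} schedules, got {len(schedules)}"
        )
    master = np.random.SeedSequence(seed)
    pain_cuts = stats.norm.ppf(np.cumsum(config.pain_probs)[:2])

    # first pass: covariate series and random effects per participant
    draws = []
    for p in range(config.n_participants):
        schedule = schedules[p]
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(p,)))
        n = len(schedule.days)
        G = config.random_effects_cov
        u0, u1 = rng.multivariate_normal([0.0, 0.0], G, method="svd")
        r_latent = min(config.se_mot_correlation / _DISCRETIZATION_ATTENUATION,
                       0.999)
        z_se, z_mot = _correlated_pair(
            rng, n, r_latent, config.ema_person_share)
        se = _discretize_ema(z_se)
        mot = _discretize_ema(z_mot)
        # evening motivation shares the morning latent but adds fresh noise
        z_eve = 0.7 * z_mot + np.sqrt(1 - 0.7**2) * rng.standard_normal(n)
        mot_eve = _discretize_ema(z_eve)
        barriers = _discretize_ema(_person_latent(rng, n, config.ema_person_share))
        pain = np.searchsorted(
            pain_cuts, _person_latent(rng, n, config.pain_person_share)
        ).astype(float)
        resid = simulate_ar1(n, config.ar1_rho, config.resid_var, rng)
        dmi_used, bf_used = _engagement(rng, schedule, config)
        draws.append(dict(schedule=schedule, u0=u0, u1=u1, se=se, mot=mot,
                          mot_eve=mot_eve, barriers=barriers, pain=pain,
                          resid=resid, dmi_used=dmi_used, bf_used=bf_used))

    # between-person channels are centered at the cohort mean of person
    # means — the same reference the analysis models use — so the fixed
    # intercept retains its configured meaning in every generated cohort
    grand = {
        key: float(np.mean([d[key].mean() for d in draws]))
        for key in ("se", "mot", "barriers", "pain")
    }

    rows = []
    for d0 in draws:
        schedule = d0["schedule"]
        n = len(schedule.days)
        t = np.arange(1, n + 1, dtype=float)
        se, mot, barriers, pain = d0["se"], d0["mot"], d0["barriers"], d0["pain"]

        dmi = np.array([d.dmi_available for d in schedule.days], dtype=float)
        bf = np.array([d.bf_suggested for d in schedule.days], dtype=float)
        wd = np.array([d.weekday for d in schedule.days])
        wd_effect = np.asarray(config.weekday_effects)[wd - 1]

        def wb(values: np.ndarray, b_within: float, b_between: float,
               grand_mean: float) -> np.ndarray:
            pmean = values.mean()
            return b_within * (values - pmean) + b_between * (pmean - grand_mean)

        raw = (
            config.fixed_intercept + d0["u0"]
            + (config.time_slope + d0["u1"]) * t
            + wd_effect
            + config.effect_dmi * dmi
            + config.effect_bf * bf
            + wb(barriers, config.within_barriers, config.between_barriers,
                 grand["barriers"])
            + wb(pain, config.within_pain, config.between_pain, grand["pain"])
            + d0["resid"]
        )
        if config.driver == "self_efficacy":
            raw = raw + wb(se, config.within_se, config.between_se, grand["se"])
        elif config.driver == "motivation":
            raw = raw + wb(mot, config.within_mot, config.between_mot,
                           grand["mot"])

        steps = np.maximum(0, np.round(raw))
        mot_eve = d0["mot_eve"]
        dmi_used, bf_used = d0["dmi_used"], d0["bf_used"]

        for i, d in enumerate(schedule.days):
            rows.append({
                "participant_id": schedule.participant_id,
                "day_index": d.day_index,
                "weekday": d.weekday,
                "period_index": d.period_index,
                "condition": d.condition.value if d.condition else "",
                "dmi_available": int(d.dmi_available),
                "bf_suggested": int(d.bf_suggested),
                "washout": int(d.washout),
                "control": int(d.control),
                "leadout": int(d.leadout),
                "dmi_used": int(dmi_used[i]),
                "bf_used": int(bf_used[i]),
                "steps": steps[i],
                "se_morning": se[i],
                "mot_morning": mot[i],
                "mot_evening": mot_eve[i],
                "barriers": barriers[i],
                "pain": pain[i],
            })
    df = pd.DataFrame(rows, columns=DATA_COLUMNS)
    ds = LongDataset(data=df, seed=int(seed), config_hash=config.hash())
    ds.validate()
    return ds


def apply_missingness(dataset: LongDataset, config: CohortConfig, seed: int) -> LongDataset:
    """Mask values missing-completely-at-random per the configured rates.

    A participant loses *all* step data with probability
    ``p_participant_total_dropout``; remaining person-days lose steps
    independently with ``p_day_missing_steps``.  EMA missingness acts at
    the questionnaire level with probability ``p_ema_missing`` per
    questionnaire per day: a skipped morning questionnaire blanks
    self-efficacy, morning motivation and barriers together, a skipped
    evening one blanks evening motivation and pain — repeated-measure
    apps lose whole prompts, not single items.
    """
    config.validate()
    df = dataset.data.copy()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(101,)))
    blocks = (("se_morning", "mot_morning", "barriers"), ("mot_evening", "pain"))
    for pid in dataset.participants():
        mask = df["participant_id"] == pid
        if rng.random() < config.p_participant_total_dropout:
            df.loc[mask, "steps"] = np.nan
        else:
            day_drop = rng.random(mask.sum()) < config.p_day_missing_steps
            idx = df.index[mask][day_drop]
            df.loc[idx, "steps"] = np.nan
        for cols in blocks:
            ema_drop = rng.random(mask.sum()) < config.p_ema_missing
            df.loc[df.index[mask][ema_drop], list(cols)] = np.nan
    return LongDataset(data=df, seed=dataset.seed, config_hash=dataset.config_hash)


def summarize_adherence(dataset: LongDataset) -> pd.DataFrame:
    """Per-participant engagement and completion table.

    Mirrors the trial's participant characteristics table: intervention
    windows used, morning/evening EMA completion counts and percentages,
    and mean (SD) daily steps over non-missing days.
    """
    recs = []
    df = dataset.data
    for pid, g in df.groupby("participant_id", sort=False):
        n_days = len(g)
        dmi_windows = _count_windows(g["dmi_available"].to_numpy(dtype=bool))
        bf_windows = _count_windows(g["bf_suggested"].to_numpy(dtype=bool))
        steps = g["steps"].dropna()
        recs.append({
            "participant_id": pid,
            "dmi_windows": dmi_windows,
            "dmi_used": int(g["dmi_used"].sum()),
            "bf_windows": bf_windows,
            "bf_used": int(g["bf_used"].sum()),
            "morning_mot_n": int(g["mot_morning"].notna().sum()),
            "morning_se_n": int(g["se_morning"].notna().sum()),
            "morning_barriers_n": int(g["barriers"].notna().sum()),
            "evening_mot_n": int(g["mot_evening"].notna().sum()),
            "evening_pain_n": int(g["pain"].notna().sum()),
            "morning_mot_pct": _round_half_up(100 * g["mot_morning"].notna().mean()),
            "steps_days": int(steps.size),
            "steps_pct": _round_half_up(100 * steps.size / n_days),
            "steps_mean": float(steps.mean()) if steps.size else np.nan,
            "steps_sd": float(steps.std(ddof=1)) if steps.size > 1 else np.nan,
        })
    return pd.DataFrame(recs)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _count_windows(flags: np.ndarray) -> int:
    if flags.size == 0:
        return 0
    starts = flags & ~np.concatenate([[False], flags[:-1]])
    return int(starts.sum())


def simulate_study(
    config: CohortConfig,
    seed: int,
    design: DesignParams | None = None,
    missingness: bool = True,
) -> LongDataset:
    """Full pipeline: randomize schedules, generate the cohort, mask values.

    All randomness derives from ``seed`` via independent substreams, so
    identical (config, seed, design) calls return identical datasets.
    """
    design = design or CANONICAL_DESIGN
    master = np.random.SeedSequence(seed)
    schedules = []
    for p in range(config.n_participants):
        sched_seed = int(np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(1, p)).generate_state(1)[0] % 2**31)
        schedules.append(
            randomize_schedule(f"P{p + 1:02d}", sched_seed, design=design))
    gen_seed = int(np.random.SeedSequence(
        entropy=master.entropy, spawn_key=(2,)).generate_state(1)[0] % 2**31)
    ds = generate_cohort(config, schedules, gen_seed)
    if missingness:
        miss_seed = int(np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(3,)).generate_state(1)[0] % 2**31)
        ds = apply_missingness(ds, config, miss_seed)
    ds = LongDataset(data=ds.data, seed=int(seed), config_hash=config.hash())
    return ds
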