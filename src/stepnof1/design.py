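"""Randomized 40-day factorial N-of-1 schedules.

The canonical design crosses two app-delivered intervention components —
digitalized motivational interviewing (dMI) and heart-rate-variability
biofeedback (BF) — in a 2x2 factorial within each participant: twelve
3-day active periods, each randomized to one of four conditions (both
components, dMI alone, BF alone, or control).  Within an active period
the condition is available on days 1-2; day 3 is a wash-out day when the
period delivered any intervention, and a third control day otherwise.
One extra control day follows the fourth and eighth periods, and the
trial ends with a 2-day lead-out during which both components are
available.  That layout gives 40 days per participant with 7 dMI
windows, 7 biofeedback windows, 11 control days and 9 wash-out days.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Condition",
    "DesignParams",
    "DayAssignment",
    "TrialSchedule",
    "ScheduleSummary",
    "randomize_schedule",
    "summarize_schedule",
]


class Condition(str, enum.Enum):
    """The four factorial conditions a 3-day active period can carry."""

    BOTH = "BOTH"
    DMI_ONLY = "DMI_ONLY"
    BIOFEEDBACK_ONLY = "BIOFEEDBACK_ONLY"
    CONTROL = "CONTROL"

    @property
    def has_dmi(self) -> bool:
        return self in (Condition.BOTH, Condition.DMI_ONLY)

    @property
    def has_bf(self) -> bool:
        return self in (Condition.BOTH, Condition.BIOFEEDBACK_ONLY)

    @property
    def is_intervention(self) -> bool:
        return self is not Condition.CONTROL


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the schedule layout.

    Defaults reproduce the canonical 40-day design.  ``n_periods`` must be
    a multiple of the number of conditions (4) so that block randomization
    assigns every condition equally often.  ``extra_control_after`` lists
    the 1-based period indices after which a single extra control day is
    inserted.  ``start_weekday`` is the weekday of day 1 (1=Monday ..
    7=Sunday); the design itself is weekday-agnostic.
    """

    n_periods: int = 12
    period_length: int = 3
    extra_control_after: tuple[int, ...] = (4, 8)
    leadout_days: int = 2
    start_weekday: int = 1

    @property
    def n_conditions(self) -> int:
        return len(Condition)

    @property
    def n_blocks(self) -> int:
        return self.n_periods // self.n_conditions

    @property
    def n_days(self) -> int:
        return (
            self.n_periods * self.period_length
            + len(self.extra_control_after)
            + self.leadout_days
        )

    def validate(self) -> None:
        if self.n_periods % self.n_conditions != 0:
            raise ValueError(
                f"n_periods ({self.n_periods}) must be a multiple of the "
                f"{self.n_conditions} conditions"
            )
        if self.period_length < 2:
            raise ValueError("period_length must be at least 2")
        if not 1 <= self.start_weekday <= 7:
            raise ValueError("start_weekday must be in 1..7")
        if any(not 1 <= p <= self.n_periods for p in self.extra_control_after):
            raise ValueError("extra_control_after indices must be valid periods")


#: The canonical design used throughout the package.
CANONICAL_DESIGN = DesignParams()


@dataclass(frozen=True)
class DayAssignment:
    """Flags for a single study day.

    ``period_index`` is 1..n_periods for days inside an active period and
    0 for extra control and lead-out days.  Exactly one of four roles
    characterizes a day: an intervention-window day (``dmi_available`` or
    ``bf_suggested`` without ``leadout``), a wash-out day, a control day,
    or a lead-out day (with both components available).
    """

    day_index: int
    period_index: int
    condition: Condition | None
    dmi_available: bool
    bf_suggested: bool
    washout: bool
    control: bool
    leadout: bool
    weekday: int

    def validate(self) -> None:
        roles = [
            (self.dmi_available or self.bf_suggested) and not self.leadout,
            self.washout,
            self.control,
            self.leadout,
        ]
        if sum(roles) != 1:
            raise ValueError(f"day {self.day_index}: ambiguous role flags {self}")
        if self.washout and (self.dmi_available or self.bf_suggested):
            raise ValueError(f"day {self.day_index}: wash-out day offers interventions")
        if self.leadout and not (self.dmi_available and self.bf_suggested):
            raise ValueError(f"day {self.day_index}: lead-out must offer both components")
        if not 1 <= self.weekday <= 7:
            raise ValueError(f"day {self.day_index}: weekday {self.weekday} out of range")


@dataclass(frozen=True)
class TrialSchedule:
    """One participant's full schedule of day assignments."""

    participant_id: str
    days: tuple[DayAssignment, ...]
    seed: int
    design: DesignParams = field(default=CANONICAL_DESIGN)

    def validate(self) -> None:
        if len(self.days) != self.design.n_days:
            raise ValueError(
                f"schedule has {len(self.days)} days, expected {self.design.n_days}"
            )
        for i, day in enumerate(self.days, start=1):
            if day.day_index != i:
                raise ValueError(f"day indices not contiguous at position {i}")
            day.validate()
        # 1..n_periods must each appear period_length times, consecutively
        periods = [d.period_index for d in self.days if d.period_index > 0]
        for p in range(1, self.design.n_periods + 1):
            if periods.count(p) != self.design.period_length:
                raise ValueError(f"period {p} does not span {self.design.period_length} days")
        for d in self.days[-self.design.leadout_days :]:
            if not d.leadout:
                raise ValueError("final days must be lead-out days")

    def condition_of_period(self, period: int) -> Condition:
        for d in self.days:
            if d.period_index == period:
                assert d.condition is not None
                return d.condition
        raise KeyError(period)


@dataclass(frozen=True)
class ScheduleSummary:
    """Day/window counts derived from a schedule's flags."""

    n_days: int
    n_periods: int
    periods_per_condition: dict[Condition, int]
    intervention_days: int
    dmi_windows: int
    bf_windows: int
    control_days: int
    washout_days: int
    leadout_days: int

    def component_day_total(self) -> int:
        return (
            self.intervention_days
            + self.control_days
            + self.washout_days
            + self.leadout_days
        )


def randomize_schedule(
    participant_id: str,
    seed: int,
    design: DesignParams | None = None,
) -> TrialSchedule:
    """Block-randomize the four conditions to active periods for one participant.

    Randomization is repeated block randomization: the period sequence is
    split into ``n_blocks`` consecutive blocks of four periods, and each
    block receives an independent uniform permutation of the four
    conditions, guaranteeing every condition occupies exactly
    ``n_blocks`` periods.

    Parameters
    ----------
    participant_id:
        Identifier stored on the schedule.
    seed:
        Integer seed; the same (participant_id, seed) pair always yields
        an identical schedule.
    design:
        Layout parameters; defaults to the canonical 40-day design.
    """
    if isinstance(seed, bool) or not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    design = design or CANONICAL_DESIGN
    design.validate()

    rng = np.random.default_rng(int(seed))
    conditions = list(Condition)
    period_conditions: list[Condition] = []
    for _ in range(design.n_blocks):
        perm = rng.permutation(len(conditions))
        period_conditions.extend(conditions[i] for i in perm)

    days: list[DayAssignment] = []

    def weekday(day_index: int) -> int:
        return (design.start_weekday - 1 + day_index - 1) % 7 + 1

    day_index = 0

    def add(period_index: int, condition: Condition | None, *, dmi: bool, bf: bool,
            washout: bool = False, control: bool = False, leadout: bool = False) -> None:
        nonlocal day_index
        day_index += 1
        days.append(
            DayAssignment(
                day_index=day_index,
                period_index=period_index,
                condition=condition,
                dmi_available=dmi,
                bf_suggested=bf,
                washout=washout,
                control=control,
                leadout=leadout,
                weekday=weekday(day_index),
            )
        )

    for p, cond in enumerate(period_conditions, start=1):
        for _ in range(design.period_length - 1):
            add(p, cond, dmi=cond.has_dmi, bf=cond.has_bf,
                control=not cond.is_intervention)
        # third period day: wash-out after an intervention, control otherwise
        add(p, cond, dmi=False, bf=False,
            washout=cond.is_intervention, control=not cond.is_intervention)
        if p in design.extra_control_after:
            add(0, None, dmi=False, bf=False, control=True)

    for _ in range(design.leadout_days):
        add(0, None, dmi=True, bf=True, leadout=True)

    schedule = TrialSchedule(
        participant_id=participant_id,
        days=tuple(days),
        seed=int(seed),
        design=design,
    )
    schedule.validate()
    return schedule


def _count_runs(flags: list[bool]) -> int:
    """Number of maximal runs of consecutive True values."""
    runs = 0
    prev = False
    for f in flags:
        if f and not prev:
            runs += 1
        prev = f
    return runs


def summarize_schedule(schedule: TrialSchedule) -> ScheduleSummary:
    """Count days and availability windows from a schedule's flags.

    A "window" is a maximal run of consecutive days on which a component
    is available; in the canonical design each intervention period
    contributes one 2-day window and the lead-out contributes one extra
    window for each component (hence 3+3+1 = 7 per component).
    """
    schedule.validate()
    days = schedule.days
    per_condition: dict[Condition, int] = {c: 0 for c in Condition}
    for p in range(1, schedule.design.n_periods + 1):
        per_condition[schedule.condition_of_period(p)] += 1
    return ScheduleSummary(
        n_days=len(days),
        n_periods=schedule.design.n_periods,
        periods_per_condition=per_condition,
        intervention_days=sum(
            (d.dmi_available or d.bf_suggested) and not d.leadout for d in days
        ),
        dmi_windows=_count_runs([d.dmi_available for d in days]),
        bf_windows=_count_runs([d.bf_suggested for d in days]),
        control_days=sum(d.control for d in days),
        washout_days=sum(d.washout for d in days),
        leadout_days=sum(d.leadout for d in days),
    )
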