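"""Daily behavioral summaries, goal evaluation, rewards and fidelity.

Turns classified epoch data into the quantities a trial monitor or the
participant-facing app would report: per-day totals of inactive and
break time over office hours, whether the personalized break goal was
met, reward assignment against a two-week baseline, and the
trial-monitoring fidelity/adherence report (percentage of valid
tracking time, percentage of prompts delivered, and days of use per
app function).

Goal semantics follow the break recommendations the goals encode
("a 2–3 min light-activity break every 30 min of sitting", or
"a 5-min break every 60 min"): a day meets its goal when no effective
sitting spell exceeds the goal interval, where only breaks at least as
long as the goal duration reset the sitting clock.  Shorter breaks
still count in ``break_count`` but do not reset the clock.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from datetime import date as date_type, datetime, time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .epoch_io import EpochSeries, ValidationError, parse_local_time
from .classifier import ActivityState, BreakEvent
from .prompts import PromptEvent, prompts_delivered_fraction

__all__ = [
    "GoalSpec",
    "DailySummary",
    "RewardKind",
    "Reward",
    "BaselineStats",
    "FidelityReport",
    "summarize_day",
    "evaluate_goal",
    "award_rewards",
    "compute_fidelity",
    "plot_timeline",
]

DEFAULT_OFFICE_HOURS: tuple[time, time] = (time(9, 0), time(17, 0))

#: Named goal presets drawn from published break recommendations.
GOAL_PRESETS = {
    "EVERY_30": (30.0, 2.0),   # 2–3 min break every 30 min; floor of the band
    "EVERY_60": (60.0, 5.0),   # 5 min break every 60 min
}


@dataclass(frozen=True)
class GoalSpec:
    """A personalized break goal: maximum sitting interval, minimum break."""

    break_interval_min: float = 30.0
    break_duration_min: float = 2.0
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.break_interval_min <= 0 or self.break_duration_min <= 0:
            raise ValidationError("goal interval and duration must be positive")
        if self.preset is not None:
            if self.preset not in GOAL_PRESETS:
                raise ValidationError(
                    f"unknown preset {self.preset!r}; valid: {sorted(GOAL_PRESETS)}"
                )
            interval, _ = GOAL_PRESETS[self.preset]
            if self.break_interval_min != interval:
                raise ValidationError(
                    f"preset {self.preset} requires interval {interval} min"
                )
            if self.preset == "EVERY_30" and not (2 <= self.break_duration_min <= 3):
                raise ValidationError(
                    "preset EVERY_30 requires a 2–3 min break duration"
                )
            if self.preset == "EVERY_60" and self.break_duration_min != 5:
                raise ValidationError(
                    "preset EVERY_60 requires a 5 min break duration"
                )

    @classmethod
    def from_preset(cls, preset: str) -> "GoalSpec":
        interval, duration = GOAL_PRESETS[preset]
        return cls(interval, duration, preset)

    @classmethod
    def from_config(cls, config: dict) -> "GoalSpec":
        if config.get("goal_preset"):
            return cls.from_preset(config["goal_preset"])
        return cls(config["goal_interval_min"], config["goal_duration_min"])


@dataclass
class DailySummary:
    """Office-hour behavioral totals for one calendar day."""

    date: date_type
    valid_epochs: int
    inactive_epochs: int
    break_epochs: int
    break_count: int
    longest_inactive_bout_epochs: int
    goal_met: bool | None

    def __post_init__(self) -> None:
        if self.valid_epochs != self.inactive_epochs + self.break_epochs:
            raise ValidationError(
                "valid_epochs must equal inactive_epochs + break_epochs"
            )
        if self.longest_inactive_bout_epochs > self.inactive_epochs:
            raise ValidationError(
                "longest inactive bout cannot exceed total inactive epochs"
            )


class RewardKind:
    GOAL_BADGE = "GOAL_BADGE"
    IMPROVEMENT_TROPHY = "IMPROVEMENT_TROPHY"


@dataclass(frozen=True)
class Reward:
    date: date_type
    kind: str
    detail: str


@dataclass(frozen=True)
class BaselineStats:
    """Medians over the baseline window used by the improvement rule."""

    median_longest_bout_epochs: float
    median_break_count: float

    @classmethod
    def from_summaries(cls, summaries: Sequence[DailySummary]) -> "BaselineStats":
        if not summaries:
            raise ValidationError("baseline requires at least one summary")
        return cls(
            median_longest_bout_epochs=statistics.median(
                s.longest_inactive_bout_epochs for s in summaries
            ),
            median_break_count=statistics.median(
                s.break_count for s in summaries
            ),
        )


@dataclass
class FidelityReport:
    """Trial-monitoring aggregates over all observed days."""

    pct_valid_tracking: float
    pct_prompts_delivered: float
    adherence_days: dict[str, int]
    n_days: int

    def __post_init__(self) -> None:
        for name in ("pct_valid_tracking", "pct_prompts_delivered"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} must lie in [0, 100], got {v}")
        for label, days in self.adherence_days.items():
            if days > self.n_days:
                raise ValidationError(
                    f"adherence_days[{label!r}]={days} exceeds observed "
                    f"days {self.n_days}"
                )


def _office_mask(
    series: EpochSeries, date: date_type, office_hours: tuple[time, time]
) -> np.ndarray:
    start, end = (parse_local_time(office_hours[0]),
                  parse_local_time(office_hours[1]))
    ts = series.timestamps
    on_date = np.asarray(ts.date) == date
    t = np.array([x.time() for x in ts])
    in_hours = np.array([start <= x < end for x in t]) if len(t) else np.array([], bool)
    return on_date & in_hours


def summarize_day(
    series: EpochSeries,
    states: Sequence[ActivityState],
    events: Sequence[BreakEvent],
    date: date_type,
    office_hours: tuple[time, time] = DEFAULT_OFFICE_HOURS,
    goal: GoalSpec | None = None,
) -> DailySummary:
    """Compute the office-hour behavioral summary for one day.

    Totals cover valid (non-nonwear) epochs inside office hours only.
    The longest inactive bout is the longest uninterrupted run of
    inactive epochs; nonwear splits a run (the data cannot attest the
    wearer stayed seated through it).  With no valid epochs, or no
    goal, ``goal_met`` is ``None``.
    """
    if len(states) != len(series):
        raise ValidationError("states length must match series length")
    mask = _office_mask(series, date, office_hours)
    idx = np.flatnonzero(mask)
    inactive = sum(1 for i in idx if states[i] is ActivityState.INACTIVE)
    brk = sum(1 for i in idx if states[i] is ActivityState.BREAK)
    valid = inactive + brk
    idx_set = set(int(i) for i in idx)
    break_count = sum(
        1 for ev in events if any(i in idx_set for i in range(ev.start, ev.end))
    )
    longest = run = 0
    prev = None
    for i in idx:
        if states[i] is ActivityState.INACTIVE and (prev is not None and i == prev + 1 and run > 0):
            run += 1
        elif states[i] is ActivityState.INACTIVE:
            run = 1
        else:
            run = 0
        longest = max(longest, run)
        prev = i
    goal_met: bool | None = None
    if goal is not None and valid > 0:
        goal_met = evaluate_goal(series, states, events, date, office_hours, goal)
    return DailySummary(
        date=date,
        valid_epochs=valid,
        inactive_epochs=inactive,
        break_epochs=brk,
        break_count=break_count,
        longest_inactive_bout_epochs=longest,
        goal_met=goal_met,
    )


def evaluate_goal(
    series: EpochSeries,
    states: Sequence[ActivityState],
    events: Sequence[BreakEvent],
    date: date_type,
    office_hours: tuple[time, time],
    goal: GoalSpec,
) -> bool | None:
    """Decide whether a classified day meets its break goal.

    A sitting clock advances over inactive office-hour epochs; only a
    registered break of at least ``break_duration_min`` resets it
    (shorter breaks neither advance nor reset it; nonwear suspends it).
    The goal is met iff the clock never exceeds ``break_interval_min``.
    Returns ``None`` on a day without valid epochs.
    """
    mask = _office_mask(series, date, office_hours)
    idx = np.flatnonzero(mask)
    if not any(states[i] is not ActivityState.NONWEAR for i in idx):
        return None
    eps = series.epoch_length_s
    interval_epochs = goal.break_interval_min * 60.0 / eps
    qualifying_starts: dict[int, bool] = {}
    for ev in events:
        qualifies = (ev.end - ev.start) * eps >= goal.break_duration_min * 60.0
        for i in range(ev.start, ev.end):
            qualifying_starts[i] = qualifies
    clock = 0
    for i in idx:
        st = states[i]
        if st is ActivityState.INACTIVE:
            clock += 1
            if clock > interval_epochs:
                return False
        elif st is ActivityState.BREAK:
            if qualifying_starts.get(int(i), False):
                clock = 0
        # NONWEAR: clock suspended
    return True


def award_rewards(
    summaries: Sequence[DailySummary], baseline: BaselineStats
) -> list[Reward]:
    """Assign daily rewards against the baseline-period medians.

    A GOAL_BADGE marks each goal-met day.  An IMPROVEMENT_TROPHY marks a
    day whose longest inactive bout is strictly shorter than the
    baseline median *and* whose break count strictly exceeds the
    baseline median break count.
    """
    if baseline is None:
        raise ValidationError("baseline statistics are required")
    rewards: list[Reward] = []
    for s in summaries:
        if s.goal_met:
            rewards.append(Reward(s.date, RewardKind.GOAL_BADGE,
                                  "daily break goal met"))
        if (
            s.longest_inactive_bout_epochs < baseline.median_longest_bout_epochs
            and s.break_count > baseline.median_break_count
        ):
            rewards.append(
                Reward(
                    s.date,
                    RewardKind.IMPROVEMENT_TROPHY,
                    (
                        f"longest bout {s.longest_inactive_bout_epochs} < "
                        f"baseline median {baseline.median_longest_bout_epochs}; "
                        f"breaks {s.break_count} > baseline median "
                        f"{baseline.median_break_count}"
                    ),
                )
            )
    return rewards


def compute_fidelity(
    day_states: Sequence[Sequence[ActivityState]],
    prompt_logs: Sequence[Sequence[PromptEvent]],
    usage_log: Iterable[tuple[date_type, str]],
) -> FidelityReport:
    """Aggregate the trial-monitoring fidelity/adherence report.

    ``pct_valid_tracking`` is the percentage of all tracked epochs that
    are not nonwear; ``pct_prompts_delivered`` pools every day's prompt
    log (100.0 when no emission occurred at all); ``adherence_days``
    counts the distinct days on which each logged function appears in
    the usage log.
    """
    if not day_states:
        raise ValidationError("at least one observed day is required")
    total = sum(len(s) for s in day_states)
    if total == 0:
        raise ValidationError("observed days contain no epochs")
    nonwear = sum(
        sum(1 for st in s if st is ActivityState.NONWEAR) for s in day_states
    )
    pooled = [e for log in prompt_logs for e in log]
    pct_prompts = prompts_delivered_fraction(pooled) if pooled else 100.0
    days_per_fn: dict[str, set[date_type]] = {}
    for day, fn in usage_log:
        days_per_fn.setdefault(fn, set()).add(day)
    return FidelityReport(
        pct_valid_tracking=100.0 * (total - nonwear) / total,
        pct_prompts_delivered=pct_prompts,
        adherence_days={fn: len(days) for fn, days in sorted(days_per_fn.items())},
        n_days=len(day_states),
    )


def plot_timeline(
    series: EpochSeries,
    states: Sequence[ActivityState],
    events: Sequence[BreakEvent],
    path: str | Path,
) -> None:
    """Render the day's counts colored by state, mirroring a history view."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        ActivityState.INACTIVE: "#9aa0a6",
        ActivityState.BREAK: "#34a853",
        ActivityState.NONWEAR: "#ea4335",
    }
    fig, ax = plt.subplots(figsize=(12, 3))
    ax.bar(
        series.timestamps,
        series.cpe,
        width=np.timedelta64(series.epoch_length_s, "s"),
        color=[colors[s] for s in states],
        linewidth=0,
    )
    for ev in events:
        ax.axvspan(series.timestamps[ev.start],
                   series.timestamps[ev.end - 1], alpha=0.15, color="#34a853")
    ax.set_ylabel("counts per epoch")
    ax.set_xlabel("time")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
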