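"""Just-in-time break reminders driven by the inactivity timer.

An inactivity timer accumulates over consecutive inactive epochs within
office hours.  Three configurable LED stages each fire once per
inactivity bout when the timer crosses their trigger.  The wearer may
snooze a reminder (postponing it by a few minutes) up to a limit —
default three times — after which the next emission escalates to a
vibratory reminder on the wrist.  The timer resets automatically at the
start of any registered break, is suspended (not reset) during nonwear
— absence of data is not evidence of a break — and reminders falling
inside a do-not-disturb window (e.g. a meeting) are suppressed and not
re-queued until the window ends.  Every emission is logged with its
timestamp, stage, modality and outcome so intervention fidelity can be
audited afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, time
from enum import Enum
from typing import Sequence

import numpy as np

from .epoch_io import EpochSeries, ValidationError, parse_local_time
from .classifier import (
    ActivityState,
    BreakEvent,
    ClassifierParams,
    DEFAULT_PARAMS,
    classify,
)
from .synthetic import CLASS_RANGES

__all__ = [
    "LedStage",
    "PromptConfig",
    "Modality",
    "PromptOutcome",
    "ESCALATED",
    "PromptEvent",
    "ResponsePolicy",
    "UserResponseScript",
    "run_prompt_engine",
    "prompts_delivered_fraction",
    "simulate_compliance",
]


class Modality(str, Enum):
    LED = "LED"
    VIBRATION = "VIBRATION"


class PromptOutcome(str, Enum):
    DELIVERED = "DELIVERED"
    SNOOZED = "SNOOZED"
    SUPPRESSED_DND = "SUPPRESSED_DND"
    SUPPRESSED_NONWEAR = "SUPPRESSED_NONWEAR"


#: Stage label of an escalated (vibratory) emission.
ESCALATED = "ESCALATED"


class ResponsePolicy(str, Enum):
    SNOOZE = "SNOOZE"
    COMPLY = "COMPLY"
    IGNORE = "IGNORE"


@dataclass(frozen=True)
class LedStage:
    """One LED reminder stage: minutes of inactivity and a light pattern."""

    trigger_elapsed_min: float
    pattern: str


@dataclass
class PromptConfig:
    """Reminder rules: LED stages, snooze policy, DND and office hours."""

    led_events: Sequence[LedStage] = (
        LedStage(25, "GREEN_PULSE"),
        LedStage(30, "AMBER_PULSE"),
        LedStage(40, "RED_FLASH"),
    )
    snooze_limit: int = 3
    snooze_delay_min: float = 5.0
    escalation_modality: Modality = Modality.VIBRATION
    dnd_windows: Sequence[tuple[time, time]] = ()
    office_hours: tuple[time, time] = (time(9, 0), time(17, 0))

    def __post_init__(self) -> None:
        self.led_events = [
            s if isinstance(s, LedStage) else LedStage(*s) for s in self.led_events
        ]
        if len(self.led_events) != 3:
            raise ValidationError("exactly three LED stages are required")
        triggers = [s.trigger_elapsed_min for s in self.led_events]
        if any(b <= a for a, b in zip(triggers, triggers[1:])):
            raise ValidationError("LED stage triggers must be strictly increasing")
        if triggers[0] <= 0:
            raise ValidationError("LED stage triggers must be positive")
        if self.snooze_limit < 0:
            raise ValidationError("snooze_limit must be >= 0")
        if self.snooze_delay_min <= 0:
            raise ValidationError("snooze_delay_min must be positive")
        self.escalation_modality = Modality(self.escalation_modality)
        self.dnd_windows = [
            (parse_local_time(a), parse_local_time(b)) for a, b in self.dnd_windows
        ]
        self.office_hours = (
            parse_local_time(self.office_hours[0]),
            parse_local_time(self.office_hours[1]),
        )
        for a, b in [*self.dnd_windows, self.office_hours]:
            if a >= b:
                raise ValidationError(f"window start {a} must precede end {b}")

    @classmethod
    def from_config(cls, config: dict) -> "PromptConfig":
        stages = [
            LedStage(t, p)
            for t, p in zip(config["led_triggers_min"], config["led_patterns"])
        ]
        return cls(
            led_events=stages,
            snooze_limit=config["snooze_limit"],
            snooze_delay_min=config["snooze_delay_min"],
            escalation_modality=config["escalation_modality"],
            dnd_windows=[tuple(w) for w in config["dnd_windows"]],
            office_hours=tuple(config["office_hours"]),
        )


@dataclass(frozen=True)
class PromptEvent:
    """One logged emission of the reminder system."""

    timestamp: datetime
    stage: int | str
    modality: Modality
    outcome: PromptOutcome


@dataclass
class UserResponseScript:
    """Scripted user reactions, consumed one per actionable emission.

    ``policies`` are applied in order to emissions the user can act on
    (delivered or snoozable ones; suppressed and escalated emissions do
    not consume a policy).  After the list is exhausted, ``IGNORE``
    applies.  ``comply_latency_epochs`` is the delay before a COMPLY
    response turns into an actual break in the simulation harness
    (:func:`simulate_compliance`); the engine itself records a COMPLY
    simply as a delivered prompt.
    """

    policies: Sequence[ResponsePolicy] = ()
    comply_latency_epochs: int = 8

    def __post_init__(self) -> None:
        self.policies = [ResponsePolicy(p) for p in self.policies]
        if self.comply_latency_epochs < 0:
            raise ValidationError("comply_latency_epochs must be >= 0")

    def policy_for(self, k: int) -> ResponsePolicy:
        if k < len(self.policies):
            return self.policies[k]
        return ResponsePolicy.IGNORE


def _in_window(t: time, window: tuple[time, time]) -> bool:
    return window[0] <= t < window[1]


def _epochs(minutes: float, epoch_length_s: int) -> int:
    n = minutes * 60.0 / epoch_length_s
    rounded = int(round(n))
    if rounded < 1 or abs(n - rounded) > 1e-9:
        raise ValidationError(
            f"{minutes} min is not a positive whole number of "
            f"{epoch_length_s} s epochs"
        )
    return rounded


def run_prompt_engine(
    series: EpochSeries,
    states: Sequence[ActivityState],
    events: Sequence[BreakEvent],
    config: PromptConfig,
    responses: UserResponseScript | None = None,
) -> list[PromptEvent]:
    """Simulate the reminder system over a classified epoch series.

    Parameters
    ----------
    series, states, events
        The epoch series and the per-epoch states / break events the
        classifier produced for it.
    config
        Reminder rules.
    responses
        Scripted user reactions; ``None`` means ignore everything.

    Returns
    -------
    list[PromptEvent]
        The emission log, in time order.
    """
    if responses is None:
        responses = UserResponseScript()
    n = len(series)
    if len(states) != n:
        raise ValidationError("states length must match series length")
    for ev in events:
        if not (0 <= ev.start < ev.end <= n):
            raise ValidationError(f"break event {ev} lies outside the series")

    eps = series.epoch_length_s
    stage_trigger_epochs = [
        _epochs(s.trigger_elapsed_min, eps) for s in config.led_events
    ]
    snooze_delay_epochs = _epochs(config.snooze_delay_min, eps)
    times = [ts.time() for ts in series.timestamps]

    log: list[PromptEvent] = []
    pending: list[tuple[int, int | str]] = []  # (due epoch, stage label)
    timer = 0
    fired: set[int] = set()
    snoozes = 0
    escalated = False
    response_idx = 0

    def reset_bout() -> None:
        nonlocal timer, fired, snoozes, escalated, pending
        timer = 0
        fired = set()
        snoozes = 0
        escalated = False
        pending = []

    def next_wear(i: int) -> int:
        j = i
        while j < n and states[j] is ActivityState.NONWEAR:
            j += 1
        return j

    def dnd_end_epoch(i: int, window: tuple[time, time]) -> int:
        ts = series.timestamps[i]
        end_dt = datetime.combine(ts.date(), window[1])
        delta_s = (end_dt - ts.to_pydatetime()).total_seconds()
        return i + int(math.ceil(delta_s / eps))

    def emit(i: int, stage: int | str) -> None:
        nonlocal snoozes, escalated, response_idx
        ts = series.timestamps[i].to_pydatetime()
        t = times[i]
        for window in config.dnd_windows:
            if _in_window(t, window):
                log.append(PromptEvent(ts, stage, Modality.LED,
                                       PromptOutcome.SUPPRESSED_DND))
                due = dnd_end_epoch(i, window)
                if due < n:
                    pending.append((due, stage))
                return
        if snoozes >= config.snooze_limit and not escalated:
            log.append(PromptEvent(ts, ESCALATED, config.escalation_modality,
                                   PromptOutcome.DELIVERED))
            escalated = True
            return
        policy = responses.policy_for(response_idx)
        response_idx += 1
        if policy is ResponsePolicy.SNOOZE and not escalated:
            log.append(PromptEvent(ts, stage, Modality.LED,
                                   PromptOutcome.SNOOZED))
            snoozes += 1
            due = i + snooze_delay_epochs
            if due < n:
                pending.append((due, stage))
            return
        log.append(PromptEvent(ts, stage, Modality.LED, PromptOutcome.DELIVERED))

    for i in range(n):
        in_office = _in_window(times[i], config.office_hours)
        if not in_office:
            reset_bout()
            continue
        state = states[i]
        if state is ActivityState.BREAK:
            # timer resets automatically at a registered break
            reset_bout()
            continue
        if state is ActivityState.NONWEAR:
            # suspended, not reset; due emissions wait for wear to resume
            due_now = [p for p in pending if p[0] <= i]
            for due, stage in due_now:
                pending.remove((due, stage))
                ts = series.timestamps[i].to_pydatetime()
                log.append(PromptEvent(ts, stage, Modality.LED,
                                       PromptOutcome.SUPPRESSED_NONWEAR))
                resume = next_wear(i)
                if resume < n:
                    pending.append((resume, stage))
            continue

        timer += 1
        due_now = sorted(p for p in pending if p[0] <= i)
        for item in due_now:
            pending.remove(item)
            emit(i, item[1])
        for s_idx, trig in enumerate(stage_trigger_epochs):
            if s_idx not in fired and timer == trig:
                fired.add(s_idx)
                emit(i, s_idx)
    return log


def prompts_delivered_fraction(log: Sequence[PromptEvent]) -> float:
    """Percentage of prompt emissions that reached the user, in [0, 100].

    Snoozed emissions count as delivered — the user saw and acted on
    them; suppressed ones (DND or nonwear) do not.
    """
    if not log:
        raise ValidationError("delivered fraction undefined for empty log")
    delivered = sum(
        1 for e in log
        if e.outcome in (PromptOutcome.DELIVERED, PromptOutcome.SNOOZED)
    )
    return 100.0 * delivered / len(log)


def simulate_compliance(
    series: EpochSeries,
    params: ClassifierParams = DEFAULT_PARAMS,
    config: PromptConfig | None = None,
    responses: UserResponseScript | None = None,
    walk_epochs: int = 22,
    seed: int = 0,
) -> tuple[EpochSeries, list[PromptEvent]]:
    """Closed-loop harness: COMPLY responses become real walking breaks.

    Repeatedly classifies the trace and runs the prompt engine; for the
    earliest delivered prompt whose scripted policy was COMPLY and whose
    break has not yet been injected, a ``walk_epochs``-long stretch of
    walking-range counts is written into the trace
    ``comply_latency_epochs`` after the prompt.  Because an injection
    only alters epochs after its prompt, a time-ordered pass converges.

    Returns the final (modified) series and its final prompt log.
    """
    if config is None:
        config = PromptConfig()
    if responses is None:
        responses = UserResponseScript()
    rng = np.random.default_rng(seed)
    cpe = series.cpe.copy()
    injected: set[int] = set()
    lo, hi = CLASS_RANGES["WALKING"]
    for _ in range(1 + len(series)):
        current = EpochSeries(
            timestamps=series.timestamps, cpe=cpe,
            epoch_length_s=series.epoch_length_s,
        )
        states, events = classify(current, params)
        log = run_prompt_engine(current, states, events, config, responses)
        # pair delivered emissions with the response script, in order
        actionable = [
            e for e in log
            if e.outcome in (PromptOutcome.DELIVERED, PromptOutcome.SNOOZED)
            and e.stage != ESCALATED
        ]
        ts_index = {ts: i for i, ts in enumerate(series.timestamps.to_pydatetime())}
        changed = False
        for k, ev in enumerate(actionable):
            if responses.policy_for(k) is not ResponsePolicy.COMPLY:
                continue
            i = ts_index[ev.timestamp]
            if i in injected:
                continue
            start = min(i + responses.comply_latency_epochs, len(cpe))
            end = min(start + walk_epochs, len(cpe))
            if end > start:
                cpe[start:end] = rng.integers(lo, hi + 1, size=end - start)
            injected.add(i)
            changed = True
            break
        if not changed:
            break
    final = EpochSeries(
        timestamps=series.timestamps, cpe=cpe,
        epoch_length_s=series.epoch_length_s,
    )
    states, events = classify(final, params)
    return final, run_prompt_engine(final, states, events, config, responses)
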