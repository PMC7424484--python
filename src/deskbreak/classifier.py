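"""Break/inactivity classification of counts-per-epoch series.

The classifier separates *inactivity* (sitting or standing still) from
*ambulatory breaks* using intensity cut-points combined with run-length
(temporality) rules, and flags invalid tracking periods (device nonwear
or failure) as maximal runs of zero counts.

Two kinds of movement register as a break:

* a **burst** of high-intensity movement — ``burst_duration`` consecutive
  epochs with cpe strictly above ``burst_cutoff`` (default >25 CPE for 2
  epochs), the signature of walking to a different room; and
* a **sustained** spell of mild ambulation — strictly more than
  ``mild_duration`` consecutive epochs above ``mild_cutoff`` (default
  >20 epochs, i.e. >5 min, of >10 CPE), the signature of pottering
  around the room.

Classification runs as a streaming two-mode state machine.  In
*detection* mode, candidate runs accumulate while the wearer is
inactive; when a rule fires, the machine enters *register* mode and the
break is labeled retroactively from the onset of the enclosing
above-mild-cutoff run, so confirmation latency never truncates the
break.  Register mode ends only after ``exit_duration`` consecutive
epochs at or below ``exit_cutoff`` (default 1 min at ≤10 CPE); this
hysteresis suppresses rapid state flips caused by sporadic hand
movements such as fidgeting or gesturing.  All cut-point comparisons are
strict (``cpe > cutoff``), matching the calibration convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .epoch_io import EpochSeries, ValidationError

__all__ = [
    "ClassifierParams",
    "ActivityState",
    "BreakType",
    "BreakEvent",
    "NonwearInterval",
    "TailoringError",
    "detect_nonwear",
    "classify",
    "validate_tailoring",
    "valid_tracking_fraction",
    "DEFAULT_PARAMS",
]


class TailoringError(ValueError):
    """A requested parameter lies outside its researcher-tailoring bound."""


@dataclass(frozen=True)
class ClassifierParams:
    """Cut-point and run-length parameters of the break detector.

    Attributes
    ----------
    burst_cutoff
        Intensity cutoff for the high-intensity burst rule, CPE.  An
        epoch counts toward a burst only if ``cpe > burst_cutoff``.
    burst_duration
        Consecutive above-burst-cutoff epochs needed to register a
        burst break.  Lowering to 1 lets a single energetic epoch (a
        quick trip) register.
    mild_cutoff
        Intensity cutoff for mild ambulation, CPE (strict ``>``).
    mild_duration
        A run of *strictly more than* this many consecutive
        above-mild-cutoff epochs registers a sustained break.  The
        value 1 is a sentinel that disables the sustained rule
        entirely, so mild movement is never recognized as a break.
    exit_cutoff
        Intensity at or below which epochs count toward ending a
        registered break, CPE.
    exit_duration
        Consecutive at-or-below-exit-cutoff epochs that end a
        registered break (those epochs are inactive; the break ends
        where they begin).
    nonwear_zero_run
        Consecutive zero-count epochs that mark an invalid tracking
        period (nonwear or technology failure); default 240 epochs =
        60 min, the conventional window in count-based actigraphy.
    """

    burst_cutoff: int = 25
    burst_duration: int = 2
    mild_cutoff: int = 10
    mild_duration: int = 20
    exit_cutoff: int = 10
    exit_duration: int = 4
    nonwear_zero_run: int = 240

    def __post_init__(self) -> None:
        if not (self.burst_cutoff > self.mild_cutoff >= self.exit_cutoff >= 0):
            raise ValidationError(
                "cutoffs must satisfy burst_cutoff > mild_cutoff >= "
                f"exit_cutoff >= 0, got {self.burst_cutoff} / "
                f"{self.mild_cutoff} / {self.exit_cutoff}"
            )
        for name in ("burst_duration", "mild_duration", "exit_duration",
                     "nonwear_zero_run"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @classmethod
    def from_config(cls, config: dict) -> "ClassifierParams":
        return cls(
            burst_cutoff=config["burst_cutoff_cpe"],
            burst_duration=config["burst_duration_epochs"],
            mild_cutoff=config["mild_cutoff_cpe"],
            mild_duration=config["mild_duration_epochs"],
            exit_cutoff=config["exit_cutoff_cpe"],
            exit_duration=config["exit_duration_epochs"],
            nonwear_zero_run=config["nonwear_zero_epochs"],
        )


DEFAULT_PARAMS = ClassifierParams()


class ActivityState(str, Enum):
    """Per-epoch classification outcome; every epoch gets exactly one."""

    INACTIVE = "INACTIVE"
    BREAK = "BREAK"
    NONWEAR = "NONWEAR"


class BreakType(str, Enum):
    BURST = "BURST"
    SUSTAINED = "SUSTAINED"


@dataclass(frozen=True)
class BreakEvent:
    """A maximal registered break, as a half-open epoch-index interval."""

    start: int
    end: int
    type: BreakType
    peak_cpe: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("BreakEvent requires end > start")

    @property
    def duration_epochs(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NonwearInterval:
    """A maximal zero-count invalid tracking period (half-open indices)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("NonwearInterval requires end > start")

    @property
    def duration_epochs(self) -> int:
        return self.end - self.start


def detect_nonwear(
    series: EpochSeries, params: ClassifierParams = DEFAULT_PARAMS
) -> list[NonwearInterval]:
    """Find maximal runs of ≥ ``nonwear_zero_run`` consecutive zero counts.

    Returns the intervals in order; they never overlap.  An empty result
    means no qualifying run.
    """
    cpe = series.cpe
    if len(cpe) == 0:
        return []
    zero = np.concatenate(([0], (cpe == 0).astype(np.int8), [0]))
    edges = np.diff(zero)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [
        NonwearInterval(int(s), int(e))
        for s, e in zip(starts, ends)
        if e - s >= params.nonwear_zero_run
    ]


def _classify_segment(
    cpe: np.ndarray, params: ClassifierParams, offset: int,
    states: list[ActivityState],
) -> list[BreakEvent]:
    """Run the detection/register state machine on one wear segment.

    ``cpe`` is the segment's counts; confirmed BREAK epochs are written
    into ``states`` at ``offset``-shifted indices.
    """
    n = len(cpe)
    events: list[BreakEvent] = []
    i = 0
    while i < n:
        # --- detection mode: accumulate candidate runs -------------------
        mild_run = 0
        burst_run = 0
        mild_start = -1
        trigger_j = -1
        trigger_type: BreakType | None = None
        j = i
        while j < n:
            v = cpe[j]
            if v > params.mild_cutoff:
                if mild_run == 0:
                    mild_start = j
                mild_run += 1
            else:
                mild_run = 0
            if v > params.burst_cutoff:
                burst_run += 1
            else:
                burst_run = 0
            # burst checked first: the more specific trigger wins a tie
            if burst_run >= params.burst_duration:
                trigger_j, trigger_type = j, BreakType.BURST
                break
            if params.mild_duration > 1 and mild_run > params.mild_duration:
                trigger_j, trigger_type = j, BreakType.SUSTAINED
                break
            j += 1
        if trigger_type is None:
            break  # remainder stays INACTIVE

        # The break is labeled from the onset of the enclosing
        # above-mild-cutoff run (cpe > burst_cutoff implies
        # cpe > mild_cutoff, so a burst run always lies inside it).
        b_start = mild_start

        # --- register mode: hysteresis exit ------------------------------
        exit_run = 0
        b_end = n
        resume = n
        k = trigger_j + 1
        while k < n:
            if cpe[k] <= params.exit_cutoff:
                exit_run += 1
                if exit_run == params.exit_duration:
                    b_end = k - params.exit_duration + 1
                    resume = k + 1
                    break
            else:
                exit_run = 0
            k += 1

        for idx in range(b_start, b_end):
            states[offset + idx] = ActivityState.BREAK
        events.append(
            BreakEvent(
                start=offset + b_start,
                end=offset + b_end,
                type=trigger_type,
                peak_cpe=int(cpe[b_start:b_end].max()),
            )
        )
        i = resume
    return events


def classify(
    series: EpochSeries, params: ClassifierParams = DEFAULT_PARAMS
) -> tuple[list[ActivityState], list[BreakEvent]]:
    """Classify every epoch as INACTIVE, BREAK or NONWEAR.

    Nonwear intervals (from :func:`detect_nonwear`) override both modes:
    their epochs are NONWEAR, candidate runs reset at their boundaries,
    and no break event crosses them.  Returns the per-epoch state
    sequence and the registered break events in order.
    """
    if not isinstance(params, ClassifierParams):
        raise ValidationError("params must be a ClassifierParams")
    cpe = series.cpe
    n = len(cpe)
    states: list[ActivityState] = [ActivityState.INACTIVE] * n
    nonwear = detect_nonwear(series, params)
    for nw in nonwear:
        for idx in range(nw.start, nw.end):
            states[idx] = ActivityState.NONWEAR

    events: list[BreakEvent] = []
    seg_start = 0
    boundaries = [(nw.start, nw.end) for nw in nonwear] + [(n, n)]
    for nw_start, nw_end in boundaries:
        if nw_start > seg_start:
            events.extend(
                _classify_segment(cpe[seg_start:nw_start], params, seg_start, states)
            )
        seg_start = nw_end
    return states, events


def validate_tailoring(
    requested: ClassifierParams, defaults: ClassifierParams = DEFAULT_PARAMS
) -> ClassifierParams:
    """Check a requested parameter set against the tailoring bounds.

    Researchers may tailor detector sensitivity per participant, but
    only within protocol bounds: the burst intensity cutoff may be
    raised by at most 5 CPE above its default (never lowered), and the
    burst/sustained duration thresholds may be lowered to a floor of 1
    epoch (1 disabling the sustained rule).  Returns the accepted set
    unchanged; otherwise raises :class:`TailoringError` naming the
    offending parameter and its admissible range.
    """
    lo, hi = defaults.burst_cutoff, defaults.burst_cutoff + 5
    if not (lo <= requested.burst_cutoff <= hi):
        raise TailoringError(
            f"burst_cutoff={requested.burst_cutoff} outside admissible "
            f"range [{lo}, {hi}] (default {defaults.burst_cutoff}, "
            "raisable by up to 5 CPE)"
        )
    if requested.burst_duration < 1:
        raise TailoringError(
            f"burst_duration={requested.burst_duration} below floor 1"
        )
    if requested.mild_duration < 1:
        raise TailoringError(
            f"mild_duration={requested.mild_duration} below floor 1 "
            "(1 disables the sustained-ambulation rule)"
        )
    return requested


def valid_tracking_fraction(
    series: EpochSeries, nonwear: Sequence[NonwearInterval]
) -> float:
    """Percentage of tracking time that is valid (not nonwear), in [0, 100]."""
    n = len(series)
    if n == 0:
        raise ValidationError("valid tracking fraction undefined for empty series")
    nw_epochs = sum(iv.end - iv.start for iv in nonwear)
    return 100.0 * (n - nw_epochs) / n
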