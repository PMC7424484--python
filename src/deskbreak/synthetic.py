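"""Synthetic counts-per-epoch traces from scripted activity schedules.

Stands in for the wrist-worn device: renders an ordered schedule of
activity segments into an epoch series whose per-class intensity
signatures match the calibration ranges observed in structured
data-collection sessions —

========================  =======================================
class                     counts per epoch
========================  =======================================
SITTING                   0–5 most of the time, 6–10 occasionally
STANDING_STILL            0–5 (classified together with sitting)
MILD_AMBULATION           10–25
WALKING                   23–30
NONWEAR                   0
========================  =======================================

The MILD_AMBULATION/WALKING overlap is real: the two signatures overlap
in the source calibration and are deliberately preserved.  Only
epoch-count statistics are emulated; no physiologically realistic
waveform is attempted.  All randomness flows from a single seeded
integer generator owned by the script — identical seed, identical trace,
on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Sequence

import numpy as np

from .epoch_io import DEFAULT_EPOCH_LENGTH_S, EpochSeries, ValidationError

__all__ = [
    "Activity",
    "ActivitySegment",
    "ActivityScript",
    "generate_trace",
    "generate_workday",
    "WORKDAY_PROFILES",
    "SITTING_ELEVATED_PROB",
]

#: Fraction of sitting epochs drawn from the occasional elevated band
#: (6–10 CPE, e.g. a torso twist); quantifies "5 or less most of the
#: time and 5–10 occasionally".
SITTING_ELEVATED_PROB = 0.1

#: Closed integer intensity ranges per activity class.
CLASS_RANGES: dict[str, tuple[int, int]] = {
    "SITTING_LOW": (0, 5),
    "SITTING_HIGH": (6, 10),
    "STANDING_STILL": (0, 5),
    "MILD_AMBULATION": (10, 25),
    "WALKING": (23, 30),
}


class Activity(str, Enum):
    SITTING = "SITTING"
    STANDING_STILL = "STANDING_STILL"
    MILD_AMBULATION = "MILD_AMBULATION"
    WALKING = "WALKING"
    NONWEAR = "NONWEAR"


@dataclass(frozen=True)
class ActivitySegment:
    """A contiguous stretch of one activity class."""

    activity: Activity
    duration_epochs: int

    def __post_init__(self) -> None:
        if not isinstance(self.activity, Activity):
            try:
                object.__setattr__(self, "activity", Activity(self.activity))
            except ValueError:
                raise ValidationError(
                    f"unknown activity {self.activity!r}; valid: "
                    f"{[a.value for a in Activity]}"
                ) from None
        if self.duration_epochs < 1:
            raise ValidationError("duration_epochs must be >= 1")


@dataclass
class ActivityScript:
    """An ordered activity schedule plus its time base and seed."""

    segments: Sequence[ActivitySegment]
    start_time: datetime = datetime(2024, 1, 8, 9, 0)
    seed: int = 0
    epoch_length_s: int = DEFAULT_EPOCH_LENGTH_S
    sitting_elevated_prob: float = SITTING_ELEVATED_PROB

    def __post_init__(self) -> None:
        self.segments = [
            s if isinstance(s, ActivitySegment) else ActivitySegment(*s)
            for s in self.segments
        ]
        if not self.segments:
            raise ValidationError("script must contain at least one segment")

    @property
    def total_epochs(self) -> int:
        return sum(s.duration_epochs for s in self.segments)


def _render_segment(
    activity: Activity, n: int, rng: np.random.Generator, elevated_prob: float
) -> np.ndarray:
    if activity is Activity.NONWEAR:
        return np.zeros(n, dtype=np.int64)
    if activity is Activity.SITTING:
        # integer draw decides the band so the hot path stays integer-only
        resolution = 1000
        band = rng.integers(0, resolution, size=n)
        lo_l, lo_h = CLASS_RANGES["SITTING_LOW"]
        hi_l, hi_h = CLASS_RANGES["SITTING_HIGH"]
        low = rng.integers(lo_l, lo_h + 1, size=n)
        high = rng.integers(hi_l, hi_h + 1, size=n)
        return np.where(band < int(elevated_prob * resolution), high, low).astype(
            np.int64
        )
    lo, hi = CLASS_RANGES[activity.value]
    return rng.integers(lo, hi + 1, size=n).astype(np.int64)


def generate_trace(script: ActivityScript) -> EpochSeries:
    """Render an activity script into a counts-per-epoch series.

    Each epoch's count is drawn from its segment's class range; the
    output length equals the script's total duration and identical
    seeds yield identical traces.
    """
    rng = np.random.default_rng(script.seed)
    parts = [
        _render_segment(seg.activity, seg.duration_epochs, rng,
                        script.sitting_elevated_prob)
        for seg in script.segments
    ]
    return EpochSeries.from_counts(
        script.start_time, np.concatenate(parts), script.epoch_length_s
    )


# ---------------------------------------------------------------------------
# Workday presets
# ---------------------------------------------------------------------------

#: One workday is 8 h = 1920 epochs at 15 s.
WORKDAY_EPOCHS = 1920

WORKDAY_PROFILES = ("prolonged-sitter", "regular-breaker", "nonwear-heavy")


def _script_prolonged_sitter(rng: np.random.Generator) -> list[ActivitySegment]:
    # long sitting blocks (>30 min each) punctuated by brief walks
    segs: list[ActivitySegment] = []
    total = 0
    while total < WORKDAY_EPOCHS:
        sit = int(rng.integers(150, 221))
        walk = int(rng.integers(8, 13))
        segs.append(ActivitySegment(Activity.SITTING, sit))
        segs.append(ActivitySegment(Activity.WALKING, walk))
        total += sit + walk
    return segs


def _script_regular_breaker(rng: np.random.Generator) -> list[ActivitySegment]:
    # a >5-min walking bout roughly every 30 min of sitting
    segs: list[ActivitySegment] = []
    total = 0
    while total < WORKDAY_EPOCHS:
        sit = int(rng.integers(90, 101))
        walk = int(rng.integers(22, 29))
        segs.append(ActivitySegment(Activity.SITTING, sit))
        segs.append(ActivitySegment(Activity.WALKING, walk))
        total += sit + walk
    return segs


def _script_nonwear_heavy(rng: np.random.Generator) -> list[ActivitySegment]:
    # a forgotten device: a >1 h zero-count block mid-day
    segs = [
        ActivitySegment(Activity.SITTING, int(rng.integers(110, 131))),
        ActivitySegment(Activity.WALKING, int(rng.integers(22, 29))),
        ActivitySegment(Activity.NONWEAR, int(rng.integers(260, 321))),
        ActivitySegment(Activity.SITTING, int(rng.integers(110, 131))),
        ActivitySegment(Activity.MILD_AMBULATION, int(rng.integers(24, 33))),
    ]
    total = sum(s.duration_epochs for s in segs)
    while total < WORKDAY_EPOCHS:
        sit = int(rng.integers(110, 131))
        walk = int(rng.integers(22, 29))
        segs.append(ActivitySegment(Activity.SITTING, sit))
        segs.append(ActivitySegment(Activity.WALKING, walk))
        total += sit + walk
    return segs


_PROFILE_BUILDERS = {
    "prolonged-sitter": _script_prolonged_sitter,
    "regular-breaker": _script_regular_breaker,
    "nonwear-heavy": _script_nonwear_heavy,
}


def workday_script(
    profile: str,
    seed: int,
    start_time: datetime = datetime(2024, 1, 8, 9, 0),
    epoch_length_s: int = DEFAULT_EPOCH_LENGTH_S,
) -> ActivityScript:
    """Build the (randomized, seed-reproducible) script behind a preset.

    The schedule is trimmed to exactly 8 h (1920 epochs at 15 s).
    """
    if profile not in _PROFILE_BUILDERS:
        raise ValidationError(
            f"unknown profile {profile!r}; valid: {sorted(_PROFILE_BUILDERS)}"
        )
    # schedule randomness is drawn from a stream distinct from the
    # intensity randomness so the two are independently reproducible
    rng = np.random.default_rng((seed, 1))
    segs = _PROFILE_BUILDERS[profile](rng)
    # trim to exactly one workday
    trimmed: list[ActivitySegment] = []
    total = 0
    for seg in segs:
        if total + seg.duration_epochs >= WORKDAY_EPOCHS:
            trimmed.append(
                ActivitySegment(seg.activity, WORKDAY_EPOCHS - total)
            )
            break
        trimmed.append(seg)
        total += seg.duration_epochs
    return ActivityScript(
        segments=trimmed, start_time=start_time, seed=seed,
        epoch_length_s=epoch_length_s,
    )


def generate_workday(
    profile: str,
    seed: int,
    start_time: datetime = datetime(2024, 1, 8, 9, 0),
    epoch_length_s: int = DEFAULT_EPOCH_LENGTH_S,
) -> EpochSeries:
    """Generate one 8-hour workday trace from a named preset.

    Presets: ``prolonged-sitter`` (sitting blocks well beyond 30 min),
    ``regular-breaker`` (a sustained walking bout roughly every 30 min),
    ``nonwear-heavy`` (includes a >1 h zero-count block).
    """
    script = workday_script(profile, seed, start_time, epoch_length_s)
    return generate_trace(script)
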