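"""Epoch-level activity-count I/O and shared time conventions.

All modules in :mod:`deskbreak` operate on *counts per epoch* (CPE): the
processed output of a wrist-worn accelerometer, accumulated over fixed
time windows (epochs) and indicative of movement intensity.  This module
defines the canonical in-memory container (:class:`EpochSeries`), the CSV
interchange format, and the flat key–value configuration file shared by
the classifier, prompt engine, goal logic and synthetic generator.

Time conventions
----------------
* Timestamps are timezone-naive local datetimes marking the *start* of an
  epoch; the day boundary is local midnight.
* All intervals are half-open ``[start, end)``.
* The default epoch length is 15 s, so that 20 epochs equal 5 minutes —
  the duration scale on which sustained ambulation is judged.
* A valid series has strictly increasing timestamps on a constant grid
  with no gaps; the CSV reader fills missing epochs with zero counts (an
  extended data loss then surfaces through the zero-count invalid-period
  rule, exactly like device nonwear) and reports the fill count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, time
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_EPOCH_LENGTH_S",
    "DEFAULT_CONFIG",
    "ValidationError",
    "ConfigError",
    "EpochRecord",
    "EpochSeries",
    "read_epoch_csv",
    "write_epoch_csv",
    "load_config",
    "parse_local_time",
]

log = logging.getLogger(__name__)

#: Epoch length such that 20 epochs = 5 min, the scale the sustained-break
#: rule is calibrated on.
DEFAULT_EPOCH_LENGTH_S = 15


class ValidationError(ValueError):
    """A series, record or parameter set violates a structural invariant."""


class ConfigError(ValueError):
    """A configuration file is malformed or contains unknown keys."""


@dataclass(frozen=True)
class EpochRecord:
    """One epoch: its start timestamp and nonnegative activity counts."""

    timestamp: datetime
    cpe: int

    def __post_init__(self) -> None:
        if self.cpe < 0:
            raise ValidationError(f"cpe must be nonnegative, got {self.cpe}")


@dataclass
class EpochSeries:
    """A gap-free, constant-spacing sequence of counts-per-epoch records.

    Parameters
    ----------
    timestamps
        Epoch start times, strictly increasing, spaced exactly
        ``epoch_length_s`` apart and aligned to the epoch grid
        (seconds since local midnight divisible by the epoch length).
    cpe
        Nonnegative integer counts, one per epoch.
    epoch_length_s
        Epoch length in seconds (default 15).
    n_gap_filled
        Number of epochs the reader synthesized to close gaps (zero for
        series built in memory).
    """

    timestamps: pd.DatetimeIndex
    cpe: np.ndarray
    epoch_length_s: int = DEFAULT_EPOCH_LENGTH_S
    n_gap_filled: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.cpe = np.asarray(self.cpe)
        if self.epoch_length_s <= 0:
            raise ValidationError("epoch_length_s must be positive")
        if len(self.timestamps) != len(self.cpe):
            raise ValidationError("timestamps and cpe lengths differ")
        if self.timestamps.tz is not None:
            raise ValidationError("timestamps must be timezone-naive")
        if len(self.cpe) and not np.issubdtype(self.cpe.dtype, np.integer):
            as_int = self.cpe.astype(np.int64)
            if not np.array_equal(as_int, self.cpe):
                raise ValidationError("cpe values must be integers")
            self.cpe = as_int
        else:
            self.cpe = self.cpe.astype(np.int64)
        if len(self.cpe) and int(self.cpe.min()) < 0:
            raise ValidationError("cpe values must be nonnegative")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8) / 1e9
            if not np.all(deltas == self.epoch_length_s):
                raise ValidationError(
                    "timestamps must be strictly increasing with constant "
                    f"spacing of {self.epoch_length_s} s"
                )
        if len(self.timestamps):
            midnight = self.timestamps.normalize()
            secs = (self.timestamps - midnight).total_seconds()
            if np.any(np.asarray(secs) % self.epoch_length_s != 0):
                raise ValidationError(
                    "timestamps must be aligned to the epoch grid"
                )

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        start: datetime,
        cpe: Any,
        epoch_length_s: int = DEFAULT_EPOCH_LENGTH_S,
    ) -> "EpochSeries":
        """Build a series from a start time and an array of counts."""
        cpe = np.asarray(cpe)
        idx = pd.date_range(
            start=start, periods=len(cpe), freq=pd.Timedelta(seconds=epoch_length_s)
        )
        return cls(timestamps=idx, cpe=cpe, epoch_length_s=epoch_length_s)

    # -- container protocol ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.cpe)

    def __iter__(self) -> Iterator[EpochRecord]:
        for ts, c in zip(self.timestamps, self.cpe):
            yield EpochRecord(timestamp=ts.to_pydatetime(), cpe=int(c))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSeries):
            return NotImplemented
        return (
            self.epoch_length_s == other.epoch_length_s
            and self.timestamps.equals(other.timestamps)
            and np.array_equal(self.cpe, other.cpe)
        )

    def to_frame(self) -> pd.DataFrame:
        """Return a two-column ``timestamp,cpe`` DataFrame."""
        return pd.DataFrame({"timestamp": self.timestamps, "cpe": self.cpe})


def read_epoch_csv(
    path: str | Path, epoch_length_s: int = DEFAULT_EPOCH_LENGTH_S
) -> EpochSeries:
    """Read a ``timestamp,cpe`` CSV into a validated :class:`EpochSeries`.

    Rows are normalized by timestamp order.  Missing interior epochs and
    rows with a missing count are filled with ``cpe = 0`` (so data loss
    is absorbed into the zero-count invalid-period rule downstream); the
    number of filled epochs is logged and recorded on the returned series
    as ``n_gap_filled``.

    Raises
    ------
    ConfigError
        If the header is not ``timestamp,cpe``.
    ValidationError
        On malformed timestamps (naming the row), negative counts,
        duplicate timestamps, or off-grid timestamps.
    """
    df = pd.read_csv(path)
    expected = ["timestamp", "cpe"]
    if list(df.columns) != expected:
        raise ConfigError(
            f"{path}: expected header {expected!r}, got {list(df.columns)!r}"
        )
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: malformed timestamp {df['timestamp'].iloc[row]!r} "
            f"in data row {row + 1}"
        )
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValidationError(f"{path}: missing timestamp in data row {row + 1}")
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate timestamp {dup}")

    cpe = pd.to_numeric(df["cpe"], errors="coerce")
    known = cpe.notna()
    if (cpe[known] < 0).any():
        row = int(np.flatnonzero((cpe < 0).to_numpy())[0])
        raise ValidationError(
            f"{path}: negative cpe {cpe.iloc[row]} in data row {row + 1}"
        )

    order = ts.argsort().to_numpy()
    ts = ts.iloc[order].reset_index(drop=True)
    cpe = cpe.iloc[order].reset_index(drop=True)

    if len(ts) == 0:
        return EpochSeries(
            timestamps=pd.DatetimeIndex([]), cpe=np.array([], dtype=np.int64),
            epoch_length_s=epoch_length_s,
        )

    step = pd.Timedelta(seconds=epoch_length_s)
    offsets = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    if np.any(offsets % epoch_length_s != 0):
        row = int(np.flatnonzero(offsets % epoch_length_s != 0)[0])
        raise ValidationError(
            f"{path}: timestamp {ts.iloc[row]} is off the {epoch_length_s} s grid"
        )
    grid = pd.date_range(ts.iloc[0], ts.iloc[len(ts) - 1], freq=step)
    series = pd.Series(cpe.to_numpy(), index=pd.DatetimeIndex(ts))
    series = series.reindex(grid)
    n_filled = int(series.isna().sum())
    if n_filled:
        log.info("read_epoch_csv(%s): filled %d missing epoch(s) with cpe=0",
                 path, n_filled)
    series = series.fillna(0)
    return EpochSeries(
        timestamps=grid,
        cpe=series.to_numpy().astype(np.int64),
        epoch_length_s=epoch_length_s,
        n_gap_filled=n_filled,
    )


def write_epoch_csv(series: EpochSeries, path: str | Path) -> None:
    """Write a series as a ``timestamp,cpe`` CSV (ISO-8601 timestamps).

    The output round-trips through :func:`read_epoch_csv` to an identical
    series; an empty series yields a header-only file.
    """
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat())
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Flat key–value defaults shared by every module.  Intensity cutoffs are in
#: CPE, durations in epochs, prompt timings in minutes.  These mirror the
#: researcher-adjustable settings of the delivery app.
DEFAULT_CONFIG: dict[str, Any] = {
    "epoch_length_s": DEFAULT_EPOCH_LENGTH_S,
    # classifier
    "burst_cutoff_cpe": 25,
    "burst_duration_epochs": 2,
    "mild_cutoff_cpe": 10,
    "mild_duration_epochs": 20,
    "exit_cutoff_cpe": 10,
    "exit_duration_epochs": 4,
    "nonwear_zero_epochs": 240,
    # prompt engine
    "led_triggers_min": [25, 30, 40],
    "led_patterns": ["GREEN_PULSE", "AMBER_PULSE", "RED_FLASH"],
    "snooze_limit": 3,
    "snooze_delay_min": 5,
    "escalation_modality": "VIBRATION",
    "dnd_windows": [],
    "office_hours": ["09:00", "17:00"],
    # goals
    "goal_interval_min": 30,
    "goal_duration_min": 2.0,
    "goal_preset": None,
    # synthetic generator
    "sitting_elevated_prob": 0.1,
    "workday_profile": "regular-breaker",
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a flat YAML config and overlay it on :data:`DEFAULT_CONFIG`.

    ``None`` or an empty file yields the documented defaults.  Unknown
    keys are rejected with the list of valid keys; range validation of
    classifier parameters is deferred to
    :func:`deskbreak.classifier.validate_tailoring`.
    """
    merged = dict(DEFAULT_CONFIG)
    if path is None:
        return merged
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        return merged
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    unknown = sorted(set(data) - set(DEFAULT_CONFIG))
    if unknown:
        raise ConfigError(
            f"{path}: unknown key(s) {unknown}; valid keys: "
            f"{sorted(DEFAULT_CONFIG)}"
        )
    merged.update(data)
    return merged


def parse_local_time(value: str | time) -> time:
    """Parse an ``HH:MM`` string into a :class:`datetime.time`."""
    if isinstance(value, time):
        return value
    try:
        return time.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid local time {value!r} (expected HH:MM)") from exc
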