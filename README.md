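# deskbreak

A desk-scale toolkit for sedentary-behavior sensing and just-in-time
break reminders. It implements, as testable software, the decision core
of a workplace intervention built around a wrist-worn accelerometer:
epoch-level classification of stationary behavior vs ambulatory breaks,
nonwear detection, a snooze-aware LED/vibration reminder engine, and
the daily-summary / goal / reward / fidelity metrics a feasibility
trial needs. A seeded synthetic trace generator stands in for the
device, so every component runs end to end without hardware.

Intended users: researchers in digital health and occupational-health
analytics who need a reproducible reference implementation of
counts-per-epoch break detection and prompt logic for simulation
studies, protocol tailoring, or trial monitoring.

## The model

The sensor reports **counts per epoch** (CPE) — dimensionless activity
counts accumulated over 15-s epochs, a standard intensity proxy in
actigraphy. Each epoch is classified `INACTIVE`, `BREAK` or `NONWEAR`
by a streaming state machine with two registered break types:

* **burst**: ≥ *D* consecutive epochs with CPE > *C*
  (defaults *C* = 25 CPE, *D* = 2 epochs) — walking to another room;
* **sustained**: > *P* consecutive epochs with CPE > *Q*
  (defaults *Q* = 10 CPE, *P* = 20 epochs = 5 min) — sustained mild
  ambulation. *P* = 1 is a sentinel disabling this rule.

Once registered, a break persists until *B* consecutive epochs at
CPE ≤ *A* (defaults *A* = 10, *B* = 4, i.e. one calm minute), a
hysteresis that suppresses flicker from sporadic hand movements.
Maximal runs of ≥ *Z* zero-count epochs (default 240 = 60 min) are
invalid tracking periods (nonwear/failure). Researcher tailoring is
bounded: *C* may be raised by at most 5 CPE; *D* and *P* may be lowered
to 1.

The reminder engine accumulates an inactivity timer over office-hour
inactive epochs, fires three configurable LED stages (defaults 25 / 30
/ 40 min) once per bout, resets on any registered break, suspends
during nonwear, suppresses inside do-not-disturb windows, and escalates
to a vibratory reminder after three snoozes. See `docs/methods.md` for
the full account.

## Worked example

```python
from datetime import date, time
import deskbreak as db

series = db.generate_workday("prolonged-sitter", seed=42)   # 8 h, 1920 epochs
states, events = db.classify(series)                        # default params
log = db.run_prompt_engine(series, states, events, db.PromptConfig())
summary = db.summarize_day(series, states, events, date(2024, 1, 8),
                           (time(9), time(17)),
                           db.GoalSpec.from_preset("EVERY_30"))
print(len(events), events[0])
print(len(log), log[0])
print(summary)
```

prints

```text
9 BreakEvent(start=195, end=206, type=<BreakType.BURST: 'BURST'>, peak_cpe=30)
27 PromptEvent(timestamp=datetime.datetime(2024, 1, 8, 9, 24, 45), stage=0,
   modality=<Modality.LED: 'LED'>, outcome=<PromptOutcome.DELIVERED: 'DELIVERED'>)
DailySummary(date=datetime.date(2024, 1, 8), valid_epochs=1920,
   inactive_epochs=1824, break_epochs=96, break_count=9,
   longest_inactive_bout_epochs=220, goal_met=False)
```

Reading: the simulated prolonged sitter took 9 walking breaks (96
epochs = 24 min of break time) in 8 h; the first break started at epoch
195 and was a high-intensity burst peaking at 30 CPE. The wearer sat
through 27 reminders — the first LED stage fired at 09:24:45, after 25
min of continuous sitting. The longest uninterrupted sitting spell was
220 epochs (55 min), so the "break every 30 min" goal was missed.

The same workflow is available from a shell:

```sh
deskbreak generate --profile prolonged-sitter --seed 42 --out trace.csv
deskbreak classify --input trace.csv --states-out states.csv --events-out events.csv
deskbreak prompt-sim --states states.csv --events events.csv --out prompts.csv
deskbreak report --states states.csv --events events.csv \
    --prompt-log prompts.csv --out-dir report/
deskbreak run --seed 42 --out-dir run/        # all stages + manifest.json
```

All commands accept `--params <config.yaml>`, a flat YAML file
overriding any documented default. Valid keys: `epoch_length_s`,
`burst_cutoff_cpe`, `burst_duration_epochs`, `mild_cutoff_cpe`,
`mild_duration_epochs`, `exit_cutoff_cpe`, `exit_duration_epochs`,
`nonwear_zero_epochs`, `led_triggers_min`, `led_patterns`,
`snooze_limit`, `snooze_delay_min`, `escalation_modality`,
`dnd_windows`, `office_hours`, `goal_interval_min`, `goal_duration_min`,
`goal_preset`, `sitting_elevated_prob`, `workday_profile`.

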