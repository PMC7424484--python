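# Methods

## Problem and scope

`deskbreak` models the sensing and decision core of a workplace
sedentary-behavior intervention: a wrist-worn accelerometer streams
*counts per epoch* (CPE) — a dimensionless intensity proxy accumulated
over fixed 15-second windows — and the software must (a) decide, epoch
by epoch, whether the wearer is stationary, taking an ambulatory break,
or not wearing the device; (b) remind the wearer to move after
prolonged stationary time, just in time and under the wearer's control;
and (c) produce the daily summaries, goals, rewards and
fidelity/adherence metrics a feasibility trial needs. No hardware,
radio or GUI concerns are in scope; the package operates purely on
epoch-level CSV time series, and a synthetic generator stands in for
the device.

## Activity classification

Stationary behavior (sitting and standing still) is deliberately merged
into one *inactive* class; only ambulatory movement counts as a break.
Two rules, each combining an intensity cut-point with a run-length
requirement, register a break:

* **Burst rule** — `burst_duration` (default `D = 2`) consecutive
  epochs with `cpe > burst_cutoff` (default 25 CPE): walking to another
  room.
* **Sustained rule** — strictly more than `mild_duration` (default
  `P = 20` epochs = 5 min) consecutive epochs with
  `cpe > mild_cutoff` (default 10 CPE): pottering about the room.

All comparisons are strict (`>`), following the cut-point calibration
convention; a constant intensity exactly at a cutoff never trips that
cutoff's rule.

The classifier is a streaming two-mode state machine. In *detection*
mode two candidate runs accumulate; when a rule fires the machine
enters *register* mode and stays there until `exit_duration` (default
`B = 4`) consecutive epochs at or below `exit_cutoff` (default
`A = 10` CPE) occur — one minute of calm ends the break, and the break
ends where that calm begins. The hysteresis suppresses the rapid
inactive/break flips that sporadic hand movements (fidgeting,
gesturing) would otherwise cause.

**Retroactive labeling.** A confirmed break is labeled backwards to the
onset of the enclosing run of epochs above the mild cutoff (since
`burst_cutoff > mild_cutoff`, a burst run always lies inside such a
run). Anchoring on the activity onset rather than on the triggering run
has two virtues: confirmation latency never truncates a break, and
break time is monotone in the parameters — raising any of the four
detection thresholds can only shrink or delete breaks, never grow them.
Anchoring bursts on the burst run instead would break that monotonicity
(removing a burst trigger could let the sustained rule re-label a
*longer* interval). When a mild run also contains a qualifying burst,
the event is typed `BURST`: the more specific trigger wins.

**Sentinel.** `mild_duration = 1` disables the sustained rule entirely,
so mild movement is never recognized as a break; values ≥ 2 act as
genuine duration thresholds. Monotonicity in `mild_duration` therefore
holds on the ≥ 2 regime (1 is equivalent to ∞).

**Nonwear.** Maximal runs of ≥ `nonwear_zero_run` consecutive
zero-count epochs are invalid tracking periods (nonwear or device
failure). The default of 240 epochs (60 min) is the conventional window
in count-based actigraphy. Nonwear overrides both modes: candidate runs
reset at its boundaries and no break event crosses it. Because the CSV
reader fills missing epochs with zeros, extended data loss surfaces
through the same rule.

**Tailoring bounds.** Researchers may adjust sensitivity per
participant within protocol bounds: the burst cutoff may be raised by
at most 5 CPE above its default (for wearers with vigorous wrist
movements), and the burst/sustained durations may be lowered to a floor
of 1 (to recognize quick trips; 1 on the sustained side disabling that
rule). `validate_tailoring` enforces exactly these bounds.

The exit rule's values (`A = 10`, `B = 4`) are this package's choice,
made for symmetry with the mild cutoff and a one-minute confirmation;
both are configurable. The flowchart pairing of cutoffs with durations
is likewise a reconstruction from prose: burst pairs intensity 25 with
duration 2, sustained pairs 10 with 20, exit pairs 10 with 4.

## Reminder engine

An inactivity timer counts consecutive inactive epochs inside office
hours (default 09:00–17:00). Three LED stages fire once per bout at 25,
30 and 40 min by default — the guideline band around the 30-min
prolonged-sitting threshold; no canonical defaults exist, so these are
configurable per the intervention's personalization mandate. Rules:

* the timer resets to zero at the start of any registered break and at
  the office-hours boundary;
* nonwear *suspends* the timer (absence of data is not evidence of a
  break); emissions coming due during nonwear are logged as
  `SUPPRESSED_NONWEAR` and retried when wear resumes;
* a snooze postpones the pending reminder by `snooze_delay_min`
  (default 5); after `snooze_limit` (default 3) snoozes in one bout the
  next emission escalates to a vibratory wrist reminder
  (`stage = ESCALATED`), after which snoozing is disabled for the rest
  of the bout — so an escalation is always preceded by exactly
  `snooze_limit` snoozes;
* emissions inside a do-not-disturb window are logged as
  `SUPPRESSED_DND` and re-queued for the end of the window;
* stages run independently on the shared timer: a snooze cycle on one
  stage does not delay the later stages.

Snoozed emissions count as delivered in the fidelity metric (the
reminder reached the user); suppressed ones do not.

`UserResponseScript` scripts the wearer: one policy
(`SNOOZE`/`COMPLY`/`IGNORE`) per actionable emission.
`simulate_compliance` closes the loop for simulation studies: each
`COMPLY` injects a walking-range bout `comply_latency_epochs` after its
prompt and the trace is re-classified; because injections only affect
later epochs, processing them in time order converges.

## Summaries, goals, rewards, fidelity

Daily summaries cover office-hour epochs only; `valid = inactive +
break` epochs (nonwear excluded). The longest inactive bout is the
longest uninterrupted inactive run — nonwear splits a run, since the
data cannot attest the wearer stayed seated through it.

A goal (`break_interval_min`, `break_duration_min`; presets `EVERY_30`
= 2-min break per 30 min, `EVERY_60` = 5-min break per 60 min, from the
published recommendation band) is evaluated with a sitting clock: only
breaks at least as long as the goal duration reset it; shorter breaks
neither advance nor reset it, and nonwear suspends it. The goal is met
iff the clock never exceeds the interval. This makes relaxation
monotone: widening the interval or shortening the duration requirement
can never turn a met goal into a missed one.

Rewards: a `GOAL_BADGE` per goal-met day; an `IMPROVEMENT_TROPHY` when
a day beats the two-week-baseline medians on *both* measures — longest
inactive bout strictly below the baseline median and break count
strictly above it. No quantitative improvement rule is canonical; the
median-comparison rule is this package's stand-in, chosen for
robustness and auditability, and is isolated behind
`BaselineStats`/`award_rewards` so alternatives can be swapped.

Fidelity: percentage of tracked epochs that are valid, and percentage
of prompt emissions that reached the user (100.0 when no emission
occurred at all); adherence: distinct days of use per logged function.

## Synthetic generator

The generator renders scripted schedules of five activity classes into
CPE traces using the calibrated intensity signatures: sitting 0–5 CPE
with a 10% chance of the occasional 6–10 band (the 0.9/0.1 split
quantifies "5 or less most of the time, 5–10 occasionally" and is
configurable), standing still 0–5 (classified with sitting), mild
ambulation 10–25, walking 23–30, nonwear 0. The mild/walking overlap is
preserved deliberately — the calibrated signatures overlap. All draws
are integer draws from a single `numpy` generator seeded by the script,
so traces are bit-reproducible across platforms.

Three 8-hour (1920-epoch) workday presets serve as study conditions:
`prolonged-sitter` (sitting blocks of 150–220 epochs, brief walks),
`regular-breaker` (a 22–28-epoch walking bout after every 90–100 epochs
of sitting — comfortably one sustained break per half hour), and
`nonwear-heavy` (a 260–320-epoch zero block mid-day). Real office
dwell-time distributions are not modeled — no empirical distributions
exist to calibrate against — so passing tests demonstrate correctness
of the algorithms on their defining conditions, not accuracy on real
office data. Note that a walking bout is only *guaranteed* to register
if it outlasts the sustained threshold: walking epochs always exceed
the mild cutoff, but need not exceed the burst cutoff (the 23–30 range
straddles 25), so the exact-recovery guarantee used in testing scripts
bouts of ≥ 21 epochs separated by ≥ 4 sitting epochs.

## Numerical and interface choices

* Epoch length defaults to 15 s (20 epochs = 5 min) and is
  configurable; all defaults assume it. Prompt timings must be whole
  numbers of epochs.
* Timestamps are timezone-naive local; intervals half-open
  `[start, end)`; day boundary at midnight.
* Missing CSV epochs are zero-filled and counted (`n_gap_filled`,
  logged), folding technology failure into the nonwear rule.
* Determinism: identical seeds and configs reproduce byte-identical
  pipeline outputs; `deskbreak run` writes a manifest with config,
  seed and SHA-256 digests to prove it.
* Problem sizes in the test-suite property ensembles (1,000 random
  series of ≤ 500 epochs for oracle equivalence; 500 pairs for
  monotonicity; 200 scripts for label recovery) were chosen to sweep
  all parameter corners while keeping the suite fast.

## Known limitations

* Posture (sitting vs standing) is not discriminated — by design, the
  target behavior is stationary time.
* No energy-expenditure estimation and no learned classifier; the
  rules are fixed-threshold by construction.
* The register-exit parameters and the reward improvement rule have no
  canonical published values; both are documented package choices.
* The generator emulates epoch-count statistics only; conclusions
  about raw-signal processing are out of scope.
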