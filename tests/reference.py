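"""Brute-force run-length reference for the break classifier.

Independent oracle used by the equivalence tests: instead of the
streaming two-mode state machine, it run-length-encodes the series with
``itertools.groupby`` and window sums and applies the burst, sustained,
exit and nonwear rules directly to maximal runs.
"""

from itertools import groupby

import numpy as np

from deskbreak.classifier import (
    ActivityState,
    BreakEvent,
    BreakType,
    ClassifierParams,
)


def _maximal_runs(flags):
    """Yield (start, end) of maximal True runs of a boolean sequence."""
    pos = 0
    for value, group in groupby(flags):
        n = len(list(group))
        if value:
            yield pos, pos + n
        pos += n


def oracle_nonwear(cpe: np.ndarray, params: ClassifierParams):
    return [
        (s, e)
        for s, e in _maximal_runs([v == 0 for v in cpe])
        if e - s >= params.nonwear_zero_run
    ]


def _first_exit(cpe, lo, hi, params):
    """First index in [lo, hi) starting a run of exit_duration epochs <= A."""
    window = params.exit_duration
    below = np.asarray([v <= params.exit_cutoff for v in cpe], dtype=int)
    for s in range(lo, hi - window + 1):
        if below[s : s + window].sum() == window:
            return s
    return None


def _segment_events(cpe, lo, hi, params):
    events = []
    pos = lo
    while pos < hi:
        # candidate triggers from maximal runs at/after pos
        triggers = []  # (trigger index, priority, run start, type)
        for s, e in _maximal_runs([v > params.burst_cutoff for v in cpe[pos:hi]]):
            if e - s >= params.burst_duration:
                triggers.append((pos + s + params.burst_duration - 1, 0,
                                 BreakType.BURST))
        if params.mild_duration > 1:
            for s, e in _maximal_runs(
                [v > params.mild_cutoff for v in cpe[pos:hi]]
            ):
                if e - s >= params.mild_duration + 1:
                    triggers.append((pos + s + params.mild_duration, 1,
                                     BreakType.SUSTAINED))
        if not triggers:
            break
        trig_idx, _, trig_type = min(triggers)
        # break start: onset of the enclosing above-mild-cutoff run
        b_start = trig_idx
        while b_start > pos and cpe[b_start - 1] > params.mild_cutoff:
            b_start -= 1
        exit_start = _first_exit(cpe, trig_idx + 1, hi, params)
        if exit_start is None:
            b_end, nxt = hi, hi
        else:
            b_end, nxt = exit_start, exit_start + params.exit_duration
        events.append(
            BreakEvent(b_start, b_end, trig_type,
                       int(max(cpe[b_start:b_end])))
        )
        pos = nxt
    return events


def oracle_classify(cpe, params: ClassifierParams):
    """Reference classification: (states, events), same contract as classify."""
    cpe = np.asarray(cpe)
    n = len(cpe)
    states = [ActivityState.INACTIVE] * n
    events = []
    nonwear = oracle_nonwear(cpe, params)
    for s, e in nonwear:
        for i in range(s, e):
            states[i] = ActivityState.NONWEAR
    seg_lo = 0
    for nw_s, nw_e in nonwear + [(n, n)]:
        if nw_s > seg_lo:
            events.extend(_segment_events(cpe, seg_lo, nw_s, params))
        seg_lo = nw_e
    for ev in events:
        for i in range(ev.start, ev.end):
            states[i] = ActivityState.BREAK
    return states, events
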