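"""Two-session emotional stimulus-response paradigm.

Each session consists of 20 trials. A trial is a 1 s trial-number display,
then five repetitions of (warning 0.5 s, anticipation 2 s, target 2 s,
feedback 0.5 s) = 25 s of stimulus-response task, then a 35 s rest, so a
trial period is 61 s and a session spans exactly 20 x 61 = 1220 s.

Targets are emotional images. In session 1 the warning face is positive and
exactly 30 of the 100 target events are positive; in session 2 the warning
face is negative and exactly 30 of 100 targets are negative. The valence
sequence is a seeded random permutation, so counts are exact by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

TRIAL_NUMBER_S = 1.0
WARNING_S = 0.5
ANTICIPATION_S = 2.0
TARGET_S = 2.0
FEEDBACK_S = 0.5
REST_S = 35.0
N_TRIALS = 20
N_REPS = 5

REP_S = WARNING_S + ANTICIPATION_S + TARGET_S + FEEDBACK_S  # 5 s
TRIAL_PERIOD_S = TRIAL_NUMBER_S + N_REPS * REP_S + REST_S  # 61 s
SESSION_SPAN_S = N_TRIALS * TRIAL_PERIOD_S  # 1220 s

MINORITY_FRACTION = 0.3  # design ratio of session-congruent target images

EVENT_KINDS = ("trial_number", "warning", "anticipation", "target", "feedback", "rest")


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    kind: str
    valence: str  # "positive" | "negative" | "none"
    trial_index: int  # 1..20
    rep_index: Optional[int]  # 1..5 for within-repetition events, None otherwise


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered, gap-free event list for one session."""

    session_id: int
    events: tuple[Event, ...]

    @property
    def target_events(self) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.kind == "target")

    @property
    def span_s(self) -> float:
        last = self.events[-1]
        return last.onset_s + last.duration_s

    def to_frame(self) -> pd.DataFrame:
        """Events as a BIDS-style table (onset, duration, kind, valence, trial, rep)."""
        return pd.DataFrame(
            {
                "onset": [e.onset_s for e in self.events],
                "duration": [e.duration_s for e in self.events],
                "kind": [e.kind for e in self.events],
                "valence": [e.valence for e in self.events],
                "trial": [e.trial_index for e in self.events],
                "rep": [0 if e.rep_index is None else e.rep_index for e in self.events],
            }
        )


def build_session_schedule(session_id: int, seed: int) -> StimulusSchedule:
    """Construct the seeded stimulus schedule for one session.

    The 100 target events receive a random permutation of valences with an
    exact 30/70 split; the 30% minority class matches the session's warning
    face (positive in session 1, negative in session 2).
    """
    if session_id not in (1, 2):
        raise ValueError(f"session_id must be 1 or 2, got {session_id!r}")
    rng = np.random.default_rng(seed)

    minority = "positive" if session_id == 1 else "negative"
    majority = "negative" if session_id == 1 else "positive"
    n_targets = N_TRIALS * N_REPS
    n_minority = round(MINORITY_FRACTION * n_targets)
    valences = np.array([minority] * n_minority + [majority] * (n_targets - n_minority))
    valences = valences[rng.permutation(n_targets)]

    events: list[Event] = []
    k = 0
    t = 0.0
    for trial in range(1, N_TRIALS + 1):
        events.append(Event(t, TRIAL_NUMBER_S, "trial_number", "none", trial, None))
        t += TRIAL_NUMBER_S
        for rep in range(1, N_REPS + 1):
            events.append(Event(t, WARNING_S, "warning", minority, trial, rep))
            t += WARNING_S
            events.append(Event(t, ANTICIPATION_S, "anticipation", "none", trial, rep))
            t += ANTICIPATION_S
            events.append(Event(t, TARGET_S, "target", str(valences[k]), trial, rep))
            t += TARGET_S
            k += 1
            events.append(Event(t, FEEDBACK_S, "feedback", "none", trial, rep))
            t += FEEDBACK_S
        events.append(Event(t, REST_S, "rest", "none", trial, None))
        t += REST_S
    return StimulusSchedule(session_id=session_id, events=tuple(events))


def trial_onsets(schedule: StimulusSchedule) -> list[float]:
    """Task onset per trial: start of the trial's first warning stimulus.

    The 1 s trial-number display precedes it, so onsets are 1.0, 62.0, ...
    at the 61 s trial period. The [-1, 60] s epoch around this onset then
    spans the 25 s stimulus-response task plus the 35 s rest.
    """
    onsets = [
        e.onset_s for e in schedule.events if e.kind == "warning" and e.rep_index == 1
    ]
    if len(onsets) != N_TRIALS:
        raise ValueError(f"schedule has {len(onsets)} trials, expected {N_TRIALS}")
    return onsets


def target_boxcar(schedule: StimulusSchedule, fs_hz: float, n_samples: int) -> np.ndarray:
    """0/1 stimulation vector that is 1 during every target display."""
    box = np.zeros(n_samples)
    for e in schedule.target_events:
        i0 = int(np.floor(e.onset_s * fs_hz))
        i1 = min(int(np.floor((e.onset_s + e.duration_s) * fs_hz)), n_samples)
        box[i0:i1] = 1.0
    return box


def write_events(schedule: StimulusSchedule, path) -> None:
    """Write the schedule as a tab-separated event file (BIDS events.tsv style)."""
    df = schedule.to_frame()
    df.insert(0, "session", schedule.session_id)
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> StimulusSchedule:
    """Read a schedule written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t")
    required = {"session", "onset", "duration", "kind", "valence", "trial", "rep"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event file missing columns: {sorted(missing)}")
    session_id = int(df["session"].iloc[0])
    events = tuple(
        Event(
            onset_s=float(r.onset),
            duration_s=float(r.duration),
            kind=str(r.kind),
            valence=str(r.valence),
            trial_index=int(r.trial),
            rep_index=None if int(r.rep) == 0 else int(r.rep),
        )
        for r in df.itertuples()
    )
    return StimulusSchedule(session_id=session_id, events=events)
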