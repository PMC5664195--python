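"""Experimental paradigm: the mental-task battery and its trial schedule.

A subject performs 7 covert mental tasks (mental rotation ROT, word generation
WORD, mental subtraction SUB, mental singing SING, mental navigation NAV,
motor imagery MI, face imagery FACE).  A session consists of 4 subsessions;
within a subsession each task is repeated 4 times in seeded-random order
(28 trials).  Every trial is a 3 s cue, 15 s of task execution, then a rest
drawn uniformly from [10, 15] s; each subsession opens and closes with a 30 s
baseline.  Three sessions give 336 trials per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = ["TASKS", "TASK_GROUPS", "ParadigmSpec", "TrialSchedule", "generate_schedule"]

TASKS: tuple[str, ...] = ("ROT", "WORD", "SUB", "SING", "NAV", "MI", "FACE")

#: Task taxonomy: problem-solving tasks, internally animated imagery, static imagery.
TASK_GROUPS: dict[str, tuple[str, ...]] = {
    "brain_teaser": ("ROT", "WORD", "SUB"),
    "dynamic_imagery": ("SING", "NAV", "MI"),
    "static_imagery": ("FACE",),
}


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing and repetition structure of the recording paradigm."""

    tasks: tuple[str, ...] = TASKS
    reps_per_subsession: int = 4
    n_subsessions: int = 4
    n_sessions: int = 3
    cue_s: float = 3.0
    task_s: float = 15.0
    rest_min_s: float = 10.0
    rest_max_s: float = 15.0
    baseline_s: float = 30.0

    def __post_init__(self) -> None:
        if len(self.tasks) < 1 or len(set(self.tasks)) != len(self.tasks):
            raise ConfigurationError("tasks must be a non-empty set of unique labels")
        for name in ("reps_per_subsession", "n_subsessions", "n_sessions"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in ("cue_s", "task_s", "rest_min_s", "rest_max_s", "baseline_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive duration")
        if self.rest_min_s > self.rest_max_s:
            raise ConfigurationError("rest_min_s must not exceed rest_max_s")

    @property
    def trials_per_subsession(self) -> int:
        return len(self.tasks) * self.reps_per_subsession

    @property
    def total_trials(self) -> int:
        return self.trials_per_subsession * self.n_subsessions * self.n_sessions


@dataclass
class TrialSchedule:
    """Ordered trials plus the temporal layout of subsessions within sessions.

    ``trials`` columns: session, subsession, onset_s (task onset measured from
    the start of its subsession), task.  ``spans`` columns: session,
    subsession, start_s (subsession start within the session recording),
    duration_s.
    """

    trials: pd.DataFrame
    spans: pd.DataFrame
    task_s: float = 15.0
    cue_s: float = 3.0

    @property
    def sessions(self) -> list[int]:
        return sorted(self.spans["session"].unique().tolist())

    @property
    def tasks(self) -> list[str]:
        return sorted(self.trials["task"].unique().tolist())

    def session_view(self, session: int) -> "TrialSchedule":
        """Restrict the schedule to one session (recording)."""
        t = self.trials[self.trials["session"] == session].reset_index(drop=True)
        s = self.spans[self.spans["session"] == session].reset_index(drop=True)
        if s.empty:
            raise ConfigurationError(f"session {session} not present in schedule")
        return TrialSchedule(t, s, self.task_s, self.cue_s)

    def session_duration(self, session: int) -> float:
        s = self.spans[self.spans["session"] == session]
        if s.empty:
            raise ConfigurationError(f"session {session} not present in schedule")
        return float((s["start_s"] + s["duration_s"]).max())

    def absolute_trials(self, session: int) -> pd.DataFrame:
        """Trials of one session with onsets measured from the recording start."""
        t = self.trials[self.trials["session"] == session].copy()
        starts = self.spans.set_index(["session", "subsession"])["start_s"]
        offs = [starts.loc[(session, sub)] for sub in t["subsession"]]
        t["onset_abs_s"] = t["onset_s"].to_numpy() + np.asarray(offs)
        return t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.trials)


def generate_schedule(paradigm: ParadigmSpec, seed: int) -> TrialSchedule:
    """Draw a full seeded trial schedule for one subject.

    Within each subsession the task multiset (each task repeated
    ``reps_per_subsession`` times) is randomly permuted, and every trial's rest
    is drawn uniformly from [rest_min_s, rest_max_s].  Identical (paradigm,
    seed) inputs give identical schedules.
    """
    rng = np.random.default_rng(int(seed))
    rows: list[tuple[int, int, float, str]] = []
    span_rows: list[tuple[int, int, float, float]] = []
    multiset = np.repeat(np.asarray(paradigm.tasks, dtype=object), paradigm.reps_per_subsession)

    for sess in range(paradigm.n_sessions):
        t_session = 0.0
        for sub in range(paradigm.n_subsessions):
            order = rng.permutation(multiset)
            rests = rng.uniform(paradigm.rest_min_s, paradigm.rest_max_s, size=len(order))
            t = paradigm.baseline_s
            for task, rest in zip(order, rests):
                onset = t + paradigm.cue_s
                rows.append((sess, sub, onset, str(task)))
                t = onset + paradigm.task_s + rest
            duration = t + paradigm.baseline_s
            span_rows.append((sess, sub, t_session, duration))
            t_session += duration

    trials = pd.DataFrame(rows, columns=["session", "subsession", "onset_s", "task"])
    spans = pd.DataFrame(span_rows, columns=["session", "subsession", "start_s", "duration_s"])
    return TrialSchedule(trials, spans, paradigm.task_s, paradigm.cue_s)
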