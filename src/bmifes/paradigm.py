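"""Cue paradigms and trial segmentation.

Two visually cued protocols are modelled:

* **Motor imagery** — per run, rest and imagery cycles alternate (starting
  with rest); each cycle is 3 s fixation cross + 2 s task cue + the task
  period itself (10 s imagery, 30 s rest by default).  Four runs of four
  cycles per class give 160 s of imagery and 480 s of rest.
* **Movement intention** — per run, relax and movement tasks alternate; each
  task is 3 s cue + 7 s performance, and only the 4 s between seconds 4.5 and
  8.5 of the 10-s task (the ``used_data`` sub-window) feeds the classifier,
  keeping clear of cue-evoked potentials and of the movement-bracketing
  ERD/ERS transients.

Trials are 1-s windows with 500 ms overlap, aligned to period onset and fully
inside their period, so 10-s and 30-s periods yield 19 and 57 windows.
Windows are half-open ``[t, t+w)`` with 0-based time in seconds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .montage_io import EEGRecording, Event, EventList
from .preprocess import window_normalize

__all__ = [
    "ParadigmSchedule",
    "Trial",
    "TrialSet",
    "build_mi_schedule",
    "build_intention_schedule",
    "segment_trials",
    "window_count",
]

logger = logging.getLogger(__name__)

#: Labels that carry a classification class, and the class they map to.
_PERIOD_CLASS = {"mi_task": "task", "move_task": "task", "rest": "rest"}


@dataclass
class ParadigmSchedule:
    """Timed cue events for one session; events carry a run index."""

    events: list[Event] = field(default_factory=list)
    paradigm: str = "motor_imagery"

    def __iter__(self):
        return iter(self.events)

    @property
    def runs(self) -> list[int]:
        return sorted({e.run for e in self.events})

    @property
    def duration(self) -> float:
        return max((e.end for e in self.events), default=0.0)

    def with_label(self, *labels: str) -> list[Event]:
        return [e for e in self.events if e.label in labels]

    def class_periods(self) -> list[tuple[Event, str]]:
        """The (event, class) pairs that trials are cut from.

        When ``used_data`` sub-windows are present (intention protocol) only
        those are segmented, labelled by their enclosing task/rest period;
        otherwise the task/rest periods themselves are used.
        """
        used = self.with_label("used_data")
        if not used:
            return [(e, _PERIOD_CLASS[e.label])
                    for e in self.events if e.label in _PERIOD_CLASS]
        parents = [e for e in self.events if e.label in _PERIOD_CLASS]
        out = []
        for u in used:
            host = [p for p in parents
                    if p.run == u.run and p.onset - 1e-9 <= u.onset
                    and u.end <= p.end + 1e-9]
            if len(host) != 1:
                raise ValueError(
                    f"used_data at t={u.onset} not inside exactly one period")
            out.append((u, _PERIOD_CLASS[host[0].label]))
        return out

    def to_event_list(self) -> EventList:
        return EventList(events=list(self.events))


@dataclass
class Trial:
    """One labelled 1-s analysis window (channels x samples, normalised)."""

    samples: np.ndarray
    label: str
    run: int
    t0: float
    period_id: int = -1


@dataclass
class TrialSet:
    trials: list[Trial]
    fs: float
    ch_names: list[str]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.trials:
            out[t.label] = out.get(t.label, 0) + 1
        return out

    @property
    def runs(self) -> list[int]:
        return sorted({t.run for t in self.trials})

    def subset(self, indices) -> "TrialSet":
        return TrialSet([self.trials[i] for i in indices], self.fs,
                        list(self.ch_names))


# --------------------------------------------------------------------------
# schedule builders
# --------------------------------------------------------------------------

def build_mi_schedule(runs: int = 4, reps_per_task: int = 4,
                      mi_dur: float = 10.0, rest_dur: float = 30.0,
                      cross_dur: float = 3.0, cue_dur: float = 2.0,
                      gap_between_runs: float = 5.0) -> ParadigmSchedule:
    """Motor-imagery paradigm: alternating rest/imagery cycles per run.

    Each cycle is ``cross_dur`` fixation + ``cue_dur`` task cue + the task
    period.  Defaults give 160 s of imagery and 480 s of rest over 4 runs.
    """
    for name, v in [("mi_dur", mi_dur), ("rest_dur", rest_dur),
                    ("cross_dur", cross_dur), ("cue_dur", cue_dur)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    events: list[Event] = []
    t = 0.0
    for r in range(runs):
        for _ in range(reps_per_task):
            for label, dur in (("rest", rest_dur), ("mi_task", mi_dur)):
                events.append(Event(t, cross_dur, "cross", r))
                t += cross_dur
                events.append(Event(t, cue_dur, "cue", r))
                t += cue_dur
                events.append(Event(t, dur, label, r))
                t += dur
        t += gap_between_runs
    return ParadigmSchedule(events=events, paradigm="motor_imagery")


def build_intention_schedule(runs: int = 6, moves_per_run: int = 10,
                             cue_dur: float = 3.0, perform_dur: float = 7.0,
                             used_start: float = 4.5, used_dur: float = 4.0,
                             gap_between_runs: float = 5.0) -> ParadigmSchedule:
    """Movement-intention paradigm with ``used_data`` sub-windows.

    Per run, ``moves_per_run`` movement tasks (alternating extension and
    flexion, hence the even count) are interspersed with as many relax
    periods.  Each task lasts ``cue_dur + perform_dur`` seconds; the 4-s
    ``used_data`` window starts ``used_start`` seconds after task onset.
    """
    if moves_per_run % 2:
        raise ValueError("moves_per_run must be even (ext/flex alternate)")
    task_dur = cue_dur + perform_dur
    if used_start + used_dur > task_dur + 1e-9:
        raise ValueError("used_data window extends past the task")
    events: list[Event] = []
    t = 0.0
    for r in range(runs):
        for m in range(moves_per_run):
            for label in ("rest", "move_task"):
                events.append(Event(t, cue_dur, "cue", r))
                events.append(Event(t + cue_dur, perform_dur, label, r))
                events.append(Event(t + used_start, used_dur, "used_data", r))
                t += task_dur
        t += gap_between_runs
    # keep onsets nondecreasing (used_data interleaves with the next cue)
    events.sort(key=lambda e: (e.onset, e.label))
    return ParadigmSchedule(events=events, paradigm="movement_intention")


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

def window_count(period_dur: float, win: float = 1.0,
                 overlap: float = 0.5) -> int:
    """Number of ``win``-s windows with the given overlap inside a period."""
    if period_dur < win:
        return 0
    step = win - overlap
    return int(math.floor((period_dur - win) / step + 1e-9)) + 1


def _block_starts(ev: Event, block: float) -> list[tuple[float, float]]:
    """Split a period into consecutive ``block``-second sub-blocks.

    The protocols repeat in 10-s units (a 30-s rest period is three of them),
    and the printed trial arithmetic counts windows per unit — 19 per 10-s
    block, hence 57 for a 30-s period — so windows never straddle a block
    boundary.
    """
    out = []
    t = ev.onset
    while t < ev.end - 1e-9:
        out.append((t, min(block, ev.end - t)))
        t += block
    return out


def segment_trials(rec: EEGRecording, sched: ParadigmSchedule,
                   win: float = 1.0, overlap: float = 0.5,
                   normalize: bool = True,
                   min_start: float = 0.5, block: float = 10.0) -> TrialSet:
    """Cut labelled, per-window z-scored trials out of a recording.

    Windows are aligned to block onset within each period (periods longer
    than ``block`` seconds are segmented in consecutive ``block``-sized
    sub-blocks, the protocol's repetition unit); a trailing remainder shorter
    than ``win`` is dropped.  Windows starting before ``min_start`` seconds
    are discarded so the causal filters' start-up transient never enters a
    trial.
    """
    if win <= overlap:
        raise ValueError("window must be longer than the overlap")
    n_win = int(round(win * rec.fs))
    step = win - overlap
    trials: list[Trial] = []
    for pid, (ev, cls) in enumerate(sched.class_periods()):
        starts = [(b0 + i * step)
                  for b0, bdur in _block_starts(ev, block)
                  for i in range(window_count(bdur, win, overlap))]
        if not starts:
            logger.warning("period at t=%.1f s shorter than %.1f s window",
                           ev.onset, win)
            continue
        for t0 in starts:
            if t0 < min_start:
                continue
            s0 = int(round((t0 - rec.start_time) * rec.fs))
            if s0 < 0 or s0 + n_win > rec.n_samples:
                raise ValueError(
                    f"schedule window [{t0}, {t0 + win}) outside recording")
            sl = rec.data[:, s0 : s0 + n_win]
            if normalize:
                sl = window_normalize(sl, rec.labels)
            else:
                sl = sl.copy()
            trials.append(Trial(sl, cls, ev.run, t0, period_id=pid))
    return TrialSet(trials, rec.fs, list(rec.labels))
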