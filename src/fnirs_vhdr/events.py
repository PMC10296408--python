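"""Event schedules for the event-related visual stimulation design.

The default design presents 20 patterned-stimulus trials (STIM) and 20
zero-contrast mock trials (MOCK), each 5 s on followed by 10 s off, pseudo
randomly interleaved — a 10-minute block of 40 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STIM = "STIM"
MOCK = "MOCK"


@dataclass(frozen=True)
class Trial:
    onset_s: float
    on_duration_s: float
    off_duration_s: float
    condition: str

    def __post_init__(self):
        if self.condition not in (STIM, MOCK):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class EventSchedule:
    """Ordered, non-overlapping stimulus/mock trials."""

    trials: list[Trial]
    total_duration_s: float
    seed: int | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        end = -np.inf
        total = 0.0
        for tr in self.trials:
            if tr.onset_s < end - 1e-9:
                raise ValueError("trials overlap or are unsorted")
            end = tr.onset_s + tr.on_duration_s + tr.off_duration_s
            total += tr.on_duration_s + tr.off_duration_s
        if abs(total - self.total_duration_s) > 1e-6:
            raise ValueError("total_duration_s inconsistent with trial durations")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def count(self, condition: str) -> int:
        return sum(1 for t in self.trials if t.condition == condition)

    def onsets(self, condition: str | None = None) -> np.ndarray:
        return np.array(
            [t.onset_s for t in self.trials if condition is None or t.condition == condition]
        )

    def shifted(self, offset_s: float) -> "EventSchedule":
        """Return a copy with every onset delayed by ``offset_s``."""
        trials = [
            Trial(t.onset_s + offset_s, t.on_duration_s, t.off_duration_s, t.condition)
            for t in self.trials
        ]
        return EventSchedule(trials, self.total_duration_s, self.seed)


def generate_event_schedule(
    n_stim: int,
    n_mock: int,
    on_s: float = 5.0,
    off_s: float = 10.0,
    seed: int = 0,
) -> EventSchedule:
    """Generate a seeded pseudo-random interleaving of STIM and MOCK trials.

    Trials are back-to-back: each occupies ``on_s + off_s`` seconds, so the
    schedule's total duration is ``(n_stim + n_mock) * (on_s + off_s)``.
    The condition sequence is a uniform shuffle with no run-length constraint.
    """
    if n_stim < 0 or n_mock < 0:
        raise ValueError("trial counts must be non-negative")
    if on_s <= 0 or off_s <= 0:
        raise ValueError("trial durations must be positive")
    rng = np.random.default_rng(seed)
    conditions = np.array([STIM] * n_stim + [MOCK] * n_mock)
    rng.shuffle(conditions)
    trials = []
    t = 0.0
    for cond in conditions:
        trials.append(Trial(t, float(on_s), float(off_s), str(cond)))
        t += on_s + off_s
    return EventSchedule(trials=trials, total_duration_s=float(t), seed=seed)
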