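"""Phase-wise localization of responses and in-between-error intervals.

The 60-s trial is partitioned into four 15-s phases with half-open bins
[0,15), [15,30), [30,45), [45,60); a response belongs to the phase of its
onset.  Error intervals are onset-to-onset gaps between qualifying error
events: consecutive productions of the same repeated word, consecutive
intrusions, or consecutive errors of any type.  Transcripts with fewer than
two qualifying events yield no intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .scoring import (CORRECT, INTRUSION, NONWORD, PERSEVERATION,
                      ScoredResponse)

__all__ = [
    "PhaseSummary",
    "ErrorInterval",
    "INTERVAL_MODES",
    "assign_phase",
    "phase_summary",
    "error_intervals",
    "words_between_errors",
]

N_PHASES = 4
PHASE_LENGTH = 15.0
TRIAL_LENGTH = 60.0

INTERVAL_MODES = ("same_word_perseveration", "intrusion_intrusion", "any_error")


def assign_phase(onset: float, phase_length: float = PHASE_LENGTH,
                 trial_length: float = TRIAL_LENGTH) -> int:
    """1-based phase index of an onset; bins are half-open [a, a + 15)."""
    if onset < 0 or onset >= trial_length:
        raise ValueError(f"onset {onset} outside [0, {trial_length})")
    return int(onset // phase_length) + 1


@dataclass
class PhaseSummary:
    """Per-phase counts: total responses (correct + errors), intrusions
    (non-words folded in), and perseverations."""

    total_responses: np.ndarray
    n_intrusions: np.ndarray
    n_perseverations: np.ndarray

    @property
    def n_correct(self) -> np.ndarray:
        return self.total_responses - self.n_intrusions - self.n_perseverations


def phase_summary(scored: Sequence[ScoredResponse]) -> PhaseSummary:
    total = np.zeros(N_PHASES, dtype=int)
    intr = np.zeros(N_PHASES, dtype=int)
    pers = np.zeros(N_PHASES, dtype=int)
    for r in scored:
        p = assign_phase(r.onset) - 1
        total[p] += 1
        if r.label in (INTRUSION, NONWORD):
            intr[p] += 1
        elif r.label == PERSEVERATION:
            pers[p] += 1
    return PhaseSummary(total_responses=total, n_intrusions=intr,
                        n_perseverations=pers)


@dataclass
class ErrorInterval:
    mode: str
    start_onset: float
    end_onset: float
    n_intervening_correct: int

    @property
    def gap(self) -> float:
        return self.end_onset - self.start_onset


def _count_between(scored: Sequence[ScoredResponse], start: float,
                   end: float) -> int:
    return sum(1 for r in scored
               if r.label == CORRECT and start < r.onset < end)


def error_intervals(
    scored: Sequence[ScoredResponse], mode: str
) -> list[ErrorInterval]:
    """Onset-to-onset intervals between qualifying error events.

    ``same_word_perseveration``: for each repeated word, consecutive
    occurrence pairs (first production -> first repetition, then repetition
    to repetition).  ``intrusion_intrusion`` and ``any_error``: intervals
    between consecutive qualifying events in onset order; transcripts with a
    single qualifying event are excluded (no intervals).
    """
    if mode not in INTERVAL_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {INTERVAL_MODES}")
    pairs: list[tuple[float, float]] = []
    if mode == "same_word_perseveration":
        occurrences: dict[str, list[float]] = {}
        for r in scored:
            if r.word:
                occurrences.setdefault(r.word, []).append(r.onset)
        for onsets in occurrences.values():
            pairs.extend(zip(onsets, onsets[1:]))
        pairs.sort()
    else:
        if mode == "intrusion_intrusion":
            qualifying = {INTRUSION, NONWORD}
        else:
            qualifying = {INTRUSION, NONWORD, PERSEVERATION}
        events = sorted(r.onset for r in scored if r.label in qualifying)
        pairs = list(zip(events, events[1:]))
    return [
        ErrorInterval(
            mode=mode,
            start_onset=a,
            end_onset=b,
            n_intervening_correct=_count_between(scored, a, b),
        )
        for a, b in pairs
    ]


def words_between_errors(
    scored: Sequence[ScoredResponse], interval: ErrorInterval
) -> int:
    """Correct responses with onsets strictly inside the interval."""
    return _count_between(scored, interval.start_onset, interval.end_onset)
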