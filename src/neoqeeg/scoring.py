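"""Ordinal scoring: hourly amplitude-based EEG scores and neuropathology.

Two scoring systems used in neonatal hypoxic-ischemic encephalopathy models:

* **EEG score** — the first 10 min of each post-insult hour is scored from
  its background amplitude (continuous high-amplitude activity scores low,
  suppressed/isoelectric activity scores high) with 2 extra points whenever
  a seizure occurred anywhere in that hour; hourly scores are summed over
  the observation period.
* **Cortical neuropathology score (0–9)** — 40 microscope fields per region
  are labelled with their injury pattern (none < scattered < grouped <
  panlaminar); the region score follows the most severe pattern present and
  the fraction of fields showing it (<20% / 21–50% / >50%).  Subcortical
  damage is expressed as the percentage of damaged neurons.

The exact amplitude-category table is a config artifact; the shipped default
is a reconstruction with four categories (see ``DEFAULT_EEG_SCORE_TABLE``),
consistent with the published category boundaries (>25 µV continuous,
<10 µV suppressed) but not a verbatim published table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy import SeizureEvent
from .recording import EEGRecording


@dataclass(frozen=True)
class AmplitudeCategory:
    """One row of the EEG score table: amplitudes in ``[low, high)`` µV."""

    low_uv: float
    high_uv: float
    score: int
    label: str = ""


@dataclass(frozen=True)
class EEGScoreTable:
    """Amplitude-category → score mapping plus the seizure bonus."""

    categories: tuple[AmplitudeCategory, ...]
    seizure_bonus: int = 2

    def __post_init__(self) -> None:
        cats = sorted(self.categories, key=lambda c: c.low_uv)
        for a, b in zip(cats, cats[1:]):
            if b.low_uv != a.high_uv:
                raise ValueError(
                    f"categories must tile amplitudes without gaps or overlap "
                    f"({a.label or a.score} ends at {a.high_uv}, "
                    f"{b.label or b.score} starts at {b.low_uv})"
                )
        scores = [c.score for c in cats]
        if scores != sorted(scores, reverse=True):
            raise ValueError("scores must strictly decrease with rising amplitude")
        object.__setattr__(self, "categories", tuple(cats))

    def score_for_amplitude(self, amplitude_uv: float) -> int:
        for c in self.categories:
            if c.low_uv <= amplitude_uv < c.high_uv:
                return c.score
        raise ValueError(f"amplitude {amplitude_uv} µV outside table coverage")


#: Reconstructed default: four categories spanning the published boundaries.
DEFAULT_EEG_SCORE_TABLE = EEGScoreTable(
    categories=(
        AmplitudeCategory(25.0, float("inf"), 0, "continuous"),
        AmplitudeCategory(10.0, 25.0, 1, "discontinuous"),
        AmplitudeCategory(2.0, 10.0, 2, "severely depressed"),
        AmplitudeCategory(0.0, 2.0, 3, "isoelectric"),
    ),
    seizure_bonus=2,
)


def epoch_amplitude(
    epoch: EEGRecording, subwindow_s: float = 10.0
) -> float:
    """Robust epoch amplitude: median peak-to-peak over 10 s sub-windows.

    Peak-to-peak is taken per sub-window per lead and the median over all of
    them is returned — a single transient cannot dominate the measure.
    """
    n_sub = int(round(subwindow_s * epoch.fs))
    n = (epoch.n_samples // n_sub) * n_sub
    if n == 0:
        raise ValueError("epoch shorter than one amplitude sub-window")
    x = epoch.data[:, :n].reshape(epoch.n_leads, -1, n_sub)
    ptp = x.max(axis=-1) - x.min(axis=-1)
    return float(np.median(ptp))


def score_eeg_epoch(
    epoch: EEGRecording,
    seizure_present: bool = False,
    table: EEGScoreTable = DEFAULT_EEG_SCORE_TABLE,
) -> int:
    """Score one 10-min epoch: amplitude category plus the seizure bonus."""
    if epoch.n_samples == 0:
        raise ValueError("empty epoch")
    base = table.score_for_amplitude(epoch_amplitude(epoch))
    return base + (table.seizure_bonus if seizure_present else 0)


@dataclass
class ScoreRecord:
    """Collected ordinal scores for one subject/region."""

    hourly_scores: list[int] = field(default_factory=list)
    cortical_score: int | None = None
    damaged_pct: float | None = None

    @property
    def total_eeg_score(self) -> int:
        return total_score(self)


def hourly_scores(
    recording: EEGRecording,
    seizure_events: list[SeizureEvent] | None = None,
    table: EEGScoreTable = DEFAULT_EEG_SCORE_TABLE,
    scored_minutes: float = 10.0,
) -> ScoreRecord:
    """Score the first 10 min of every full hour of the recording.

    The seizure bonus applies to an hour when any detected event intersects
    that hour at all — not only the scored 10 min.
    """
    n_hours = int(recording.duration_s // 3600)
    if n_hours < 1:
        raise ValueError(
            f"recording of {recording.duration_s / 60:.1f} min spans no full hour"
        )
    events = seizure_events or []
    scores = []
    for h in range(n_hours):
        h0, h1 = h * 3600.0, (h + 1) * 3600.0
        epoch = recording.slice_time(h0, h0 + scored_minutes * 60.0)
        seizure = any(e.end_s > h0 and e.start_s < h1 for e in events)
        scores.append(score_eeg_epoch(epoch, seizure_present=seizure, table=table))
    return ScoreRecord(hourly_scores=scores)


def total_score(record: ScoreRecord) -> int:
    """Sum of the hourly EEG scores over the observation period."""
    if not record.hourly_scores:
        raise ValueError("no hourly scores to sum")
    return int(sum(record.hourly_scores))


# --------------------------------------------------------------------------
# neuropathology

PATTERN_SEVERITY = {"none": 0, "scattered": 1, "grouped": 2, "panlaminar": 3}


@dataclass(frozen=True)
class FieldGrid:
    """Injury-pattern label for each microscope field of one region."""

    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("field grid is empty")
        unknown = set(self.patterns) - set(PATTERN_SEVERITY)
        if unknown:
            raise ValueError(f"unknown pattern(s) {sorted(unknown)}")

    @property
    def n_fields(self) -> int:
        return len(self.patterns)


def cortical_score(grid: FieldGrid | tuple[str, ...]) -> int:
    """0–9 neuropathology score from the most severe pattern and its extent.

    Base score by pattern: scattered → 1–3, grouped → 4–6, panlaminar → 7–9;
    within a pattern the level follows the fraction of fields showing exactly
    that pattern: ≤20% (first level), 20–50% (second), >50% (third).  The
    published table's gap between "<20%" and "21–50%" is resolved by
    assigning fractions of exactly 20% (and below) to the lower level.  All
    fields undamaged → 0.
    """
    if not isinstance(grid, FieldGrid):
        grid = FieldGrid(tuple(grid))
    severities = [PATTERN_SEVERITY[p] for p in grid.patterns]
    worst = max(severities)
    if worst == 0:
        return 0
    fraction = severities.count(worst) / grid.n_fields
    if fraction <= 0.20:
        level = 1
    elif fraction <= 0.50:
        level = 2
    else:
        level = 3
    return 3 * (worst - 1) + level


def damaged_percentage(damaged: int, total: int) -> float:
    """Percentage of damaged neurons: ``100 × damaged / total``."""
    if total <= 0:
        raise ValueError("total neuron count must be positive")
    if not 0 <= damaged <= total:
        raise ValueError(f"damaged count {damaged} outside [0, {total}]")
    return 100.0 * damaged / total
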