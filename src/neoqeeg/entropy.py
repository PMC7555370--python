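"""Normalized Shannon spectral entropy and entropy-based seizure detection.

Spectral entropy treats a PSD frame as a probability distribution over
frequency bins: ``p_i = PSD_i / Σ PSD`` and ``H = −Σ p_i log p_i / log K``
with ``K`` bins, so a flat spectrum maps to 1 and a single tone to 0.  Two
scopes are used:

* **InstSpEnt** — instantaneous spectral entropy of the whole 1–30 Hz
  spectrum, one value per sliding-window frame per lead.  Rhythmic activity
  (seizures) concentrates spectral power and drives it down.
* **SpEnt** — entropy restricted to one classical band's bins (δ/θ/α/β), a
  narrower per-band complexity measure.

Traces are thresholded at ``mean − SD`` (sample SD); sustained
below-threshold runs on a majority of leads, confirmed by a rhythmic
spectral peak, are reported as seizure events with their dominant frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .recording import EEGRecording
from .spectral import (
    TOTAL_BAND,
    BandDefinition,
    TimeFrequencyMap,
    sliding_psd,
)


def shannon_spectral_entropy(psd_frame: np.ndarray) -> float:
    """Normalized Shannon entropy of one PSD frame; NaN for an all-zero frame.

    An all-zero frame carries no spectral information: it is reported as
    missing (NaN), never 0, because 0 means *concentrated* power.
    """
    p = np.asarray(psd_frame, dtype=float)
    if p.ndim != 1:
        raise ValueError("psd_frame must be one-dimensional")
    if np.any(p < 0):
        raise ValueError("PSD values must be non-negative")
    return float(_entropy_frames(p[None, :])[0])


def _entropy_frames(psd: np.ndarray) -> np.ndarray:
    """Vectorized entropy over the last axis; NaN where total power is 0."""
    k = psd.shape[-1]
    total = psd.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = psd / total
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        h = -plogp.sum(axis=-1) / np.log(k)
    return np.where(total[..., 0] > 0, h, np.nan)


@dataclass
class EntropyTrace:
    """Per-frame normalized spectral entropy per lead, with optional threshold.

    ``values`` has shape ``(n_leads, n_frames)``; entries are in [0, 1] or
    NaN for zero-power frames.  After :func:`apply_threshold`, ``threshold``
    holds the per-lead ``mean − SD`` level and ``below_mask`` flags frames
    strictly below it.
    """

    values: np.ndarray
    frame_times_s: np.ndarray
    lead_names: tuple[str, ...]
    scope: str = "whole-signal"            # or "band"
    band_name: str | None = None
    threshold: np.ndarray | None = None    # per lead
    below_mask: np.ndarray | None = None   # (n_leads, n_frames)

    def summary(self, mode: str = "mean") -> float:
        """Scalar summary over all leads and frames.

        ``mean`` — mean entropy; ``min`` — lowest instantaneous value;
        ``mean_below_threshold`` — mean of below-threshold frames (requires
        :func:`apply_threshold` first).  All ignore missing frames.
        """
        v = self.values
        if mode == "mean":
            return float(np.nanmean(v))
        if mode == "min":
            return float(np.nanmin(v))
        if mode == "mean_below_threshold":
            if self.below_mask is None:
                raise ValueError("apply_threshold before summarizing below-threshold frames")
            sel = v[self.below_mask]
            return float(np.nanmean(sel)) if sel.size else float("nan")
        raise ValueError(f"unknown summary mode {mode!r}")

    def to_dataframe(self):
        import pandas as pd

        n_l, n_t = self.values.shape
        return pd.DataFrame({
            "lead": np.repeat(self.lead_names, n_t),
            "frame_s": np.tile(self.frame_times_s, n_l),
            "value": self.values.ravel(),
        })


def _trace_from_map(
    tfmap: TimeFrequencyMap, bins: np.ndarray, scope: str, band_name: str | None
) -> EntropyTrace:
    return EntropyTrace(
        values=_entropy_frames(tfmap.psd[:, :, bins]),
        frame_times_s=tfmap.frame_times_s,
        lead_names=tfmap.lead_names,
        scope=scope,
        band_name=band_name,
    )


def inst_spent(
    recording: EEGRecording,
    window_s: float = 30.0,
    step_s: float = 1.0,
    tfmap: TimeFrequencyMap | None = None,
) -> EntropyTrace:
    """Instantaneous spectral entropy of the whole 1–30 Hz spectrum.

    The recording should already be bandpassed to 1–30 Hz; the entropy is
    computed on the bins inside that band regardless.  Pass a precomputed
    ``tfmap`` to reuse a PSD from an earlier stage.
    """
    if tfmap is None:
        tfmap = sliding_psd(recording, window_s=window_s, step_s=step_s)
    bins = tfmap.band_bins(TOTAL_BAND)
    return _trace_from_map(tfmap, bins, "whole-signal", None)


def spent_per_band(
    recording: EEGRecording,
    band: BandDefinition,
    window_s: float = 30.0,
    step_s: float = 1.0,
    tfmap: TimeFrequencyMap | None = None,
) -> EntropyTrace:
    """Spectral entropy restricted to one band's frequency bins."""
    if tfmap is None:
        tfmap = sliding_psd(recording, window_s=window_s, step_s=step_s)
    bins = tfmap.band_bins(band)
    if bins.sum() < 2:
        raise ValueError(
            f"band {band.name} spans {int(bins.sum())} bin(s); entropy needs ≥ 2"
        )
    return _trace_from_map(tfmap, bins, "band", band.name)


def apply_threshold(trace: EntropyTrace) -> EntropyTrace:
    """Attach the ``mean − SD`` threshold (sample SD, per lead) and its mask.

    Frames strictly below threshold are flagged; missing (NaN) frames are
    never flagged.  Requires at least two non-missing values per lead.
    """
    v = trace.values
    n_valid = np.sum(~np.isnan(v), axis=1)
    if np.any(n_valid < 2):
        bad = [trace.lead_names[i] for i in np.where(n_valid < 2)[0]]
        raise ValueError(f"fewer than 2 entropy values on lead(s) {bad}")
    mean = np.nanmean(v, axis=1)
    sd = np.nanstd(v, axis=1, ddof=1)
    threshold = mean - sd
    with np.errstate(invalid="ignore"):
        mask = v < threshold[:, None]
    return EntropyTrace(
        values=v, frame_times_s=trace.frame_times_s,
        lead_names=trace.lead_names, scope=trace.scope,
        band_name=trace.band_name, threshold=threshold, below_mask=mask,
    )


@dataclass(frozen=True)
class SeizureEvent:
    """A detected electrographic seizure."""

    start_s: float
    end_s: float
    dominant_hz: float
    peak_leads: tuple[str, ...]
    mean_entropy: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event end must follow start")


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the entropy-based seizure detector.

    ``min_duration_s`` — shortest reportable event; ``merge_gap_s`` — runs
    separated by at most this are one event; ``min_leads`` — leads that must
    be below threshold simultaneously (None = majority of the montage);
    ``power_floor_uv2`` — total 1–30 Hz power below which a frame is treated
    as suppressed rather than rhythmic (suppressed EEG also lowers entropy);
    ``peak_ratio`` — required peak-to-median ratio of the event-average
    spectrum after whitening by the recording's own median spectrum,
    confirming a rhythmic discharge rather than ordinary colored background.
    """

    min_duration_s: float = 10.0
    merge_gap_s: float = 5.0
    min_leads: int | None = None
    power_floor_uv2: float = 1.0
    peak_ratio: float = 5.0
    window_s: float = 30.0
    step_s: float = 1.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_seizures(
    recording: EEGRecording,
    params: DetectionParams = DetectionParams(),
    tfmap: TimeFrequencyMap | None = None,
) -> list[SeizureEvent]:
    """Detect seizures as sustained low-entropy, rhythmic, multi-lead episodes.

    The recording should be bandpassed to 1–30 Hz first.  Candidate frames
    are those below the per-lead ``mean − SD`` entropy threshold with total
    band power above the floor, on at least ``min_leads`` leads; runs at
    least ``min_duration_s`` long (merged across gaps ≤ ``merge_gap_s``) are
    kept if the event-average spectrum, whitened by the recording's median
    per-bin spectrum (background EEG is itself colored, so an absolute
    peak-to-median test would fire on any delta-dominated segment), has a
    dominant peak at least ``peak_ratio`` times its median.  Event times are
    reported at window
    centers, so a seizure occupying ``[t0, t1]`` in the signal maps onto
    approximately that same interval.
    """
    if tfmap is None:
        tfmap = sliding_psd(recording, window_s=params.window_s, step_s=params.step_s)
    bins = tfmap.band_bins(TOTAL_BAND)
    band_psd = tfmap.psd[:, :, bins]
    freqs = tfmap.freqs_hz[bins]
    power = band_psd.sum(axis=-1) * tfmap.df            # (leads, frames)

    values = _entropy_frames(band_psd)
    n_valid = np.sum(~np.isnan(values), axis=1)
    if not np.any(n_valid >= 2):
        return []  # e.g. an all-zero recording: every frame missing entropy
    # per-lead mean − SD threshold; leads with < 2 valid frames never trigger
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        threshold = np.nanmean(values, axis=1) - np.nanstd(values, axis=1, ddof=1)
        candidate = (values < threshold[:, None]) & (power >= params.power_floor_uv2)
    trace = EntropyTrace(
        values=values, frame_times_s=tfmap.frame_times_s,
        lead_names=tfmap.lead_names, threshold=threshold, below_mask=candidate,
    )

    n_leads = len(tfmap.lead_names)
    k = params.min_leads if params.min_leads is not None else n_leads // 2 + 1
    frame_ok = candidate.sum(axis=0) >= k

    runs = _runs(frame_ok)
    # merge runs separated by short gaps (gap in frames = gap_s / step_s)
    max_gap = int(round(params.merge_gap_s / params.step_s))
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] <= max_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    half_win = params.window_s / 2.0
    # reference spectrum of the recording: per-bin median over frames (robust
    # to the seizure frames themselves), averaged over leads
    background = np.median(band_psd.mean(axis=0), axis=0)
    events: list[SeizureEvent] = []
    for a, b in merged:
        spectrum = band_psd[:, a:b, :].mean(axis=(0, 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(background > 0, spectrum / background, 0.0)
        med = np.median(rel)
        if med <= 0 or rel.max() / med < params.peak_ratio:
            continue
        j = int(np.argmax(spectrum))
        # Boundary refinement: entropy saturates once the rhythm dominates a
        # window, which blurs edges by up to half a window.  Power at the
        # dominant bin instead grows linearly with the window's overlap of the
        # discharge, so the half-maximum crossing sits where a window is half
        # covered — i.e. at the true edge once times are taken at window
        # centers.
        p_dom = band_psd[:, :, j].mean(axis=0)
        lo = max(a - max_gap, 0)
        hi = min(b + max_gap, len(p_dom))
        core = slice(a, b)
        thresh = 0.5 * np.percentile(p_dom[core], 90)
        i_peak = a + int(np.argmax(p_dom[core]))
        a2, b2 = i_peak, i_peak + 1
        while a2 > lo and p_dom[a2 - 1] >= thresh:
            a2 -= 1
        while b2 < hi and p_dom[b2] >= thresh:
            b2 += 1
        start = tfmap.frame_times_s[a2] + half_win
        end = tfmap.frame_times_s[b2 - 1] + params.step_s + half_win
        if end - start < params.min_duration_s:
            continue
        involved = candidate[:, a:b].mean(axis=1) >= 0.5
        peak_leads = tuple(
            name for name, inv in zip(tfmap.lead_names, involved) if inv
        )
        events.append(SeizureEvent(
            start_s=float(start),
            end_s=float(end),
            dominant_hz=float(freqs[j]),
            peak_leads=peak_leads or tuple(tfmap.lead_names),
            mean_entropy=float(np.nanmean(trace.values[:, a2:b2])),
        ))
    return events


def events_to_dataframe(events: list[SeizureEvent]):
    import pandas as pd

    return pd.DataFrame(
        [
            (e.start_s, e.end_s, e.dominant_hz, len(e.peak_leads), e.mean_entropy)
            for e in events
        ],
        columns=["start_s", "end_s", "dominant_hz", "n_leads", "mean_entropy"],
    )
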