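"""Flash visual-evoked-potential epoching, averaging and P100 metrics.

VEPs are evoked by 1 Hz flashes; at least 100 trials are averaged to obtain
a stable waveform, and the P100 component (the positive deflection near
100 ms post-stimulus on the occipital leads O1/O2) is characterized by its
latency and amplitude, optionally expressed relative to a pre-insult
baseline session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .recording import EEGRecording

OCCIPITAL_LEADS = ("O1", "O2")
DEFAULT_EPOCH_MS = (-50.0, 500.0)
DEFAULT_SEARCH_MS = (50.0, 200.0)


@dataclass
class TrialSet:
    """Epoched trials: ``data`` of shape ``(n_leads, n_trials, n_samples)``.

    ``times_ms`` is relative to the stimulus (0 = flash); ``n_skipped``
    counts triggers whose epoch fell outside the recording.
    """

    data: np.ndarray
    times_ms: np.ndarray
    lead_names: tuple[str, ...]
    n_skipped: int = 0

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]


@dataclass
class VEPResult:
    """Average VEP waveform and P100 metrics.

    ``waveform`` is the grand mean (µV) on the ``times_ms`` grid.  Metrics
    are NaN until :func:`p100_metrics` runs; normalized metrics are ratios
    to a baseline session and NaN until :func:`normalize_vep`.
    """

    waveform: np.ndarray
    times_ms: np.ndarray
    n_trials: int
    leads_used: tuple[str, ...]
    p100_latency_ms: float = float("nan")
    p100_amplitude_uv: float = float("nan")
    normalized_latency: float = float("nan")
    normalized_amplitude: float = float("nan")

    @property
    def has_metrics(self) -> bool:
        return not (np.isnan(self.p100_latency_ms) or np.isnan(self.p100_amplitude_uv))


def extract_trials(
    recording: EEGRecording,
    triggers_s: np.ndarray,
    window_ms: tuple[float, float] = DEFAULT_EPOCH_MS,
    leads: tuple[str, ...] | None = None,
    baseline_correct: bool = True,
) -> TrialSet:
    """Cut one epoch per trigger per lead, optionally baseline-corrected.

    Baseline correction subtracts the pre-stimulus mean of each epoch.
    Triggers whose epoch would run past either end of the recording are
    skipped and counted in ``n_skipped``.
    """
    pre, post = window_ms
    if post <= pre:
        raise ValueError("epoch window must have post > pre")
    if leads is None:
        leads = recording.lead_names
    fs = recording.fs
    i_pre = int(round(pre * fs / 1000.0))
    i_post = int(round(post * fs / 1000.0))
    n_samp = i_post - i_pre
    times_ms = (i_pre + np.arange(n_samp)) * 1000.0 / fs
    rows = [recording.lead_index(name) for name in leads]

    epochs = []
    n_skipped = 0
    for t in np.atleast_1d(triggers_s):
        i0 = int(round(t * fs)) + i_pre
        if i0 < 0 or i0 + n_samp > recording.n_samples:
            n_skipped += 1
            continue
        epochs.append(recording.data[rows, i0 : i0 + n_samp])
    if not epochs:
        raise ValueError("no trigger produced a full epoch inside the recording")
    data = np.stack(epochs, axis=1)  # (leads, trials, samples)
    if baseline_correct:
        pre_mask = times_ms < 0
        if pre_mask.any():
            data = data - data[:, :, pre_mask].mean(axis=-1, keepdims=True)
    return TrialSet(data=data, times_ms=times_ms, lead_names=tuple(leads),
                    n_skipped=n_skipped)


def average_trials(
    trials: TrialSet,
    min_trials: int = 100,
    grand_mean_leads: tuple[str, ...] = OCCIPITAL_LEADS,
) -> VEPResult:
    """Pointwise trial mean per lead, then grand mean over the occipital leads.

    A warning (not an error) is issued below ``min_trials`` — fewer trials
    only makes the average noisier.  Leads absent from the trial set are
    ignored; if none of ``grand_mean_leads`` is present, all leads are used.
    """
    if trials.n_trials < 1:
        raise ValueError("no trials to average")
    if trials.n_trials < min_trials:
        warnings.warn(
            f"averaging {trials.n_trials} trials (< {min_trials}); "
            "waveform may not be stable",
            stacklevel=2,
        )
    per_lead = trials.data.mean(axis=1)  # (leads, samples)
    rows = [i for i, name in enumerate(trials.lead_names) if name in grand_mean_leads]
    used = tuple(trials.lead_names[i] for i in rows) or trials.lead_names
    if not rows:
        rows = list(range(len(trials.lead_names)))
    waveform = per_lead[rows].mean(axis=0)
    return VEPResult(waveform=waveform, times_ms=trials.times_ms,
                     n_trials=trials.n_trials, leads_used=used)


def p100_metrics(
    result: VEPResult,
    search_window_ms: tuple[float, float] = DEFAULT_SEARCH_MS,
    amplitude_mode: str = "baseline-to-peak",
) -> VEPResult:
    """Locate the P100 peak inside the search window.

    Latency is the time of the maximal positive deflection (earliest sample
    on ties).  Amplitude is baseline-to-peak (the peak value of the
    baseline-corrected waveform) or, with ``amplitude_mode='peak-to-peak'``,
    peak minus the minimum inside the window.  If the window contains no
    positive deflection the metrics stay NaN (flagged, not zero).
    """
    lo, hi = search_window_ms
    sel = (result.times_ms >= lo) & (result.times_ms <= hi)
    if not sel.any():
        raise ValueError(f"search window [{lo}, {hi}] ms contains no samples")
    seg = result.waveform[sel]
    t_seg = result.times_ms[sel]
    i_peak = int(np.argmax(seg))
    if seg[i_peak] <= 0:
        warnings.warn("no positive deflection in the P100 search window", stacklevel=2)
        return result
    if amplitude_mode == "baseline-to-peak":
        amp = float(seg[i_peak])
    elif amplitude_mode == "peak-to-peak":
        amp = float(seg[i_peak] - seg.min())
    else:
        raise ValueError(f"unknown amplitude mode {amplitude_mode!r}")
    return replace(result, p100_latency_ms=float(t_seg[i_peak]),
                   p100_amplitude_uv=amp)


def normalize_vep(current: VEPResult, baseline: VEPResult) -> VEPResult:
    """Express P100 metrics as ratios to a (pre-insult) baseline session."""
    if not baseline.has_metrics or not current.has_metrics:
        raise ValueError("both sessions need P100 metrics before normalization")
    if baseline.p100_amplitude_uv == 0 or baseline.p100_latency_ms == 0:
        raise ValueError("baseline P100 metrics must be nonzero")
    return replace(
        current,
        normalized_amplitude=current.p100_amplitude_uv / baseline.p100_amplitude_uv,
        normalized_latency=current.p100_latency_ms / baseline.p100_latency_ms,
    )
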