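"""Synthetic neonatal EEG, VEP, histology and qPCR data with ground truth.

Every generator here emulates the statistical structure the analysis modules
assume, with known parameters, so the whole pipeline can be exercised and
validated without animal recordings:

* band-structured background EEG in the amplitude states seen across
  hypoxic-ischemic encephalopathy (continuous > 25 µV, low-amplitude,
  suppressed < 10 µV, isoelectric) built as band-filtered Gaussian noise;
* generalized spike-and-wave seizure trains with a chosen rhythm
  (default ~7 Hz, the generalized-seizure rhythm these models show);
* flash-VEP trials: a deterministic template with a positive P100 peak plus
  independent noise, triggers at 1 Hz;
* 40-field cortical injury grids with an exact pattern mixture;
* qPCR Ct tables with duplicate wells, two stable reference genes and known
  fold changes (the inverse of the ΔΔCt model).

All generators are seeded and byte-for-byte reproducible; each returns the
ground truth needed for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .recording import DEFAULT_FS, DEFAULT_MONTAGE, Annotation, EEGRecording
from .spectral import DEFAULT_BANDS

STATES = ("continuous", "low_amplitude", "suppressed", "isoelectric", "seizure")

#: Default amplitude scale per state.  Background states are µV RMS, chosen
#: so 10 s peak-to-peak epoch amplitudes land in the clinical categories
#: (continuous > 25 µV, low-amplitude 10–25 µV, suppressed/isoelectric
#: < 10 µV); the seizure value is the spike peak amplitude in µV.
DEFAULT_STATE_AMPLITUDE = {
    "continuous": 10.0,
    "low_amplitude": 2.5,
    "suppressed": 1.0,
    "isoelectric": 0.12,
    "seizure": 100.0,
}

#: Default background band-power fractions (δ, θ, α, β): delta-dominated,
#: the usual shape of sedated neonatal EEG.
DEFAULT_BAND_WEIGHTS = {"delta": 0.45, "theta": 0.25, "alpha": 0.18, "beta": 0.12}

#: Default inter-lead correlation of the background (shared-source model).
DEFAULT_LEAD_CORRELATION = 0.7

DEFAULT_SEIZURE_HZ = 7.0


@dataclass(frozen=True)
class Segment:
    """One scheduled state interval."""

    state: str
    start_s: float
    duration_s: float
    amplitude_uv: float | None = None  # None → state default
    rhythm_hz: float | None = None     # seizure only

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.start_s < 0:
            raise ValueError("segment start must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.state == "seizure":
            rhythm = self.rhythm_hz if self.rhythm_hz is not None else DEFAULT_SEIZURE_HZ
            if not 1.0 < rhythm < 30.0:
                raise ValueError(
                    f"seizure rhythm {rhythm} Hz outside (1, 30) Hz — it would "
                    "be destroyed by the 1–30 Hz bandpass"
                )

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def amplitude(self) -> float:
        return (DEFAULT_STATE_AMPLITUDE[self.state]
                if self.amplitude_uv is None else self.amplitude_uv)

    @property
    def rhythm(self) -> float:
        return DEFAULT_SEIZURE_HZ if self.rhythm_hz is None else self.rhythm_hz


@dataclass
class StateSchedule:
    """An ordered, non-overlapping sequence of state segments."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start_s)
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(
                    f"segments overlap: {a.state} [{a.start_s}, {a.end_s}) and "
                    f"{b.state} [{b.start_s}, {b.end_s})"
                )
        self.segments = segs

    @property
    def duration_s(self) -> float:
        return max(s.end_s for s in self.segments)

    def seizure_intervals(self) -> list[tuple[float, float, float]]:
        return [
            (s.start_s, s.end_s, s.rhythm)
            for s in self.segments if s.state == "seizure"
        ]


@dataclass
class GroundTruth:
    """True parameters behind a generated artifact."""

    schedule: StateSchedule | None = None
    seizure_intervals: list[tuple[float, float, float]] = field(default_factory=list)
    vep_params: tuple[float, float] | None = None  # (p100 µV, latency ms)
    field_patterns: tuple[str, ...] | None = None
    fold_truth: dict | None = None


# --------------------------------------------------------------------------
# background EEG

def _band_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band_weights: dict[str, float],
) -> np.ndarray:
    """Unit-variance noise whose band-power fractions match ``band_weights``."""
    out = np.zeros(n)
    for band in DEFAULT_BANDS:
        w = band_weights.get(band.name, 0.0)
        if w <= 0:
            continue
        # order 6 keeps ≳94% of each component's power inside its band
        sos = signal.butter(
            6, [band.low_hz, band.high_hz], btype="bandpass", output="sos", fs=fs
        )
        x = signal.sosfilt(sos, rng.standard_normal(n))
        sd = x.std()
        if sd > 0:
            out += math.sqrt(w) * x / sd
    sd = out.std()
    return out / sd if sd > 0 else out


def _validate_weights(band_weights: dict[str, float]) -> dict[str, float]:
    unknown = set(band_weights) - {b.name for b in DEFAULT_BANDS}
    if unknown:
        raise ValueError(f"unknown band(s) {sorted(unknown)}")
    if any(w < 0 for w in band_weights.values()):
        raise ValueError("band weights must be non-negative")
    total = sum(band_weights.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"band weights must sum to 1 (got {total})")
    return band_weights


def gen_background_eeg(
    duration_s: float,
    n_leads: int = 9,
    band_weights: dict[str, float] | None = None,
    amplitude_uv_rms: float = DEFAULT_STATE_AMPLITUDE["continuous"],
    seed: int = 0,
    lead_correlation: float = DEFAULT_LEAD_CORRELATION,
    fs: float = DEFAULT_FS,
) -> EEGRecording:
    """Background EEG: band-filtered Gaussian noise with set band fractions.

    Leads are correlated copies (shared source plus per-lead noise at
    correlation ``lead_correlation``); each lead is scaled to exactly
    ``amplitude_uv_rms`` µV RMS.  ``amplitude_uv_rms=0`` yields a zero
    recording.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    weights = _validate_weights(dict(band_weights or DEFAULT_BAND_WEIGHTS))
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    shared = _band_noise(rng, n, fs, weights)
    data = np.empty((n_leads, n))
    for i in range(n_leads):
        own = _band_noise(rng, n, fs, weights)
        x = math.sqrt(lead_correlation) * shared + math.sqrt(1 - lead_correlation) * own
        sd = x.std()
        data[i] = amplitude_uv_rms * x / sd if sd > 0 else 0.0
    names = (DEFAULT_MONTAGE if n_leads == len(DEFAULT_MONTAGE)
             else tuple(f"L{i + 1}" for i in range(n_leads)))
    return EEGRecording(data, fs=fs, lead_names=names)


# --------------------------------------------------------------------------
# seizures

def gen_seizure_segment(
    duration_s: float,
    rhythm_hz: float = DEFAULT_SEIZURE_HZ,
    amplitude_uv: float = DEFAULT_STATE_AMPLITUDE["seizure"],
    seed: int = 0,
    fs: float = DEFAULT_FS,
) -> np.ndarray:
    """One-channel spike-and-wave train with its fundamental at ``rhythm_hz``.

    Each cycle is a biphasic spike (~70 ms: sharp positive lobe, small
    negative rebound) followed by a large slow wave filling the rest of the
    cycle; the slow wave outweighs the spike so the spectral fundamental
    dominates the harmonics at any in-band rhythm.  The train is zero-mean
    and scaled so the waveform peak is ``amplitude_uv``; cycle amplitudes
    are modulated ±10% (seeded) for a natural appearance.
    """
    if not 1.0 < rhythm_hz < 30.0:
        raise ValueError(
            f"rhythm {rhythm_hz} Hz outside (1, 30) Hz — would be removed by "
            "the 1–30 Hz bandpass"
        )
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    cycle = 1.0 / rhythm_hz
    tau = np.mod(t, cycle)  # time within cycle, s

    spike_len = min(0.07, 0.5 * cycle)
    pos = np.exp(-0.5 * ((tau - 0.30 * spike_len) / (0.15 * spike_len)) ** 2)
    neg = -0.35 * np.exp(-0.5 * ((tau - 0.75 * spike_len) / (0.20 * spike_len)) ** 2)
    wave_len = cycle - spike_len
    in_wave = tau >= spike_len
    slow = np.where(
        in_wave, 1.4 * np.sin(np.pi * (tau - spike_len) / wave_len), 0.0
    )
    x = pos + neg + slow

    rng = np.random.default_rng(seed)
    n_cycles = int(np.ceil(duration_s * rhythm_hz))
    mod = 1.0 + 0.1 * rng.uniform(-1, 1, size=n_cycles)
    x = x * mod[np.minimum((t * rhythm_hz).astype(int), n_cycles - 1)]

    x -= x.mean()
    peak = np.max(np.abs(x))
    return amplitude_uv * x / peak if peak > 0 else x


def compose_recording(
    schedule: StateSchedule,
    n_leads: int = 9,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    band_weights: dict[str, float] | None = None,
    crossfade_s: float = 1.0,
    seizure_background_rms: float = 3.0,
) -> tuple[EEGRecording, GroundTruth]:
    """Concatenate scheduled states into one recording, with ground truth.

    Segment edges are ramped linearly over ``crossfade_s`` to avoid step
    discontinuities (broadband artifacts).  During seizures the spike-and-wave
    train (shared across leads with mild per-lead gain spread, mirroring a
    generalized discharge seen on all leads) rides on low-amplitude
    background noise.  Gaps in the schedule are silent.  The returned
    :class:`GroundTruth` carries the scheduled seizure intervals exactly.
    """
    total = int(round(schedule.duration_s * fs))
    data = np.zeros((n_leads, total))
    rng = np.random.default_rng(seed)
    annotations: list[Annotation] = []

    for seg in schedule.segments:
        i0 = int(round(seg.start_s * fs))
        i1 = int(round(seg.end_s * fs))
        nseg = i1 - i0
        seg_seed = int(rng.integers(0, 2**31 - 1))
        if seg.state == "seizure":
            train = gen_seizure_segment(
                nseg / fs, rhythm_hz=seg.rhythm,
                amplitude_uv=seg.amplitude, seed=seg_seed, fs=fs,
            )[:nseg]
            bg = gen_background_eeg(
                nseg / fs, n_leads=n_leads, band_weights=band_weights,
                amplitude_uv_rms=seizure_background_rms,
                seed=seg_seed + 1, fs=fs,
            ).data[:, :nseg]
            gains = 1.0 - 0.2 * rng.random(n_leads)
            chunk = gains[:, None] * train[None, :] + bg
        else:
            chunk = gen_background_eeg(
                nseg / fs, n_leads=n_leads, band_weights=band_weights,
                amplitude_uv_rms=seg.amplitude, seed=seg_seed, fs=fs,
            ).data[:, :nseg]
        ramp_n = min(int(round(crossfade_s * fs)), nseg // 4)
        if ramp_n > 0:
            env = np.ones(nseg)
            env[:ramp_n] = np.linspace(0, 1, ramp_n)
            env[-ramp_n:] = np.linspace(1, 0, ramp_n)
            chunk = chunk * env
        data[:, i0:i1] += chunk
        annotations.append(Annotation(seg.start_s, seg.end_s, seg.state))

    names = (DEFAULT_MONTAGE if n_leads == len(DEFAULT_MONTAGE)
             else tuple(f"L{i + 1}" for i in range(n_leads)))
    rec = EEGRecording(data, fs=fs, lead_names=names, annotations=annotations)
    truth = GroundTruth(
        schedule=schedule, seizure_intervals=schedule.seizure_intervals()
    )
    return rec, truth


# --------------------------------------------------------------------------
# VEP

def vep_template(
    times_ms: np.ndarray, p100_amplitude_uv: float, p100_latency_ms: float,
    width_ms: float = 15.0,
) -> np.ndarray:
    """Deterministic single-trial template: Gaussian P100 deflection."""
    return p100_amplitude_uv * np.exp(
        -0.5 * ((times_ms - p100_latency_ms) / width_ms) ** 2
    )


def gen_vep_trials(
    n_trials: int,
    p100_amplitude_uv: float = 10.0,
    p100_latency_ms: float = 100.0,
    noise_sd_uv: float = 20.0,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    window_ms: tuple[float, float] = (-50.0, 500.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-lead flash-VEP trials: template plus independent Gaussian noise.

    Returns ``(trials, times_ms, trigger_times_s)`` with ``trials`` of shape
    ``(n_trials, n_samples)`` and triggers spaced 1 s apart (1 Hz flash).
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    pre, post = window_ms
    if not pre < p100_latency_ms < post:
        raise ValueError(
            f"P100 latency {p100_latency_ms} ms outside the epoch window "
            f"[{pre}, {post}] ms"
        )
    n_samp = int(round((post - pre) * fs / 1000.0))
    times_ms = pre + np.arange(n_samp) * 1000.0 / fs
    template = vep_template(times_ms, p100_amplitude_uv, p100_latency_ms)
    rng = np.random.default_rng(seed)
    trials = template[None, :] + noise_sd_uv * rng.standard_normal((n_trials, n_samp))
    triggers = np.arange(n_trials, dtype=float)  # 1 Hz flashes
    return trials, times_ms, triggers


def gen_vep_recording(
    n_trials: int,
    p100_amplitude_uv: float = 10.0,
    p100_latency_ms: float = 100.0,
    noise_sd_uv: float = 20.0,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    leads: tuple[str, ...] = DEFAULT_MONTAGE,
    response_leads: tuple[str, ...] = ("O1", "O2"),
) -> tuple[EEGRecording, np.ndarray, GroundTruth]:
    """A continuous recording with evoked responses embedded at 1 Hz flashes.

    The P100 template is added to the occipital ``response_leads`` at each
    trigger; all leads carry independent Gaussian noise.  Returns the
    recording (triggers also stored as zero-length ``flash`` annotations),
    trigger times, and ground truth.
    """
    duration_s = n_trials + 1.0
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    data = noise_sd_uv * rng.standard_normal((len(leads), n))
    triggers = 0.5 + np.arange(n_trials, dtype=float)
    t_ms = np.arange(n) * 1000.0 / fs
    for trig in triggers:
        for lead in response_leads:
            i = leads.index(lead)
            data[i] += vep_template(t_ms - trig * 1000.0, p100_amplitude_uv,
                                    p100_latency_ms)
    ann = [Annotation(t, t, "flash") for t in triggers]
    rec = EEGRecording(data, fs=fs, lead_names=leads, annotations=ann)
    truth = GroundTruth(vep_params=(p100_amplitude_uv, p100_latency_ms))
    return rec, triggers, truth


# --------------------------------------------------------------------------
# histology field grids

PATTERNS = ("none", "scattered", "grouped", "panlaminar")  # severity order


def gen_field_grid(
    n_fields: int = 40,
    pattern_mixture: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[tuple[str, ...], GroundTruth]:
    """Per-field injury-pattern labels matching ``pattern_mixture`` exactly.

    Counts are assigned by largest-remainder rounding (deterministic; ties go
    to the more severe pattern) and the field order is then shuffled with
    ``seed``.  Default mixture is all ``none`` (no damage).
    """
    if n_fields < 1:
        raise ValueError("need at least one field")
    mixture = dict(pattern_mixture or {"none": 1.0})
    unknown = set(mixture) - set(PATTERNS)
    if unknown:
        raise ValueError(f"unknown pattern(s) {sorted(unknown)}")
    if any(v < 0 for v in mixture.values()):
        raise ValueError("mixture fractions must be non-negative")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mixture fractions must sum to 1 (got {total})")

    quotas = {p: mixture.get(p, 0.0) * n_fields for p in PATTERNS}
    counts = {p: int(math.floor(q)) for p, q in quotas.items()}
    leftover = n_fields - sum(counts.values())
    by_remainder = sorted(
        PATTERNS,
        key=lambda p: (-(quotas[p] - counts[p]), -PATTERNS.index(p)),
    )
    for p in by_remainder[:leftover]:
        counts[p] += 1

    labels = [p for p in PATTERNS for _ in range(counts[p])]
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    grid = tuple(labels)
    return grid, GroundTruth(field_patterns=grid)


# --------------------------------------------------------------------------
# qPCR Ct tables

def gen_ct_table(
    genes: list[str],
    groups: list[str],
    true_fold_changes: dict[str, dict[str, float]],
    calibrator_group: str | None = None,
    reference_genes: tuple[str, str] = ("PPIA2", "GAPDH"),
    base_ct: float = 26.0,
    ref_ct: float = 20.0,
    noise_sd: float = 0.0,
    n_samples: int = 7,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Tidy Ct table (sample, group, gene, replicate, ct) with known folds.

    Target Ct for a sample in group *g* is ``base_ct − log2(fold[g])`` (the
    calibrator group has fold 1 by construction); reference genes sit at
    ``ref_ct`` in every group.  Independent N(0, ``noise_sd``) cycles are
    added per well.  Duplicate wells per sample by default.
    """
    if calibrator_group is None:
        calibrator_group = groups[0]
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} not in groups")
    for gene, per_group in true_fold_changes.items():
        for grp, fold in per_group.items():
            if fold <= 0:
                raise ValueError(f"fold change must be positive ({gene}/{grp}: {fold})")

    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, dict[str, float]] = {}
    for gene in genes:
        truth[gene] = {
            grp: (1.0 if grp == calibrator_group
                  else true_fold_changes.get(gene, {}).get(grp, 1.0))
            for grp in groups
        }
    for grp in groups:
        for s in range(n_samples):
            sample_id = f"{grp}_{s + 1}"
            for gene in genes:
                ct0 = base_ct - math.log2(truth[gene][grp])
                for rep in range(1, n_replicates + 1):
                    rows.append((sample_id, grp, gene, rep,
                                 ct0 + noise_sd * rng.standard_normal()))
            for ref in reference_genes:
                for rep in range(1, n_replicates + 1):
                    rows.append((sample_id, grp, ref, rep,
                                 ref_ct + noise_sd * rng.standard_normal()))
    table = pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
    return table, GroundTruth(fold_truth=truth)
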