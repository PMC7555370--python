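# neoqeeg

Quantitative EEG, evoked-potential, ordinal-scoring and laboratory
calculations for neonatal hypoxic-ischemic encephalopathy (HIE) models —
plus a seeded synthetic-signal generator so the entire analysis chain can be
exercised, validated and demonstrated without any animal data.

## Who this is for

Translational HIE research (typically in the newborn piglet, whose brain
development and metabolism resemble the term human neonate) monitors injury
and treatment response with a standard battery: multichannel scalp EEG
(256 Hz, 9-lead modified neonatal 10–20 montage), flash visual evoked
potentials, amplitude-based EEG scoring, 0–9 cortical neuropathology
scoring, relative qPCR gene expression, and — when gas therapies such as
molecular H₂ are studied — amperometric microsensor measurements of brain
gas levels. `neoqeeg` implements that battery as a tested, importable
Python library.

## What it computes

**Spectra.** The broadband signal is bandpassed to 1–30 Hz (zero-phase) and
decomposed into the classical bands δ (1–4 Hz), θ (4–8 Hz), α (8–13 Hz),
β (13–30 Hz). Power spectral densities are estimated on a 30 s window
sliding in 1 s steps, Welch-averaged over Gaussian-windowed sub-segments;
band powers are Σ PSD·Δf and can be normalized to a pre-insult baseline.

**Spectral entropy.** Treating a PSD frame as a probability distribution
p_i = PSD_i / Σ PSD, the normalized Shannon spectral entropy is

    H = −Σᵢ p_i log p_i / log K          (K frequency bins, H ∈ [0, 1])

computed per sliding-window frame over the whole 1–30 Hz spectrum
(*instantaneous* spectral entropy, InstSpEnt) or restricted to one band's
bins (SpEnt). A flat spectrum gives H = 1; a pure rhythm gives H → 0.
Traces are thresholded at mean − SD, and sustained below-threshold runs on
a majority of leads — confirmed by a dominant rhythmic peak after whitening
by the recording's own median spectrum — are reported as seizure events
with their dominant frequency (generalized spike-and-wave seizures in this
model run at ~7 Hz).

**Evoked potentials.** 1 Hz flash trials are epoched, baseline-corrected,
averaged (≥100 trials for a stable waveform, grand mean of O1/O2), and the
P100 component is characterized by latency and amplitude, optionally as
ratios to the pre-insult session.

**Scores.** The first 10 min of each post-insult hour is scored by
background amplitude (continuous >25 µV scores low, isoelectric scores
high; +2 points if a seizure occurred in that hour) and summed over the
observation period. Cortical injury is scored 0–9 from the most severe
pattern (none < scattered < grouped < panlaminar) in 40 microscope fields
and the fraction of fields showing it; subcortical injury as the percentage
of damaged neurons.

**Lab calculations.** Two-point H₂ microsensor calibration (zero in
N₂-bubbled water; maximum in 5% H₂: 0.05 atm × 794.64 µmol L⁻¹ atm⁻¹ =
39.732 µM) with van 't Hoff temperature correction of solubility, plateau
(steady-state) detection on 1 Hz traces, and ΔΔCt relative expression with
two reference genes (PPIA2, GAPDH): fold = 2^(−ΔΔCt).

**Synthetic data.** `neoqeeg.syngen` generates every input with known
ground truth: band-structured background EEG in the clinical amplitude
states, spike-and-wave seizure trains, VEP trials, field grids with exact
pattern mixtures, and Ct tables with known fold changes.

## Worked example

```python
from neoqeeg import bandpass, detect_seizures, inst_spent, apply_threshold
from neoqeeg.syngen import Segment, StateSchedule, compose_recording

schedule = StateSchedule([
    Segment("continuous", 0, 240),
    Segment("seizure", 240, 60),     # 60 s generalized 7 Hz spike-and-wave
    Segment("continuous", 300, 300),
])
recording, truth = compose_recording(schedule, n_leads=9, seed=3)
filtered = bandpass(recording)
trace = apply_threshold(inst_spent(filtered))
print(trace.summary("mean"), trace.summary("min"))
for e in detect_seizures(filtered):
    print(e.start_s, e.end_s, e.dominant_hz, len(e.peak_leads))
```

prints (see `examples/03_seizure_detection.py` for the annotated version):

```
InstSpEnt: mean 0.805, min 0.412
detected seizure 241-300 s (scheduled (240, 300)), dominant 7.00 Hz on 9/9 leads
```

The entropy trace sits near 1 during broadband background activity, drops
during the rhythmic discharge, and the detector recovers the scheduled
interval and its 7 Hz rhythm. The other capabilities each have a short
narrative script under `examples/` (band power, VEP/P100, scoring, H₂ and
ΔΔCt calculations).

A thin CLI wraps the same library: `neoqeeg run --config run.yaml` drives
the full chain (filter → PSD → entropy → seizure detection → scores → VEP)
from a YAML config and writes per-stage CSVs plus a JSON manifest with
checksums; `neoqeeg syngen|ddct|h2|fields` expose the individual pieces.

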