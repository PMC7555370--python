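# Methods

This note documents the models, conventions and numerical choices behind
`neoqeeg`, in the order data flows through the package.

## Signal model of the synthetic generator

The generator is the package's substitute for animal recordings, so its
assumptions bound what passing tests demonstrate.

**Background EEG** is a sum of band-filtered Gaussian noise: independent
white noise is filtered into each classical band (order-6 Butterworth, which
keeps ≳94% of each component's power inside its band), scaled so band-power
fractions equal the requested weights, summed, and rescaled to an exact
per-lead RMS. Default weights (δ 0.45, θ 0.25, α 0.18, β 0.12) give the
delta-dominated spectrum of sedated neonatal EEG. The nine leads are
correlated copies — a shared source plus per-lead noise at correlation 0.7 —
because generalized activity in this preparation appears on all leads; the
correlation value is a convention, not a measured fact. Amplitude-state
defaults are chosen so the robust epoch amplitude (below) lands inside each
clinical category: continuous 10 µV RMS (~60 µV peak-to-peak), low-amplitude
2.5, suppressed 1.0, isoelectric 0.12.

**Seizures** are spike-and-wave trains: per cycle, a biphasic spike
(~70 ms; sharp positive lobe, small negative rebound) followed by a slow
wave filling the rest of the cycle at relative amplitude 1.4. The slow wave
is deliberately the larger component so that the spectral fundamental
dominates every harmonic for rhythms anywhere in (1, 30) Hz — verified by
periodogram in the tests — because the detector reports the dominant peak as
the seizure rhythm. Default rhythm 7 Hz, default amplitude 100 µV (peak),
±10% seeded cycle-amplitude modulation. During composed seizures the train
rides on 3 µV RMS background so entropy denominators never degenerate.

**Composition** concatenates scheduled states with 1 s linear edge ramps
(step discontinuities would inject broadband energy); ground-truth seizure
intervals are carried through exactly as scheduled.

What the generator does *not* model: volume conduction and realistic lead
topography, ocular/ECG/movement artifacts, burst-suppression microstructure,
non-stationary drifts, and 1/f spectral slope beyond the band-weight
parameterization. Detector performance on real neonatal EEG therefore cannot
be inferred from these tests; the tests show the algorithms are correct under
the stated signal model.

## Spectral chain

* **Bandpass 1–30 Hz**, zero-phase. The filter is a Butterworth bandpass
  designed with `scipy.signal.buttord` against an explicit doubled-pass
  template — ±1 dB over [low+0.5, high−0.5] Hz and ≥20 dB at 0.5·low and
  1.5·high — and applied forward-backward (`sosfiltfilt`), so event timing
  is preserved exactly. A fixed 4th-order design cannot meet this template
  (−3 dB at its own corner), which is why the order is solved for (≈5, with
  widened natural frequencies) rather than fixed.
* **Sliding Welch PSD**: 30 s window, 1 s step; inside each window, Welch
  averaging of 4 s Gaussian-windowed sub-segments (σ = length/6) with 50%
  overlap. Sub-segment length trades variance against resolution; 4 s gives
  Δf = 0.25 Hz, enough to separate a 7 Hz rhythm from its neighbors while
  averaging ~14 periodograms per frame. Scaling is one-sided density
  (µV²/Hz) with window-power normalization, so integrated PSD of stationary
  noise equals its variance (checked to 5%, Parseval). Frame timestamps are
  window starts, 0-based; trailing samples short of a full window are
  dropped.
* **Band powers** are Σ PSD·Δf with half-open bin assignment [low, high);
  the β band additionally owns the 30 Hz bin, so the four bands partition
  1–30 Hz exactly and their sum equals total band power bin-for-bin.
* **Baseline normalization** divides each frame by the mean band power over
  a chosen baseline interval, per lead — each electrode relative to its own
  pre-insult level. Normalizing to a control-group mean instead is a
  different convention; callers can pass any baseline values they like, but
  own-baseline is the default and only built-in mode.

## Spectral entropy and seizure detection

Entropy is normalized by log K so the uniform spectrum maps to 1,
consistent with reporting values in (0, 1). An all-zero frame returns NaN,
never 0 — zero means concentrated power, not absent power. The per-band
"SpEnt" restricts the same 30 s/1 s frames to the band's bins rather than
using shorter time windows; the InstSpEnt trace can be summarized as the
mean, the minimum, or the mean of below-threshold frames (all three are
exposed; which one corresponds to any given published summary number is not
always determinable, so none is privileged).

Thresholding uses mean − SD with the sample SD (ddof = 1), per lead;
values strictly below threshold are flagged.

The detector marks frames that are (a) below the entropy threshold,
(b) above an absolute total-power floor (default 1 µV²; suppressed EEG also
has low entropy, for the wrong reason), on (c) at least a majority of leads
(default ⌊n/2⌋+1). Runs are merged across gaps ≤ 5 s and kept if
≥ 10 s long. Each run must then pass a rhythmicity check: the event-average
spectrum is divided by the recording's per-bin median spectrum (background
EEG is itself delta-dominated, so an unwhitened peak-to-median test fires
on any ordinary segment) and the whitened peak must exceed 5× its median.
Event boundaries are refined on the power profile at the dominant bin:
entropy saturates once the rhythm dominates a window, blurring edges by up
to half a window, whereas dominant-bin power grows linearly with window
overlap, so its half-maximum crossings — with frame times taken at window
centers — sit at the true onset/offset. Measured on the synthetic model:
interval Jaccard ≈ 0.95–0.98, sensitivity 20/20 seeds, no false positives
in 8 × 10-min seizure-free recordings.

## VEP

Epochs default to −50…+500 ms around each 1 Hz flash, baseline-corrected by
the pre-stimulus mean; triggers whose epoch leaves the recording are skipped
and counted. Averages below 100 trials warn but proceed. The grand mean is
the equal-weight average of the O1 and O2 lead means. P100 search window
defaults to 50–200 ms; latency is the argmax of the positive deflection
(earliest sample on ties) and amplitude is baseline-to-peak by default, with
a peak-to-peak switch. Noiseless recovery is exact to the sampling grid
(≈3.9 ms at 256 Hz). Both raw and baseline-normalized metrics are emitted;
normalization is a plain ratio for amplitude and latency alike.

## Scoring

The published category-to-score table for amplitude-based EEG scoring lives
in an appendix that is not reproduced here; the shipped default is a
declared reconstruction with four categories (continuous >25 µV → 0,
discontinuous 10–25 → 1, severely depressed 2–10 → 2, isoelectric <2 → 3)
and a +2 seizure bonus, consistent with the stated boundaries
(continuous >25 µV; depressed/isoelectric <10 µV). Any table with
gap-free, strictly score-decreasing amplitude categories can be supplied.
The epoch amplitude measure — which no published description pins down — is
the median peak-to-peak over 10 s sub-windows across leads, robust to single
transients. The bonus applies to an hour when a seizure intersects it
anywhere, not only in the scored 10 min.

The 0–9 cortical score is 3·(severity−1) + extent level, with severity
scattered/grouped/panlaminar = 1/2/3, counting only fields showing exactly
the most severe pattern present, and extent levels ≤20% / 20–50% / >50%.
The published table's wording leaves fractions between 20% and 21%
unassigned; they go to the lower level here (with 40 fields, fractions are
multiples of 2.5%, so only 20.0% itself is affected).

## Lab calculations

Calibration is strictly two-point linear; the curve reproduces its own
endpoints exactly. Temperature correction multiplies concentrations by the
ratio of H₂ solubilities at measurement vs calibration temperature, with
solubility given by a van 't Hoff form anchored at the tabulated 22 °C
value (794.64 µmol L⁻¹ atm⁻¹) and the standard temperature dependence of
the H₂ Henry constant (d ln S / d(1/T) ≈ 530 K). A closed form was chosen
over a bundled lookup table: it encodes the same physics, is smooth in T,
and is valid over the 0–45 °C range enforced here. Plateau detection scans
120 s windows for the earliest least-squares slope within 0.001 µM/s
(≈0.06 µM/min, appropriate for traces that reach steady state in 10–15 min)
and reports mean ± SD from there to the end of the trace.

ΔΔCt assumes perfect doubling per cycle (no efficiency correction).
Replicate Cts are averaged per sample/gene (pairs spreading >1 cycle are
flagged); the reference level is the arithmetic mean of the two reference
Cts, which at perfect efficiency equals the geometric mean of the reference
quantities — a single-reference mode is provided. Samples missing target or
reference values are dropped with a warning; group summaries are means of
per-sample folds.

## Problem sizes and determinism

Monte-Carlo checks in the test suite use the sizes their claims state:
10-min, 9-lead recordings and 20 seeds for detector sensitivity and for the
seizure-vs-twin entropy ordering; 10 seeds for band-fraction and √n
averaging laws; 20 seeds × 7 samples for noisy ΔΔCt recovery. Every
stochastic component takes an explicit integer seed and is byte-for-byte
reproducible; the pipeline writes per-output SHA-256 checksums in its
manifest, and identical configs reproduce identical checksums.

## Known limitations

* The generator's realism limits (listed above) mean validation is of the
  algorithms, not of clinical performance.
* The EEG score table and the InstSpEnt summary statistic are declared
  reconstructions/conventions where the source protocols are underspecified.
* EDF writing is a minimal implementation (16-bit, one record/s, µV); it
  round-trips against mne's reader but does not cover EDF+ annotations,
  which travel in CSV sidecars instead.
* The H₂ temperature correction extrapolates a single anchor value; for
  work where absolute µM accuracy matters, calibrate at the measurement
  temperature.
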