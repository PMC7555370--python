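"""Generator contracts: band structure, amplitude states, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from neoqeeg.recording import EEGRecording
from neoqeeg.scoring import epoch_amplitude
from neoqeeg.syngen import (
    PATTERNS,
    Segment,
    StateSchedule,
    compose_recording,
    gen_background_eeg,
    gen_ct_table,
    gen_field_grid,
    gen_seizure_segment,
    gen_vep_trials,
    vep_template,
)

FS = 256.0


def band_fractions(x: np.ndarray, fs: float = FS) -> dict[str, float]:
    """Independent periodogram oracle: power fraction per classical band."""
    f, p = signal.periodogram(x, fs=fs)
    total = p[(f >= 1) & (f <= 30)].sum()
    edges = {"delta": (1, 4), "theta": (4, 8), "alpha": (8, 13), "beta": (13, 30.001)}
    return {name: p[(f >= lo) & (f < hi)].sum() / total for name, (lo, hi) in edges.items()}


class TestBackgroundEEG:
    def test_all_delta_power_confined_to_delta(self):
        rec = gen_background_eeg(120, n_leads=1, band_weights={"delta": 1.0}, seed=3)
        assert band_fractions(rec.data[0])["delta"] >= 0.90

    def test_zero_amplitude_yields_zero_signal(self):
        rec = gen_background_eeg(60, n_leads=2, amplitude_uv_rms=0.0, seed=0)
        assert np.all(rec.data == 0)

    def test_rms_matches_request(self):
        rec = gen_background_eeg(60, n_leads=3, amplitude_uv_rms=12.0, seed=1)
        rms = np.sqrt((rec.data**2).mean(axis=1))
        assert np.allclose(rms, 12.0, rtol=0.10)

    def test_equal_weights_recovered_within_5_points(self):
        weights = {b: 0.25 for b in ("delta", "theta", "alpha", "beta")}
        fracs = []
        for seed in range(10):
            rec = gen_background_eeg(120, n_leads=1, band_weights=weights, seed=seed)
            fracs.append(list(band_fractions(rec.data[0]).values()))
        mean = np.mean(fracs, axis=0)
        assert np.all(np.abs(mean - 0.25) < 0.05)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            gen_background_eeg(10, band_weights={"delta": 0.5, "beta": 0.4})
        with pytest.raises(ValueError, match="non-negative"):
            gen_background_eeg(10, band_weights={"delta": 1.2, "beta": -0.2})
        with pytest.raises(ValueError, match="duration"):
            gen_background_eeg(0.0)

    def test_same_seed_reproduces_bytes(self):
        a = gen_background_eeg(30, n_leads=2, seed=7)
        b = gen_background_eeg(30, n_leads=2, seed=7)
        c = gen_background_eeg(30, n_leads=2, seed=8)
        assert a.data.tobytes() == b.data.tobytes()
        assert a.data.tobytes() != c.data.tobytes()


class TestSeizureSegment:
    @pytest.mark.parametrize("rhythm", [3.0, 7.0, 12.0])
    def test_dominant_peak_at_rhythm(self, rhythm):
        x = gen_seizure_segment(60, rhythm_hz=rhythm, seed=0)
        f, p = signal.periodogram(x, fs=FS)
        m = (f >= 1) & (f <= 30)
        assert abs(f[m][np.argmax(p[m])] - rhythm) <= 0.25

    def test_zero_amplitude(self):
        assert np.all(gen_seizure_segment(10, amplitude_uv=0.0) == 0)

    def test_out_of_band_rhythm_rejected(self):
        for bad in (0.5, 1.0, 30.0, 35.0):
            with pytest.raises(ValueError, match="1, 30"):
                gen_seizure_segment(10, rhythm_hz=bad)


class TestComposeRecording:
    def test_single_segment_duration_and_no_seizures(self):
        rec, truth = compose_recording(
            StateSchedule([Segment("continuous", 0, 60)]), n_leads=2, seed=0
        )
        assert rec.duration_s == pytest.approx(60.0)
        assert truth.seizure_intervals == []

    def test_ground_truth_intervals_exact(self):
        sched = StateSchedule([
            Segment("continuous", 0, 60),
            Segment("isoelectric", 60, 30),
            Segment("seizure", 90, 45, rhythm_hz=7.0),
            Segment("continuous", 135, 60),
        ])
        _, truth = compose_recording(sched, n_leads=2, seed=0)
        assert truth.seizure_intervals == [(90, 135, 7.0)]

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StateSchedule([
                Segment("continuous", 0, 100),
                Segment("seizure", 50, 30),
            ])

    def test_amplitude_states_separable(self):
        """Epoch peak-to-peak sits in the clinical category for each state."""
        sched = StateSchedule([
            Segment("continuous", 0, 60),
            Segment("suppressed", 60, 60),
            Segment("isoelectric", 120, 60),
        ])
        rec, _ = compose_recording(sched, n_leads=2, seed=5)
        # measure away from the cross-fade ramps
        continuous = epoch_amplitude(rec.slice_time(10, 50))
        suppressed = epoch_amplitude(rec.slice_time(70, 110))
        isoelectric = epoch_amplitude(rec.slice_time(130, 170))
        assert continuous > 25.0
        assert suppressed < 10.0
        assert isoelectric < 10.0


class TestVEPTrials:
    def test_noiseless_trials_equal_template(self):
        trials, times_ms, triggers = gen_vep_trials(5, noise_sd_uv=0.0, seed=0)
        template = vep_template(times_ms, 10.0, 100.0)
        assert np.allclose(trials, template[None, :])
        assert np.allclose(np.diff(triggers), 1.0)  # 1 Hz flashes

    def test_sqrt_n_noise_suppression(self):
        one, _, _ = gen_vep_trials(1, p100_amplitude_uv=0, noise_sd_uv=20, seed=1)
        many, _, _ = gen_vep_trials(400, p100_amplitude_uv=0, noise_sd_uv=20, seed=1)
        ratio = one.mean(axis=0).std() / many.mean(axis=0).std()
        assert 16 < ratio < 24  # √400 = 20 within sampling tolerance

    def test_latency_outside_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            gen_vep_trials(10, p100_latency_ms=600.0)


class TestFieldGrid:
    def test_pure_none_grid(self):
        grid, _ = gen_field_grid(40, {"none": 1.0})
        assert grid == ("none",) * 40

    @pytest.mark.parametrize(
        "mixture, expected",
        [
            ({"panlaminar": 0.6, "grouped": 0.4}, {"panlaminar": 24, "grouped": 16}),
            ({"scattered": 0.1, "none": 0.9}, {"scattered": 4, "none": 36}),
        ],
    )
    def test_largest_remainder_counts(self, mixture, expected):
        grid, _ = gen_field_grid(40, mixture, seed=0)
        for pattern, count in expected.items():
            assert grid.count(pattern) == count

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            gen_field_grid(40, {"none": 1.5, "scattered": -0.5})

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4),
        st.integers(1, 80),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_counts_sum_and_track_quotas(self, raw, n_fields):
        total = sum(raw)
        mixture = {p: w / total for p, w in zip(PATTERNS, raw)}
        grid, _ = gen_field_grid(n_fields, mixture, seed=0)
        assert len(grid) == n_fields
        for p, frac in mixture.items():
            assert abs(grid.count(p) - frac * n_fields) < 1.0


class TestCtTable:
    def test_noiseless_fold2_target_one_cycle_below_calibrator(self):
        table, _ = gen_ct_table(
            ["BDNF"], ["C-NT", "A-HT"], {"BDNF": {"A-HT": 2.0}}, noise_sd=0.0,
            n_samples=2,
        )
        target = table[table.gene == "BDNF"]
        cal = target[target.group == "C-NT"].ct.mean()
        treated = target[target.group == "A-HT"].ct.mean()
        assert treated == pytest.approx(cal - 1.0)

    def test_reference_genes_stable_across_groups(self):
        table, _ = gen_ct_table(
            ["BDNF"], ["C-NT", "A-HT"], {"BDNF": {"A-HT": 10.0}}, noise_sd=0.0,
            n_samples=2,
        )
        refs = table[table.gene.isin(["PPIA2", "GAPDH"])]
        assert refs.groupby("group").ct.nunique().eq(1).all()

    def test_non_positive_fold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gen_ct_table(["BDNF"], ["a", "b"], {"BDNF": {"b": 0.0}})

    def test_seeded_reproducibility(self):
        kwargs = dict(noise_sd=0.3, n_samples=3, seed=11)
        t1, _ = gen_ct_table(["AIF"], ["a", "b"], {"AIF": {"b": 2.0}}, **kwargs)
        t2, _ = gen_ct_table(["AIF"], ["a", "b"], {"AIF": {"b": 2.0}}, **kwargs)
        assert t1.equals(t2)
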