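"""H2 sensor calibration arithmetic and ΔΔCt relative quantification."""

import numpy as np
import pandas as pd
import pytest

from neoqeeg.labcalc import (
    calibrate,
    ddct,
    find_plateau,
    h2_solubility,
    max_concentration,
    raw_to_concentration,
)
from neoqeeg.syngen import gen_ct_table


class TestMaxConcentration:
    def test_worked_example(self):
        assert max_concentration(0.05, 794.64) == pytest.approx(39.732, abs=1e-9)

    def test_identity_at_one_atm(self):
        assert max_concentration(1.0, 794.64) == pytest.approx(794.64)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            max_concentration(0.0, 794.64)
        with pytest.raises(ValueError):
            max_concentration(0.05, -1.0)


class TestCalibration:
    def test_gain(self):
        curve = calibrate(0.1, 2.1, 39.732)
        assert curve.gain_um_per_unit == pytest.approx(19.866)

    def test_endpoints_reproduced_exactly(self):
        curve = calibrate(0.1, 2.1, 39.732)
        assert curve.concentration(0.1) == pytest.approx(0.0, abs=1e-12)
        assert curve.concentration(2.1) == pytest.approx(39.732, abs=1e-12)

    def test_affine_in_reading(self):
        curve = calibrate(0.0, 2.0, 40.0)
        readings = np.linspace(-1.0, 3.0, 9)
        conc = curve.concentration(readings)
        assert np.allclose(np.diff(conc, 2), 0.0)  # equal steps in, equal steps out

    def test_equal_readings_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            calibrate(1.0, 1.0, 39.732)


class TestRawToConcentration:
    def test_constant_trace_at_max_reading(self):
        curve = calibrate(0.1, 2.1, 39.732)
        conc = raw_to_concentration(np.full(10, 2.1), curve)
        assert np.allclose(conc, 39.732)

    def test_zero_reading_trace_is_zero(self):
        curve = calibrate(0.1, 2.1, 39.732)
        assert np.allclose(raw_to_concentration(np.full(5, 0.1), curve), 0.0)

    def test_temperature_correction_reduces_warm_measurements(self):
        # solubility falls with temperature: same sensor signal = less gas
        assert h2_solubility(38.5) < h2_solubility(22.0)
        curve = calibrate(0.0, 2.0, 39.732)
        warm = raw_to_concentration(np.full(3, 2.0), curve, 38.5)
        assert np.all(warm < 39.732)
        same = raw_to_concentration(np.full(3, 2.0), curve, 22.0)
        assert np.allclose(same, 39.732)

    def test_solubility_anchor_at_22c(self):
        assert h2_solubility(22.0) == pytest.approx(794.64)

    def test_out_of_range_temperature_rejected(self):
        curve = calibrate(0.0, 2.0, 39.732)
        with pytest.raises(ValueError, match="temperature"):
            raw_to_concentration(np.ones(3), curve, 60.0)

    def test_plateau_found_in_ramp_to_steady_state(self):
        # emulate a 25-min 1 Hz trace reaching steady state at ~12 min
        t = np.arange(1500.0)
        conc = 13.0 * (1 - np.exp(-t / 180.0))
        conc += 0.05 * np.sin(t / 7.0)  # small sensor wobble
        plateau = find_plateau(conc, fs_hz=1.0, window_s=120.0)
        assert 600.0 <= plateau.start_s <= 900.0
        assert plateau.mean_um == pytest.approx(13.0, rel=0.05)


class TestDdct:
    @staticmethod
    def _noiseless_table(folds: dict[str, float]):
        table, _ = gen_ct_table(
            ["BDNF"], ["C-NT", *folds], {"BDNF": folds}, noise_sd=0.0, n_samples=3,
        )
        return table

    def test_calibrator_fold_is_one(self):
        table = self._noiseless_table({"A-HT": 2.0})
        per_sample, per_group = ddct(table, "BDNF", "C-NT")
        cal = per_group[per_group.group == "C-NT"].fold.iloc[0]
        assert cal == pytest.approx(1.0, abs=1e-12)

    def test_ddct_minus_one_is_fold_two(self):
        table = self._noiseless_table({"A-HT": 2.0})
        per_sample, _ = ddct(table, "BDNF", "C-NT")
        treated = per_sample[per_sample.group == "A-HT"]
        assert np.allclose(treated.ddct, -1.0)
        assert np.allclose(treated.fold, 2.0)

    @pytest.mark.parametrize("fold", [0.5, 1.0, 2.0, 10.0])
    def test_noiseless_roundtrip_exact(self, fold):
        table = self._noiseless_table({"A-HT": fold})
        _, per_group = ddct(table, "BDNF", "C-NT")
        got = per_group[per_group.group == "A-HT"].fold.iloc[0]
        assert got == pytest.approx(fold, abs=1e-9)

    def test_global_ct_shift_leaves_folds_unchanged(self):
        table = self._noiseless_table({"A-HT": 4.0})
        shifted = table.assign(ct=table.ct + 3.21)
        _, g1 = ddct(table, "BDNF", "C-NT")
        _, g2 = ddct(shifted, "BDNF", "C-NT")
        assert np.allclose(g1.fold, g2.fold)

    def test_per_sample_shift_of_target_and_refs_cancels(self):
        table = self._noiseless_table({"A-HT": 4.0})
        sample = table["sample"].iloc[0]
        bumped = table.copy()
        bumped.loc[bumped["sample"] == sample, "ct"] += 1.5
        _, g1 = ddct(table, "BDNF", "C-NT")
        _, g2 = ddct(bumped, "BDNF", "C-NT")
        assert np.allclose(g1.fold, g2.fold)

    def test_mean_ct_equals_geometric_mean_of_quantities(self):
        ct1, ct2 = 19.3, 21.7
        mean_ct_quantity = 2.0 ** (-(ct1 + ct2) / 2)
        geometric_mean = np.sqrt(2.0**-ct1 * 2.0**-ct2)
        assert mean_ct_quantity == pytest.approx(geometric_mean, rel=1e-12)

    @pytest.mark.filterwarnings("ignore:.*replicate set.*:UserWarning")
    def test_noisy_recovery_within_30_percent(self):
        folds = {0.5: [], 2.0: [], 10.0: []}
        for seed in range(20):
            table, _ = gen_ct_table(
                ["BDNF"], ["C-NT", "f05", "f2", "f10"],
                {"BDNF": {"f05": 0.5, "f2": 2.0, "f10": 10.0}},
                noise_sd=0.3, n_samples=7, seed=seed,
            )
            _, per_group = ddct(table, "BDNF", "C-NT")
            for grp, truth in [("f05", 0.5), ("f2", 2.0), ("f10", 10.0)]:
                folds[truth].append(per_group[per_group.group == grp].fold.iloc[0])
        for truth, values in folds.items():
            assert abs(np.median(values) - truth) <= 0.3 * truth

    def test_sample_missing_reference_dropped_with_warning(self):
        table = self._noiseless_table({"A-HT": 2.0})
        sample = table["sample"].iloc[0]
        broken = table[~((table["sample"] == sample) & (table.gene == "GAPDH"))]
        with pytest.warns(UserWarning, match="dropped 1 sample"):
            per_sample, _ = ddct(broken, "BDNF", "C-NT")
        assert sample not in set(per_sample["sample"])

    def test_empty_calibrator_rejected(self):
        table = self._noiseless_table({"A-HT": 2.0})
        with pytest.raises(ValueError, match="calibrator"):
            ddct(table, "BDNF", "no-such-group")

    def test_wide_replicate_spread_warns(self):
        table = self._noiseless_table({"A-HT": 2.0})
        table.loc[0, "ct"] += 2.5
        with pytest.warns(UserWarning, match="replicate"):
            ddct(table, "BDNF", "C-NT")

    def test_single_reference_mode(self):
        table = self._noiseless_table({"A-HT": 2.0})
        _, per_group = ddct(table, "BDNF", "C-NT", reference_mode="single")
        got = per_group[per_group.group == "A-HT"].fold.iloc[0]
        assert got == pytest.approx(2.0, abs=1e-9)
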