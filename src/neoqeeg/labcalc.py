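"""Laboratory calculations: H₂ microsensor calibration and ΔΔCt expression.

**H₂ sensor.**  Amperometric H₂ microsensors are calibrated at two points:
a zero reading in N₂-bubbled water and a maximal reading in water
equilibrated with 5% H₂ (partial pressure 0.05 atm).  The maximal
concentration is partial pressure × solubility — with the tabulated
solubility of 794.64 µmol L⁻¹ atm⁻¹ at 22 °C this gives 39.732 µM.  Because
calibration happens at room temperature while measurements are at body
temperature, concentrations are corrected by the ratio of H₂ solubilities
at the two temperatures (van 't Hoff temperature dependence of the Henry
constant, anchored at the 22 °C tabulated value).

**ΔΔCt.**  Relative gene expression from qPCR threshold cycles with perfect
(2-fold/cycle) amplification efficiency: replicate Cts are averaged per
sample and gene, the reference level is the mean Ct of the two reference
genes (PPIA2, GAPDH — equivalent to the geometric mean of their relative
quantities), ΔCt = Ct_target − Ct_ref, ΔΔCt subtracts the calibrator-group
mean ΔCt, and fold change = 2^(−ΔΔCt).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Tabulated H₂ solubility in water at the calibration temperature.
H2_SOLUBILITY_22C_UM_PER_ATM = 794.64
_H2_VANT_HOFF_K = 530.0  # d(ln S)/d(1/T), standard H₂ Henry-law dependence
_T22_K = 295.15

DEFAULT_REFERENCE_GENES = ("PPIA2", "GAPDH")


def max_concentration(partial_pressure_atm: float, solubility_um_per_atm: float) -> float:
    """Saturation concentration (µM) = partial pressure × solubility."""
    if partial_pressure_atm <= 0 or solubility_um_per_atm <= 0:
        raise ValueError("partial pressure and solubility must be positive")
    return partial_pressure_atm * solubility_um_per_atm


def h2_solubility(temperature_c: float) -> float:
    """H₂ solubility in water (µmol L⁻¹ atm⁻¹) at ``temperature_c``.

    Van 't Hoff extrapolation from the 22 °C anchor value; valid over the
    0–45 °C range relevant to calibration and physiology.
    """
    _check_temperature(temperature_c)
    t_k = temperature_c + 273.15
    return H2_SOLUBILITY_22C_UM_PER_ATM * math.exp(
        _H2_VANT_HOFF_K * (1.0 / t_k - 1.0 / _T22_K)
    )


def _check_temperature(temperature_c: float) -> None:
    if not 0.0 <= temperature_c <= 45.0:
        raise ValueError(
            f"temperature {temperature_c} °C outside the supported 0–45 °C range"
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """Two-point linear sensor calibration (reading → µM)."""

    zero_reading: float
    max_reading: float
    max_concentration_um: float
    temperature_c: float = 22.0

    def __post_init__(self) -> None:
        if self.max_reading == self.zero_reading:
            raise ValueError("zero and maximal readings must differ")
        if self.max_concentration_um <= 0:
            raise ValueError("maximal concentration must be positive")
        _check_temperature(self.temperature_c)

    @property
    def gain_um_per_unit(self) -> float:
        return self.max_concentration_um / (self.max_reading - self.zero_reading)

    def concentration(self, reading) -> np.ndarray | float:
        return (np.asarray(reading, dtype=float) - self.zero_reading) * self.gain_um_per_unit


def calibrate(
    zero_reading: float,
    max_reading: float,
    max_concentration_um: float,
    temperature_c: float = 22.0,
) -> CalibrationCurve:
    """Two-point calibration through (zero, 0) and (max reading, max µM)."""
    return CalibrationCurve(zero_reading, max_reading, max_concentration_um,
                            temperature_c)


@dataclass(frozen=True)
class Plateau:
    """Steady-state segment of a concentration trace."""

    start_s: float
    end_s: float
    mean_um: float
    sd_um: float


def raw_to_concentration(
    trace: np.ndarray,
    curve: CalibrationCurve,
    measurement_temperature_c: float | None = None,
    fs_hz: float = 1.0,
) -> np.ndarray:
    """Convert a raw sensor trace (1 Hz by default) to concentrations in µM.

    When a measurement temperature is given, concentrations are multiplied
    by ``solubility(measurement T) / solubility(calibration T)`` — the same
    sensor signal corresponds to less dissolved gas at body temperature.
    """
    conc = curve.concentration(np.asarray(trace, dtype=float))
    if measurement_temperature_c is not None:
        conc = conc * (
            h2_solubility(measurement_temperature_c)
            / h2_solubility(curve.temperature_c)
        )
    return conc


def find_plateau(
    concentration_um: np.ndarray,
    fs_hz: float = 1.0,
    window_s: float = 120.0,
    slope_tol_um_per_s: float = 0.001,
) -> Plateau:
    """Locate the steady state of a ramp-to-plateau trace.

    Scans fixed windows for the earliest one whose least-squares slope stays
    within ``slope_tol_um_per_s``; the plateau runs from there to the end of
    the trace and is reported as mean ± SD.
    """
    x = np.asarray(concentration_um, dtype=float)
    win = int(round(window_s * fs_hz))
    if len(x) < win:
        raise ValueError("trace shorter than one plateau window")
    t = np.arange(win) / fs_hz
    t = t - t.mean()
    denom = float((t * t).sum())
    start = None
    for i in range(0, len(x) - win + 1):
        seg = x[i : i + win]
        slope = float((t * (seg - seg.mean())).sum()) / denom
        if abs(slope) <= slope_tol_um_per_s:
            start = i
            break
    if start is None:
        raise ValueError("no steady state found within slope tolerance")
    tail = x[start:]
    return Plateau(
        start_s=start / fs_hz,
        end_s=len(x) / fs_hz,
        mean_um=float(tail.mean()),
        sd_um=float(tail.std(ddof=1)),
    )


# --------------------------------------------------------------------------
# ΔΔCt

def ddct(
    table: pd.DataFrame,
    target_gene: str,
    calibrator_group: str,
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES,
    reference_mode: str = "mean_ct",
    replicate_warn_cycles: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ΔΔCt relative expression for one target gene.

    Parameters
    ----------
    table
        Tidy Ct table with columns ``sample, group, gene, replicate, ct``.
    reference_mode
        ``mean_ct`` — reference level is the mean Ct of the reference genes
        (the default; equals the geometric mean of their quantities at
        perfect efficiency); ``single`` — use only the first reference gene.

    Returns
    -------
    per_sample, per_group
        Per-sample frame (sample, group, ct_target, ct_ref, dct, ddct, fold)
        and a per-group summary (mean fold of per-sample folds, n).

    Samples missing the target or a reference gene are dropped with a
    warning; replicate pairs spreading more than ``replicate_warn_cycles``
    are flagged with a warning but kept.
    """
    required = {"sample", "group", "gene", "replicate", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s) {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    refs = reference_genes[:1] if reference_mode == "single" else reference_genes
    if reference_mode not in ("mean_ct", "single"):
        raise ValueError(f"unknown reference mode {reference_mode!r}")

    spread = table.groupby(["sample", "gene"])["ct"].agg(lambda c: c.max() - c.min())
    wide_spread = spread[spread > replicate_warn_cycles]
    if len(wide_spread):
        warnings.warn(
            f"{len(wide_spread)} sample/gene replicate set(s) spread more than "
            f"{replicate_warn_cycles} cycle(s)",
            stacklevel=2,
        )

    mean_ct = (
        table.groupby(["sample", "group", "gene"], as_index=False)["ct"].mean()
    )
    by_sample = mean_ct.pivot_table(index=["sample", "group"], columns="gene",
                                    values="ct").reset_index()
    needed = [target_gene, *refs]
    absent = [g for g in needed if g not in by_sample.columns]
    if absent:
        raise ValueError(f"gene(s) {absent} absent from the Ct table")
    complete = by_sample.dropna(subset=needed)
    n_dropped = len(by_sample) - len(complete)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} sample(s) missing target or reference Cts",
            stacklevel=2,
        )

    out = complete[["sample", "group"]].copy()
    out["ct_target"] = complete[target_gene].to_numpy()
    out["ct_ref"] = complete[list(refs)].mean(axis=1).to_numpy()
    out["dct"] = out["ct_target"] - out["ct_ref"]
    cal = out.loc[out["group"] == calibrator_group, "dct"]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    out["ddct"] = out["dct"] - cal.mean()
    out["fold"] = 2.0 ** (-out["ddct"])

    per_group = (
        out.groupby("group", as_index=False)
        .agg(fold=("fold", "mean"), n=("fold", "size"))
    )
    return out.reset_index(drop=True), per_group
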