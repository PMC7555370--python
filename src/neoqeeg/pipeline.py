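"""End-to-end orchestration: config in, per-stage CSV/JSON artifacts out.

The pipeline runs the analysis chain in its natural order — load or
synthesize the EEG, bandpass, sliding Welch PSD, band powers (optionally
baseline-normalized), instantaneous spectral entropy, seizure detection,
hourly EEG scores, and VEP extraction when triggers are supplied — and
writes one CSV per stage plus a JSON manifest with the config hash, package
version, per-file checksums and accumulated warnings.  Independent stages
fail soft: a missing-trigger VEP stage is skipped with a warning rather
than aborting the run.

Every output CSV carries explicit unit-bearing column names (seconds,
0-based window-start frame times, µV², dimensionless entropy).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edf import read_edf
from .entropy import (
    DetectionParams,
    apply_threshold,
    detect_seizures,
    events_to_dataframe,
    inst_spent,
)
from .recording import EEGRecording
from .scoring import DEFAULT_EEG_SCORE_TABLE, hourly_scores, total_score
from .spectral import DEFAULT_BANDS, band_power, bandpass, normalize_to_baseline, sliding_psd
from .syngen import Segment, StateSchedule, compose_recording
from .vep import average_trials, extract_trials, normalize_vep, p100_metrics


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _load_recording(cfg: dict, seed: int) -> tuple[EEGRecording, list]:
    eeg = cfg.get("eeg", {})
    source = eeg.get("source", "syngen")
    if source == "csv":
        return EEGRecording.from_csv(eeg["path"], fs=eeg.get("fs")), []
    if source == "edf":
        return read_edf(eeg["path"], expected_fs=eeg.get("fs")), []
    if source == "syngen":
        segments = [
            Segment(
                state=s["state"],
                start_s=float(s["start_s"]),
                duration_s=float(s["duration_s"]),
                amplitude_uv=s.get("amplitude_uv"),
                rhythm_hz=s.get("rhythm_hz"),
            )
            for s in eeg.get("schedule", [
                {"state": "continuous", "start_s": 0.0, "duration_s": 300.0},
            ])
        ]
        rec, truth = compose_recording(
            StateSchedule(segments), n_leads=int(eeg.get("n_leads", 9)), seed=seed
        )
        return rec, truth.seizure_intervals
    raise ValueError(f"unknown eeg source {source!r}")


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run all configured stages; return the manifest (also written to JSON)."""
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(output_dir or config.get("output_dir", "neoqeeg_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    analysis = config.get("analysis", {})
    window_s = float(analysis.get("window_s", 30.0))
    step_s = float(analysis.get("step_s", 1.0))
    low_hz = float(analysis.get("low_hz", 1.0))
    high_hz = float(analysis.get("high_hz", 30.0))

    captured: list[str] = []
    outputs: dict[str, Path] = {}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        recording, _truth = _load_recording(config, seed)
        filtered = bandpass(recording, low_hz, high_hz)
        tfmap = sliding_psd(filtered, window_s=window_s, step_s=step_s)

        # band powers, optionally baseline-normalized
        frames = []
        baseline = analysis.get("baseline_s")
        for band in DEFAULT_BANDS:
            trace = band_power(tfmap, band)
            if baseline is not None:
                trace = normalize_to_baseline(trace, tuple(baseline))
            df = pd.DataFrame(trace.values.T, columns=list(trace.lead_names))
            df.insert(0, "frame_start_s", trace.frame_times_s)
            df.insert(1, "band", band.name)
            frames.append(df)
        bp_path = out_dir / "band_power.csv"
        pd.concat(frames).to_csv(bp_path, index=False)
        outputs["band_power"] = bp_path

        ent = apply_threshold(inst_spent(filtered, tfmap=tfmap))
        ent_path = out_dir / "inst_spent.csv"
        ent.to_dataframe().to_csv(ent_path, index=False)
        outputs["inst_spent"] = ent_path

        det_cfg = config.get("detection", {})
        params = DetectionParams(**{
            k: det_cfg[k] for k in det_cfg
            if k in {f.name for f in dataclasses.fields(DetectionParams)}
        })
        events = detect_seizures(filtered, params=params, tfmap=tfmap)
        ev_path = out_dir / "seizure_events.csv"
        events_to_dataframe(events).to_csv(ev_path, index=False)
        outputs["seizure_events"] = ev_path

        # hourly scores need at least one full hour
        if recording.duration_s >= 3600.0:
            record = hourly_scores(filtered, events, DEFAULT_EEG_SCORE_TABLE)
            sc = pd.DataFrame({
                "hour": np.arange(len(record.hourly_scores)),
                "score": record.hourly_scores,
            })
            sc_path = out_dir / "eeg_scores.csv"
            sc.to_csv(sc_path, index=False)
            outputs["eeg_scores"] = sc_path
            captured.append(f"total EEG score {total_score(record)}")
        else:
            warnings.warn("recording shorter than 1 h; hourly scoring skipped")

        vep_cfg = config.get("vep")
        if vep_cfg and vep_cfg.get("triggers_csv"):
            triggers = pd.read_csv(vep_cfg["triggers_csv"])["time_s"].to_numpy()
            trials = extract_trials(
                filtered if vep_cfg.get("use_filtered", False) else recording,
                triggers,
            )
            result = p100_metrics(average_trials(trials))
            if vep_cfg.get("baseline_metrics"):
                base = vep_cfg["baseline_metrics"]
                ref = dataclasses.replace(
                    result,
                    p100_amplitude_uv=float(base["amplitude_uv"]),
                    p100_latency_ms=float(base["latency_ms"]),
                )
                result = normalize_vep(result, ref)
            wf_path = out_dir / "vep_waveform.csv"
            pd.DataFrame({"time_ms": result.times_ms, "uv": result.waveform}
                         ).to_csv(wf_path, index=False)
            metrics_path = out_dir / "vep_metrics.csv"
            pd.DataFrame([{
                "n_trials": result.n_trials,
                "p100_latency_ms": result.p100_latency_ms,
                "p100_amplitude_uv": result.p100_amplitude_uv,
                "normalized_latency": result.normalized_latency,
                "normalized_amplitude": result.normalized_amplitude,
            }]).to_csv(metrics_path, index=False)
            outputs["vep_waveform"] = wf_path
            outputs["vep_metrics"] = metrics_path
        elif vep_cfg is not None:
            warnings.warn("vep section present but no triggers_csv; VEP stage skipped")

        captured.extend(str(w.message) for w in caught)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                    for k, p in outputs.items()},
        "warnings": captured,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
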