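"""EDF (European Data Format) reading and writing for :class:`EEGRecording`.

Reading goes through :mod:`mne`.  Writing is a compact EDF implementation
(fixed-width ASCII header, one data record per second, 16-bit samples): the
format's arithmetic is simple enough that the writer fits in a page, and the
write → read round trip is exercised against mne's reader in the test suite.
Voltages are stored with physical dimension µV; the 16-bit quantization step
is ``(physical_max − physical_min) / 65535``.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .recording import Annotation, EEGRecording

_HDR_DATE = _dt.datetime(2000, 1, 1, 0, 0, 0)  # fixed start stamp: reproducible files


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds EDF width {width}")
    return s.ljust(width).encode("ascii")


def write_edf(recording: EEGRecording, path: str | Path) -> None:
    """Write ``recording`` to ``path`` as EDF (µV, one data record per second).

    Trailing samples that do not fill a whole 1 s record are dropped (EDF
    records are fixed-length).  Annotations are not embedded; use the CSV
    sidecar from :mod:`neoqeeg.recording` for event intervals.
    """
    if recording.fs != int(recording.fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(recording.fs)
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one 1 s EDF data record")
    data = recording.data[:, : n_records * fs]
    n_sig = recording.n_leads

    # Physical range: symmetric, covering the data with headroom, never zero.
    phys_max = float(np.max(np.abs(data))) if np.any(data) else 1.0
    phys_max = max(phys_max * 1.01, 1e-6)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min) * gain) + dig_min, dig_min, dig_max
    ).astype("<i2")

    header = b"".join([
        _ascii("0", 8),                      # version
        _ascii("X X X X", 80),               # patient id (anonymous)
        _ascii("Startdate 01-JAN-2000 X X X", 80),
        _ascii(_HDR_DATE.strftime("%d.%m.%y"), 8),
        _ascii(_HDR_DATE.strftime("%H.%M.%S"), 8),
        _ascii(256 + 256 * n_sig, 8),        # header bytes
        _ascii("", 44),                      # reserved
        _ascii(n_records, 8),
        _ascii("1", 8),                      # record duration s
        _ascii(n_sig, 4),
    ])
    fields: list[tuple[object, int]] = []
    fields += [(name, 16) for name in recording.lead_names]
    fields += [("AgAgCl electrode", 80)] * n_sig
    fields += [("uV", 8)] * n_sig
    fields += [(f"{phys_min:.6g}", 8)] * n_sig
    fields += [(f"{phys_max:.6g}", 8)] * n_sig
    fields += [(dig_min, 8)] * n_sig
    fields += [(dig_max, 8)] * n_sig
    fields += [("", 80)] * n_sig             # prefiltering
    fields += [(fs, 8)] * n_sig              # samples per record
    fields += [("", 32)] * n_sig             # reserved
    header += b"".join(_ascii(v, w) for v, w in fields)

    with open(path, "wb") as fh:
        fh.write(header)
        # records: for each second, each signal's fs samples contiguously
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_edf(path: str | Path, expected_fs: float | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (voltages in µV).

    Parameters
    ----------
    expected_fs
        If given, reject files whose sampling rate differs (guards a pipeline
        configured for one rate against mismatched inputs).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise ValueError(
            f"{path}: sampling rate {fs} Hz does not match configured "
            f"{expected_fs} Hz"
        )
    data_uv = raw.get_data() * 1e6  # mne loads volts
    ann = [
        Annotation(float(a["onset"]), float(a["onset"] + a["duration"]),
                   str(a["description"]))
        for a in raw.annotations
    ]
    return EEGRecording(data_uv, fs=fs, lead_names=tuple(raw.ch_names),
                        annotations=ann)
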