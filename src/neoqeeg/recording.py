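"""In-memory containers for multichannel EEG and its annotations.

The central container is :class:`EEGRecording`: a ``(n_leads, n_samples)``
float array of voltages in microvolts at a fixed sampling rate, with lead
labels and a flat list of interval annotations (seizures, state labels,
stimulus triggers).  Everything downstream (filtering, spectra, entropy,
scoring) operates on this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Default 9-lead modified neonatal 10-20 montage (fronto-parietal +
#: occipital coverage, as used for piglet scalp recordings).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "C3", "C4", "Cz", "P3", "P4", "O1", "O2",
)

#: Acquisition sampling rate used throughout (Hz).
DEFAULT_FS: float = 256.0


@dataclass(frozen=True)
class Annotation:
    """A labelled time interval on a recording (seconds from record start)."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError(
                f"annotation end {self.end_s} precedes start {self.start_s}"
            )


@dataclass
class EEGRecording:
    """Multichannel voltage time series in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_leads, n_samples)``, physical unit µV.
    fs
        Sampling rate in Hz.
    lead_names
        One label per row of ``data``.
    annotations
        Labelled intervals (seizure ground truth, state segments, triggers).
    """

    data: np.ndarray
    fs: float = DEFAULT_FS
    lead_names: tuple[str, ...] = DEFAULT_MONTAGE
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.lead_names = tuple(self.lead_names)
        if len(self.lead_names) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.lead_names)} lead names"
            )

    @property
    def n_leads(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based)."""
        return np.arange(self.n_samples) / self.fs

    def lead_index(self, name: str) -> int:
        try:
            return self.lead_names.index(name)
        except ValueError:
            raise KeyError(
                f"lead {name!r} not in montage {self.lead_names}"
            ) from None

    def slice_time(self, start_s: float, end_s: float) -> "EEGRecording":
        """Return the sub-recording covering ``[start_s, end_s)``."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        if not 0 <= i0 < i1 <= self.n_samples:
            raise ValueError(
                f"interval [{start_s}, {end_s}) s outside recording "
                f"of {self.duration_s} s"
            )
        kept = [
            a for a in self.annotations
            if a.end_s > start_s and a.start_s < end_s
        ]
        shifted = [
            Annotation(max(a.start_s - start_s, 0.0),
                       min(a.end_s, end_s) - start_s, a.label)
            for a in kept
        ]
        return replace(self, data=self.data[:, i0:i1], annotations=shifted)

    def with_annotations(self, annotations: list[Annotation]) -> "EEGRecording":
        return replace(self, annotations=list(annotations))

    # ---------------------------------------------------------------- CSV I/O
    # Plain-matrix dialect: first column time in seconds, one column per lead,
    # header row of names.  Annotations travel in a sidecar CSV
    # (start_s, end_s, label).

    def to_csv(self, path: str | Path, annotations_path: str | Path | None = None) -> None:
        """Write the recording as a time + leads matrix CSV (values in µV)."""
        df = pd.DataFrame(self.data.T, columns=list(self.lead_names))
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False, float_format="%.6f")
        if annotations_path is not None:
            annotations_to_csv(self.annotations, annotations_path)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        fs: float | None = None,
        annotations_path: str | Path | None = None,
    ) -> "EEGRecording":
        """Read the plain-matrix CSV dialect written by :meth:`to_csv`."""
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: expected a 'time_s' first column")
        t = df["time_s"].to_numpy()
        if fs is None:
            if len(t) < 2:
                raise ValueError(f"{path}: cannot infer sampling rate from one row")
            fs = 1.0 / np.median(np.diff(t))
            # timestamps are written with finite precision; snap to the
            # integer rate they were sampled at
            if abs(fs - round(fs)) < 0.05:
                fs = float(round(fs))
        leads = [c for c in df.columns if c != "time_s"]
        ann: list[Annotation] = []
        if annotations_path is not None:
            ann = annotations_from_csv(annotations_path)
        return cls(df[leads].to_numpy().T, fs=float(fs),
                   lead_names=tuple(leads), annotations=ann)


def annotations_to_csv(annotations: list[Annotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.start_s, a.end_s, a.label) for a in annotations],
        columns=["start_s", "end_s", "label"],
    ).to_csv(path, index=False)


def annotations_from_csv(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path)
    return [
        Annotation(float(r.start_s), float(r.end_s), str(r.label))
        for r in df.itertuples()
    ]
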