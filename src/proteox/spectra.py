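"""Centroided spectral data container and plain-text I/O.

A :class:`SpectralDataset` holds a sequence of centroid scans with
acquisition times in minutes.  The same container covers LC-MS runs (the
time axis is retention time) and direct-infusion time courses (the time
axis is infusion time).

The native on-disk format is a documented long-form CSV with columns
``scan_time_min, mz, intensity``; mzML files can be read through pyteomics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["Scan", "SpectralDataset", "read_spectra_csv", "write_spectra_csv", "read_mzml"]


@dataclass(frozen=True)
class Scan:
    time_min: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity arrays differ in length")


@dataclass(frozen=True)
class SpectralDataset:
    """An ordered collection of centroid scans."""

    scans: tuple[Scan, ...]

    def __post_init__(self):
        times = [s.time_min for s in self.scans]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("scan times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self) -> Iterator[Scan]:
        return iter(self.scans)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_min for s in self.scans])

    def between(self, t0: float, t1: float) -> "SpectralDataset":
        """Scans with time in the half-open window [t0, t1)."""
        return SpectralDataset(tuple(s for s in self.scans if t0 <= s.time_min < t1))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.time_min, m, i)
            for s in self.scans
            for m, i in zip(s.mz, s.intensity)
        ]
        return pd.DataFrame(rows, columns=["scan_time_min", "mz", "intensity"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectralDataset":
        scans = []
        for t, grp in df.groupby("scan_time_min", sort=True):
            scans.append(
                Scan(float(t), grp["mz"].to_numpy(float), grp["intensity"].to_numpy(float))
            )
        return cls(tuple(scans))


def write_spectra_csv(dataset: SpectralDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_spectra_csv(path) -> SpectralDataset:
    return SpectralDataset.from_frame(pd.read_csv(path))


def read_mzml(path) -> SpectralDataset:
    """Read centroid MS1 scans from an mzML file (retention times in minutes)."""
    from pyteomics import mzml

    scans = []
    with mzml.MzML(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            t = spec["scanList"]["scan"][0]["scan start time"]
            # pyteomics returns a unitfloat; mzML times may be in seconds
            if getattr(t, "unit_info", "minute") == "second":
                t = float(t) / 60.0
            scans.append(Scan(float(t), np.asarray(spec["m/z array"]), np.asarray(spec["intensity array"])))
    scans.sort(key=lambda s: s.time_min)
    return SpectralDataset(tuple(scans))
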