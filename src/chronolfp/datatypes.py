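"""Core in-memory containers shared across the pipeline.

Recordings are represented as a raw voltage trace (``RawTrace``), a binned
scalar series (``BinnedSeries``: band power, RMS amplitude, or z-units), or a
bins x bands matrix (``BandPowerSeries``), each carrying the recording
metadata (animal, genotype, region, light regimen, Zeitgeber start time and
sampling rate).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import BAND_NAMES

GENOTYPES = ("wildtype", "cry_ko")
REGIONS = ("SCN", "NAC")
REGIMENS = ("LD", "DD")


@dataclass(frozen=True)
class RecordingMeta:
    """Identity and acquisition metadata of one recording."""

    animal_id: str = "sim"
    genotype: str = "wildtype"
    region: str = "SCN"
    regimen: str = "LD"
    zt_start: float = 0.0
    fs: float = 500.0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        if self.region.upper() not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        object.__setattr__(self, "region", self.region.upper())
        if self.regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {self.regimen!r}; expected one of {REGIMENS}")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if not 0.0 <= self.zt_start < 24.0:
            raise ValueError("zt_start must lie in [0, 24)")

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "genotype": self.genotype,
            "region": self.region,
            "regimen": self.regimen,
            "zt_start": self.zt_start,
            "fs": self.fs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        return cls(**{k: d[k] for k in ("animal_id", "genotype", "region", "regimen", "zt_start", "fs")})


@dataclass
class RawTrace:
    """Uniformly sampled voltage trace in mV."""

    meta: RecordingMeta
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def fs(self) -> float:
        return self.meta.fs

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "RawTrace":
        return RawTrace(meta=self.meta, samples=samples)


def _check_bins(zt_hours: np.ndarray, bin_s: float) -> None:
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    if zt_hours.size >= 2:
        dz = np.diff(zt_hours)
        if np.any(dz <= 0):
            raise ValueError("zt_hours must be strictly increasing")


@dataclass
class BinnedSeries:
    """One scalar per time bin; ``kind`` flags the unit (power/amplitude/z)."""

    meta: RecordingMeta
    bin_s: float
    zt_hours: np.ndarray
    values: np.ndarray
    kind: str = "power"
    band: str | None = None

    def __post_init__(self) -> None:
        self.zt_hours = np.asarray(self.zt_hours, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.zt_hours.shape != self.values.shape or self.values.ndim != 1:
            raise ValueError("zt_hours and values must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        _check_bins(self.zt_hours, self.bin_s)

    @property
    def n_bins(self) -> int:
        return self.values.size

    def is_gap_free(self, rtol: float = 1e-6) -> bool:
        if self.n_bins < 2:
            return True
        dz = np.diff(self.zt_hours)
        return bool(np.allclose(dz, self.bin_s / 3600.0, rtol=rtol, atol=1e-9))

    def replace(self, **kw) -> "BinnedSeries":
        return replace(self, **kw)


@dataclass
class BandPowerSeries:
    """Time bins x canonical bands power matrix (arbitrary units, >= 0)."""

    meta: RecordingMeta
    bin_s: float
    zt_hours: np.ndarray
    values: np.ndarray
    band_names: Sequence[str] = field(default_factory=lambda: BAND_NAMES)

    def __post_init__(self) -> None:
        self.zt_hours = np.asarray(self.zt_hours, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.band_names = tuple(self.band_names)
        if self.values.ndim != 2 or self.values.shape[0] != self.zt_hours.size:
            raise ValueError("values must be (n_bins, n_bands)")
        if self.values.shape[1] != len(self.band_names):
            raise ValueError("column count must match band_names")
        if np.any(self.values < 0):
            raise ValueError("band power must be nonnegative")
        _check_bins(self.zt_hours, self.bin_s)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def band(self, name: str) -> BinnedSeries:
        """Extract one band as a BinnedSeries."""
        j = self.band_names.index(name)
        return BinnedSeries(
            meta=self.meta, bin_s=self.bin_s, zt_hours=self.zt_hours,
            values=self.values[:, j], kind="power", band=name,
        )

    def iter_bands(self):
        for name in self.band_names:
            yield name, self.band(name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.band_names))
        df.insert(0, "zt_hours", self.zt_hours)
        return df

    def is_gap_free(self, rtol: float = 1e-6) -> bool:
        if self.n_bins < 2:
            return True
        dz = np.diff(self.zt_hours)
        return bool(np.allclose(dz, self.bin_s / 3600.0, rtol=rtol, atol=1e-9))
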