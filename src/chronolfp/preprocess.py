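"""Raw-trace conditioning and spectral decomposition.

Implements the standard conditioning chain for chronic LFP telemetry:
zero-phase high-pass filtering at 0.5 Hz, amplitude-threshold artifact
screening (1 mV), selection of a gap-free 24-h epoch starting at ZT 0,
per-bin periodogram decomposition into the ten canonical bands, per-bin RMS
amplitude, z-scoring, the spectral area-under-curve summary of a binned
24-h series, hourly profiles, and a display spectrogram.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .bands import BandDefinition, CANONICAL_BANDS, F_TOTAL_HI, F_TOTAL_LO
from .datatypes import BandPowerSeries, BinnedSeries, RawTrace


@dataclass(frozen=True)
class PreprocessConfig:
    hp_cutoff_hz: float = 0.5
    hp_order: int = 4
    artifact_threshold_mv: float = 1.0
    artifact_warn_count: int = 30
    # total 0.5-70 Hz power below this fraction of the artifact threshold's
    # scale flags a flat, contentless recording for exclusion
    flat_power_floor: float = 1e-12
    spectrogram_window: int = 32
    epoch_start_zt: float = 0.0
    epoch_length_h: float = 24.0
    taper: str | None = None  # optional per-bin taper; None = rectangular


@dataclass
class ArtifactReport:
    mask: np.ndarray          # bool per sample, True inside an excursion
    count: int                # number of contiguous suprathreshold excursions
    warn_flag: bool
    exclude_flag: bool


def highpass(trace: RawTrace, cfg: PreprocessConfig = PreprocessConfig()) -> RawTrace:
    """Zero-phase Butterworth high-pass (forward-backward)."""
    nyq = trace.fs / 2.0
    if cfg.hp_cutoff_hz >= nyq:
        raise ValueError(f"high-pass cutoff {cfg.hp_cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(cfg.hp_order, cfg.hp_cutoff_hz, btype="highpass",
                        fs=trace.fs, output="sos")
    return trace.with_samples(signal.sosfiltfilt(sos, trace.samples))


def detect_artifacts(trace: RawTrace, cfg: PreprocessConfig = PreprocessConfig()) -> ArtifactReport:
    """Mark contiguous |v| > threshold excursions; flag noisy or flat traces."""
    x = trace.samples
    if x.size == 0:
        raise ValueError("empty trace")
    above = np.abs(x) > cfg.artifact_threshold_mv
    # count maximal runs of True
    d = np.diff(above.astype(np.int8))
    count = int(np.sum(d == 1) + (1 if above[0] else 0))
    total_power = band_total_power(x, trace.fs)
    exclude = bool(total_power < cfg.flat_power_floor)
    return ArtifactReport(mask=above, count=count,
                          warn_flag=count > cfg.artifact_warn_count,
                          exclude_flag=exclude)


def _onesided_power(x2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram power rows scaled so each row sums to the row's
    sum of squared samples (Parseval)."""
    n = x2d.shape[-1]
    spec = np.fft.rfft(x2d, axis=-1)
    p = (np.abs(spec) ** 2) / n
    # double the interior coefficients so the one-sided sum matches Parseval
    scale = np.full(p.shape[-1], 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return p * scale, np.arange(p.shape[-1])


def band_total_power(x: np.ndarray, fs: float,
                     f_lo: float = F_TOTAL_LO, f_hi: float = F_TOTAL_HI) -> float:
    """Total one-sided periodogram power in [f_lo, f_hi]."""
    p, _ = _onesided_power(np.asarray(x, dtype=float)[None, :])
    f = np.fft.rfftfreq(np.asarray(x).size, d=1.0 / fs)
    sel = (f >= f_lo) & (f <= f_hi)
    return float(np.sum(p[0, sel]))


def excise_artifacts(series: BinnedSeries | BandPowerSeries, mask: np.ndarray,
                     fs: float | None = None) -> BinnedSeries | BandPowerSeries:
    """Drop every bin that overlaps a masked (artifactual) sample.

    ``mask`` is per raw sample; bin k covers samples
    [k*bin_s*fs, (k+1)*bin_s*fs). Bin timestamps are preserved, so the
    output may contain gaps; downstream 24-h operations require gap-free
    input after epoch re-selection.
    """
    fs = series.meta.fs if fs is None else fs
    mask = np.asarray(mask, dtype=bool)
    spb = int(round(series.bin_s * fs))
    n = series.n_bins
    keep = np.ones(n, dtype=bool)
    for k in range(n):
        lo, hi = k * spb, min((k + 1) * spb, mask.size)
        if lo < mask.size and mask[lo:hi].any():
            keep[k] = False
    if not keep.any():
        raise ValueError("artifact excision removed every bin")
    if isinstance(series, BandPowerSeries):
        return BandPowerSeries(meta=series.meta, bin_s=series.bin_s,
                               zt_hours=series.zt_hours[keep],
                               values=series.values[keep], band_names=series.band_names)
    return series.replace(zt_hours=series.zt_hours[keep], values=series.values[keep])


def extract_epoch(series: BinnedSeries | BandPowerSeries, start_zt: float = 0.0,
                  length_h: float = 24.0) -> BinnedSeries | BandPowerSeries:
    """Select a gap-free window [start_zt, start_zt + length_h)."""
    zt = series.zt_hours
    sel = (zt >= start_zt) & (zt < start_zt + length_h)
    expected = int(round(length_h * 3600.0 / series.bin_s))
    idx = np.nonzero(sel)[0]
    if idx.size != expected:
        # name the first missing bin
        want = start_zt + np.arange(expected) * series.bin_s / 3600.0
        have = set(np.round(zt[sel], 9))
        for w in want:
            if round(float(w), 9) not in have:
                raise ValueError(f"gap inside epoch: missing bin at zt={float(w):.6f} h")
        raise ValueError("epoch window does not contain the expected number of bins")
    new_zt = zt[idx] - start_zt
    if isinstance(series, BandPowerSeries):
        return BandPowerSeries(meta=series.meta, bin_s=series.bin_s,
                               zt_hours=new_zt, values=series.values[idx],
                               band_names=series.band_names)
    return series.replace(zt_hours=new_zt, values=series.values[idx])


def _bin_view(x: np.ndarray, samples_per_bin: int) -> np.ndarray:
    n_bins = x.size // samples_per_bin
    return x[: n_bins * samples_per_bin].reshape(n_bins, samples_per_bin)


def band_power_series(trace: RawTrace, bin_s: float = 4.0,
                      bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
                      taper: str | None = None) -> BandPowerSeries:
    """Per-bin periodogram band powers.

    For every bin, the power in band [f_lo, f_hi) is the sum of squared DFT
    magnitudes over that half-open range (the top band is closed at its
    upper edge), computed on the bin's samples with a rectangular window by
    default. Trailing samples not filling a whole bin are discarded.
    """
    spb = int(round(bin_s * trace.fs))
    f_lo_min = min(b.f_lo for b in bands)
    if bin_s < 2.0 / f_lo_min:
        raise ValueError(f"bin of {bin_s}s cannot resolve the {f_lo_min}-Hz band edge")
    xb = _bin_view(trace.samples, spb)
    window = np.ones(spb) if taper is None else signal.get_window(taper, spb)
    freqs = np.fft.rfftfreq(spb, d=1.0 / trace.fs)
    power, _ = _onesided_power(xb * window)
    f_top = max(b.f_hi for b in bands)
    values = np.empty((xb.shape[0], len(bands)))
    for j, b in enumerate(bands):
        if b.f_hi == f_top:
            sel = (freqs >= b.f_lo) & (freqs <= b.f_hi)
        else:
            sel = (freqs >= b.f_lo) & (freqs < b.f_hi)
        values[:, j] = power[:, sel].sum(axis=1)
    zt = trace.meta.zt_start + np.arange(xb.shape[0]) * bin_s / 3600.0
    return BandPowerSeries(meta=trace.meta, bin_s=bin_s, zt_hours=zt, values=values,
                           band_names=tuple(b.name for b in bands))


def amplitude_series(trace: RawTrace, bin_s: float = 4.0) -> BinnedSeries:
    """Per-bin RMS amplitude (mV)."""
    spb = int(round(bin_s * trace.fs))
    xb = _bin_view(trace.samples, spb)
    rms = np.sqrt(np.mean(xb ** 2, axis=1))
    zt = trace.meta.zt_start + np.arange(xb.shape[0]) * bin_s / 3600.0
    return BinnedSeries(meta=trace.meta, bin_s=bin_s, zt_hours=zt, values=rms,
                        kind="amplitude")


def zscore(series: BinnedSeries) -> BinnedSeries:
    """Standardize to mean 0, SD 1 (population SD)."""
    v = series.values
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant series")
    return series.replace(values=(v - v.mean()) / sd, kind="z")


def zscore_values(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant array")
    return (v - v.mean()) / sd


def fft_auc(series: BinnedSeries, expected_bins: int | None = 21600) -> float:
    """Area under |DFT| of a binned 24-h series (trapezoid over frequency
    index, DC term included)."""
    v = series.values
    if expected_bins is not None and v.size != expected_bins:
        raise ValueError(f"expected {expected_bins} bins, got {v.size}")
    mag = np.abs(np.fft.rfft(v))
    return float(np.trapezoid(mag))


def hourly_profile(series: BinnedSeries) -> "np.ndarray":
    """24 x (mean, sd) summary; hour h summarizes bins with zt in [h, h+1)."""
    if not series.is_gap_free():
        raise ValueError("hourly_profile requires a gap-free series")
    hours = np.floor(series.zt_hours).astype(int)
    out = np.full((24, 2), np.nan)
    for h in range(24):
        sel = hours == h
        if sel.any():
            out[h, 0] = series.values[sel].mean()
            out[h, 1] = series.values[sel].std()
    if np.isnan(out).any():
        raise ValueError("series does not cover all 24 hours")
    return out


def spectrogram(trace: RawTrace, window: int = 32):
    """Short-time FFT magnitude matrix for display.

    Returns (freqs_hz, times_s, magnitude) with non-overlapping windows of
    the given sample length, matching a plain specgram display.
    """
    if window > trace.samples.size:
        raise ValueError("window longer than trace")
    f, t, sxx = signal.spectrogram(trace.samples, fs=trace.fs, window="hann",
                                   nperseg=window, noverlap=0, mode="magnitude")
    return f, t, sxx
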