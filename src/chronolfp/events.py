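"""Transient oscillatory-event detection via Morlet continuous wavelet
transform.

The raw trace is convolved with complex Morlet wavelets of fixed width
(7 cycles: the Gaussian envelope's SD in time is n_cycles/(2*pi*f)) on a
log-spaced frequency grid, giving a time-frequency power plane with a
cone-of-influence marking edge-contaminated cells.  Two detectors operate on
the plane:

* significance bouts — power is whitened against a theoretical AR(1)
  red-noise background (lag-1 coefficient estimated from the segment,
  globally calibrated to unit mean), and the whitened *amplitude* is
  thresholded at 1.96, i.e. roughly the 95% criterion for a unit-RMS
  Rayleigh amplitude; maximal suprathreshold runs per frequency row are the
  bouts, and local maxima of the smoothed bout-count spectrum identify the
  event-prone frequencies;
* percentile events — within each frequency row, temporal local maxima
  exceeding the row's empirical 98th percentile are events, with duration
  the contiguous suprathreshold span, interval the gap to the next event in
  the row, and relative power the peak as a fraction of the row median.

Both detectors use only relative thresholds, so event counts are invariant
under rescaling the trace.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .datatypes import RawTrace


@dataclass(frozen=True)
class EventConfig:
    cycles: float = 7.0
    significance_z: float = 1.96
    percentile: float = 98.0
    f_min: float = 2.0
    f_max: float = 120.0
    voices_per_octave: int = 12
    zt_windows: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    window_min: float = 6.0

    def __post_init__(self) -> None:
        if self.cycles <= 0:
            raise ValueError("cycles must be > 0")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")

    def frequency_grid(self) -> np.ndarray:
        n_oct = np.log2(self.f_max / self.f_min)
        n = int(np.floor(n_oct * self.voices_per_octave)) + 1
        return self.f_min * 2.0 ** (np.arange(n) / self.voices_per_octave)


@dataclass
class TimeFrequencyPlane:
    times_s: np.ndarray
    frequencies_hz: np.ndarray    # log-spaced, ascending
    power: np.ndarray             # (n_freq, n_times), |coefficient|^2
    coi_mask: np.ndarray          # True where inside the cone of influence (valid)
    fs: float

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def _morlet(fs: float, freq: float, cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, L2-ish normalized, truncated at 5 sigma."""
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    wave = gauss * np.exp(2j * np.pi * freq * t)
    wave -= wave.mean()  # zero-mean correction
    norm = np.sqrt(np.sum(np.abs(wave) ** 2))
    return wave / norm


def cwt_power(trace: RawTrace | np.ndarray, frequencies: np.ndarray | None = None,
              cycles: float = 7.0, fs: float | None = None,
              cfg: EventConfig | None = None) -> TimeFrequencyPlane:
    """Morlet wavelet power plane with cone-of-influence marking."""
    if cfg is None:
        cfg = EventConfig(cycles=cycles)
    if isinstance(trace, RawTrace):
        x, fs = trace.samples, trace.fs
    else:
        x = np.asarray(trace, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    freqs = cfg.frequency_grid() if frequencies is None else np.asarray(frequencies, dtype=float)
    if np.any(freqs >= fs / 2.0):
        raise ValueError("frequencies must be below Nyquist")
    n = x.size
    power = np.empty((freqs.size, n))
    coi = np.ones((freqs.size, n), dtype=bool)
    t_idx = np.arange(n)
    for i, f in enumerate(freqs):
        w = _morlet(fs, f, cfg.cycles)
        coefs = fftconvolve(x, w, mode="same")
        power[i] = np.abs(coefs) ** 2
        # edge influence extends sqrt(2)*sigma_t from either end
        sigma_t = cfg.cycles / (2.0 * np.pi * f)
        edge = int(np.ceil(np.sqrt(2.0) * sigma_t * fs))
        coi[i] = (t_idx >= edge) & (t_idx < n - edge)
    return TimeFrequencyPlane(times_s=t_idx / fs, frequencies_hz=freqs,
                              power=power, coi_mask=coi, fs=fs)


# ---------------------------------------------------------------------------
# red-noise significance bouts
# ---------------------------------------------------------------------------

@dataclass
class Bout:
    frequency_hz: float
    start_s: float
    end_s: float


def _ar1_coefficient(x: np.ndarray) -> float:
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        raise ValueError("degenerate (constant) trace")
    return float(np.clip(np.dot(xc[:-1], xc[1:]) / denom, -0.999, 0.999))


def _red_noise_spectrum(freqs: np.ndarray, fs: float, rho: float) -> np.ndarray:
    """Theoretical AR(1) power spectrum (unit variance), evaluated per freq."""
    return (1.0 - rho ** 2) / (1.0 + rho ** 2 - 2.0 * rho * np.cos(2.0 * np.pi * freqs / fs))


def significance_bouts(plane: TimeFrequencyPlane, trace: RawTrace | np.ndarray,
                       z: float = 1.96) -> dict:
    """Suprathreshold bouts per frequency against an AR(1) background.

    The plane's power is divided by the theoretical red-noise spectrum at
    each frequency (lag-1 coefficient estimated from the analyzed segment)
    and scaled to unit mean over valid cells; maximal runs where the ratio
    exceeds ``z`` are bouts.  Returns per-frequency bout counts and spans.
    """
    x = trace.samples if isinstance(trace, RawTrace) else np.asarray(trace, dtype=float)
    rho = _ar1_coefficient(x)
    bg = _red_noise_spectrum(plane.frequencies_hz, plane.fs, rho)
    # calibrate the background globally so the whitened power has unit mean
    # over valid cells; the significance ratio is the whitened *amplitude*
    # (RMS 1 under the background), thresholded at z
    whitened = plane.power / bg[:, None]
    valid_all = plane.coi_mask
    scale = whitened[valid_all].mean() if valid_all.any() else 1.0
    if scale <= 0:
        raise ValueError("degenerate power plane")
    ratio = np.sqrt(whitened / scale)
    counts = np.zeros(plane.frequencies_hz.size, dtype=int)
    bouts: list[Bout] = []
    for i, f in enumerate(plane.frequencies_hz):
        above = (ratio[i] > z) & plane.coi_mask[i]
        starts, ends = _runs(above)
        counts[i] = starts.size
        for s, e in zip(starts, ends):
            bouts.append(Bout(frequency_hz=float(f),
                              start_s=float(plane.times_s[s]),
                              end_s=float(plane.times_s[e - 1])))
    return {"counts": counts, "bouts": bouts,
            "frequencies_hz": plane.frequencies_hz,
            "ratio": ratio, "rho": rho}


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and end (exclusive) indices of maximal True runs."""
    m = np.asarray(mask, dtype=bool)
    d = np.diff(m.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if m.size and m[0]:
        starts = np.r_[0, starts]
    if m.size and m[-1]:
        ends = np.r_[ends, m.size]
    return starts, ends


def find_event_peak_freqs(bout_counts: np.ndarray, frequencies_hz: np.ndarray) -> list[float]:
    """Strict local maxima of the 3-point-smoothed bout-count spectrum.

    Endpoints are excluded; a monotone count profile therefore yields an
    empty list.  Ties break toward the lower frequency.
    """
    c = np.asarray(bout_counts, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 frequencies")
    padded = np.r_[c[0], c, c[-1]]  # replicate-pad so endpoints average cleanly
    sm = np.convolve(padded, np.ones(3) / 3.0, mode="valid")
    peaks = []
    for i in range(1, c.size - 1):
        if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1] and sm[i] > 0:
            peaks.append(float(frequencies_hz[i]))
    return peaks


# ---------------------------------------------------------------------------
# percentile event detection
# ---------------------------------------------------------------------------

def detect_events(plane: TimeFrequencyPlane, percentile: float = 98.0) -> pd.DataFrame:
    """Per-frequency 98th-percentile peak events.

    Within each frequency row the threshold is the empirical percentile of
    the row's valid (inside-cone) power.  Events are temporal local maxima
    above threshold; each carries the duration of its contiguous
    suprathreshold span, the interval to the next event in the same row, and
    the peak power as a fraction of the row median.  Constant rows yield no
    events.
    """
    rows = []
    dt = float(np.median(np.diff(plane.times_s))) if plane.times_s.size > 1 else 1.0
    for i, f in enumerate(plane.frequencies_hz):
        p = plane.power[i]
        valid = plane.coi_mask[i]
        pv = p[valid]
        if pv.size == 0 or np.all(pv == pv[0]):
            continue
        thr = np.percentile(pv, percentile)
        median = np.median(pv)
        above = (p > thr) & valid
        starts, ends = _runs(above)
        t_peaks = []
        for s, e in zip(starts, ends):
            seg = p[s:e]
            k = s + int(np.argmax(seg))
            t_peaks.append((k, s, e))
        t_peaks.sort()
        for idx, (k, s, e) in enumerate(t_peaks):
            nxt = t_peaks[idx + 1][0] if idx + 1 < len(t_peaks) else None
            rows.append({
                "frequency_hz": float(f),
                "t_peak_s": float(plane.times_s[k]),
                "duration_s": float((e - s) * dt),
                "interval_s": float((nxt - k) * dt) if nxt is not None else np.nan,
                "rel_power": float(p[k] / median) if median > 0 else np.inf,
            })
    df = pd.DataFrame(rows, columns=["frequency_hz", "t_peak_s", "duration_s",
                                     "interval_s", "rel_power"])
    return df.sort_values(["frequency_hz", "t_peak_s"]).reset_index(drop=True)


def event_statistics(table: pd.DataFrame, grouping: list[str] | None = None) -> dict:
    """Distribution summaries of event duration, interval and relative power.

    When ``grouping`` columns are present the summaries are per group;
    an empty table yields empty summaries.  Kernel-density estimates are
    attached where a group has enough spread to support one.
    """
    from scipy.stats import gaussian_kde

    def _summary(sub: pd.DataFrame) -> dict:
        out = {}
        for col in ("duration_s", "interval_s", "rel_power"):
            v = sub[col].dropna().to_numpy()
            entry = {"n": int(v.size),
                     "mean": float(v.mean()) if v.size else np.nan,
                     "sd": float(v.std()) if v.size else np.nan,
                     "values": v}
            if v.size >= 5 and v.std() > 0:
                entry["kde"] = gaussian_kde(v)
            out[col] = entry
        return out

    if table.empty:
        return {}
    if not grouping:
        return {"all": _summary(table)}
    return {key: _summary(sub) for key, sub in table.groupby(grouping)}
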