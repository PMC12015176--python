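"""Seeded generator for two-region LFP recordings with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume in chronically recorded SCN/NAc band-power series and raw traces:

* multiplicative circadian modulation of each band's power,
  ``x_f(t) = M_f * (1 + A_f * cos(2*pi*(t - phi_f)/tau)) * g(t) + eps_t``,
  clipped at zero (power is nonnegative);
* a two-state high/low activity block process ``g(t)`` with exponential
  (memoryless) dwell times, which controls diurnal fragmentation;
* stationary AR(1) short-range noise ``eps`` (``noise_sd`` is the marginal
  standard deviation, innovations are scaled by sqrt(1 - rho^2));
* lagged linear coupling of the second region onto the first,
  ``nac(t) = w * scn(t - L) + (1 - w) * eta(t)`` with an independent
  realization ``eta`` of the same marginal model;
* raw 500-Hz traces as 1/f-shaped background noise plus Poisson-timed,
  lognormal-duration, band-limited oscillatory bursts whose amplitude
  follows the circadian envelope.

Every simulated object carries a :class:`GroundTruth` with the generating
parameters, realized state-switch times and injected event times, so
parameter recovery can be scored exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np

from .bands import BAND_NAMES, CANONICAL_BANDS
from .datatypes import BandPowerSeries, RawTrace, RecordingMeta, GENOTYPES, REGIMENS

_AR_WARMUP_BINS = 100


@dataclass(frozen=True)
class BandParams:
    """Per-band generating parameters."""

    mesor: float              # M_f, mean power (a.u.)
    amplitude: float          # A_f, relative circadian amplitude (>= 0)
    acrophase_zt: float       # phi_f, ZT hours of the circadian peak
    ar_coef: float = 0.5      # rho, |rho| < 1
    noise_sd: float = 1.0     # sigma, marginal SD of the AR(1) noise (a.u.)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not abs(self.ar_coef) < 1:
            raise ValueError("|ar_coef| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SwitchingParams:
    """Two-state block process: exponential dwell times, low:high level ratio."""

    dwell_high_s: float = 7200.0
    dwell_low_s: float = 7200.0
    low_ratio: float = 0.5    # in (0, 1]

    def __post_init__(self) -> None:
        if self.dwell_high_s <= 0 or self.dwell_low_s <= 0:
            raise ValueError("dwell means must be > 0")
        if not 0 < self.low_ratio <= 1:
            raise ValueError("low_ratio must be in (0, 1]")


@dataclass(frozen=True)
class CouplingParams:
    weight: float = 0.7       # w in [0, 1]
    lag_s: float = 8.0        # L, SCN lead in seconds

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError("weight must be in [0, 1]")
        if self.lag_s < 0:
            raise ValueError("lag_s must be >= 0")


@dataclass(frozen=True)
class EventParams:
    """One Poisson stream of band-limited oscillatory bursts."""

    rate_per_s: float = 0.2
    duration_log_mu: float = -1.2   # lognormal mu of duration (s)
    duration_log_sigma: float = 0.5
    center_freq_hz: float = 8.3
    rel_amplitude: float = 3.0      # burst amplitude / background SD

    def __post_init__(self) -> None:
        if self.rate_per_s < 0:
            raise ValueError("rate must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    duration_h: float = 24.0
    fs: float = 500.0
    bin_s: float = 4.0
    genotype: str = "wildtype"
    regimen: str = "LD"
    tau_h: float | None = 24.0       # None = arrhythmic
    band_params: Mapping[str, BandParams] = field(default_factory=dict)
    switching: SwitchingParams = SwitchingParams()
    coupling: CouplingParams = CouplingParams()
    events: tuple[EventParams, ...] = (EventParams(),)
    background_sd_mv: float = 0.05   # raw-trace 1/f background SD (mV)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.bin_s not in (1, 4, 1.0, 4.0):
            raise ValueError("bin_s must be 1 or 4 seconds")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {self.regimen!r}")
        if self.tau_h is not None and self.tau_h <= 0:
            raise ValueError("tau_h must be > 0 or None")
        if not self.band_params:
            object.__setattr__(self, "band_params", _default_band_params(0.6, 16.0))
        unknown = set(self.band_params) - set(BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown bands in band_params: {sorted(unknown)}")

    @property
    def n_bins(self) -> int:
        n = self.duration_h * 3600.0 / self.bin_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_h*3600 must be an integer multiple of bin_s")
        return int(round(n))

    @property
    def n_samples(self) -> int:
        n = self.duration_h * 3600.0 * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_h*3600*fs must be an integer")
        return int(round(n))

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Generating parameters plus realized randomness of one simulated object."""

    config: SimulationConfig
    region: str = "SCN"
    switch_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_freqs_hz: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_durations_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        d = asdict(self.config)
        d["band_params"] = {k: asdict(v) for k, v in self.config.band_params.items()}
        return {
            "config": d,
            "region": self.region,
            "switch_times_s": np.asarray(self.switch_times_s).tolist(),
            "event_times_s": np.asarray(self.event_times_s).tolist(),
            "event_freqs_hz": np.asarray(self.event_freqs_hz).tolist(),
            "event_durations_s": np.asarray(self.event_durations_s).tolist(),
        }


def _default_band_params(amplitude: float, acrophase: float,
                         ar_coef: float = 0.5, noise_frac: float = 0.25) -> dict[str, BandParams]:
    # 1/f-like mesor profile over the canonical bands
    out = {}
    for b in CANONICAL_BANDS:
        mesor = 100.0 / np.sqrt(b.center)
        out[b.name] = BandParams(
            mesor=float(mesor), amplitude=amplitude, acrophase_zt=acrophase,
            ar_coef=ar_coef, noise_sd=float(noise_frac * mesor),
        )
    return out


def preset_config(genotype: str, regimen: str, **overrides) -> SimulationConfig:
    """Deterministic study-condition presets.

    Wild-type animals under a light-dark cycle are strongly 24-h rhythmic with
    long consolidated activity blocks; under constant darkness they free-run
    with a slightly longer period and roughly halved circadian amplitude.
    Clock-deficient (Cry1/2 knockout) animals retain only light-driven
    rhythmicity (LD) or none (DD) and fragment their activity into shorter
    blocks; the knockout dwell-time ordering encodes the qualitative
    direction, as no quantitative event-rate parameters are established.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    if regimen not in REGIMENS:
        raise ValueError(f"unknown regimen {regimen!r}; expected one of {REGIMENS}")
    key = (genotype, regimen)
    if key == ("wildtype", "LD"):
        tau, amp, dwell = 24.0, 0.6, 7200.0
    elif key == ("wildtype", "DD"):
        tau, amp, dwell = 24.3, 0.3, 7200.0
    elif key == ("cry_ko", "LD"):
        tau, amp, dwell = 24.0, 0.3, 1800.0
    else:  # cry_ko / DD: arrhythmic
        tau, amp, dwell = None, 0.0, 900.0
    cfg = SimulationConfig(
        genotype=genotype, regimen=regimen, tau_h=tau,
        band_params=_default_band_params(amp, acrophase=16.0),
        switching=SwitchingParams(dwell_high_s=dwell, dwell_low_s=dwell, low_ratio=0.5),
        events=(
            EventParams(rate_per_s=0.15, center_freq_hz=8.3, duration_log_mu=-1.0),
            EventParams(rate_per_s=0.15, center_freq_hz=66.8, duration_log_mu=-2.2),
        ),
    )
    return cfg.replace(**overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

_REGION_STREAM = {"SCN": 0, "NAC": 1}


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def _two_state(rng: np.random.Generator, n_bins: int, bin_s: float,
               sw: SwitchingParams) -> tuple[np.ndarray, np.ndarray]:
    """Alternating 1 / low_ratio multiplier with exponential dwell times."""
    total_s = n_bins * bin_s
    t = 0.0
    high = bool(rng.integers(0, 2))
    switch_times = []
    g = np.empty(n_bins)
    edges = np.arange(n_bins + 1) * bin_s
    levels = []
    seg_bounds = [0.0]
    while t < total_s:
        mean = sw.dwell_high_s if high else sw.dwell_low_s
        dwell = rng.exponential(mean)
        t += dwell
        levels.append(1.0 if high else sw.low_ratio)
        seg_bounds.append(min(t, total_s))
        if t < total_s:
            switch_times.append(t)
        high = not high
    # per-bin value = level of the segment covering the bin midpoint
    mids = (edges[:-1] + edges[1:]) / 2.0
    seg_idx = np.searchsorted(np.asarray(seg_bounds[1:]), mids, side="right")
    seg_idx = np.clip(seg_idx, 0, len(levels) - 1)
    g = np.asarray(levels)[seg_idx]
    return g, np.asarray(switch_times)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    e = rng.standard_normal(n) * innov_sd
    if rho == 0:
        return e
    out = np.empty(n)
    out[0] = rng.standard_normal() * sd
    # scipy.signal.lfilter would do, but the direct recursion keeps the
    # state initialization explicit
    from scipy.signal import lfilter
    out = lfilter([1.0], [1.0, -rho], e, zi=[rho * out[0]])[0]
    return out


def _circadian(t_h: np.ndarray, amp: float, acrophase: float, tau_h: float | None) -> np.ndarray:
    if tau_h is None or amp == 0:
        return np.ones_like(t_h)
    return 1.0 + amp * np.cos(2.0 * np.pi * (t_h - acrophase) / tau_h)


def simulate_band_series(config: SimulationConfig, region_label: str = "SCN",
                         seed: int | None = None) -> tuple[BandPowerSeries, GroundTruth]:
    """Simulate one region's binned band-power matrix.

    Returns exactly ``duration_h*3600/bin_s`` bins; an initial burn-in
    (AR warm-up plus the coupling lag) is simulated and discarded so the
    first returned bin is already stationary and sits at ZT 0.
    """
    seed = config.seed if seed is None else seed
    region = region_label.upper()
    if region not in _REGION_STREAM:
        raise ValueError(f"unknown region {region_label!r}")
    n = config.n_bins
    lag_bins = int(np.ceil(config.coupling.lag_s / config.bin_s))
    burn = max(lag_bins, _AR_WARMUP_BINS)
    series, truth = _simulate_band_matrix(config, region, seed, n, burn)
    return series, truth


def _simulate_band_matrix(config: SimulationConfig, region: str, seed: int,
                          n: int, burn: int,
                          stream: int | None = None) -> tuple[BandPowerSeries, GroundTruth]:
    stream = _REGION_STREAM[region] if stream is None else stream
    rng_state = _rng(seed, stream, 0)
    m = n + burn
    # extended time axis: bin k of the returned series has zt = k*bin_s/3600
    t_h = np.arange(-burn, n) * config.bin_s / 3600.0
    g, switch_times = _two_state(rng_state, m, config.bin_s, config.switching)
    values = np.empty((m, len(BAND_NAMES)))
    for j, name in enumerate(BAND_NAMES):
        bp = config.band_params.get(name)
        if bp is None:
            bp = BandParams(mesor=1.0, amplitude=0.0, acrophase_zt=0.0)
        rng_b = _rng(seed, stream, 1 + j)
        circ = _circadian(t_h, bp.amplitude, bp.acrophase_zt, config.tau_h)
        eps = _ar1(rng_b, m, bp.ar_coef, bp.noise_sd)
        values[:, j] = np.clip(bp.mesor * circ * g + eps, 0.0, None)
    zt = np.arange(n) * config.bin_s / 3600.0
    meta = RecordingMeta(animal_id=f"sim{seed}", genotype=config.genotype,
                         region=region, regimen=config.regimen, fs=config.fs)
    series = BandPowerSeries(meta=meta, bin_s=float(config.bin_s), zt_hours=zt,
                             values=values[burn:])
    truth = GroundTruth(config=config, region=region,
                        switch_times_s=switch_times - burn * config.bin_s)
    return series, truth


def simulate_region_pair(config: SimulationConfig, seed: int | None = None) -> dict:
    """Simulate a simultaneously recorded SCN/NAc pair.

    NAc band power is a lagged mixture of the SCN series (weight ``w``, lag
    ``L``) with an independent realization of the same marginal model, so the
    cross-correlation peak sits at +L with the SCN leading.
    """
    seed = config.seed if seed is None else seed
    if config.coupling.lag_s >= config.duration_h * 3600.0:
        raise ValueError("coupling lag must be shorter than the recording")
    n = config.n_bins
    lag_bins = int(round(config.coupling.lag_s / config.bin_s))
    burn = max(lag_bins, _AR_WARMUP_BINS)

    # extended SCN matrix so that scn(t - L) exists for every returned bin
    stream_scn = _REGION_STREAM["SCN"]
    rng_state = _rng(seed, stream_scn, 0)
    m = n + burn
    t_h = np.arange(-burn, n) * config.bin_s / 3600.0
    g, switch_times = _two_state(rng_state, m, config.bin_s, config.switching)
    ext = np.empty((m, len(BAND_NAMES)))
    for j, name in enumerate(BAND_NAMES):
        bp = config.band_params.get(name, BandParams(mesor=1.0, amplitude=0.0, acrophase_zt=0.0))
        rng_b = _rng(seed, stream_scn, 1 + j)
        circ = _circadian(t_h, bp.amplitude, bp.acrophase_zt, config.tau_h)
        eps = _ar1(rng_b, m, bp.ar_coef, bp.noise_sd)
        ext[:, j] = np.clip(bp.mesor * circ * g + eps, 0.0, None)

    zt = np.arange(n) * config.bin_s / 3600.0
    meta_scn = RecordingMeta(animal_id=f"sim{seed}", genotype=config.genotype,
                             region="SCN", regimen=config.regimen, fs=config.fs)
    scn = BandPowerSeries(meta=meta_scn, bin_s=float(config.bin_s), zt_hours=zt,
                          values=ext[burn:])

    eta, _ = _simulate_band_matrix(config, "NAC", seed, n, burn)
    w = config.coupling.weight
    shifted = ext[burn - lag_bins: m - lag_bins]
    nac_values = w * shifted + (1.0 - w) * eta.values
    meta_nac = RecordingMeta(animal_id=f"sim{seed}", genotype=config.genotype,
                             region="NAC", regimen=config.regimen, fs=config.fs)
    nac = BandPowerSeries(meta=meta_nac, bin_s=float(config.bin_s), zt_hours=zt,
                          values=nac_values)
    truth = GroundTruth(config=config, region="SCN",
                        switch_times_s=switch_times - burn * config.bin_s)
    return {"scn": scn, "nac": nac, "truth": truth, "burn_in_s": lag_bins * config.bin_s}


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Gaussian noise shaped to a 1/f power spectrum, scaled to SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = 1.0 / np.sqrt(f[nz])
    shape[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shape, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_raw_trace(config: SimulationConfig, seed: int | None = None) -> tuple[RawTrace, GroundTruth]:
    """Simulate a raw voltage trace: 1/f background plus oscillatory bursts.

    Bursts are Poisson-timed Hann-windowed sinusoids at each configured
    center frequency with lognormal durations; burst amplitude follows the
    circadian envelope averaged over the configured bands.
    """
    seed = config.seed if seed is None else seed
    if config.fs < 2.0 * 70.0:
        raise ValueError("fs must be at least twice the highest band edge (140 Hz)")
    n = config.n_samples
    rng_bg = _rng(seed, 10)
    x = _one_over_f_noise(rng_bg, n, config.fs, config.background_sd_mv)

    amps = [bp.amplitude for bp in config.band_params.values()]
    phis = [bp.acrophase_zt for bp in config.band_params.values()]
    a_bar = float(np.mean(amps)) if amps else 0.0
    phi_bar = float(np.mean(phis)) if phis else 0.0

    ev_times, ev_freqs, ev_durs = [], [], []
    total_s = config.duration_h * 3600.0
    for k, ev in enumerate(config.events):
        if ev.rate_per_s <= 0 or ev.rel_amplitude == 0:
            continue
        rng_e = _rng(seed, 11, k)
        n_ev = rng_e.poisson(ev.rate_per_s * total_s)
        t0 = np.sort(rng_e.uniform(0.0, total_s, n_ev))
        dur = rng_e.lognormal(ev.duration_log_mu, ev.duration_log_sigma, n_ev)
        phase = rng_e.uniform(0, 2 * np.pi, n_ev)
        for ti, di, ph in zip(t0, dur, phase):
            i0 = int(ti * config.fs)
            i1 = min(int((ti + di) * config.fs), n)
            if i1 - i0 < 4:
                continue
            tt = np.arange(i0, i1) / config.fs
            window = np.hanning(i1 - i0)
            env = _circadian(np.array([ti / 3600.0]), a_bar, phi_bar, config.tau_h)[0]
            amp = ev.rel_amplitude * config.background_sd_mv * max(env, 0.0)
            x[i0:i1] += amp * window * np.sin(2 * np.pi * ev.center_freq_hz * tt + ph)
            ev_times.append(ti + di / 2.0)
            ev_freqs.append(ev.center_freq_hz)
            ev_durs.append(di)

    meta = RecordingMeta(animal_id=f"sim{seed}", genotype=config.genotype,
                         region="SCN", regimen=config.regimen, fs=config.fs)
    truth = GroundTruth(config=config, region="SCN",
                        event_times_s=np.asarray(ev_times),
                        event_freqs_hz=np.asarray(ev_freqs),
                        event_durations_s=np.asarray(ev_durs))
    return RawTrace(meta=meta, samples=x), truth
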