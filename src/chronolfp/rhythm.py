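"""24-h rhythmicity: harmonic regression, circular phase summaries, and
Lomb-Scargle dominant-period extraction.

The harmonic model is the single-component cosinor,

    y(t) = b0 + bs*sin(2*pi*t/T) + bc*cos(2*pi*t/T) + e,    T = 24 h,

fitted by ordinary least squares.  The fitted curve equals
``b0 + amp*cos(2*pi*(t - peak_zt)/T)`` with amplitude ``sqrt(bs^2 + bc^2)``
and acrophase ``peak_zt`` at the curve maximum, so for a single harmonic the
amplitude-from-coefficients and curve-maximum definitions coincide.

Dominant periods are read off a standard-normalized Lomb-Scargle periodogram
evaluated on a uniform period grid (default 2-36 h in 0.1-h steps at the
default oversampling); the global maximum is taken regardless of amplitude,
and its absolute deviation from 24 h is the free-running-period summary.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .datatypes import BinnedSeries


@dataclass
class SineFit:
    """Cosinor coefficients and derived rhythm descriptors."""

    beta0: float
    beta_sin: float
    beta_cos: float
    amplitude: float
    peak_zt: float
    residual_sd: float
    n: int

    def predict(self, t_hours: np.ndarray, period_h: float = 24.0) -> np.ndarray:
        w = 2.0 * np.pi / period_h
        t = np.asarray(t_hours, dtype=float)
        return self.beta0 + self.beta_sin * np.sin(w * t) + self.beta_cos * np.cos(w * t)


class CircadianHarmonicModel:
    """OLS cosinor model of a binned series against a fixed period.

    Parameters
    ----------
    endog : array-like
        Observed values (band power, amplitude, or z-units).
    t_hours : array-like
        Zeitgeber time of each observation, hours.
    period_h : float
        Fixed rhythm period (24 h by default).
    """

    def __init__(self, endog, t_hours, period_h: float = 24.0):
        self.endog = np.asarray(endog, dtype=float)
        self.t_hours = np.asarray(t_hours, dtype=float)
        if self.endog.shape != self.t_hours.shape or self.endog.ndim != 1:
            raise ValueError("endog and t_hours must be equal-length 1-D")
        if np.unique(self.t_hours).size < 3:
            raise ValueError("need at least 3 distinct timestamps")
        if self.endog.std() == 0:
            raise ValueError("endog has zero variance")
        self.period_h = float(period_h)

    @classmethod
    def from_series(cls, series: BinnedSeries, period_h: float = 24.0) -> "CircadianHarmonicModel":
        return cls(series.values, series.zt_hours, period_h=period_h)

    def fit(self) -> "CircadianHarmonicResults":
        w = 2.0 * np.pi / self.period_h
        X = np.column_stack([np.ones_like(self.t_hours),
                             np.sin(w * self.t_hours),
                             np.cos(w * self.t_hours)])
        beta, *_ = np.linalg.lstsq(X, self.endog, rcond=None)
        resid = self.endog - X @ beta
        return CircadianHarmonicResults(self, beta, resid)


class CircadianHarmonicResults:
    """Fit results: coefficients, amplitude, acrophase, residual spread."""

    def __init__(self, model: CircadianHarmonicModel, params: np.ndarray, resid: np.ndarray):
        self.model = model
        self.params = params
        self.resid = resid
        b0, bs, bc = params
        self.amplitude = float(np.hypot(bs, bc))
        # fitted curve = b0 + amp*cos(w*t - phi), maximum at w*t = phi
        phi = float(np.arctan2(bs, bc))
        self.peak_zt = float((phi / (2.0 * np.pi) * model.period_h) % model.period_h)
        self.residual_sd = float(resid.std())

    @property
    def nobs(self) -> int:
        return self.model.endog.size

    def to_sine_fit(self) -> SineFit:
        b0, bs, bc = self.params
        return SineFit(beta0=float(b0), beta_sin=float(bs), beta_cos=float(bc),
                       amplitude=self.amplitude, peak_zt=self.peak_zt,
                       residual_sd=self.residual_sd, n=self.nobs)

    def summary(self) -> str:
        b0, bs, bc = self.params
        lines = [
            "Circadian harmonic (cosinor) fit",
            f"  period       : {self.model.period_h:.2f} h",
            f"  n            : {self.nobs}",
            f"  intercept    : {b0:.6g}",
            f"  beta_sin     : {bs:.6g}",
            f"  beta_cos     : {bc:.6g}",
            f"  amplitude    : {self.amplitude:.6g}",
            f"  peak ZT      : {self.peak_zt:.3f} h",
            f"  residual SD  : {self.residual_sd:.6g}",
        ]
        return "\n".join(lines)


def fit_sine24(series: BinnedSeries | np.ndarray, t_hours: np.ndarray | None = None) -> SineFit:
    """Fixed-period (24 h) cosinor fit of a binned series."""
    if isinstance(series, BinnedSeries):
        span = series.zt_hours[-1] - series.zt_hours[0] + series.bin_s / 3600.0
        if span < 24.0 - 1e-9:
            raise ValueError("series must span at least 24 h")
        model = CircadianHarmonicModel.from_series(series)
    else:
        if t_hours is None:
            raise ValueError("t_hours required when passing a bare array")
        model = CircadianHarmonicModel(series, t_hours)
    return model.fit().to_sine_fit()


@dataclass
class CircularSummary:
    mean_zt: float          # hours, undefined (nan) when resultant length ~ 0
    circular_sd: float      # radians
    arrow_length: float     # 1 / circular SD, capped
    resultant_length: float
    n: int
    undefined: bool = False


def circular_phase_summary(peak_zts, arrow_cap: float = 100.0) -> CircularSummary:
    """Circular mean and dispersion of acrophases on the 24-h clock.

    Angles are theta = 2*pi*zt/24; the circular SD is sqrt(-2 ln Rbar) with
    Rbar the mean resultant length, and the display arrow length is the
    inverse circular SD capped at ``arrow_cap``.
    """
    zts = np.asarray(peak_zts, dtype=float)
    if zts.size < 1:
        raise ValueError("need at least one phase")
    theta = 2.0 * np.pi * zts / 24.0
    c, s = np.mean(np.cos(theta)), np.mean(np.sin(theta))
    rbar = float(np.hypot(c, s))
    if rbar < 1e-12:
        return CircularSummary(mean_zt=float("nan"), circular_sd=float("inf"),
                               arrow_length=0.0, resultant_length=rbar,
                               n=zts.size, undefined=True)
    mean_zt = float((np.arctan2(s, c) / (2.0 * np.pi) * 24.0) % 24.0)
    csd = float(np.sqrt(max(-2.0 * np.log(rbar), 0.0)))
    arrow = arrow_cap if csd == 0 else min(1.0 / csd, arrow_cap)
    return CircularSummary(mean_zt=mean_zt, circular_sd=csd, arrow_length=arrow,
                           resultant_length=rbar, n=zts.size)


@dataclass
class PeriodogramResult:
    period_h: np.ndarray
    power: np.ndarray
    dominant_period_h: float
    dominant_power: float
    deviation_24h: float
    span_h: float = 0.0
    oversample: int = 4

    def period_resolution(self, period_h: float | None = None) -> float:
        """Natural period resolution at a given period.

        One step of the classical oversampled frequency grid,
        df = 1/(span*oversample), mapped to period units:
        dp ~ period^2 * df.  Peak locations cannot be localized better
        than this, whatever the display grid spacing.
        """
        p = self.dominant_period_h if period_h is None else period_h
        return p * p / (self.span_h * self.oversample)


def lomb_scargle(series: BinnedSeries | np.ndarray, t_hours: np.ndarray | None = None,
                 period_range: tuple[float, float] = (2.0, 36.0),
                 oversample: int = 4) -> PeriodogramResult:
    """Standard-normalized Lomb-Scargle periodogram over a period grid.

    The grid is uniform in period with step ``0.4 / oversample`` hours
    (0.1 h at the default oversampling), so deviations near 24 h are
    resolved at the 0.1-h level.  Power is normalized by N*var/2, giving 1
    for a noise-free sinusoid.  The dominant period is the global maximum
    regardless of its amplitude.
    """
    if isinstance(series, BinnedSeries):
        y, t = series.values, series.zt_hours
    else:
        y, t = np.asarray(series, dtype=float), np.asarray(t_hours, dtype=float)
    p_lo, p_hi = period_range
    if not 0 < p_lo < p_hi:
        raise ValueError("invalid period range")
    span = t[-1] - t[0]
    if span < (4.0 / 3.0) * p_hi:
        raise ValueError(
            f"series span {span:.1f} h too short for periods up to {p_hi} h")
    if y.std() == 0:
        raise ValueError("constant series")
    step = 0.4 / oversample
    periods = np.arange(p_lo, p_hi + step / 2, step)
    omega = 2.0 * np.pi / periods
    yc = y - y.mean()
    pgram = lombscargle(t, yc, omega)
    power = pgram * 2.0 / (y.size * yc.var())
    k = int(np.argmax(power))
    dom = float(periods[k])
    return PeriodogramResult(period_h=periods, power=power,
                             dominant_period_h=dom,
                             dominant_power=float(power[k]),
                             deviation_24h=abs(dom - 24.0),
                             span_h=float(span), oversample=oversample)
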