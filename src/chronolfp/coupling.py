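"""Within- and between-region co-activity measures.

Covers Pearson correlation with its regression line, day/night band-pair
correlation matrices, sign-concordance count plots over 3-h windows,
cross-/autocorrelation at 1-s lags with four-lag-bin averaging,
Welch-estimated magnitude-squared coherence in 108-s bins, and pairwise
Granger-causality F tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .datatypes import BandPowerSeries


# ---------------------------------------------------------------------------
# Pearson correlation and band-pair matrices
# ---------------------------------------------------------------------------

def pearson_xy(a, b) -> dict:
    """Sample Pearson r plus the least-squares line b = slope*a + intercept."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need equal-length 1-D arrays of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(a, b)[0, 1])
    slope = r * b.std() / a.std()
    intercept = float(b.mean() - slope * a.mean())
    return {"r": r, "slope": float(slope), "intercept": intercept}


def band_pair_matrix(scn: BandPowerSeries, nac: BandPowerSeries) -> pd.DataFrame:
    """Day/night correlation matrix over all within- and between-region band
    pairs.

    The upper triangle holds correlations over the first half-day (ZT 0-12),
    the lower triangle over the second half (ZT 12-24); the diagonal is 1.
    Rows/columns are labelled ``REGION:band``.
    """
    if scn.n_bins != nac.n_bins or not np.allclose(scn.zt_hours, nac.zt_hours):
        raise ValueError("series are misaligned")
    labels = [f"{scn.meta.region}:{b}" for b in scn.band_names] + \
             [f"{nac.meta.region}:{b}" for b in nac.band_names]
    X = np.hstack([scn.values, nac.values])
    day = scn.zt_hours < 12.0
    night = ~day
    c_day = np.corrcoef(X[day].T)
    c_night = np.corrcoef(X[night].T)
    out = np.where(np.triu(np.ones_like(c_day, dtype=bool), 1), c_day, c_night)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=labels, columns=labels)


def matching_band_coefficients(matrix: pd.DataFrame, n_bands: int = 10) -> dict:
    """The same-band SCN x NAc coefficients, per half-day."""
    m = matrix.to_numpy()
    day = np.array([m[i, n_bands + i] for i in range(n_bands)])
    night = np.array([m[n_bands + i, i] for i in range(n_bands)])
    return {"day": day, "night": night}


# ---------------------------------------------------------------------------
# sign-concordance count plot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountPlotConfig:
    window_h: float = 3.0

    def __post_init__(self) -> None:
        if not (24.0 / self.window_h).is_integer():
            raise ValueError("windows must tile 24 h")


CATEGORIES = ("high_high", "high_low", "low_high", "low_low")


def correlation_count(z_a: np.ndarray, z_b: np.ndarray, zt_hours: np.ndarray,
                      cfg: CountPlotConfig = CountPlotConfig()) -> pd.DataFrame:
    """Counts of sign-concordance categories per 3-h window.

    Categories are the sign pair of the two z-scored values at each bin,
    with z >= 0 counting as "high".  Rows are windows (start ZT), columns
    the four categories; each row sums to the bins in that window.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    zt = np.asarray(zt_hours, dtype=float)
    if not (z_a.shape == z_b.shape == zt.shape):
        raise ValueError("misaligned inputs")
    n_win = int(round(24.0 / cfg.window_h))
    win = np.clip((zt // cfg.window_h).astype(int), 0, n_win - 1)
    hi_a, hi_b = z_a >= 0, z_b >= 0
    cat = np.select(
        [hi_a & hi_b, hi_a & ~hi_b, ~hi_a & hi_b],
        [0, 1, 2], default=3,
    )
    counts = np.zeros((n_win, 4), dtype=int)
    np.add.at(counts, (win, cat), 1)
    idx = [cfg.window_h * k for k in range(n_win)]
    return pd.DataFrame(counts, index=pd.Index(idx, name="window_start_zt"),
                        columns=list(CATEGORIES))


# ---------------------------------------------------------------------------
# cross- and autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class LagCorrelation:
    lags_s: np.ndarray
    coefficients: np.ndarray

    def at(self, lag_s: float) -> float:
        i = int(np.argmin(np.abs(self.lags_s - lag_s)))
        if abs(self.lags_s[i] - lag_s) > 1e-9:
            raise ValueError(f"lag {lag_s} not on the grid")
        return float(self.coefficients[i])


def cross_correlation(a, b, max_lag_s: float = 60.0, bin_s: float = 1.0) -> LagCorrelation:
    """Sample cross-correlation at integer-second lags.

    The value at lag l is corr(a_t, b_{t+l}) with global-moment (classical)
    normalization: positive lags mean the first series leads.
    ``cross_correlation(a, a)`` is the autocorrelation, 1 at lag 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length 1-D arrays")
    n = a.size
    max_lag = int(round(max_lag_s / bin_s))
    if max_lag >= n:
        raise ValueError("max_lag must be shorter than the series")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance input")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = n * a.std() * b.std()
    lags = np.arange(-max_lag, max_lag + 1)
    coef = np.empty(lags.size)
    for i, l in enumerate(lags):
        if l >= 0:
            coef[i] = np.dot(ac[: n - l], bc[l:]) / denom
        else:
            coef[i] = np.dot(ac[-l:], bc[: n + l]) / denom
    return LagCorrelation(lags_s=lags * bin_s, coefficients=coef)


def lag_bin_summary(lagcorr: LagCorrelation) -> dict:
    """Average the +/-60-s lag profile within four bins, excluding lag 0.

    Bins: [-60, -30], [-29, -1], [+1, +29], [+30, +60] seconds.
    """
    lags = lagcorr.lags_s
    if lags.min() > -60 or lags.max() < 60:
        raise ValueError("lag profile must span +/-60 s")
    c = lagcorr.coefficients
    bins = {
        "neg_far": (lags >= -60) & (lags <= -30),
        "neg_near": (lags >= -29) & (lags <= -1),
        "pos_near": (lags >= 1) & (lags <= 29),
        "pos_far": (lags >= 30) & (lags <= 60),
    }
    out = {}
    for name, sel in bins.items():
        if not sel.any():
            raise ValueError(f"no lags in bin {name}")
        out[name] = float(c[sel].mean())
    return out


# ---------------------------------------------------------------------------
# magnitude-squared coherence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoherenceConfig:
    bin_len_s: float = 108.0
    bin_overlap_s: float = 36.0
    n_bins: int = 3
    sub_segment_s: float = 2.0    # Welch sub-segments (Hann, 50% overlap)

    def __post_init__(self) -> None:
        if self.bin_overlap_s >= self.bin_len_s:
            raise ValueError("overlap must be smaller than bin length")


def msc_coherence(a: np.ndarray, b: np.ndarray, fs: float,
                  cfg: CoherenceConfig = CoherenceConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence averaged over overlapping analysis bins.

    Each 108-s bin is Welch-estimated with 2-s Hann sub-segments at 50%
    overlap (single-segment coherence is degenerately 1, so sub-segmentation
    is required); the coherence spectrum is the mean over the three bins.
    Returns (frequencies_hz, coherence in [0, 1]).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length 1-D arrays")
    bin_n = int(round(cfg.bin_len_s * fs))
    step = int(round((cfg.bin_len_s - cfg.bin_overlap_s) * fs))
    if a.size < bin_n:
        raise ValueError("traces shorter than one coherence bin")
    nperseg = int(round(cfg.sub_segment_s * fs))
    specs = []
    freqs = None
    for k in range(cfg.n_bins):
        lo = k * step
        hi = lo + bin_n
        if hi > a.size:
            break
        f, cxy = signal.coherence(a[lo:hi], b[lo:hi], fs=fs, window="hann",
                                  nperseg=nperseg, noverlap=nperseg // 2)
        freqs = f
        specs.append(cxy)
    return freqs, np.mean(specs, axis=0)


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

@dataclass
class GrangerResult:
    direction: str
    order: int
    f_stat: float
    p_value: float
    df_num: int
    df_den: int


def _granger_one_way(x: np.ndarray, y: np.ndarray, p: int) -> tuple[float, float, int, int]:
    """F test of whether lags of x improve prediction of y (x -> y)."""
    n = y.size
    rows = n - p
    Y = y[p:]
    own = np.column_stack([y[p - k - 1: n - k - 1] for k in range(p)])
    other = np.column_stack([x[p - k - 1: n - k - 1] for k in range(p)])
    ones = np.ones((rows, 1))
    Xr = np.hstack([ones, own])
    Xu = np.hstack([ones, own, other])
    for X in (Xr, Xu):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design (constant or collinear series)")
    rss_r = float(np.sum((Y - Xr @ np.linalg.lstsq(Xr, Y, rcond=None)[0]) ** 2))
    rss_u = float(np.sum((Y - Xu @ np.linalg.lstsq(Xu, Y, rcond=None)[0]) ** 2))
    df_den = rows - (2 * p + 1)
    f = ((rss_r - rss_u) / p) / (rss_u / df_den)
    f = max(f, 0.0)
    pval = float(stats.f.sf(f, p, df_den))
    return f, pval, p, df_den


def granger_test(a: np.ndarray, b: np.ndarray, order: int = 1) -> dict:
    """Both-direction Granger F tests at the given lag order.

    For each direction the restricted model (own lags only) is compared with
    the unrestricted one (own plus the other series' lags) by an F test on
    the residual sums of squares.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length 1-D arrays")
    if a.size <= 10 * order:
        raise ValueError("series too short for the requested order")
    f_ab, p_ab, dfn, dfd = _granger_one_way(a, b, order)
    f_ba, p_ba, _, _ = _granger_one_way(b, a, order)
    return {
        "a->b": GrangerResult("a->b", order, f_ab, p_ab, dfn, dfd),
        "b->a": GrangerResult("b->a", order, f_ba, p_ba, dfn, dfd),
    }
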