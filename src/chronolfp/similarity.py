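"""Regularity and similarity batteries.

Implements the timepoint-matched Euclidean distance between labelled series
(with band averaging and binary-variable pair grouping), slope-magnitude
histograms with skewness, sample entropy, PCA over band variables with
within-group principal-component pair distances, and the fold-change summary
table against the wild-type/LD reference group.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

# ---------------------------------------------------------------------------
# timepoint-matched Euclidean distance
# ---------------------------------------------------------------------------


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Summed per-timepoint distance between two aligned series.

    For matched time grids the x-difference at each timepoint is zero, so
    the per-timepoint 2-D Euclidean summand reduces to |b_t - a_t| and the
    distance is sum(|b - a|).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be aligned 1-D arrays of equal length")
    return float(np.sum(np.abs(b - a)))


@dataclass
class DistanceMatrix:
    """Pairwise distances between labelled series; symmetric, zero diagonal."""

    labels: pd.DataFrame   # one row per series: animal, genotype, region, regimen, band, ...
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or len(self.labels) != n:
            raise ValueError("matrix must be square and match the labels")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def distance_matrix(series_values: np.ndarray, labels: pd.DataFrame) -> DistanceMatrix:
    """All pairwise timepoint-matched distances between the given series.

    ``series_values`` is (n_series, n_bins); all series must be aligned.
    """
    X = np.asarray(series_values, dtype=float)
    if X.ndim != 2:
        raise ValueError("series_values must be (n_series, n_bins)")
    if len(labels) != X.shape[0]:
        raise ValueError("labels must have one row per series")
    d = pdist(X, metric="cityblock")
    from scipy.spatial.distance import squareform
    m = squareform(d)
    return DistanceMatrix(labels=labels.reset_index(drop=True), matrix=m)


def average_over_bands(matrices: list[DistanceMatrix]) -> DistanceMatrix:
    """Elementwise mean of per-band distance matrices with matching labels."""
    if not matrices:
        raise ValueError("no matrices to average")
    base = matrices[0]
    check_cols = [c for c in base.labels.columns if c != "band"]
    for m in matrices[1:]:
        if m.matrix.shape != base.matrix.shape or \
           not m.labels[check_cols].equals(base.labels[check_cols]):
            raise ValueError("inconsistent labels across band matrices")
    mean = np.mean([m.matrix for m in matrices], axis=0)
    labels = base.labels.drop(columns=[c for c in ("band",) if c in base.labels])
    return DistanceMatrix(labels=labels, matrix=mean)


def group_distances(dm: DistanceMatrix, variable: str) -> dict:
    """Split all off-diagonal pairs into three groups by a binary variable.

    Groups: both series at the first level, mixed, both at the second level.
    Every unordered pair is assigned exactly once.
    """
    if variable not in dm.labels.columns:
        raise ValueError(f"unknown variable {variable!r}")
    vals = dm.labels[variable].to_numpy()
    levels = sorted(pd.unique(vals))
    if len(levels) > 2:
        raise ValueError(f"variable {variable!r} is not binary: {levels}")
    if len(levels) == 1:
        levels = [levels[0], None]
    g1, gm, g2 = [], [], []
    n = dm.n
    for i in range(n):
        for j in range(i + 1, n):
            pair = {vals[i], vals[j]}
            if pair == {levels[0]}:
                g1.append(dm.matrix[i, j])
            elif levels[1] is not None and pair == {levels[1]}:
                g2.append(dm.matrix[i, j])
            else:
                gm.append(dm.matrix[i, j])
    return {
        f"both_{levels[0]}": np.asarray(g1),
        "mixed": np.asarray(gm),
        f"both_{levels[1]}": np.asarray(g2),
    }


# ---------------------------------------------------------------------------
# slope histograms and skewness
# ---------------------------------------------------------------------------

@dataclass
class SlopeResult:
    slopes: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    skewness: float
    undefined: bool = False


def slope_skewness(z: np.ndarray, dt: float, binwidth: float = 20.0) -> SlopeResult:
    """Consecutive-difference slope magnitudes, their histogram, and skewness.

    Slopes are |y_{i+1} - y_i| / dt; skewness is the moment estimator
    m3 / m2^(3/2) of the slope values (flagged undefined when every slope
    is identical).
    """
    z = np.asarray(z, dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 points")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    slopes = np.abs(np.diff(z)) / dt
    edges = np.arange(0.0, slopes.max() + binwidth, binwidth)
    if edges.size < 2:
        edges = np.array([0.0, binwidth])
    counts, edges = np.histogram(slopes, bins=edges)
    if np.all(slopes == slopes[0]):
        return SlopeResult(slopes, counts, edges, float("nan"), undefined=True)
    return SlopeResult(slopes, counts, edges, float(stats.skew(slopes, bias=True)))


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntropyConfig:
    m: int = 2
    r_factor: float = 0.2   # tolerance = r_factor * series SD (Chebyshev)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")


@dataclass
class SampEnResult:
    value: float
    a_count: int     # matches at length m+1
    b_count: int     # matches at length m
    r: float
    undefined: bool = False
    degenerate_r: bool = False

    def __float__(self) -> float:
        return self.value


def sample_entropy(x: np.ndarray, cfg: EntropyConfig = EntropyConfig(),
                   chunk: int = 1024) -> SampEnResult:
    """SampEn(m, r) = -ln(A/B) with Chebyshev template matching.

    A and B count unordered template pairs (self-matches excluded) that stay
    within tolerance r at lengths m+1 and m respectively, over the common
    template index range.  The blocked vectorized count equals the naive
    double-loop definition exactly.
    """
    x = np.asarray(x, dtype=float)
    m = cfg.m
    if x.size <= m + 1:
        raise ValueError("series too short for the embedding dimension")
    sd = x.std()
    r = cfg.r_factor * sd
    degenerate = sd == 0
    n_t = x.size - m  # number of (m+1)-length windows; shared index range
    W = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (n_t, m+1)
    a = 0
    b = 0
    col = np.ascontiguousarray(W.T)  # (m+1, n_t)
    for i0 in range(0, n_t, chunk):
        i1 = min(i0 + chunk, n_t)
        # running Chebyshev maximum, one template column at a time (in place)
        dm = np.abs(col[0, i0:i1, None] - col[0, None, :])
        scratch = np.empty_like(dm)
        for k in range(1, m):
            np.abs(np.subtract(col[k, i0:i1, None], col[k, None, :], out=scratch),
                   out=scratch)
            np.maximum(dm, scratch, out=dm)
        rows = np.arange(i0, i1)[:, None]
        upper = np.arange(n_t)[None, :] > rows
        b += int(np.count_nonzero((dm <= r) & upper))
        np.abs(np.subtract(col[m, i0:i1, None], col[m, None, :], out=scratch),
               out=scratch)
        np.maximum(dm, scratch, out=dm)
        a += int(np.count_nonzero((dm <= r) & upper))
    if b == 0 or a == 0:
        if degenerate:
            # constant series: every template matches at tolerance 0
            return SampEnResult(0.0, a, b, r, degenerate_r=True)
        return SampEnResult(float("inf"), a, b, r, undefined=True)
    return SampEnResult(float(-np.log(a / b)), a, b, r, degenerate_r=degenerate)


def sample_entropy_naive(x: np.ndarray, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Literal double-loop SampEn; the independent oracle for the fast path."""
    x = np.asarray(x, dtype=float)
    m = cfg.m
    r = cfg.r_factor * x.std()
    n_t = x.size - m
    a = b = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return 0.0 if x.std() == 0 else float("inf")
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# PCA over band variables
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray        # observations x components
    loadings: np.ndarray      # variables x components, orthonormal columns
    variance_fractions: np.ndarray
    column_means: np.ndarray


def pca_bands(matrix: np.ndarray) -> PCAResult:
    """Column-centered (unscaled) PCA by singular-value decomposition.

    Time bins are the observations, spectral bands the variables.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 observations and 2 variables")
    mu = X.mean(axis=0)
    Xc = X - mu
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else np.full_like(var, 1.0 / var.size)
    return PCAResult(scores=scores, loadings=vt.T, variance_fractions=frac,
                     column_means=mu)


def pc_pair_distances(scores_pc12: np.ndarray, group_labels,
                      binwidth: float | None = None) -> dict:
    """Within-group pairwise Euclidean distances on the PC1/PC2 plane,
    histograms, and the two-sample KS comparison between every group pair."""
    pts = np.asarray(scores_pc12, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be (n, 2)")
    labels = np.asarray(group_labels)
    groups = {}
    for g in pd.unique(labels):
        sel = labels == g
        if np.count_nonzero(sel) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 points")
        groups[g] = pdist(pts[sel])
    hists = {}
    if binwidth is not None:
        top = max(d.max() for d in groups.values())
        edges = np.arange(0.0, top + binwidth, binwidth)
        for g, d in groups.items():
            hists[g] = np.histogram(d, bins=edges)
    ks = {}
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = stats.ks_2samp(groups[names[i]], groups[names[j]])
            ks[(names[i], names[j])] = {"D": float(res.statistic), "p": float(res.pvalue)}
    return {"distances": groups, "histograms": hists, "ks": ks}


# ---------------------------------------------------------------------------
# fold-change table
# ---------------------------------------------------------------------------

GROUP_ORDER = ("WT-LD", "WT-DD", "KO-LD", "KO-DD")


@dataclass
class FoldChangeTable:
    fold: pd.DataFrame        # measures x groups, all >= 1
    direction: pd.DataFrame   # "increase" / "decrease" / "none"


def fold_change_table(measure_means: dict[str, dict[str, float]],
                      reference: str = "WT-LD") -> FoldChangeTable:
    """Fold changes of pooled group means against the wild-type/LD group.

    Raw fold change is group mean / reference mean; values below 1 are
    reported as their reciprocal with the direction flagged "decrease", so
    the table always shows the magnitude of change.
    """
    measures = list(measure_means)
    groups = sorted({g for d in measure_means.values() for g in d},
                    key=lambda g: GROUP_ORDER.index(g) if g in GROUP_ORDER else 99)
    fold = pd.DataFrame(index=measures, columns=groups, dtype=float)
    direction = pd.DataFrame(index=measures, columns=groups, dtype=object)
    for meas, by_group in measure_means.items():
        ref = by_group.get(reference)
        if ref is None:
            raise ValueError(f"measure {meas!r} lacks the reference group {reference!r}")
        if ref == 0:
            raise ValueError(f"zero reference mean for measure {meas!r}")
        for g, val in by_group.items():
            fc = val / ref
            if np.isclose(fc, 1.0):
                fold.loc[meas, g], direction.loc[meas, g] = 1.0, "none"
            elif fc < 1.0:
                fold.loc[meas, g], direction.loc[meas, g] = 1.0 / fc, "decrease"
            else:
                fold.loc[meas, g], direction.loc[meas, g] = fc, "increase"
    return FoldChangeTable(fold=fold, direction=direction)
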