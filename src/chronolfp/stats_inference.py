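"""Group-comparison statistics and the a-priori power computation.

Covers the pooled-variance two-sample t test, Type II two-way ANOVA, the
Wilcoxon rank-sum / signed-rank and two-sample Kolmogorov-Smirnov tests,
ordinary least-squares regression with per-coefficient Wald tests, and
exact noncentral-t sample-size determination.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    effect: dict | None = None
    undefined: bool = False


def t_test_unpaired(x, y) -> TestResult:
    """Student (pooled-variance) two-sample t test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return TestResult("t_unpaired", 0.0, 1.0, df, undefined=True)
        raise ValueError("zero pooled variance with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    return TestResult("t_unpaired", float(t), float(p), df, effect={"cohens_d": float(d)})


def anova_type2(values, factor_a, factor_b) -> dict[str, TestResult]:
    """Type II two-way ANOVA with interaction.

    Each main effect is adjusted for the other (Type II sums of squares);
    the interaction is tested last.  Returns a TestResult per term.
    """
    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "A": pd.Categorical(factor_a),
        "B": pd.Categorical(factor_b),
    })
    counts = df.groupby(["A", "B"], observed=False).size()
    if (counts == 0).any():
        empty = counts[counts == 0].index.tolist()
        raise ValueError(f"empty design cells make terms inestimable: {empty}")
    model = ols("y ~ C(A) * C(B)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=2)
    out = {}
    name_map = {"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"}
    for row, term in name_map.items():
        if row not in tab.index:
            continue
        out[term] = TestResult(
            test="anova_type2",
            statistic=float(tab.loc[row, "F"]),
            p_value=float(tab.loc[row, "PR(>F)"]),
            df=(float(tab.loc[row, "df"]), float(tab.loc["Residual", "df"])),
        )
    return out


_WILCOXON_ALIAS = {"wilcoxon_paired_rank_sum": "wilcoxon_paired_signed_rank"}


def rank_and_distribution_tests(x, y, kind: str) -> TestResult:
    """Rank-sum, signed-rank, or two-sample KS test.

    ``wilcoxon_paired_rank_sum`` is accepted as an alias for the signed-rank
    test with a warning: a "paired rank-sum" test is a contradiction in
    terms, and the signed-rank test is the paired procedure it names.
    Wilcoxon variants use exact enumeration for n <= 8 (no ties), the normal
    asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind in _WILCOXON_ALIAS:
        warnings.warn("'paired rank-sum' interpreted as the Wilcoxon signed-rank test")
        kind = _WILCOXON_ALIAS[kind]
    if kind == "wilcoxon_unpaired":
        method = "exact" if max(x.size, y.size) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return TestResult("wilcoxon_unpaired", float(res.statistic), float(res.pvalue))
    if kind == "wilcoxon_paired_signed_rank":
        if x.size != y.size:
            raise ValueError("paired test requires equal length")
        d = x - y
        if np.all(d == 0):
            raise ValueError("all paired differences are zero")
        method = "exact" if x.size <= 8 else "approx"
        res = stats.wilcoxon(x, y, alternative="two-sided", method=method)
        return TestResult("wilcoxon_paired_signed_rank", float(res.statistic), float(res.pvalue))
    if kind == "ks_two_sample":
        res = stats.ks_2samp(x, y)
        return TestResult("ks_two_sample", float(res.statistic), float(res.pvalue))
    raise ValueError(f"unknown test kind {kind!r}")


def ols_regression(y, predictors: pd.DataFrame | np.ndarray) -> dict:
    """OLS with intercept; coefficients, standard errors, Wald t tests."""
    X = pd.DataFrame(predictors)
    y = np.asarray(y, dtype=float)
    Xd = sm.add_constant(X, has_constant="add")
    arr = np.asarray(Xd, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the dependent columns via QR pivoting on the correlation structure
        bad = []
        for j in range(arr.shape[1]):
            others = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(str(Xd.columns[j]))
        raise ValueError(f"collinear design; dependent columns: {bad}")
    fit = sm.OLS(y, Xd).fit()
    results = {
        name: TestResult("wald_t", float(fit.tvalues[name]), float(fit.pvalues[name]),
                         df=float(fit.df_resid))
        for name in Xd.columns
    }
    return {
        "params": fit.params,
        "bse": fit.bse,
        "r_squared": float(fit.rsquared),
        "tests": results,
        "fit": fit,
    }


@dataclass(frozen=True)
class PowerSpec:
    effect_size: float
    power: float = 0.9
    alpha: float = 0.05
    design: str = "two_sample"
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.power < 1 or not 0 < self.alpha < 1:
            raise ValueError("power and alpha must lie in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size must be > 0")
        if self.design not in ("two_sample", "one_sample", "paired"):
            raise ValueError(f"unknown design {self.design!r}")


def _t_power(n: int, spec: PowerSpec) -> float:
    """Exact power of the t test at per-group size n via the noncentral t."""
    d = spec.effect_size
    if spec.design == "two_sample":
        df = 2 * n - 2
        nc = d * np.sqrt(n / 2.0)
    else:  # one_sample and paired share the same arithmetic on n differences
        df = n - 1
        nc = d * np.sqrt(n)
    if df < 1:
        return 0.0
    if spec.two_sided:
        tc = stats.t.ppf(1 - spec.alpha / 2, df)
        return float(stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))
    tc = stats.t.ppf(1 - spec.alpha, df)
    return float(stats.nct.sf(tc, df, nc))


def power_sample_size(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest per-group n with exact noncentral-t power >= the target."""
    if spec.power <= spec.alpha:
        raise ValueError("requested power must exceed alpha")
    n = 2
    while n <= n_max:
        if _t_power(n, spec) >= spec.power:
            return n
        n += 1
    raise RuntimeError("no n found below n_max")
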