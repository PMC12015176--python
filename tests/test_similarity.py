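"""Distance, slope, entropy, PCA and fold-change operations."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chronolfp.similarity import (EntropyConfig, average_over_bands,
                                  distance_matrix, euclidean_distance,
                                  fold_change_table, group_distances, pc_pair_distances,
                                  pca_bands, sample_entropy, sample_entropy_naive,
                                  slope_skewness)


class TestEuclideanDistance:
    def test_identity_zero(self, rng):
        a = rng.standard_normal(100)
        assert euclidean_distance(a, a) == 0.0

    def test_constant_offset_closed_form(self, rng):
        a = rng.standard_normal(250)
        assert euclidean_distance(a, a + 0.5) == pytest.approx(250 * 0.5)

    def test_matches_bruteforce_loop_oracle(self, rng):
        a, b = rng.standard_normal((2, 500))
        brute = sum(np.sqrt((b[i] - a[i]) ** 2) for i in range(500))
        assert euclidean_distance(a, b) == pytest.approx(brute, rel=1e-9)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            euclidean_distance(rng.standard_normal(10), rng.standard_normal(11))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_pseudometric_on_random_triples(self, seed):
        r = np.random.default_rng(seed)
        a, b, c = r.standard_normal((3, 50))
        dab = euclidean_distance(a, b)
        assert dab == pytest.approx(euclidean_distance(b, a))
        assert dab <= euclidean_distance(a, c) + euclidean_distance(c, b) + 1e-9


class TestDistanceMatrix:
    def _labels(self, n, **cols):
        base = {"animal": [f"a{i}" for i in range(n)],
                "genotype": ["wildtype"] * n, "regimen": ["LD"] * n}
        base.update(cols)
        return pd.DataFrame(base)

    def test_symmetric_zero_diagonal(self, rng):
        X = rng.standard_normal((5, 100))
        dm = distance_matrix(X, self._labels(5))
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)

    def test_duplicated_series_zero_offdiagonal(self, rng):
        x = rng.standard_normal(100)
        dm = distance_matrix(np.vstack([x, x, x + 1]), self._labels(3))
        assert dm.matrix[0, 1] == 0.0
        assert dm.matrix[0, 2] > 0.0

    def test_entries_match_scalar_distance(self, rng):
        X = rng.standard_normal((4, 60))
        dm = distance_matrix(X, self._labels(4))
        assert dm.matrix[1, 3] == pytest.approx(euclidean_distance(X[1], X[3]))

    def test_band_average_equals_elementwise_mean(self, rng):
        mats = [distance_matrix(rng.standard_normal((4, 50)),
                                self._labels(4, band=[b] * 4)) for b in ("delta", "theta1")]
        avg = average_over_bands(mats)
        expected = (mats[0].matrix + mats[1].matrix) / 2.0
        assert np.allclose(avg.matrix, expected)


class TestGroupDistances:
    def test_partition_covers_all_pairs(self, rng):
        n = 6
        labels = pd.DataFrame({"regimen": ["LD", "LD", "LD", "DD", "DD", "DD"]})
        dm = distance_matrix(rng.standard_normal((n, 30)), labels)
        groups = group_distances(dm, "regimen")
        assert sum(g.size for g in groups.values()) == n * (n - 1) // 2

    def test_single_level_degenerate(self, rng):
        labels = pd.DataFrame({"regimen": ["LD"] * 4})
        dm = distance_matrix(rng.standard_normal((4, 30)), labels)
        groups = group_distances(dm, "regimen")
        assert groups["both_LD"].size == 6
        assert groups["mixed"].size == 0

    def test_matches_bruteforce_pair_classification(self, rng):
        levels = rng.choice(["wildtype", "cry_ko"], size=8)
        labels = pd.DataFrame({"genotype": levels})
        dm = distance_matrix(rng.standard_normal((8, 20)), labels)
        groups = group_distances(dm, "genotype")
        brute = {"both_cry_ko": [], "mixed": [], "both_wildtype": []}
        for i in range(8):
            for j in range(i + 1, 8):
                if levels[i] == levels[j] == "cry_ko":
                    brute["both_cry_ko"].append(dm.matrix[i, j])
                elif levels[i] == levels[j] == "wildtype":
                    brute["both_wildtype"].append(dm.matrix[i, j])
                else:
                    brute["mixed"].append(dm.matrix[i, j])
        for k, v in brute.items():
            assert np.allclose(np.sort(groups[k]), np.sort(v))

    def test_nonbinary_variable_rejected(self, rng):
        labels = pd.DataFrame({"band": ["delta", "theta1", "alpha1"]})
        dm = distance_matrix(rng.standard_normal((3, 10)), labels)
        with pytest.raises(ValueError):
            group_distances(dm, "band")


class TestSlopeSkewness:
    def test_constant_series_undefined(self):
        res = slope_skewness(np.ones(100), dt=1.0)
        assert res.undefined and np.isnan(res.skewness)
        assert np.all(res.slopes == 0)

    def test_slope_count_contract(self, rng):
        res = slope_skewness(rng.standard_normal(500), dt=1.0)
        assert res.slopes.size == 499

    def test_exponential_slopes_skewness_two(self):
        rng = np.random.default_rng(77)
        incr = rng.exponential(1.0, 100_000) * rng.choice([-1, 1], 100_000)
        series = np.cumsum(incr)
        res = slope_skewness(series, dt=1.0)
        assert res.skewness == pytest.approx(2.0, abs=0.1)


class TestSampleEntropy:
    def test_fast_equals_naive_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(1000)
        fast = sample_entropy(x)
        assert fast.value == sample_entropy_naive(x)

    def test_constant_series_degenerate_zero(self):
        res = sample_entropy(np.ones(50))
        assert res.value == 0.0 and res.degenerate_r

    def test_sine_more_regular_than_permutation(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 8 * np.pi, 1000)
        sine = np.sin(t)
        wins = 0
        for _ in range(100):
            perm = rng.permutation(sine)
            wins += sample_entropy(sine).value < sample_entropy(perm).value
        assert wins >= 95

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(400)
        v1 = sample_entropy(x).value
        v2 = sample_entropy(5.0 * x - 3.0).value
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), EntropyConfig(m=2))


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        res = pca_bands(rng.standard_normal((200, 10)))
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_input_single_component(self, rng):
        base = rng.standard_normal(100)
        X = np.outer(base, rng.uniform(0.5, 2.0, 10))
        res = pca_bands(X)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_uncorrelated(self, rng):
        res = pca_bands(rng.standard_normal((300, 6)))
        cov = res.scores.T @ res.scores
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-9 * np.max(np.abs(cov))

    def test_reconstruction(self, rng):
        X = rng.standard_normal((50, 8))
        res = pca_bands(X)
        back = res.scores @ res.loadings.T + res.column_means
        assert np.allclose(back, X, atol=1e-9)

    def test_loadings_orthonormal(self, rng):
        res = pca_bands(rng.standard_normal((100, 5)))
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-9)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.decomposition import PCA
        X = rng.standard_normal((120, 7))
        ours = pca_bands(X)
        ref = PCA().fit(X)
        assert np.allclose(ours.variance_fractions, ref.explained_variance_ratio_,
                           atol=1e-9)


class TestPCPairDistances:
    def test_pair_count_combinatorics(self, rng):
        pts = rng.standard_normal((10, 2))
        out = pc_pair_distances(pts, ["g"] * 10)
        assert out["distances"]["g"].size == 45

    def test_coincident_points_zero(self):
        pts = np.zeros((5, 2))
        out = pc_pair_distances(pts, ["g"] * 5)
        assert np.all(out["distances"]["g"] == 0)

    def test_ks_null_behavior_under_dependence(self):
        # all-pairs distances are strongly dependent samples, so the KS test
        # on them is anticonservative under the null: the rejection rate
        # exceeds the nominal 5%, while the D statistic still shrinks with n.
        rng = np.random.default_rng(42)
        rejections = 0
        d_small, d_large = [], []
        n_runs = 100
        for _ in range(n_runs):
            pts = rng.standard_normal((40, 2))
            labels = np.array(["a"] * 20 + ["b"] * 20)
            out = pc_pair_distances(pts, labels)
            rejections += out["ks"][("a", "b")]["p"] < 0.05
            d_small.append(out["ks"][("a", "b")]["D"])
            pts = rng.standard_normal((120, 2))
            labels = np.array(["a"] * 60 + ["b"] * 60)
            d_large.append(pc_pair_distances(pts, labels)["ks"][("a", "b")]["D"])
        assert rejections / n_runs > 0.05
        assert np.mean(d_large) < np.mean(d_small)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            pc_pair_distances(rng.standard_normal((3, 2)), ["a", "a", "b"])


class TestFoldChange:
    def test_reference_column_is_one(self):
        out = fold_change_table({"m": {"WT-LD": 2.0, "WT-DD": 4.0}})
        assert out.fold.loc["m", "WT-LD"] == 1.0
        assert out.direction.loc["m", "WT-LD"] == "none"

    def test_doubling_reports_increase(self):
        out = fold_change_table({"m": {"WT-LD": 2.0, "KO-LD": 4.0}})
        assert out.fold.loc["m", "KO-LD"] == pytest.approx(2.0)
        assert out.direction.loc["m", "KO-LD"] == "increase"

    def test_halving_reports_reciprocal_decrease(self):
        out = fold_change_table({"m": {"WT-LD": 2.0, "KO-DD": 1.0}})
        assert out.fold.loc["m", "KO-DD"] == pytest.approx(2.0)
        assert out.direction.loc["m", "KO-DD"] == "decrease"

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_change_table({"m": {"WT-LD": 0.0, "KO-LD": 1.0}})
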