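import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import euclidean
from scipy.stats import pearsonr

from thermoraac import (
    FeatureMatrix,
    FeatureMeta,
    correlation_prune,
    mrmd_rank,
    mrmd_select,
    normalize,
    pca_fit,
    pca_transform,
    pearson,
)
from thermoraac.reduction import MRMDScore, choose_k, correlation_matrix


def _fm(values, labels=None, names=None, normalized=False):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    return FeatureMatrix(
        values,
        [FeatureMeta(n, "physchem188") for n in names],
        ids=[f"s{i}" for i in range(values.shape[0])],
        labels=None if labels is None else np.asarray(labels),
        normalized=normalized,
    )


class TestNormalize:
    def test_min_max_endpoints(self):
        out = normalize(_fm([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.values[:, 0], [0.0, 0.5, 1.0])
        assert out.normalized

    def test_constant_column_becomes_zero(self, caplog):
        out = normalize(_fm([[5.0], [5.0], [5.0]]))
        assert np.all(out.values == 0.0)

    def test_unit_range_column_unchanged(self):
        col = np.array([[0.0], [0.3], [0.7], [1.0]])
        assert np.allclose(normalize(_fm(col)).values, col)


class TestPearson:
    def test_perfect_positive(self):
        assert pearson([0, 1, 2], [0, 2, 4]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_worked_example(self):
        got = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert got == pytest.approx(0.8)
        assert got == pytest.approx(pearsonr([1, 2, 3, 4], [1, 3, 2, 4]).statistic)

    def test_zero_variance_returns_zero(self):
        assert pearson([1, 1, 1], [1, 2, 3]) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1], [2])

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.lists(st.floats(-100, 100), min_size=3, max_size=20),
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    def test_shift_scale_invariance_and_bounds(self, x, shift, scale):
        rng = np.random.default_rng(abs(hash(tuple(x))) % 2**31)
        y = rng.normal(size=len(x))
        r = pearson(x, y)
        assert -1.0 <= r <= 1.0
        assert pearson(np.array(x) * scale + shift, y) == pytest.approx(
            r, abs=1e-8
        )
        assert pearson(y, x) == pytest.approx(r, abs=1e-12)


def _orthonormal_columns(n=8):
    """Mean-zero orthogonal unit columns for building exact correlations."""
    rng = np.random.default_rng(4)
    base = rng.normal(size=(n, 4))
    base -= base.mean(axis=0)
    q, _ = np.linalg.qr(base)
    return q


class TestCorrelationPrune:
    def test_identical_columns(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(size=10)
        fm = normalize(_fm(np.column_stack([col, col]), names=["f1", "f2"]))
        result = correlation_prune(fm, 0.85)
        assert result.reserved == {"f1"}
        assert result.removed == {"f2"}

    def test_no_high_pairs_keeps_everything(self):
        q = _orthonormal_columns()
        fm = normalize(_fm(q[:, :3]))
        result = correlation_prune(fm, 0.85)
        assert result.removed == set() and result.reserved == set()

    def test_chain_rule_sequence(self):
        # f1~f2 (rho 0.9), f2~f3 (rho 0.9), f1~f3 (rho 0.81 <= T)
        q = _orthonormal_columns()
        u, v, w = q[:, 0], q[:, 1], q[:, 2]
        f1 = u
        f2 = 0.9 * u + np.sqrt(1 - 0.81) * v
        f3 = 0.9 * f2 + np.sqrt(1 - 0.81) * w
        fm = normalize(_fm(np.column_stack([f1, f2, f3]), names=["f1", "f2", "f3"]))
        corr = correlation_matrix(fm.values)
        assert abs(corr[0, 1]) > 0.85 and abs(corr[1, 2]) > 0.85
        assert abs(corr[0, 2]) <= 0.85
        result = correlation_prune(fm, 0.85)
        assert result.reserved == {"f1"}
        assert result.removed == {"f2", "f3"}

    def test_requires_normalized_matrix(self):
        with pytest.raises(ValueError, match="normalized"):
            correlation_prune(_fm(np.eye(3)), 0.85)

    def test_deterministic_rerun(self, rng):
        X = rng.uniform(size=(12, 10))
        X[:, 5] = X[:, 2] * 0.99 + 0.01 * rng.uniform(size=12)
        fm = normalize(_fm(X))
        a = correlation_prune(fm, 0.85)
        b = correlation_prune(fm, 0.85)
        assert (a.removed, a.reserved) == (b.removed, b.reserved)
        assert a.driving_pairs == b.driving_pairs

    @pytest.mark.parametrize("seed", range(10))
    def test_strict_mode_leaves_no_correlated_retained_pair(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(12, 8))
        # plant extra correlation structure
        X[:, 4] = X[:, 0] + 0.05 * rng.uniform(size=12)
        X[:, 5] = X[:, 0] + 0.05 * rng.uniform(size=12)
        fm = normalize(_fm(X))
        result = correlation_prune(fm, threshold=0.85, strict=True)
        kept = [n for n in fm.feature_names if n not in result.removed]
        kept_fm = fm.select_features(kept)
        corr = correlation_matrix(kept_fm.values)
        off = corr[np.triu_indices(len(kept), k=1)]
        assert np.all(np.abs(off) <= 0.85 + 1e-12)

    def test_removed_features_have_driving_pairs(self, rng):
        X = rng.uniform(size=(15, 10))
        X[:, 7] = X[:, 1]
        fm = normalize(_fm(X))
        result = correlation_prune(fm, 0.85)
        in_pairs = {n for pair in result.driving_pairs for n in pair[:2]}
        assert result.removed <= in_pairs
        assert result.reserved <= in_pairs
        assert not (result.removed & result.reserved)


class TestMRMDRank:
    def test_label_copy_feature_has_maximal_relevance(self):
        y = np.array([1, 0, 1, 0, 1, 0])
        rng = np.random.default_rng(1)
        X = np.column_stack([y.astype(float), rng.uniform(size=6)])
        fm = normalize(_fm(X, labels=y, names=["copy", "noise"]))
        scores = {s.name: s for s in mrmd_rank(fm)}
        assert scores["copy"].relevance == pytest.approx(1.0)

    def test_duplicate_columns_contribute_zero_mutual_distance(self):
        y = np.array([1, 0, 1, 0])
        col = np.array([0.1, 0.9, 0.4, 0.2])
        other = np.array([0.5, 0.5, 0.0, 1.0])
        fm = _fm(
            np.column_stack([col, col, other]), labels=y,
            names=["a", "b", "c"], normalized=True,
        )
        scores = {s.name: s for s in mrmd_rank(fm)}
        d_ac = euclidean(col, other)
        assert scores["a"].distance == pytest.approx(d_ac / 2)  # (0 + d_ac) / 2

    def test_matches_brute_force_oracle(self, rng):
        """Full ranking agrees with a direct per-feature computation."""
        for _ in range(5):
            X = rng.uniform(size=(10, 8))
            y = rng.integers(0, 2, size=10)
            if len(set(y.tolist())) < 2:
                y[0] = 1 - y[0]
            fm = _fm(X, labels=y, normalized=True)
            got = mrmd_rank(fm)
            expected = []
            for i in range(8):
                mr = abs(pearsonr(X[:, i], y).statistic)
                md = np.mean([
                    euclidean(X[:, i], X[:, k]) for k in range(8) if k != i
                ])
                expected.append((f"f{i}", mr + md))
            expected.sort(key=lambda t: (-t[1], t[0]))
            assert [s.name for s in got] == [n for n, _ in expected]
            for s, (_, total) in zip(got, expected):
                assert s.total == pytest.approx(total)

    def test_single_feature_errors(self):
        fm = _fm(np.ones((4, 1)), labels=[0, 1, 0, 1], normalized=True)
        with pytest.raises(ValueError, match="at least 2"):
            mrmd_rank(fm)


class TestMRMDSelect:
    def test_perfect_feature_selected_alone(self):
        rng = np.random.default_rng(3)
        y = np.array([1, 0] * 15)
        X = np.column_stack([y.astype(float), rng.uniform(size=30), rng.uniform(size=30)])
        fm = _fm(X, labels=y, names=["sep", "n1", "n2"], normalized=True)
        ranked = [MRMDScore("sep", 1.0, 1.0), MRMDScore("n1", 0.1, 1.0),
                  MRMDScore("n2", 0.1, 0.9)]
        result = mrmd_select(ranked, fm, folds=5, seed=0)
        assert result.k == 1
        assert result.feature_names == ["sep"]
        assert result.accuracy == pytest.approx(100.0)

    def test_pure_noise_accuracy_near_chance(self):
        rng = np.random.default_rng(8)
        n = 60
        y = np.array([1, 0] * (n // 2))
        X = rng.uniform(size=(n, 4))
        fm = _fm(X, labels=y, normalized=True)
        result = mrmd_select(mrmd_rank(fm), fm, folds=5, seed=1)
        # two-sided binomial 95% interval around 50% for n = 60
        half_width = 100 * 1.96 * np.sqrt(0.25 / n)
        assert abs(result.accuracy - 50.0) <= half_width + 1e-9

    def test_single_feature_returned_without_search(self):
        y = np.array([1, 0] * 10)
        fm = _fm(y.astype(float).reshape(-1, 1), labels=y, names=["only"],
                 normalized=True)
        result = mrmd_select([MRMDScore("only", 1.0, 0.0)], fm, folds=5, seed=0)
        assert result.k == 1 and result.feature_names == ["only"]

    def test_patience_stops_early(self):
        rng = np.random.default_rng(5)
        y = np.array([1, 0] * 20)
        X = np.column_stack([y.astype(float)] + [rng.uniform(size=40) for _ in range(10)])
        fm = _fm(X, labels=y, normalized=True)
        ranked = [MRMDScore(n, 0.0, 0.0) for n in fm.feature_names]
        result = mrmd_select(ranked, fm, folds=5, seed=0, patience=3)
        assert len(result.trace) <= 1 + 3  # best at k=1, then 3 non-improving


class TestPCA:
    def test_choose_k_on_stated_shares(self):
        assert choose_k(np.array([0.90, 0.08, 0.02]), 0.95) == 2
        assert choose_k(np.array([0.90, 0.08, 0.02]), 0.90) == 1
        assert choose_k(np.array([0.90, 0.08, 0.02]), 1.00) == 3

    def test_rank_one_data(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([2 * t + 1, -3 * t + 4])  # points exactly on a line
        model = pca_fit(X, t_prime=0.5)
        assert model.k == 1
        assert model.cumulative_contribution == pytest.approx(1.0)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(20, 5))
        model = pca_fit(X, k_override=5)
        proj = pca_transform(model, X)
        recon = proj @ model.components + model.mean
        assert np.allclose(recon, X, atol=1e-10)

    def test_mean_row_maps_to_origin(self, rng):
        X = rng.normal(size=(15, 4))
        model = pca_fit(X, t_prime=0.95)
        assert np.allclose(pca_transform(model, X.mean(axis=0, keepdims=True)), 0.0)

    def test_eigenvalues_non_increasing_and_variance_conserved(self, rng):
        X = rng.normal(size=(30, 6))
        model = pca_fit(X, k_override=6)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        total_var = np.var(X, axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total_var)

    def test_projected_columns_uncorrelated(self, rng):
        X = rng.normal(size=(40, 5))
        model = pca_fit(X, k_override=4)
        proj = pca_transform(model, X)
        cov = np.cov(proj, rowvar=False)
        off = cov[np.triu_indices(4, k=1)]
        assert np.allclose(off, 0.0, atol=1e-10)

    def test_k_override_beyond_rank_errors(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t])
        with pytest.raises(ValueError, match="rank"):
            pca_fit(X, k_override=2)

    def test_sign_convention_largest_loading_positive(self, rng):
        X = rng.normal(size=(25, 6))
        model = pca_fit(X, k_override=3)
        for row in model.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_k_override_width(self, rng):
        X = rng.normal(size=(40, 20))
        model = pca_fit(X, k_override=12)
        assert pca_transform(model, X).shape == (40, 12)

    def test_dimension_mismatch_errors(self, rng):
        X = rng.normal(size=(10, 4))
        model = pca_fit(X)
        with pytest.raises(ValueError, match="match"):
            pca_transform(model, rng.normal(size=(3, 5)))
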