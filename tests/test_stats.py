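"""PCA contracts, loading similarity, and nonparametric tests."""

import numpy as np
import pandas as pd
import pytest

from radimm.stats import (
    fit_pca,
    kruskal_wallis,
    loading_similarity,
    mann_whitney,
    multigroup_pca,
    n_components_80,
    pc_cross_correlation,
    zscore,
)


def random_standardized(n, p, seed, corr=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if corr:
        common = rng.standard_normal((n, 1))
        X = np.sqrt(1 - corr) * X + np.sqrt(corr) * common
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    return zscore(df)


class TestZscore:
    def test_small_example(self):
        out = zscore(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["a"], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        df = random_standardized(50, 3, 0)
        again = zscore(df)
        assert np.allclose(df.to_numpy(), again.to_numpy(), atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant column 'b'"):
            out = zscore(df)
        assert list(out.columns) == ["a"]

    def test_all_missing_column_is_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="'b'"):
            zscore(df)

    def test_missing_cells_stay_missing(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0, 5.0]})
        out = zscore(df)
        assert out["a"].isna().sum() == 1


class TestFitPca:
    def test_collinear_data_has_single_component(self):
        x = np.arange(10.0)
        df = zscore(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        model = fit_pca(df)
        assert model.explained[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self):
        model = fit_pca(random_standardized(40, 6, 1))
        assert model.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self):
        model = fit_pca(random_standardized(40, 6, 2))
        L = model.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_reconstruction_with_all_components(self):
        df = random_standardized(30, 5, 3)
        model = fit_pca(df)
        X = df.to_numpy()
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T + X.mean(axis=0)
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_repeated_fits_bit_identical(self):
        df = random_standardized(30, 5, 4)
        m1, m2 = fit_pca(df), fit_pca(df)
        assert np.array_equal(m1.loadings.to_numpy(), m2.loadings.to_numpy())
        assert np.array_equal(m1.scores.to_numpy(), m2.scores.to_numpy())

    def test_sign_convention(self):
        model = fit_pca(random_standardized(30, 5, 5))
        L = model.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_incomplete_rows_dropped(self):
        df = random_standardized(30, 4, 6)
        df.iloc[0, 0] = np.nan
        model = fit_pca(df)
        assert model.n_used == 29
        assert 0 not in model.scores.index

    def test_too_few_rows_is_error(self):
        with pytest.raises(ValueError, match="2 complete rows"):
            fit_pca(pd.DataFrame({"a": [1.0], "b": [2.0]}))


class TestNComponents80:
    @pytest.mark.parametrize(
        "explained,expected",
        [([0.5, 0.3, 0.15, 0.05], 2), ([0.5, 0.29, 0.15, 0.06], 3), ([1.0], 1)],
    )
    def test_threshold_inclusive(self, explained, expected):
        model = fit_pca(random_standardized(20, 4, 7))
        model.explained = np.array(explained)
        assert n_components_80(model) == expected


class TestMultigroupPca:
    def test_single_group_equals_pooled(self):
        df = pd.DataFrame(
            np.random.default_rng(8).standard_normal((40, 5)),
            columns=[f"f{i}" for i in range(5)],
        )
        groups, pooled = multigroup_pca({"only": df})
        assert np.allclose(
            groups["only"].loadings.to_numpy(), pooled.loadings.to_numpy(), atol=1e-10
        )

    def test_orthogonal_dominant_axes(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.standard_normal(n)
        a = pd.DataFrame({"f0": x, "f1": x + 0.1 * rng.standard_normal(n)})
        y = rng.standard_normal(n)
        b = pd.DataFrame({"f0": y, "f1": -y + 0.1 * rng.standard_normal(n)})
        groups, _ = multigroup_pca({"a": a, "b": b})
        va = groups["a"].loadings.to_numpy()[:, 0]
        vb = groups["b"].loadings.to_numpy()[:, 0]
        assert abs(va @ vb) < 0.3

    def test_tiny_group_skipped_with_warning(self):
        rng = np.random.default_rng(10)
        big = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        tiny = pd.DataFrame(rng.standard_normal((1, 3)), columns=list("abc"))
        with pytest.warns(UserWarning, match="skipped"):
            groups, _ = multigroup_pca({"big": big, "tiny": tiny})
        assert set(groups) == {"big"}


class TestPcCrossCorrelation:
    def test_self_pair_diagonal_is_one_and_offdiag_zero(self):
        model = fit_pca(random_standardized(50, 6, 11))
        mats = pc_cross_correlation({"t": model}, k=4)
        mat = mats[("t", "t")].to_numpy()
        assert np.allclose(np.diag(mat), 1.0, atol=1e-10)
        off = mat[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-10  # score orthogonality

    def test_independent_structures_have_small_cross_correlation(self):
        exceed = total = 0
        for seed in range(20):
            a = fit_pca(random_standardized(200, 6, 1000 + seed, corr=0.5))
            b = fit_pca(random_standardized(200, 6, 2000 + seed, corr=0.5))
            mat = pc_cross_correlation({"a": a, "b": b}, k=4)[("a", "b")].to_numpy()
            exceed += int((np.abs(mat) >= 0.2).sum())
            total += mat.size
        assert exceed / total <= 0.05

    def test_insufficient_overlap_gives_missing(self):
        a = fit_pca(random_standardized(20, 4, 12))
        b = fit_pca(random_standardized(20, 4, 13))
        b.scores.index = b.scores.index + 100  # no shared subjects
        mat = pc_cross_correlation({"a": a, "b": b}, k=2)[("a", "b")]
        assert mat.isna().all().all()


class TestLoadingSimilarity:
    def test_self_similarity_is_exactly_one(self):
        L = fit_pca(random_standardized(30, 6, 14)).loadings
        res = loading_similarity(L, L)
        assert res.value == 1.0
        assert res.k_used == L.shape[1]

    def test_anti_aligned_matrices_score_zero(self):
        L = fit_pca(random_standardized(30, 6, 15)).loadings
        assert loading_similarity(L, -L).value == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = pd.DataFrame(rng.standard_normal((17, 4)))
        b = pd.DataFrame(rng.standard_normal((17, 4)))
        ab, ba = loading_similarity(a, b), loading_similarity(b, a)
        assert ab.value == ba.value
        assert 0.0 <= ab.value <= 1.0

    def test_feature_mismatch_error_lists_difference(self):
        a = pd.DataFrame(np.eye(3), index=["x", "y", "z"])
        b = pd.DataFrame(np.eye(3), index=["x", "y", "w"])
        with pytest.raises(ValueError, match="w"):
            loading_similarity(a, b)

    def test_component_truncation(self):
        L = fit_pca(random_standardized(30, 6, 16)).loadings
        res = loading_similarity(L, L.iloc[:, :3], k=5)
        assert res.k_used == 3


class TestRankTests:
    def test_kruskal_identical_pooled_values(self):
        h, p = kruskal_wallis([np.ones(5), np.ones(4), np.ones(6)])
        assert h == 0.0 and p == 1.0

    def test_kruskal_complete_separation(self):
        groups = [np.arange(1, 21), np.arange(101, 121), np.arange(201, 221)]
        _, p = kruskal_wallis([g.astype(float) for g in groups])
        assert p < 1e-6

    def test_kruskal_empty_group_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis([np.ones(3), np.array([])])

    def test_mann_whitney_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        u, p = mann_whitney(x, x)
        assert p == 1.0

    def test_mann_whitney_complete_separation_u_zero(self):
        u, p = mann_whitney(np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0]))
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=0.01)  # exact two-sided p = 2/20

    def test_mann_whitney_empty_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney(np.array([]), np.ones(3))

    def test_two_group_kruskal_agrees_with_mann_whitney_decision(self):
        agree = 0
        for seed in range(50):
            rng = np.random.default_rng(3000 + seed)
            shift = rng.choice([0.0, 1.5])
            x = rng.standard_normal(25)
            y = rng.standard_normal(25) + shift
            _, p_kw = kruskal_wallis([x, y])
            _, p_mw = mann_whitney(x, y)
            agree += int((p_kw < 0.05) == (p_mw < 0.05))
        assert agree == 50

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            groups = [rng.standard_normal(rng.integers(3, 15)) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            assert 0.0 <= p <= 1.0
            _, p = mann_whitney(groups[0], groups[1])
            assert 0.0 <= p <= 1.0
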