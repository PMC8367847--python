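import numpy as np
import pandas as pd
import pytest

from scnpipe import cohort, outcomes
from scnpipe.outcomes import (
    OutcomeBattery,
    fit_pca,
    permutation_significance,
    preprocess_battery,
    retain_components,
    splithalf_reliability,
)


def _battery(scores, age, normed=None):
    scores = pd.DataFrame(scores)
    scores.columns = [f"m{i}" for i in range(scores.shape[1])]
    if normed is None:
        normed = [False] * scores.shape[1]
    return OutcomeBattery(
        scores=scores,
        age_normed=pd.Series(normed, index=scores.columns),
        age_years=pd.Series(age, index=scores.index),
    )


def _planted_Z(rng, N=200, M=32, noise=0.5, k=3):
    F = rng.standard_normal((N, k))
    L = np.zeros((M, k))
    for j in range(k):
        L[j * (M // k) : (j + 1) * (M // k), j] = 0.9 - 0.1 * j
    Z = F @ L.T + noise * rng.standard_normal((N, M))
    return (Z - Z.mean(0)) / Z.std(0, ddof=1), F


class TestPreprocess:
    def test_standardization_and_age_removal(self, rng):
        age = rng.uniform(4, 7, 20)
        scores = rng.normal(size=(20, 5)) + np.outer(age, rng.normal(size=5))
        Z = preprocess_battery(_battery(scores, age))
        np.testing.assert_allclose(Z.mean(0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(0, ddof=1), 1.0, atol=1e-10)
        for c in Z.columns:
            assert abs(np.corrcoef(Z[c], age)[0, 1]) < 1e-10

    def test_age_normed_columns_skip_residualization(self, rng):
        age = rng.uniform(4, 7, 30)
        col = rng.normal(size=30) + 2.0 * age  # age-dependent on purpose
        scores = np.column_stack([col, rng.normal(size=30)])
        Z = preprocess_battery(_battery(scores, age, normed=[True, False]))
        expected = (col - col.mean()) / col.std(ddof=1)
        np.testing.assert_allclose(Z["m0"], expected, atol=1e-12)
        assert abs(np.corrcoef(Z["m0"], age)[0, 1]) > 0.5  # age signal kept

    def test_column_linear_in_age_rejected(self, rng):
        age = rng.uniform(4, 7, 20)
        scores = np.column_stack([3.0 * age + 1.0, rng.normal(size=20)])
        with pytest.raises(ValueError, match="constant column after residualization"):
            preprocess_battery(_battery(scores, age))

    def test_missing_age_rejected(self, rng):
        age = rng.uniform(4, 7, 20)
        age[3] = np.nan
        with pytest.raises(ValueError, match="missing age"):
            preprocess_battery(_battery(rng.normal(size=(20, 3)), age))

    def test_high_missingness_subject_dropped(self, rng):
        scores = rng.normal(size=(20, 10))
        scores[0, :5] = np.nan  # 50% missing
        scores[1, 0] = np.nan  # 10% missing -> imputed
        Z = preprocess_battery(_battery(scores, rng.uniform(4, 7, 20)))
        assert Z.shape[0] == 19


class TestFitPCA:
    def test_dominant_shared_factor(self, rng):
        f = rng.standard_normal(100)
        Z = np.outer(f, np.ones(6)) + 0.3 * rng.standard_normal((100, 6))
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        comps = fit_pca(pd.DataFrame(Z))
        assert comps.var_explained[0] > comps.var_explained[1:].max() + 0.3

    def test_var_explained_sums_to_one(self, rng):
        comps = fit_pca(pd.DataFrame(rng.standard_normal((50, 8))))
        assert comps.var_explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(comps.var_explained) <= 1e-12)

    def test_matches_direct_eigendecomposition(self, rng):
        Z = rng.standard_normal((6, 3))
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        comps = fit_pca(pd.DataFrame(Z))
        C = np.corrcoef(Z, rowvar=False)
        vals, vecs = np.linalg.eigh(C)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        for j in range(3):
            got = comps.loadings.iloc[:, j].to_numpy()
            want = vecs[:, j]
            if np.sign(got[np.argmax(np.abs(got))]) != np.sign(want[np.argmax(np.abs(want))]):
                want = -want
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_scores_orthogonal(self, rng):
        Z, _ = _planted_Z(rng, N=80, M=10)
        comps = fit_pca(pd.DataFrame(Z))
        G = comps.scores.to_numpy().T @ comps.scores.to_numpy()
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_sign_convention(self, rng):
        Z, _ = _planted_Z(rng, N=60, M=9)
        comps = fit_pca(pd.DataFrame(Z))
        L = comps.loadings.to_numpy()
        peak = L[np.argmax(np.abs(L), axis=0), np.arange(L.shape[1])]
        assert np.all(peak > 0)

    def test_measure_order_invariance(self, rng):
        Z, _ = _planted_Z(rng, N=100, M=12)
        Zdf = pd.DataFrame(Z, columns=[f"m{i}" for i in range(12)])
        perm = rng.permutation(12)
        a = fit_pca(Zdf)
        b = fit_pca(Zdf.iloc[:, perm])
        for j in range(3):
            r = np.corrcoef(a.scores.iloc[:, j], b.scores.iloc[:, j])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_too_few_measures(self, rng):
        with pytest.raises(ValueError):
            fit_pca(pd.DataFrame(rng.standard_normal((10, 1))))


class TestPermutationSignificance:
    def test_p_values_in_unit_interval(self, rng):
        Z, _ = _planted_Z(rng, N=60, M=8)
        p = permutation_significance(Z, n_perm=100, seed=0)
        assert np.all(p > 0) and np.all(p <= 1)

    def test_planted_factors_significant(self, rng):
        Z, _ = _planted_Z(rng, N=200, M=32, noise=0.5)
        p = permutation_significance(Z, n_perm=500, seed=0)
        assert np.all(p[:3] < 0.05)
        assert p[3] > 0.05

    def test_too_few_permutations(self, rng):
        Z, _ = _planted_Z(rng, N=60, M=8)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_significance(Z, n_perm=50)
        with pytest.raises(ValueError, match="alpha resolution"):
            permutation_significance(Z, n_perm=100, alpha=0.001)


class TestSplithalfReliability:
    def test_identical_halves_give_unity(self, rng):
        Z, _ = _planted_Z(rng, N=40, M=8)
        idx = np.arange(40)
        r = splithalf_reliability(Z, C_test=3, splits=[(idx, idx)])
        np.testing.assert_allclose(r, 1.0, atol=1e-10)

    def test_planted_factors_reliable(self, rng):
        Z, _ = _planted_Z(rng, N=300, M=30, noise=0.5)
        r = splithalf_reliability(Z, C_test=3, n_splits=20, seed=0)
        assert np.all(r >= 0.8)

    def test_noise_unreliable(self, rng):
        Z = rng.standard_normal((200, 30))
        r = splithalf_reliability(Z, C_test=1, n_splits=20, seed=0)
        assert r[0] < 0.7

    def test_small_half_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            splithalf_reliability(rng.standard_normal((19, 5)), C_test=2, n_splits=2)


class TestRetention:
    def _components(self, perm_p, shr):
        comps = fit_pca(pd.DataFrame(np.random.default_rng(0).standard_normal((30, len(perm_p)))))
        comps.perm_p = np.asarray(perm_p)
        comps.splithalf_r = np.asarray(shr)
        return comps

    def test_three_component_outcome(self):
        comps = self._components([0.001, 0.002, 0.01, 0.2], [0.9, 0.85, 0.75, 0.4])
        comps = retain_components(comps, alpha=0.05, r_min=0.7)
        assert comps.n_retained == 3
        np.testing.assert_array_equal(comps.retained, [True, True, True, False])

    def test_nothing_significant(self):
        comps = self._components([0.2, 0.3, 0.4], [0.9, 0.9, 0.9])
        assert retain_components(comps).n_retained == 0

    def test_prefix_rule(self):
        comps = self._components([0.001, 0.2, 0.001], [0.9, 0.9, 0.9])
        comps = retain_components(comps)
        assert comps.n_retained == 1
        np.testing.assert_array_equal(comps.retained, [True, False, False])

    def test_requires_filled_diagnostics(self, rng):
        comps = fit_pca(pd.DataFrame(rng.standard_normal((30, 4))))
        with pytest.raises(ValueError, match="must be filled"):
            retain_components(comps)


class TestFactorRecovery:
    def test_pca_recovers_orthogonal_factor_scores(self, rng):
        # orthogonal (block-diagonal) measure loadings, noise at half the
        # loading scale: component scores match true factors at |r| >= 0.9
        N, M = 200, 30
        F = rng.standard_normal((N, 3))
        L = np.zeros((M, 3))
        L[:12, 0], L[12:21, 1], L[21:, 2] = 0.8, 0.75, 0.7
        age = rng.uniform(4, 7, N)
        scores = F @ L.T + 0.35 * rng.standard_normal((N, M)) + 0.2 * age[:, None]
        battery = _battery(scores, age)
        comps = fit_pca(preprocess_battery(battery))
        S = comps.scores.to_numpy()[:, :3]
        corr = np.abs(np.corrcoef(np.column_stack([S, F]), rowvar=False)[:3, 3:])
        assert np.all(corr.max(axis=0) >= 0.9)

    def test_generator_battery_recovers_factors(self):
        # the study-structured battery (with its deliberate cross-loadings)
        # still identifies each planted factor, with mild rotational mixing
        c = cohort.make_covariates(200, seed=5)
        F = cohort.make_factors(c, None, seed=6)
        battery, _ = cohort.make_battery(F, c, seed=7)
        comps = fit_pca(preprocess_battery(battery))
        S = comps.scores.to_numpy()[:, :3]
        corr = np.abs(np.corrcoef(np.column_stack([S, F]), rowvar=False)[:3, 3:])
        assert np.all(corr.max(axis=0) >= 0.8)
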