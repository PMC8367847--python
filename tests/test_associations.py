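import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scnpipe import associations
from scnpipe.associations import (
    AnalysisBundle,
    bonferroni_threshold,
    followup_univariate,
    full_additive_model,
    interaction_lrt,
    omnibus_multivariate,
    sensitivity_suite,
)


class TestBonferroni:
    def test_fifteen_model_threshold(self):
        value, display = bonferroni_threshold(0.05, 15)
        assert value == pytest.approx(0.05 / 15)
        assert display == ".003"

    def test_three_models(self):
        value, _ = bonferroni_threshold(0.05, 3)
        assert value == pytest.approx(0.016667, abs=1e-6)

    def test_single_model_identity(self):
        assert bonferroni_threshold(0.05, 1)[0] == 0.05

    def test_monotone_decisions(self, rng):
        # lowering alpha never adds a significant result
        p_raw = rng.uniform(0, 1, 50)
        for n_tests in (1, 3, 15):
            adj = np.minimum(1, p_raw * n_tests)
            sig_05 = adj < 0.05
            sig_01 = adj < 0.01
            assert not np.any(sig_01 & ~sig_05)


def _pillai_sscp_oracle(Y, X, term_idx):
    """From-scratch Pillai's trace via hypothesis/error SSCP matrices."""
    G = np.linalg.inv(X.T @ X)
    B = G @ X.T @ Y
    E = (Y - X @ B).T @ (Y - X @ B)
    L = np.zeros((1, X.shape[1]))
    L[0, term_idx] = 1.0
    H = (L @ B).T @ np.linalg.inv(L @ G @ L.T) @ (L @ B)
    return float(np.trace(H @ np.linalg.inv(H + E)))


class TestOmnibus:
    def test_hand_case_matches_sscp_oracle(self, rng):
        Y = rng.standard_normal((12, 2))
        x = rng.standard_normal(12)
        cov = rng.standard_normal((12, 1))
        res = omnibus_multivariate(Y, x, cov)
        X = np.column_stack([np.ones(12), x, cov])
        assert res.omnibus_stat == pytest.approx(_pillai_sscp_oracle(Y, X, 1), abs=1e-8)

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        Y = rng.standard_normal((40, 3))
        x = rng.standard_normal(40)
        cov = rng.standard_normal((40, 2))
        res = omnibus_multivariate(Y, x, cov)
        df = pd.DataFrame(
            np.column_stack([Y, x, cov]), columns=["y1", "y2", "y3", "x", "c1", "c2"]
        )
        mv = MANOVA.from_formula("y1 + y2 + y3 ~ x + c1 + c2", data=df)
        tbl = mv.mv_test().results["x"]["stat"]
        assert res.omnibus_stat == pytest.approx(tbl.loc["Pillai's trace", "Value"], abs=1e-8)
        assert res.omnibus_F == pytest.approx(tbl.loc["Pillai's trace", "F Value"], rel=1e-6)
        assert res.omnibus_p == pytest.approx(tbl.loc["Pillai's trace", "Pr > F"], abs=1e-8)

    def test_single_outcome_equals_univariate_partial_F(self, rng):
        import statsmodels.api as sm

        y = rng.standard_normal(30)
        x = rng.standard_normal(30)
        cov = rng.standard_normal((30, 2))
        res = omnibus_multivariate(y[:, None], x, cov)
        X = sm.add_constant(np.column_stack([x, cov]))
        fit = sm.OLS(y, X).fit()
        t = fit.tvalues[1]
        assert res.omnibus_F == pytest.approx(t**2, abs=1e-8)
        assert res.omnibus_p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_orthogonal_predictor_null(self, rng):
        Y = rng.standard_normal((20, 2))
        Yc = Y - Y.mean(0)
        # build a predictor exactly orthogonal to both outcome columns
        x = rng.standard_normal(20)
        x -= x.mean()
        x -= Yc @ np.linalg.lstsq(Yc, x, rcond=None)[0]
        res = omnibus_multivariate(Y, x)
        assert res.omnibus_stat == pytest.approx(0.0, abs=1e-12)
        assert res.omnibus_p == pytest.approx(1.0, abs=1e-9)

    def test_wilks_agrees_for_single_df(self, rng):
        Y = rng.standard_normal((25, 3))
        x = rng.standard_normal(25)
        pil = omnibus_multivariate(Y, x, statistic="pillai")
        wil = omnibus_multivariate(Y, x, statistic="wilks")
        assert pil.omnibus_p == pytest.approx(wil.omnibus_p, abs=1e-8)

    def test_listwise_deletion_recorded(self, rng):
        Y = rng.standard_normal((30, 2))
        x = rng.standard_normal(30)
        x[5] = np.nan
        res = omnibus_multivariate(Y, x)
        assert res.n_used == 29

    def test_type1_error_calibrated(self, rng):
        rej = 0
        reps = 500
        for _ in range(reps):
            Y = rng.standard_normal((150, 3))
            x = rng.standard_normal(150)
            cov = rng.standard_normal((150, 4))
            rej += omnibus_multivariate(Y, x, cov).omnibus_p < 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestFollowup:
    def test_bonferroni_arithmetic(self, rng):
        Y = rng.standard_normal((40, 3))
        x = rng.standard_normal(40)
        effects = followup_univariate(Y, x, n_tests=3)
        for e in effects:
            assert e.p_adjusted == pytest.approx(min(1.0, e.p_raw * 3))

    def test_duplicate_covariate_rejected(self, rng):
        Y = rng.standard_normal((20, 2))
        x = rng.standard_normal(20)
        cov = np.column_stack([x, x])
        with pytest.raises(ValueError, match="rank-deficient"):
            followup_univariate(Y, x, cov)

    def test_beta_coverage(self):
        # planted coefficient recovered within 2 SE in >= 93% of replicates
        # (true 2-SE coverage ~94.5%)
        rng = np.random.default_rng(2024)
        b = 0.4
        inside = 0
        reps = 300
        for _ in range(reps):
            x = rng.standard_normal(60)
            cov = rng.standard_normal((60, 2))
            y = b * x + cov @ [0.2, -0.1] + rng.standard_normal(60)
            e = followup_univariate(y[:, None], x, cov)[0]
            inside += abs(e.beta - b) <= 2 * e.se
        assert inside / reps >= 0.93


class TestFullAdditiveModel:
    def test_orthogonal_predictors_keep_single_model_betas(self, rng):
        n = 60
        s = rng.standard_normal(n)
        g = rng.standard_normal(n)
        g -= g.mean() + (s - s.mean()) * np.dot(g - g.mean(), s - s.mean()) / np.dot(
            s - s.mean(), s - s.mean()
        )
        s -= s.mean()
        Y = rng.standard_normal((n, 2)) + np.outer(s, [0.5, 0.0]) + np.outer(g, [0.0, -0.4])
        res_s, res_g = full_additive_model(Y, s, g)
        single_s = followup_univariate(Y, s)
        single_g = followup_univariate(Y, g)
        for joint, single in zip(res_s.per_component, single_s):
            assert joint.beta == pytest.approx(single.beta, abs=1e-6)
        for joint, single in zip(res_g.per_component, single_g):
            assert joint.beta == pytest.approx(single.beta, abs=1e-6)

    def test_collinear_predictors_rejected(self, rng):
        Y = rng.standard_normal((30, 2))
        x = rng.standard_normal(30)
        with pytest.raises(ValueError, match="rank-deficient"):
            full_additive_model(Y, x, 2.0 * x)

    def test_planted_pattern_recovered(self, rng):
        # SCN drives outcome 2 only, parenting drives outcome 1 only
        hits = 0
        reps = 60
        for _ in range(reps):
            n = 150
            s = rng.standard_normal(n)
            g = rng.standard_normal(n)
            Y = np.column_stack(
                [
                    -0.4 * g + rng.standard_normal(n),
                    0.4 * s + rng.standard_normal(n),
                    rng.standard_normal(n),
                ]
            )
            res_s, res_g = full_additive_model(Y, s, g)
            ok = (
                res_s.per_component[1].significant
                and res_g.per_component[0].significant
                and not res_s.per_component[0].significant
                and not res_s.per_component[2].significant
                and not res_g.per_component[1].significant
                and not res_g.per_component[2].significant
            )
            hits += ok
        assert hits / reps >= 0.60  # joint pattern; individual power ~0.99, nulls ~0.95 each


class TestInteractionLRT:
    def test_constant_predictor_rejected(self, rng):
        y = rng.standard_normal(20)
        with pytest.raises(ValueError, match="constant predictor"):
            interaction_lrt(y, np.ones(20), rng.standard_normal(20))

    def test_hand_rss_oracle(self, rng):
        n = 10
        y = rng.standard_normal(n)
        s = rng.standard_normal(n)
        g = rng.standard_normal(n)
        F, (d1, d2), p = interaction_lrt(y, s, g)
        sc, gc = s - s.mean(), g - g.mean()
        Xr = np.column_stack([np.ones(n), sc, gc])
        Xf = np.column_stack([Xr, sc * gc])
        rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        F_exp = ((rss(Xr) - rss(Xf)) / 1) / (rss(Xf) / (n - 4))
        assert F == pytest.approx(F_exp, abs=1e-10)
        assert (d1, d2) == (1, n - 4)

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(500):
            n = 40
            s = rng.standard_normal(n)
            g = rng.standard_normal(n)
            y = 0.3 * s - 0.2 * g + rng.standard_normal(n)  # no interaction
            ps.append(interaction_lrt(y, s, g)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def _bundle(rng, n=80, degenerate_extras=True):
    idx = pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id")
    pcs = pd.DataFrame(rng.standard_normal((n, 3)), index=idx, columns=["PC1", "PC2", "PC3"])
    # bounded draws for screened variables so no incidental 3-SD outliers arise
    vols = pd.DataFrame(rng.uniform(-1, 1, (n, 2)) * 0.1, index=idx, columns=["scn_1", "scn_2"])
    cov = pd.DataFrame(
        {
            "GA_weeks": rng.uniform(24, 32, n),
            "PMA_weeks": rng.uniform(38, 45, n),
            "sex": rng.integers(0, 2, n),
            "IMD": rng.uniform(0, 50, n),
            "parenting": rng.uniform(12, 23, n),
            "twin_group": [""] * n,
            "lesion_grade": np.zeros(n, dtype=int) if degenerate_extras else rng.integers(0, 2, n),
            "maternal_age": np.full(n, 33.0) if degenerate_extras else rng.normal(33, 5, n),
            "maternal_educ": np.zeros(n) if degenerate_extras else rng.integers(0, 3, n),
        },
        index=idx,
    )
    if degenerate_extras:
        cov["maternal_educ"] = cov["IMD"]
    battery = pd.DataFrame(rng.uniform(-2, 2, (n, 5)), index=idx)
    return AnalysisBundle(pcs=pcs, scn_volumes=vols, covariates=cov, battery=battery, focal_scn="scn_1")


class TestSensitivitySuite:
    def test_noop_variants_reproduce_primary(self, rng):
        # no twins, no outliers, constant lesion grade, maternal columns that
        # duplicate the primary design -> every variant is an exact no-op
        bundle = _bundle(rng)
        with pytest.warns(UserWarning, match="constant covariates"):
            res = sensitivity_suite(bundle, seed=0)
        prim = res["primary"]
        for variant in ("twins", "outliers", "lesions", "maternal"):
            for model in ("scn", "parenting"):
                a, b = prim[model], res[variant][model]
                assert b.omnibus_stat == pytest.approx(a.omnibus_stat, abs=1e-12)
                assert b.omnibus_p == pytest.approx(a.omnibus_p, abs=1e-12)
                assert b.n_used == a.n_used
                for ea, eb in zip(a.per_component, b.per_component):
                    assert eb.beta == pytest.approx(ea.beta, abs=1e-12)

    def test_outlier_excluded(self, rng):
        bundle = _bundle(rng)
        cov = bundle.covariates.copy()
        mu, sd = cov["parenting"].mean(), cov["parenting"].std(ddof=1)
        cov.loc[cov.index[0], "parenting"] = mu + 4 * sd
        bundle = AnalysisBundle(
            pcs=bundle.pcs, scn_volumes=bundle.scn_volumes, covariates=cov,
            battery=bundle.battery, focal_scn="scn_1",
        )
        res = sensitivity_suite(bundle, which={"outliers"}, seed=0)
        assert res["outliers"]["scn"].n_used == res["primary"]["scn"].n_used - 1

    def test_twin_removal_keeps_one_per_group(self, rng):
        bundle = _bundle(rng)
        cov = bundle.covariates.copy()
        cov.iloc[0, cov.columns.get_loc("twin_group")] = "T1"
        cov.iloc[1, cov.columns.get_loc("twin_group")] = "T1"
        bundle = AnalysisBundle(
            pcs=bundle.pcs, scn_volumes=bundle.scn_volumes, covariates=cov,
            battery=bundle.battery, focal_scn="scn_1",
        )
        res = sensitivity_suite(bundle, which={"twins"}, seed=0)
        assert res["twins"]["scn"].n_used == res["primary"]["scn"].n_used - 1

    def test_missing_columns_rejected(self, rng):
        bundle = _bundle(rng)
        cov = bundle.covariates.drop(columns=["twin_group"])
        bundle = AnalysisBundle(
            pcs=bundle.pcs, scn_volumes=bundle.scn_volumes, covariates=cov,
            battery=bundle.battery,
        )
        with pytest.raises(ValueError, match="twin_group"):
            sensitivity_suite(bundle, which={"twins"}, seed=0)

    def test_robust_effect_sign_preserved(self, rng):
        preserved = 0
        reps = 50
        for _ in range(reps):
            bundle = _bundle(rng, n=120, degenerate_extras=False)
            pcs = bundle.pcs.copy()
            zs = stats.zscore(bundle.scn_volumes["scn_1"])
            zg = stats.zscore(bundle.covariates["parenting"])
            pcs["PC2"] = 0.5 * zs + rng.standard_normal(120)
            pcs["PC1"] = -0.5 * zg + rng.standard_normal(120)
            bundle = AnalysisBundle(
                pcs=pcs, scn_volumes=bundle.scn_volumes, covariates=bundle.covariates,
                battery=bundle.battery, focal_scn="scn_1",
            )
            res = sensitivity_suite(bundle, seed=1)
            signs_ok = all(
                res[v]["scn"].per_component[1].beta > 0
                and res[v]["parenting"].per_component[0].beta < 0
                for v in res
            )
            preserved += signs_ok
        assert preserved / reps >= 0.95
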