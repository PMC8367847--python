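"""Brain- and environment-outcome association models.

The framework mirrors a two-stage multivariate regression scheme: for each
predictor of interest (a network volume, or the cognitively stimulating
parenting score) an omnibus multivariate linear model tests its effect on all
retained outcome components simultaneously, controlling for gestational age,
postmenstrual age at scan, sex and socioeconomic deprivation; significant
omnibus effects are followed up with per-component univariate regressions
under Bonferroni correction.  A combined additive model enters both
predictors at once, and nested-model F tests probe whether a
parenting x network-volume interaction improves fit.  A sensitivity suite
reruns the primary models under twin removal, outlier exclusion, lesion
adjustment, and alternative socioeconomic covariates.

The omnibus statistic is Pillai's trace with its standard F approximation
(Wilks' lambda available via the `statistic` argument); with a single
outcome both reduce exactly to the univariate partial F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ComponentEffect:
    component: str
    beta: float
    se: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class AssociationResult:
    predictor: str
    statistic_name: str
    omnibus_stat: float
    omnibus_F: float
    omnibus_df: tuple[float, float]
    omnibus_p: float
    n_used: int
    per_component: list[ComponentEffect] = field(default_factory=list)

    def component_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "predictor": self.predictor,
                    "component": e.component,
                    "beta": e.beta,
                    "se": e.se,
                    "p_raw": e.p_raw,
                    "p_adjusted": e.p_adjusted,
                    "significant": e.significant,
                }
                for e in self.per_component
            ]
        )


def bonferroni_threshold(alpha: float, n_models: int) -> tuple[float, str]:
    """Corrected significance threshold alpha / n_models.

    Returns the full-precision value together with its 3-decimal display form
    in APA style (leading zero dropped), e.g. (0.003333…, ".003").
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    value = alpha / n_models
    display = f"{value:.3f}"
    if display.startswith("0."):
        display = display[1:]
    return value, display


def _as_2d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _complete_cases(*arrays) -> np.ndarray:
    ok = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        if a is None:
            continue
        ok &= np.all(np.isfinite(_as_2d(a)), axis=1)
    return ok


def _design(columns: list[np.ndarray]) -> np.ndarray:
    X = np.column_stack([np.ones(columns[0].shape[0])] + columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    return X


def _multivariate_test(
    Y: np.ndarray,
    X: np.ndarray,
    term_idx: int,
    statistic: str = "pillai",
) -> tuple[float, float, tuple[float, float], float]:
    """Test one design column in the multivariate linear model Y = X B + E.

    Builds the hypothesis and error sums-of-squares-and-cross-products (SSCP)
    matrices for the single-df contrast selecting the term, then applies the
    conventional F approximation of the chosen statistic.
    """
    n, p = Y.shape
    r = X.shape[1]
    G = np.linalg.inv(X.T @ X)
    B = G @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    df_e = n - r
    if df_e <= p:
        raise ValueError("sample too small for the multivariate test")
    L = np.zeros((1, r))
    L[0, term_idx] = 1.0
    LB = L @ B
    M = np.linalg.inv(L @ G @ L.T)
    Hm = LB.T @ M @ LB
    q = 1  # hypothesis df
    s = min(p, q)
    if statistic == "pillai":
        V = float(np.trace(np.linalg.solve(E + Hm, Hm)))
        V = min(max(V, 0.0), float(s))
        m = (abs(p - q) - 1) / 2.0
        nn = (df_e - p - 1) / 2.0
        df1 = s * (2 * m + s + 1)
        df2 = s * (2 * nn + s + 1)
        denom = s - V
        F = (df2 / df1) * V / denom if denom > 0 else np.inf
        stat = V
    elif statistic == "wilks":
        sign_e, logdet_e = np.linalg.slogdet(E)
        sign_t, logdet_t = np.linalg.slogdet(E + Hm)
        if sign_e <= 0 or sign_t <= 0:
            raise ValueError("singular error SSCP matrix")
        lam = float(np.exp(logdet_e - logdet_t))
        # Rao's F approximation; exact for q = 1
        t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
        w = df_e + q - (p + q + 1) / 2.0
        df1 = p * q
        df2 = w * t - (p * q - 2) / 2.0
        lam_t = lam ** (1.0 / t)
        F = (1 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else np.inf
        stat = lam
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    pval = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return stat, float(F), (float(df1), float(df2)), pval


def omnibus_multivariate(
    Y,
    predictor,
    covariates=None,
    predictor_name: str = "predictor",
    statistic: str = "pillai",
) -> AssociationResult:
    """Omnibus multivariate test of one predictor on all outcome components.

    Listwise deletion on Y, predictor and covariates; n_used records the
    analyzed sample.  The per-component follow-ups are left unfilled.
    """
    Yv = _as_2d(Y.to_numpy() if isinstance(Y, pd.DataFrame) else Y)
    pv = _as_2d(predictor.to_numpy() if isinstance(predictor, (pd.Series, pd.DataFrame)) else predictor)
    cv = None
    if covariates is not None:
        cv = _as_2d(covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else covariates)
    ok = _complete_cases(Yv, pv, cv)
    Yv, pv = Yv[ok], pv[ok]
    cv = cv[ok] if cv is not None else None
    n, C = Yv.shape
    q_cov = 0 if cv is None else cv.shape[1]
    if n <= C + q_cov + 2:
        raise ValueError("N too small for the requested model")
    X = _design([pv] + ([cv] if cv is not None else []))
    stat, F, df, pval = _multivariate_test(Yv, X, term_idx=1, statistic=statistic)
    return AssociationResult(
        predictor=predictor_name,
        statistic_name=statistic,
        omnibus_stat=stat,
        omnibus_F=F,
        omnibus_df=df,
        omnibus_p=pval,
        n_used=int(n),
    )


def followup_univariate(
    Y,
    predictor,
    covariates=None,
    n_tests: int | None = None,
    alpha: float = 0.05,
    term_idx: int = 1,
    extra_predictors=None,
) -> list[ComponentEffect]:
    """Per-component OLS follow-ups with Bonferroni-adjusted p-values.

    Each outcome component is regressed on the predictor (plus covariates and
    any extra predictors); p_adjusted = min(1, p * n_tests) with n_tests
    defaulting to the number of components.
    """
    import statsmodels.api as sm

    Ydf = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(_as_2d(Y))
    Yv = Ydf.to_numpy(float)
    pv = _as_2d(predictor.to_numpy() if isinstance(predictor, (pd.Series, pd.DataFrame)) else predictor)
    cv = None
    if covariates is not None:
        cv = _as_2d(covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else covariates)
    ev = None
    if extra_predictors is not None:
        ev = _as_2d(
            extra_predictors.to_numpy()
            if isinstance(extra_predictors, (pd.Series, pd.DataFrame))
            else extra_predictors
        )
    ok = _complete_cases(Yv, pv, cv, ev)
    Yv, pv = Yv[ok], pv[ok]
    cv = cv[ok] if cv is not None else None
    ev = ev[ok] if ev is not None else None
    cols = [pv] + ([ev] if ev is not None else []) + ([cv] if cv is not None else [])
    X = _design(cols)
    if n_tests is None:
        n_tests = Yv.shape[1]
    out = []
    for c in range(Yv.shape[1]):
        fit = sm.OLS(Yv[:, c], X).fit()
        beta = float(fit.params[term_idx])
        se = float(fit.bse[term_idx])
        p_raw = float(fit.pvalues[term_idx])
        p_adj = min(1.0, p_raw * n_tests)
        out.append(
            ComponentEffect(
                component=str(Ydf.columns[c]),
                beta=beta,
                se=se,
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    return out


def run_predictor_analysis(
    Y,
    predictor,
    covariates=None,
    predictor_name: str = "predictor",
    alpha: float = 0.05,
    statistic: str = "pillai",
) -> AssociationResult:
    """Omnibus test plus per-component follow-ups for one predictor."""
    res = omnibus_multivariate(
        Y, predictor, covariates, predictor_name=predictor_name, statistic=statistic
    )
    res.per_component = followup_univariate(Y, predictor, covariates, alpha=alpha)
    return res


def full_additive_model(
    Y,
    scn_volume,
    parenting,
    covariates=None,
    alpha: float = 0.05,
    statistic: str = "pillai",
) -> tuple[AssociationResult, AssociationResult]:
    """Combined additive model with both predictors, each adjusted for the other.

    Returns (scn_result, parenting_result) from the single joint multivariate
    model; follow-ups likewise contain both predictors.
    """
    Yv = _as_2d(Y.to_numpy() if isinstance(Y, pd.DataFrame) else Y)
    sv = _as_2d(scn_volume.to_numpy() if isinstance(scn_volume, (pd.Series, pd.DataFrame)) else scn_volume)
    gv = _as_2d(parenting.to_numpy() if isinstance(parenting, (pd.Series, pd.DataFrame)) else parenting)
    cv = None
    if covariates is not None:
        cv = _as_2d(covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else covariates)
    ok = _complete_cases(Yv, sv, gv, cv)
    Yv, sv, gv = Yv[ok], sv[ok], gv[ok]
    cv = cv[ok] if cv is not None else None
    X = _design([sv, gv] + ([cv] if cv is not None else []))
    Ydf = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(Yv)

    results = []
    for name, idx, pred, other in (
        ("scn_volume", 1, sv, gv),
        ("parenting", 2, gv, sv),
    ):
        stat, F, df, pval = _multivariate_test(Yv, X, term_idx=idx, statistic=statistic)
        res = AssociationResult(
            predictor=name,
            statistic_name=statistic,
            omnibus_stat=stat,
            omnibus_F=F,
            omnibus_df=df,
            omnibus_p=pval,
            n_used=int(Yv.shape[0]),
        )
        res.per_component = followup_univariate(
            pd.DataFrame(Yv, columns=Ydf.columns),
            pred,
            cv,
            alpha=alpha,
            extra_predictors=other,
        )
        results.append(res)
    return results[0], results[1]


def interaction_lrt(
    y_component,
    scn_volume,
    parenting,
    covariates=None,
) -> tuple[float, tuple[int, int], float]:
    """Nested-model F test for a parenting x network-volume interaction.

    The reduced model contains both (mean-centered) predictors and the
    covariates; the full model adds their product.  The extra-sum-of-squares
    F statistic F = ((RSS_r - RSS_f)/Δdf) / (RSS_f/df_f) is exact under
    Gaussian errors, so the nested-model comparison is a likelihood-ratio
    test in F form.
    """
    y = np.asarray(
        y_component.to_numpy() if isinstance(y_component, pd.Series) else y_component, float
    ).ravel()
    sv = np.asarray(
        scn_volume.to_numpy() if isinstance(scn_volume, pd.Series) else scn_volume, float
    ).ravel()
    gv = np.asarray(
        parenting.to_numpy() if isinstance(parenting, pd.Series) else parenting, float
    ).ravel()
    cv = None
    if covariates is not None:
        cv = _as_2d(covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else covariates)
    ok = _complete_cases(y, sv, gv, cv)
    y, sv, gv = y[ok], sv[ok], gv[ok]
    cv = cv[ok] if cv is not None else None
    if np.ptp(sv) == 0 or np.ptp(gv) == 0:
        raise ValueError("constant predictor")
    svc, gvc = sv - sv.mean(), gv - gv.mean()
    inter = (svc * gvc)[:, None]
    Xr = _design([svc[:, None], gvc[:, None]] + ([cv] if cv is not None else []))
    Xf = np.column_stack([Xr, inter])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("rank-deficient design (interaction collinear)")

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_r, rss_f = rss(Xr), rss(Xf)
    d_df = Xf.shape[1] - Xr.shape[1]
    df_f = len(y) - Xf.shape[1]
    F = ((rss_r - rss_f) / d_df) / (rss_f / df_f)
    p = float(stats.f.sf(F, d_df, df_f))
    return float(F), (d_df, df_f), p


@dataclass
class AnalysisBundle:
    """Joined analysis inputs keyed by subject, for the primary and sensitivity models.

    pcs: retained component scores (subjects x C); scn_volumes: network
    volume table (subjects x k); covariates: the covariate table (must carry
    GA_weeks, PMA_weeks, sex, IMD, parenting; optionally lesion_grade,
    maternal_educ, maternal_age, twin_group); battery: the raw behavioral
    score table used for the outlier screen; focal_scn: column of
    scn_volumes carrying the network of interest.
    """

    pcs: pd.DataFrame
    scn_volumes: pd.DataFrame
    covariates: pd.DataFrame
    battery: pd.DataFrame | None = None
    focal_scn: str | None = None

    def aligned(self) -> "AnalysisBundle":
        idx = self.pcs.index.intersection(self.scn_volumes.index).intersection(
            self.covariates.index
        )
        return AnalysisBundle(
            pcs=self.pcs.loc[idx],
            scn_volumes=self.scn_volumes.loc[idx],
            covariates=self.covariates.loc[idx],
            battery=self.battery.loc[self.battery.index.intersection(idx)]
            if self.battery is not None
            else None,
            focal_scn=self.focal_scn,
        )


SCN_COVARIATES = ["GA_weeks", "PMA_weeks", "sex", "IMD"]
PARENTING_COVARIATES = ["GA_weeks", "sex", "IMD"]


def _primary_models(
    bundle: AnalysisBundle,
    scn_covs: list[str],
    parenting_covs: list[str],
    alpha: float,
    statistic: str,
) -> dict[str, AssociationResult]:
    b = bundle.aligned()
    focal = b.focal_scn or b.scn_volumes.columns[0]

    def usable(names: list[str]) -> list[str]:
        # a covariate with no variance in the analysis sample (e.g. lesion
        # grade when nobody has lesions) carries no information and would
        # make the design singular; drop it
        kept = [c for c in names if np.ptp(b.covariates[c].to_numpy(float)) > 0]
        dropped = set(names) - set(kept)
        if dropped:
            warnings.warn(f"dropping constant covariates {sorted(dropped)}", stacklevel=3)
        return kept

    scn_covs = usable(scn_covs)
    parenting_covs = usable(parenting_covs)
    out = {
        "scn": run_predictor_analysis(
            b.pcs,
            b.scn_volumes[focal],
            b.covariates[scn_covs],
            predictor_name=focal,
            alpha=alpha,
            statistic=statistic,
        ),
        "parenting": run_predictor_analysis(
            b.pcs,
            b.covariates["parenting"],
            b.covariates[parenting_covs],
            predictor_name="parenting",
            alpha=alpha,
            statistic=statistic,
        ),
    }
    return out


def sensitivity_suite(
    bundle: AnalysisBundle,
    which: set[str] = frozenset({"twins", "outliers", "lesions", "maternal"}),
    seed: int = 0,
    alpha: float = 0.05,
    statistic: str = "pillai",
) -> dict[str, dict[str, AssociationResult]]:
    """Rerun the primary SCN and parenting models under robustness variants.

    twins: keep one randomly chosen member per twin/triplet group (seeded);
    outliers: drop subjects beyond mean +/- 3 SD on any behavioral measure,
    network volume, or the parenting score (computed once on the analysis
    sample); lesions: add lesion grade (none=0, minor=1) as a covariate;
    maternal: replace the deprivation index with maternal education and add
    maternal age.
    """
    bundle = bundle.aligned()
    results: dict[str, dict[str, AssociationResult]] = {
        "primary": _primary_models(bundle, SCN_COVARIATES, PARENTING_COVARIATES, alpha, statistic)
    }
    cov = bundle.covariates

    if "twins" in which:
        if "twin_group" not in cov.columns:
            raise ValueError("twins variant requires a twin_group column")
        rng = np.random.default_rng(seed)
        keep = []
        groups = cov["twin_group"]
        singles = groups.isna() | (groups == "")
        keep.extend(cov.index[singles])
        for _, members in cov.index[~singles].to_series().groupby(groups[~singles]):
            keep.append(rng.choice(members.to_numpy()))
        sub = bundle_subset(bundle, pd.Index(keep))
        results["twins"] = _primary_models(sub, SCN_COVARIATES, PARENTING_COVARIATES, alpha, statistic)

    if "outliers" in which:
        screen = [bundle.scn_volumes, cov[["parenting"]]]
        if bundle.battery is not None:
            screen.insert(0, bundle.battery)
        ok = pd.Series(True, index=bundle.pcs.index)
        for tbl in screen:
            tbl = tbl.reindex(bundle.pcs.index)
            mu, sd = tbl.mean(), tbl.std(ddof=1)
            inside = ((tbl - mu).abs() <= 3 * sd) | tbl.isna()
            ok &= inside.all(axis=1)
        sub = bundle_subset(bundle, bundle.pcs.index[ok])
        results["outliers"] = _primary_models(sub, SCN_COVARIATES, PARENTING_COVARIATES, alpha, statistic)

    if "lesions" in which:
        if "lesion_grade" not in cov.columns:
            raise ValueError("lesions variant requires a lesion_grade column")
        results["lesions"] = _primary_models(
            bundle,
            SCN_COVARIATES + ["lesion_grade"],
            PARENTING_COVARIATES + ["lesion_grade"],
            alpha,
            statistic,
        )

    if "maternal" in which:
        missing = {"maternal_educ", "maternal_age"} - set(cov.columns)
        if missing:
            raise ValueError(f"maternal variant requires columns {sorted(missing)}")
        scn_covs = ["GA_weeks", "PMA_weeks", "sex", "maternal_educ", "maternal_age"]
        par_covs = ["GA_weeks", "sex", "maternal_educ", "maternal_age"]
        results["maternal"] = _primary_models(bundle, scn_covs, par_covs, alpha, statistic)

    return results


def bundle_subset(bundle: AnalysisBundle, idx: pd.Index) -> AnalysisBundle:
    return AnalysisBundle(
        pcs=bundle.pcs.loc[bundle.pcs.index.isin(idx)],
        scn_volumes=bundle.scn_volumes.loc[bundle.scn_volumes.index.isin(idx)],
        covariates=bundle.covariates.loc[bundle.covariates.index.isin(idx)],
        battery=bundle.battery.loc[bundle.battery.index.isin(idx)]
        if bundle.battery is not None
        else None,
        focal_scn=bundle.focal_scn,
    )
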