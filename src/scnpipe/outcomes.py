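"""Behavioral outcome components: preprocessing, PCA, and retention.

A battery of cognitive and behavioral measures (parent questionnaires plus
age-normed intelligence subscales) is reduced to orthogonal principal
components.  Measures that are not already age-normed are residualized on age
at assessment; all measures are then standardized, so the PCA operates on the
correlation scale.  Components are retained when they are both significant
under a column-permutation (parallel-analysis style) test and reliable under
repeated split-half analysis, with retention restricted to a prefix of the
component order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class OutcomeBattery:
    """Subjects x measures score table with per-measure age-norming flags.

    age_normed marks measures already standardized against age norms (the
    intelligence subscales); these skip the age residualization.  age_years
    is the (GA-corrected) age at the follow-up assessment.
    """

    scores: pd.DataFrame
    age_normed: pd.Series
    age_years: pd.Series

    def __post_init__(self) -> None:
        self.age_normed = self.age_normed.reindex(self.scores.columns)
        if self.age_normed.isna().any():
            raise ValueError("age_normed flag missing for some measures")
        self.age_years = self.age_years.reindex(self.scores.index)

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_measures(self) -> int:
        return self.scores.shape[1]


@dataclass
class OutcomeComponents:
    """PCA solution plus the retention diagnostics that get filled in later."""

    loadings: pd.DataFrame  # measures x components
    scores: pd.DataFrame  # subjects x components
    var_explained: np.ndarray
    perm_p: np.ndarray | None = None
    splithalf_r: np.ndarray | None = None
    retained: np.ndarray | None = None
    eigenvalues: np.ndarray = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_retained(self) -> int:
        if self.retained is None:
            raise ValueError("retention not yet decided")
        return int(np.sum(self.retained))

    def retained_scores(self) -> pd.DataFrame:
        return self.scores.loc[:, np.asarray(self.retained, bool)]


def preprocess_battery(
    battery: OutcomeBattery,
    max_missing_fraction: float = 0.20,
) -> pd.DataFrame:
    """Residualize non-age-normed measures on age, then standardize everything.

    Subjects missing more than max_missing_fraction of measures are dropped;
    remaining gaps are median-imputed before residualization.  Each retained
    column ends with mean 0 and unit (sample) variance.
    """
    scores = battery.scores.astype(float)
    if scores.shape[0] < 10:
        raise ValueError("need at least 10 subjects")
    age = battery.age_years.astype(float)
    keep = scores.isna().mean(axis=1) <= max_missing_fraction
    scores = scores.loc[keep]
    age = age.loc[keep]
    if age.isna().any():
        raise ValueError("missing age for some subjects")
    scores = scores.fillna(scores.median())

    a = age.to_numpy()
    X_age = np.column_stack([np.ones_like(a), a])
    out = {}
    for name in scores.columns:
        y = scores[name].to_numpy()
        if np.ptp(y) == 0:
            raise ValueError(f"constant column {name!r}")
        if not battery.age_normed[name]:
            beta, *_ = np.linalg.lstsq(X_age, y, rcond=None)
            y = y - X_age @ beta
        sd = np.std(y, ddof=1)
        if sd < 1e-12:
            raise ValueError(f"constant column after residualization: {name!r}")
        out[name] = (y - y.mean()) / sd
    return pd.DataFrame(out, index=scores.index)


def _pca_eig(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the sample correlation matrix of standardized Z."""
    n = Z.shape[0]
    C = (Z.T @ Z) / (n - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return np.maximum(vals[order], 0.0), vecs[:, order]


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive per component."""
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs


def fit_pca(Z: pd.DataFrame | np.ndarray) -> OutcomeComponents:
    """PCA of a standardized battery; components ordered by variance explained."""
    if isinstance(Z, pd.DataFrame):
        names, index, Zv = list(Z.columns), Z.index, Z.to_numpy(float)
    else:
        Zv = np.asarray(Z, float)
        names = [f"m{i + 1}" for i in range(Zv.shape[1])]
        index = pd.RangeIndex(Zv.shape[0])
    if Zv.shape[1] < 2:
        raise ValueError("need at least 2 measures")
    vals, vecs = _pca_eig(Zv)
    loadings = _fix_signs(vecs)
    scores = Zv @ loadings
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return OutcomeComponents(
        loadings=pd.DataFrame(loadings, index=names, columns=comp_names),
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
        var_explained=vals / vals.sum(),
        eigenvalues=vals,
    )


def permutation_significance(
    Z: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Per-component permutation p-values for variance explained.

    The null permutes each measure independently across subjects (destroying
    between-measure covariance while preserving marginals, as in parallel
    analysis); perm_p[c] uses the add-one estimator
    (1 + #{null >= observed}) / (1 + n_perm), so p is always in (0, 1].
    """
    Zv = Z.to_numpy(float) if isinstance(Z, pd.DataFrame) else np.asarray(Z, float)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if 1.0 / (n_perm + 1) > alpha:
        raise ValueError("n_perm too small for requested alpha resolution")
    n = Zv.shape[0]
    obs_vals, _ = _pca_eig(Zv)
    obs = obs_vals / obs_vals.sum()
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        Zp = rng.permuted(Zv, axis=0)
        null_vals = np.linalg.eigvalsh((Zp.T @ Zp) / (n - 1))[::-1]
        null = null_vals / null_vals.sum()
        exceed += null >= obs
    return (1.0 + exceed) / (1.0 + n_perm)


def _match_loadings(La: np.ndarray, Lb: np.ndarray, C_test: int) -> np.ndarray:
    """Match components across halves by maximal |loading correlation|."""
    La, Lb = La[:, :C_test], Lb[:, :C_test]
    Za = (La - La.mean(0)) / np.maximum(La.std(0), 1e-12)
    Zb = (Lb - Lb.mean(0)) / np.maximum(Lb.std(0), 1e-12)
    corr = np.abs(Za.T @ Zb) / La.shape[0]
    rows, cols = linear_sum_assignment(-corr)
    out = np.empty(C_test)
    out[rows] = corr[rows, cols]
    return out


def splithalf_reliability(
    Z: pd.DataFrame | np.ndarray,
    C_test: int,
    n_splits: int = 100,
    seed: int = 0,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Mean absolute loading correlation of matched components across random halves.

    Per split, subjects are divided at random into halves and the PCA is
    refitted in each; component c's reliability is the mean (over splits) of
    its matched absolute loading correlation (exact one-to-one assignment,
    absolute values absorb the sign indeterminacy of principal axes).
    `splits` overrides the random halves with explicit (indices_a, indices_b)
    pairs, e.g. for deterministic checks.
    """
    Zv = Z.to_numpy(float) if isinstance(Z, pd.DataFrame) else np.asarray(Z, float)
    n = Zv.shape[0]
    if n < 20:
        raise ValueError("need at least 20 subjects")
    if splits is None:
        if n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        half = n // 2
        if half < 10:
            raise ValueError("half-sample smaller than 10")
        rng = np.random.default_rng(seed)
        splits = []
        for _ in range(n_splits):
            perm = rng.permutation(n)
            splits.append((perm[:half], perm[half : 2 * half]))
    acc = np.zeros(C_test)
    for idx_a, idx_b in splits:
        _, va = _pca_eig(Zv[np.asarray(idx_a)])
        _, vb = _pca_eig(Zv[np.asarray(idx_b)])
        acc += _match_loadings(va, vb, C_test)
    return acc / len(splits)


def retain_components(
    components: OutcomeComponents,
    alpha: float = 0.05,
    r_min: float = 0.70,
) -> OutcomeComponents:
    """Retain the leading components that are both significant and reliable.

    retained[c] requires perm_p[c] < alpha AND splithalf_r[c] >= r_min, and
    the retained set is forced to be a prefix of the component order: once a
    component fails, no later component is retained (later components explain
    less variance, so a lone significant late component is not interpretable
    as a standalone outcome dimension).
    """
    if components.perm_p is None or components.splithalf_r is None:
        raise ValueError("perm_p and splithalf_r must be filled before retention")
    C = min(len(components.perm_p), len(components.splithalf_r))
    ok = (np.asarray(components.perm_p[:C]) < alpha) & (
        np.asarray(components.splithalf_r[:C]) >= r_min
    )
    retained = np.zeros(components.n_components, dtype=bool)
    for c in range(C):
        if not ok[c]:
            break
        retained[c] = True
    components.retained = retained
    return components


def analyze_battery(
    battery: OutcomeBattery,
    n_perm: int = 1000,
    n_splits: int = 100,
    C_test: int = 6,
    alpha: float = 0.05,
    r_min: float = 0.70,
    seed: int = 0,
) -> OutcomeComponents:
    """Full outcome chain: preprocess, PCA, permutation test, split-half, retain."""
    Z = preprocess_battery(battery)
    comps = fit_pca(Z)
    perm_p = permutation_significance(Z, n_perm=n_perm, alpha=alpha, seed=seed)
    C_test = min(C_test, comps.n_components)
    shr = splithalf_reliability(Z, C_test=C_test, n_splits=n_splits, seed=seed + 1)
    comps.perm_p = perm_p
    comps.splithalf_r = np.concatenate([shr, np.full(comps.n_components - C_test, np.nan)])
    return retain_components(comps, alpha=alpha, r_min=r_min)
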