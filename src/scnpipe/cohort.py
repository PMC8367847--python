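"""Synthetic very-preterm cohort generator for parameter-recovery validation.

Emulates the statistical structure the analysis chain assumes, without any
anatomical realism:

* smooth, minimally overlapping non-negative spatial networks mixed into
  per-subject log-Jacobian maps with lognormal subject loadings and Gaussian
  voxel noise;
* a 32-measure behavioral battery driven by three latent factors with the
  characteristic sign pattern (a "preterm phenotype" factor loading
  positively on symptom scales and negatively on intelligence subscales, a
  "cognitive" factor on the intelligence subscales, a "socioemotional"
  factor on temperament/empathy scales) plus age-related drift on measures
  that are not age-normed;
* covariates drawn to match the cohort's demographic table (gestational age
  median ~30.3 weeks in [23.57, 32.86], postmenstrual age at scan centered
  ~42.6 weeks, deprivation index N(20.02, 11.82) truncated at 0, parenting
  score N(17.68, 2.43), maternal education/age categories);
* planted effects: one designated network's expression partially drives the
  cognitive factor, and the parenting score negatively drives the preterm
  phenotype factor.

Every draw descends from a single seed via numpy SeedSequence spawning, so a
cohort is byte-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .nnmf import cosine_similarity_matrix
from .volumes import AtlasMask, VolumetricMap

GA_RANGE = (23.57, 32.86)
PMA_RANGE = (37.86, 44.86)
DEFAULT_GRID = (20, 24, 20)
DEFAULT_SPACING = 2.0

# per-instrument subscale battery (32 measures); age_normed marks the
# intelligence subscales, which are standardized against age norms upstream
MEASURES: list[tuple[str, str, bool]] = [
    # name, block, age_normed — block keys into the factor loading pattern
    ("SDQ_hyperactivity_inattention", "symptom", False),
    ("SDQ_emotional_symptoms", "symptom_weak", False),
    ("SDQ_conduct_problems", "symptom_weak", False),
    ("SDQ_peer_problems", "symptom_weak", False),
    ("SDQ_prosocial", "socioemotional", False),
    ("ADHD_inattention", "symptom", False),
    ("ADHD_hyperactivity", "symptom", False),
    ("SRS_social_awareness", "symptom", False),
    ("SRS_social_cognition", "symptom", False),
    ("SRS_social_communication", "symptom", False),
    ("SRS_social_motivation", "symptom", False),
    ("SRS_mannerisms", "symptom", False),
    ("BRIEF_inhibit", "symptom", False),
    ("BRIEF_shift", "symptom", False),
    ("BRIEF_working_memory", "symptom", False),
    ("BRIEF_plan_organize", "symptom", False),
    ("BRIEF_emotional_control", "symptom_weak", False),
    ("CBQ_negative_affect", "socioemotional", False),
    ("CBQ_surgency", "socioemotional", False),
    ("CBQ_effortful_control", "socioemotional", False),
    ("EmQue_emotion_contagion", "socioemotional", False),
    ("EmQue_attention_to_feelings", "socioemotional", False),
    ("EmQue_prosocial_actions", "socioemotional", False),
    ("WPPSI_verbal_comprehension", "cognitive", True),
    ("WPPSI_visuospatial", "cognitive", True),
    ("WPPSI_fluid_reasoning", "cognitive", True),
    ("WPPSI_working_memory", "cognitive", True),
    ("WPPSI_processing_speed", "cognitive", True),
    ("WPPSI_vocabulary", "cognitive", True),
    ("WPPSI_nonverbal", "cognitive_general", True),
    ("WPPSI_general_ability", "cognitive_general", True),
    ("WPPSI_cognitive_proficiency", "cognitive", True),
]

# factor loading pattern per block: (preterm phenotype, cognitive, socioemotional)
BLOCK_LOADINGS: dict[str, tuple[float, float, float]] = {
    "symptom": (0.80, 0.0, 0.0),
    "symptom_weak": (0.55, 0.15, 0.0),
    "socioemotional": (0.0, 0.0, 0.70),
    "cognitive": (0.0, 0.80, 0.0),
    "cognitive_general": (-0.30, 0.75, 0.0),
}


@dataclass
class GroundTruth:
    """Planted parameters a recovery analysis is checked against."""

    W_true: np.ndarray  # V x k_true (in-mask voxels, matrix scan order)
    H_true: np.ndarray  # k_true x N
    networks_grid: np.ndarray  # k_true x grid, full-field maps
    factor_scores: np.ndarray  # N x 3 (final, with planted effects)
    measure_loadings: np.ndarray  # M x 3
    designated_network: int
    cognitive_driver: np.ndarray  # N latent driver of the designated network
    true_volumes: pd.DataFrame  # N x k_true weighted mean log-Jacobians (noiseless)
    beta_scn_pc2: float
    beta_parenting_pc1: float
    noise_sds: dict[str, float] = field(default_factory=dict)
    seed: int = 0


@dataclass
class SyntheticCohort:
    maps: list[VolumetricMap]
    mask: AtlasMask
    battery: "object"  # OutcomeBattery (import cycle avoided)
    covariates: pd.DataFrame
    truth: GroundTruth


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_covariates(N: int, seed: int = 0, twin_fraction: float = 0.10) -> pd.DataFrame:
    """Draw a covariate table matching the cohort's demographic profile.

    GA at birth: scaled Beta (left-skewed) truncated to [23.57, 32.86] weeks
    with median ~30.3; PMA at scan: truncated normal centered 42.6 weeks in
    [37.86, 44.86] (always > GA); sex: Bernoulli(0.508) female; IMD:
    N(20.02, 11.82) truncated at 0; parenting: N(17.68, 2.43); maternal
    education: 4 ordinal categories with the cohort's frequencies; lesion
    grade: 0 = none, 1 = minor (major lesions are excluded upstream of any
    imaging analysis); a twin_fraction of subjects is paired into twin
    groups.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = GA_RANGE
    # Beta(3.2, 1.45) scaled to the GA range has median ~0.72 -> ~30.3 weeks
    ga = lo + (hi - lo) * rng.beta(3.2, 1.45, size=N)
    pma = _trunc_normal(rng, 42.57, 1.4, *PMA_RANGE, size=N)
    sex = (rng.random(N) < 0.508).astype(int)  # 1 = female
    imd = _trunc_normal(rng, 20.02, 11.82, 0.0, np.inf, size=N)
    parenting = rng.normal(17.68, 2.43, size=N)
    maternal_educ = rng.choice(4, size=N, p=[0.105, 0.164, 0.731, 0.0])
    # "still in full-time education" folded into the top category; keep 3 used levels
    maternal_age = rng.normal(32.84, 5.70, size=N)
    lesion_grade = (rng.random(N) < 0.568).astype(int)  # 0 none, 1 minor

    twin_group = np.array([""] * N, dtype=object)
    n_pairs = int(np.floor(twin_fraction * N / 2))
    if n_pairs > 0:
        paired = rng.choice(N, size=2 * n_pairs, replace=False)
        for g in range(n_pairs):
            twin_group[paired[2 * g]] = f"T{g + 1:03d}"
            twin_group[paired[2 * g + 1]] = f"T{g + 1:03d}"

    idx = [f"S{i + 1:04d}" for i in range(N)]
    return pd.DataFrame(
        {
            "GA_weeks": ga,
            "PMA_weeks": pma,
            "sex": sex,
            "IMD": imd,
            "parenting": parenting,
            "maternal_educ": maternal_educ,
            "maternal_age": maternal_age,
            "lesion_grade": lesion_grade,
            "twin_group": twin_group,
        },
        index=pd.Index(idx, name="subject_id"),
    )


def make_networks(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    k_true: int = 6,
    seed: int = 0,
    smooth_sigma: float = 1.2,
    min_support: int = 50,
    max_cosine: float = 0.2,
    floor: float = 0.20,
    shape_exponent: float = 0.05,
) -> np.ndarray:
    """Plant k_true smooth, non-overlapping networks on the grid.

    Each network is the smoothed indicator of an ellipsoidal blob placed in
    its own lattice cell (jittered), truncated at `floor` (relative to the
    peak) to keep supports disjoint, flattened by `shape_exponent` into a
    plateau with soft edges, and peak-normalized to 1.  The plateau shape keeps the
    exponentiation applied downstream nearly rank-preserving within each
    network's support, which is what makes factorization-based recovery of
    the planted maps well-posed.  Returns an array of shape
    (k_true, *grid_shape).  Raises if blobs cannot be placed with pairwise
    cosine < max_cosine.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in grid_shape)
    coords = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")

    # jittered-lattice placement: split the grid into the smallest lattice of
    # cells that can host k_true blobs, one blob per cell, so centers are
    # separated by construction for any seed
    splits = np.ones(3, dtype=int)
    while np.prod(splits) < k_true:
        ax = int(np.argmax(np.asarray(shape) / splits))
        splits[ax] += 1
    cell = np.asarray(shape) / splits
    if cell.min() < 6:
        raise ValueError("blobs cannot be placed disjointly on this grid")
    cells = np.array(
        [(i, j, l) for i in range(splits[0]) for j in range(splits[1]) for l in range(splits[2])]
    )
    chosen = cells[rng.choice(len(cells), size=k_true, replace=False)]

    nets = []
    for cidx in chosen:
        center = (cidx + 0.5) * cell + rng.uniform(-1.0, 1.0, size=3)
        radii = rng.uniform(2.0, min(3.0, cell.min() / 2 - 0.5), size=3)
        d2 = sum(((g - cc) / r) ** 2 for g, cc, r in zip(coords, center, radii))
        blob = (d2 <= 1.0).astype(float)
        w = ndimage.gaussian_filter(blob, smooth_sigma)
        w[w < floor * w.max()] = 0.0
        if w.max() <= 0 or np.count_nonzero(w) < min_support:
            raise ValueError("blobs cannot be placed disjointly on this grid")
        w = (w / w.max()) ** shape_exponent
        nets.append(w / w.max())

    W = np.stack(nets)
    flat = W.reshape(k_true, -1).T
    sim = cosine_similarity_matrix(flat, flat)
    off = sim[~np.eye(k_true, dtype=bool)]
    if off.size and off.max() >= max_cosine:
        raise ValueError("blobs cannot be placed disjointly on this grid")
    return W


def networks_mask(networks_grid: np.ndarray, dilate: int = 1) -> AtlasMask:
    """Analysis mask emulating a tissue atlas: union of network supports, dilated.

    Restricting the mask to covered tissue mirrors a gray-matter atlas mask
    and avoids a large signal-free background whose constant exponentiated
    baseline would be split arbitrarily across factorization components.
    """
    support = networks_grid.sum(axis=0) > 0
    if dilate > 0:
        support = ndimage.binary_dilation(support, iterations=dilate)
    return AtlasMask(labels=support.astype(int))


def make_maps(
    W_true: np.ndarray,
    covariates: pd.DataFrame,
    noise_sd: float = 0.05,
    scn_effect: tuple[int, float] = (0, 0.35),
    seed: int = 0,
    loading_mu: float = 0.6,
    loading_sigma: float = 0.4,
    max_log_dev: float = 1.1,
    spacing_mm: float = DEFAULT_SPACING,
) -> tuple[list[VolumetricMap], np.ndarray, np.ndarray]:
    """Mix planted networks into per-subject log-Jacobian maps.

    Subject loadings are truncated lognormal, H[j, n] = exp(mu + dev) with
    the stochastic deviation dev = sigma * xi (plus coupling * g_n for the
    designated network, where g is a standard-normal latent "cognitive
    driver") clipped to +/- max_log_dev.  The truncation keeps the
    exponentiated data within a physically plausible dynamic range; an
    unbounded lognormal tail occasionally produces a single subject-network
    block that dominates the Frobenius loss and derails the factorization.
    Each map is logJ_n = sum_j W_true[j] * H[j, n] + Gaussian voxel noise.

    Returns (maps, H_true, driver).
    """
    k = W_true.shape[0]
    grid = W_true.shape[1:]
    N = len(covariates)
    j_star, coupling = scn_effect
    if not 0 <= j_star < k:
        raise ValueError("designated network index out of range")
    rng = np.random.default_rng(seed)
    driver = rng.standard_normal(N)
    dev = loading_sigma * rng.standard_normal((k, N))
    dev[j_star] += coupling * driver
    H_true = np.exp(loading_mu + np.clip(dev, -max_log_dev, max_log_dev))
    flatW = W_true.reshape(k, -1)
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    maps = []
    for n, sid in enumerate(covariates.index):
        logj = (H_true[:, n][:, None] * flatW).sum(axis=0).reshape(grid)
        if noise_sd > 0:
            logj = logj + noise_sd * rng.standard_normal(grid)
        maps.append(
            VolumetricMap(
                values=logj,
                spacing_mm=(spacing_mm,) * 3,
                affine=affine,
                subject_id=str(sid),
            )
        )
    return maps, H_true, driver


def true_scn_volumes(
    W_true: np.ndarray,
    H_true: np.ndarray,
    mask: AtlasMask,
    subject_ids,
) -> pd.DataFrame:
    """Noiseless weighted mean log-Jacobian of each planted network."""
    from .nnmf import scn_volumes

    idx = np.nonzero(mask.labels > 0)
    flatW = np.stack([w[idx] for w in W_true], axis=1)  # V x k
    logJ = flatW @ H_true  # V x N, noiseless in-mask signal
    return scn_volumes(logJ, flatW, subject_ids=list(subject_ids))


def make_factors(
    covariates: pd.DataFrame,
    scn_true_volume: np.ndarray | None,
    beta_parenting: float = -0.40,
    beta_scn: float = 0.40,
    seed: int = 0,
) -> np.ndarray:
    """Latent outcome factors with the planted brain/environment effects.

    On the standardized scale: factor 1 ("preterm phenotype") =
    beta_parenting * z(parenting) + residual; factor 2 ("cognitive") =
    beta_scn * z(designated network volume) + residual; factor 3
    ("socioemotional") is pure residual.  Residual variances keep each factor
    at unit variance.
    """
    N = len(covariates)
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((N, 3))
    z_par = stats.zscore(covariates["parenting"].to_numpy(float), ddof=0)
    f1 = beta_parenting * z_par + np.sqrt(max(1 - beta_parenting**2, 0.0)) * base[:, 0]
    if scn_true_volume is not None and beta_scn != 0:
        z_vol = stats.zscore(np.asarray(scn_true_volume, float), ddof=0)
        f2 = beta_scn * z_vol + np.sqrt(max(1 - beta_scn**2, 0.0)) * base[:, 1]
    else:
        f2 = base[:, 1]
    return np.column_stack([f1, f2, base[:, 2]])


def measure_metadata() -> pd.DataFrame:
    rows = [
        {"measure": n, "block": b, "age_normed": a} for n, b, a in MEASURES
    ]
    return pd.DataFrame(rows).set_index("measure")


def make_battery(
    factor_scores: np.ndarray,
    covariates: pd.DataFrame,
    M: int = 32,
    noise_sd: float = 0.7,
    seed: int = 0,
    age_drift: float = 0.30,
) -> tuple["object", np.ndarray]:
    """Generate the behavioral battery from the latent factors.

    Each measure loads primarily on one factor following the cohort's sign
    pattern (symptom scales positive on the preterm-phenotype factor,
    intelligence subscales positive on the cognitive factor and the
    general/nonverbal ones negative on the phenotype factor), with i.i.d.
    Gaussian measurement noise.  Measures that are not age-normed receive a
    linear drift in age at assessment, which the preprocessing removes.

    Returns (OutcomeBattery, measure_loadings).
    """
    from .outcomes import OutcomeBattery

    if M != len(MEASURES):
        raise ValueError(f"M must be {len(MEASURES)} (one per named subscale)")
    F = np.asarray(factor_scores, float)
    if F.shape != (len(covariates), 3):
        raise ValueError("factor_scores must be N x 3")
    rng = np.random.default_rng(seed)
    loadings = np.array([BLOCK_LOADINGS[b] for _, b, _ in MEASURES])
    names = [n for n, _, _ in MEASURES]
    normed = np.array([a for _, _, a in MEASURES])

    # corrected age at assessment: median ~4.65 years, right-skewed tail
    age = 4.1 + rng.gamma(2.0, 0.35, size=len(covariates))
    z_age = stats.zscore(age, ddof=0)

    scores = F @ loadings.T + noise_sd * rng.standard_normal((len(covariates), M))
    scores[:, ~normed] += age_drift * z_age[:, None]
    battery = OutcomeBattery(
        scores=pd.DataFrame(scores, index=covariates.index, columns=names),
        age_normed=pd.Series(normed, index=names),
        age_years=pd.Series(age, index=covariates.index),
    )
    return battery, loadings


def make_cohort(
    N: int = 200,
    k_true: int = 6,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    M: int = 32,
    seed: int = 0,
    voxel_noise_sd: float = 0.05,
    measure_noise_sd: float = 0.7,
    beta_parenting: float = -0.40,
    beta_scn: float = 0.40,
    scn_coupling: float = 0.35,
    designated_network: int = 0,
    twin_fraction: float = 0.10,
) -> SyntheticCohort:
    """Generate a full cohort: maps + mask + battery + covariates + ground truth.

    All randomness descends from `seed` through SeedSequence spawning, one
    child per stage, so cohorts are reproducible and stages statistically
    independent.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

    covariates = make_covariates(N, seed=seeds[0], twin_fraction=twin_fraction)
    networks = make_networks(grid_shape, k_true=k_true, seed=seeds[1])
    mask = networks_mask(networks)
    maps, H_true, driver = make_maps(
        networks,
        covariates,
        noise_sd=voxel_noise_sd,
        scn_effect=(designated_network, scn_coupling),
        seed=seeds[2],
    )
    truth_vols = true_scn_volumes(networks, H_true, mask, covariates.index)
    v_star = truth_vols.iloc[:, designated_network].to_numpy()
    factors = make_factors(
        covariates,
        v_star,
        beta_parenting=beta_parenting,
        beta_scn=beta_scn,
        seed=seeds[3],
    )
    battery, loadings = make_battery(
        factors, covariates, M=M, noise_sd=measure_noise_sd, seed=seeds[4]
    )

    idx = np.nonzero(mask.labels > 0)
    W_flat = np.stack([w[idx] for w in networks], axis=1)
    truth = GroundTruth(
        W_true=W_flat,
        H_true=H_true,
        networks_grid=networks,
        factor_scores=factors,
        measure_loadings=loadings,
        designated_network=designated_network,
        cognitive_driver=driver,
        true_volumes=truth_vols,
        beta_scn_pc2=beta_scn,
        beta_parenting_pc1=beta_parenting,
        noise_sds={"voxel": voxel_noise_sd, "measure": measure_noise_sd},
        seed=seed,
    )
    return SyntheticCohort(
        maps=maps, mask=mask, battery=battery, covariates=covariates, truth=truth
    )
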