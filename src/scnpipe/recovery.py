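"""Parameter-recovery evaluation of a study run against a synthetic cohort's truth.

The synthetic generator plants known networks, factors and effects; these
helpers measure how well a pipeline run recovered them: which fitted network
corresponds to the planted (designated) one, which retained component tracks
each latent factor (and with what sign, since principal axes are
sign-indeterminate), and whether the planted brain->cognition and
parenting->phenotype effects were detected with the correct signs at the
corrected threshold — while non-planted predictor-component pairs stay quiet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import associations, nnmf
from .cohort import SyntheticCohort
from .pipeline import StudyResult


@dataclass
class DetectionOutcome:
    retained_three: bool
    network_recovery_cosine: float
    designated_label: str
    scn_omnibus_detected: bool
    scn_effect_detected: bool  # follow-up on the cognitive component, correct sign
    parenting_omnibus_detected: bool
    parenting_effect_detected: bool  # follow-up on the phenotype component, correct sign
    false_omnibus_networks: int
    false_pairs: int
    n_nondesignated: int


def match_components_to_factors(pcs, factor_scores) -> tuple[np.ndarray, np.ndarray]:
    """Map each retained component to its best-matching latent factor.

    Returns (factor_index_per_component, sign_per_component), where the sign
    is the sign of the score correlation with the matched factor.
    """
    S = np.asarray(pcs, float)
    F = np.asarray(factor_scores, float)
    k = S.shape[1]
    corr = np.corrcoef(np.column_stack([S, F]), rowvar=False)[:k, k:]
    match = np.abs(corr).argmax(axis=1)
    signs = np.sign(corr[np.arange(k), match])
    return match, signs


def evaluate_detection(
    cohort: SyntheticCohort,
    result: StudyResult,
    alpha: float = 0.05,
) -> DetectionOutcome:
    """Score one pipeline run against the cohort's planted ground truth."""
    truth = cohort.truth
    perm, sims = nnmf.match_networks(truth.W_true, result.model.W)
    designated = f"scn_{perm[truth.designated_network] + 1}"

    pcs = result.components.retained_scores()
    retained_three = pcs.shape[1] == 3

    scn_omni = scn_eff = par_omni = par_eff = False
    false_omni = false_pairs = 0
    n_nd = len(result.scn_results) - 1

    if retained_three:
        match, signs = match_components_to_factors(pcs.to_numpy(), truth.factor_scores)
        pc_cog = int(np.where(match == 1)[0][0]) if (match == 1).any() else None
        pc_phe = int(np.where(match == 0)[0][0]) if (match == 0).any() else None

        if designated in result.significant_scns:
            scn_omni = True
            if pc_cog is not None:
                e = result.scn_results[designated].per_component[pc_cog]
                scn_eff = bool(e.significant and np.sign(e.beta) * signs[pc_cog] > 0)

        pr = result.parenting_result
        par_omni = pr.omnibus_p < alpha
        if par_omni and pc_phe is not None:
            e = pr.per_component[pc_phe]
            par_eff = bool(e.significant and np.sign(e.beta) * signs[pc_phe] < 0)

        for name in result.significant_scns:
            if name == designated:
                continue
            false_omni += 1
            false_pairs += sum(
                e.significant for e in result.scn_results[name].per_component
            )

    return DetectionOutcome(
        retained_three=retained_three,
        network_recovery_cosine=float(np.mean(sims)),
        designated_label=designated,
        scn_omnibus_detected=scn_omni,
        scn_effect_detected=scn_eff,
        parenting_omnibus_detected=par_omni,
        parenting_effect_detected=par_eff,
        false_omnibus_networks=false_omni,
        false_pairs=false_pairs,
        n_nondesignated=n_nd,
    )


def recovered_betas(cohort: SyntheticCohort, result: StudyResult) -> dict[str, float]:
    """Standardized planted-effect estimates from the fitted pipeline.

    Re-expresses the follow-up regression coefficients on the standardized
    scale of the planted couplings: effect of a 1-SD change of the predictor
    on the matched component, in units of that component's SD.
    """
    truth = cohort.truth
    perm, _ = nnmf.match_networks(truth.W_true, result.model.W)
    designated = f"scn_{perm[truth.designated_network] + 1}"
    pcs = result.components.retained_scores()
    match, signs = match_components_to_factors(pcs.to_numpy(), truth.factor_scores)
    out: dict[str, float] = {}
    cov = cohort.covariates

    if (match == 1).any():
        pc_cog = int(np.where(match == 1)[0][0])
        effects = associations.followup_univariate(
            pcs,
            result.scn_volumes.loc[pcs.index, designated],
            cov.loc[pcs.index, associations.SCN_COVARIATES],
        )
        e = effects[pc_cog]
        scale = result.scn_volumes[designated].std(ddof=1) / pcs.iloc[:, pc_cog].std(ddof=1)
        out["beta_scn_cognitive_std"] = float(e.beta * scale * signs[pc_cog])
    if (match == 0).any():
        pc_phe = int(np.where(match == 0)[0][0])
        effects = associations.followup_univariate(
            pcs,
            cov.loc[pcs.index, "parenting"],
            cov.loc[pcs.index, associations.PARENTING_COVARIATES],
        )
        e = effects[pc_phe]
        scale = cov["parenting"].std(ddof=1) / pcs.iloc[:, pc_phe].std(ddof=1)
        out["beta_parenting_phenotype_std"] = float(e.beta * scale * signs[pc_phe])
    return out
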