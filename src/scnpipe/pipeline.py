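"""End-to-end orchestration: prep -> networks -> outcome components -> associations.

Two entry points:

* run_study(...) runs the whole chain on in-memory objects (a SyntheticCohort
  or equivalent pieces) and returns a StudyResult; every stage is also
  callable on its own through the underlying modules.
* run_pipeline(config) is the file-based driver: it reads a config file
  (paths to a map manifest, mask, scores, covariates), persists intermediate
  artifacts and a combined report, and returns the StudyResult.

Deterministic stages are bit-reproducible given identical inputs; every
stochastic stage (rank-selection splits, permutation test, split-half
reliability, sensitivity subsampling) takes an explicit seed resolved from
the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations, nnmf, outcomes, volumes
from .associations import AnalysisBundle, AssociationResult
from .nnmf import RankSelectionReport, SCNModel
from .outcomes import OutcomeBattery, OutcomeComponents


@dataclass
class PipelineConfig:
    """Resolved configuration; every stochastic stage has an explicit seed."""

    # paths (file-based runs; unused for in-memory runs)
    manifest: str | None = None
    mask: str | None = None
    scores: str | None = None
    measure_meta: str | None = None
    covariates: str | None = None
    out_dir: str = "pipeline_out"
    # preprocessing
    fwhm_mm: float = 4.0
    target_spacing_mm: float = 2.0
    # factorization / rank selection
    candidate_ranks: list[int] = field(default_factory=lambda: list(range(2, 11)))
    n_rank_splits: int = 8
    stability_threshold: float = 0.85
    stability_metric: str = "pearson"
    fixed_rank: int | None = None
    # outcome components
    n_perm: int = 1000
    n_splits: int = 100
    reliability_threshold: float = 0.70
    # statistics
    alpha: float = 0.05
    statistic: str = "pillai"
    run_sensitivity: bool = True
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fwhm_mm is not None and self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        offsets = {"rank": 11, "nnmf": 13, "outcomes": 17, "sensitivity": 19}
        return int((self.seed * 100 + offsets[stage]) % (2**31))


@dataclass
class StudyResult:
    rank_report: RankSelectionReport | None
    model: SCNModel
    scn_volumes: pd.DataFrame
    components: OutcomeComponents
    scn_results: dict[str, AssociationResult]
    parenting_result: AssociationResult
    full_model: tuple[AssociationResult, AssociationResult] | None
    interactions: pd.DataFrame | None
    sensitivity: dict | None
    sample_sizes: dict[str, int]
    significant_scns: list[str]

    def report_text(self) -> str:
        lines = ["== Study report ==", "", "Sample sizes:"]
        for k, v in self.sample_sizes.items():
            lines.append(f"  {k}: {v}")
        if self.rank_report is not None:
            lines += ["", "Rank selection:", self.rank_report.to_text()]
        lines += ["", "Outcome components:"]
        c = self.components
        for i in range(min(6, c.n_components)):
            lines.append(
                f"  PC{i + 1}: var {c.var_explained[i]:.3f} perm_p {c.perm_p[i]:.4f} "
                f"splithalf_r {c.splithalf_r[i]:.3f} retained {bool(c.retained[i])}"
            )
        n_models = len(self.scn_results)
        thr, disp = associations.bonferroni_threshold(0.05, n_models)
        lines += [
            "",
            f"Per-network omnibus tests (threshold .05/{n_models} = {disp}):",
        ]
        for name, res in self.scn_results.items():
            flag = "*" if res.omnibus_p < thr else " "
            lines.append(
                f"  {name}: {res.statistic_name}={res.omnibus_stat:.4f} "
                f"F={res.omnibus_F:.3f} p={res.omnibus_p:.4g}{flag} (n={res.n_used})"
            )
        pr = self.parenting_result
        lines += [
            "",
            f"Parenting omnibus: {pr.statistic_name}={pr.omnibus_stat:.4f} "
            f"F={pr.omnibus_F:.3f} p={pr.omnibus_p:.4g} (n={pr.n_used})",
        ]
        for e in pr.per_component:
            lines.append(
                f"  {e.component}: beta={e.beta:.4f} p={e.p_raw:.4g} "
                f"p_adj={e.p_adjusted:.4g} sig={e.significant}"
            )
        if self.significant_scns:
            lines += ["", f"Networks passing correction: {', '.join(self.significant_scns)}"]
            for name in self.significant_scns:
                for e in self.scn_results[name].per_component:
                    lines.append(
                        f"  {name} -> {e.component}: beta={e.beta:.4f} "
                        f"p={e.p_raw:.4g} p_adj={e.p_adjusted:.4g} sig={e.significant}"
                    )
        if self.interactions is not None and len(self.interactions):
            lines += ["", "Interaction (parenting x network volume) nested-model F tests:"]
            for _, row in self.interactions.iterrows():
                lines.append(
                    f"  {row['scn']} x parenting -> {row['component']}: "
                    f"F={row['F']:.3f} p={row['p']:.4g}"
                )
        return "\n".join(lines)


def run_study(
    voxel_matrix: volumes.VoxelMatrix,
    log_matrix: np.ndarray,
    battery: OutcomeBattery,
    covariates: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> StudyResult:
    """Run factorization, outcome components and association models in memory.

    voxel_matrix holds the exponentiated data for the factorization;
    log_matrix is the same voxels x subjects matrix in the log domain, used
    for the weighted network volumes.
    """
    cfg = config or PipelineConfig()

    if cfg.fixed_rank is not None:
        rank_report = None
        k = cfg.fixed_rank
    else:
        rank_report = nnmf.select_rank(
            voxel_matrix.data,
            cfg.candidate_ranks,
            n_splits=cfg.n_rank_splits,
            seed=cfg.stage_seed("rank"),
            threshold=cfg.stability_threshold,
            metric=cfg.stability_metric,
        )
        k = rank_report.selected_rank
    model = nnmf.fit_nnmf(
        voxel_matrix.data, k, seed=cfg.stage_seed("nnmf"), max_iter=500, tol=1e-6
    )
    vols = nnmf.scn_volumes(log_matrix, model.W, subject_ids=voxel_matrix.subject_ids)

    components = outcomes.analyze_battery(
        battery,
        n_perm=cfg.n_perm,
        n_splits=cfg.n_splits,
        alpha=cfg.alpha,
        r_min=cfg.reliability_threshold,
        seed=cfg.stage_seed("outcomes"),
    )
    pcs = components.retained_scores()

    # subjects with both imaging and outcomes
    joint = pcs.index.intersection(vols.index)
    cov_j = covariates.loc[covariates.index.intersection(joint)]
    scn_covs = [c for c in associations.SCN_COVARIATES if c in covariates.columns]
    par_covs = [c for c in associations.PARENTING_COVARIATES if c in covariates.columns]

    n_models = vols.shape[1]
    omnibus_thr, _ = associations.bonferroni_threshold(cfg.alpha, n_models)
    scn_results: dict[str, AssociationResult] = {}
    significant: list[str] = []
    for name in vols.columns:
        res = associations.omnibus_multivariate(
            pcs.loc[joint],
            vols.loc[joint, name],
            cov_j[scn_covs],
            predictor_name=name,
            statistic=cfg.statistic,
        )
        if res.omnibus_p < omnibus_thr:
            res.per_component = associations.followup_univariate(
                pcs.loc[joint], vols.loc[joint, name], cov_j[scn_covs], alpha=cfg.alpha
            )
            significant.append(name)
        scn_results[name] = res

    # parenting models use every subject with outcomes
    par_idx = pcs.index.intersection(covariates.index)
    parenting_result = associations.run_predictor_analysis(
        pcs.loc[par_idx],
        covariates.loc[par_idx, "parenting"],
        covariates.loc[par_idx, par_covs],
        predictor_name="parenting",
        alpha=cfg.alpha,
        statistic=cfg.statistic,
    )

    full_model = None
    inter_rows = []
    for name in significant:
        full_model = associations.full_additive_model(
            pcs.loc[joint],
            vols.loc[joint, name],
            cov_j["parenting"],
            cov_j[scn_covs],
            alpha=cfg.alpha,
            statistic=cfg.statistic,
        )
        for comp in pcs.columns:
            F, df, p = associations.interaction_lrt(
                pcs.loc[joint, comp],
                vols.loc[joint, name],
                cov_j["parenting"],
                cov_j[scn_covs],
            )
            inter_rows.append({"scn": name, "component": comp, "F": F, "df1": df[0], "df2": df[1], "p": p})
    interactions = pd.DataFrame(inter_rows) if inter_rows else None

    sensitivity = None
    if cfg.run_sensitivity:
        bundle = AnalysisBundle(
            pcs=pcs.loc[joint],
            scn_volumes=vols.loc[joint],
            covariates=covariates.loc[joint],
            battery=battery.scores.loc[battery.scores.index.intersection(joint)],
            focal_scn=significant[0] if significant else None,
        )
        which = {"outliers"}
        if "twin_group" in covariates.columns:
            which.add("twins")
        if "lesion_grade" in covariates.columns:
            which.add("lesions")
        if {"maternal_educ", "maternal_age"} <= set(covariates.columns):
            which.add("maternal")
        sensitivity = associations.sensitivity_suite(
            bundle, which=which, seed=cfg.stage_seed("sensitivity"), alpha=cfg.alpha
        )

    return StudyResult(
        rank_report=rank_report,
        model=model,
        scn_volumes=vols,
        components=components,
        scn_results=scn_results,
        parenting_result=parenting_result,
        full_model=full_model,
        interactions=interactions,
        sensitivity=sensitivity,
        sample_sizes={
            "imaging": voxel_matrix.n_subjects,
            "outcomes": int(pcs.shape[0]),
            "combined": int(len(joint)),
        },
        significant_scns=significant,
    )


def run_cohort_study(cohort, config: PipelineConfig | None = None) -> StudyResult:
    """Convenience wrapper: preprocess a SyntheticCohort's maps and run the study."""
    vm_exp = volumes.build_voxel_matrix(cohort.maps, cohort.mask, exponentiate=True)
    vm_log = volumes.build_voxel_matrix(cohort.maps, cohort.mask, exponentiate=False)
    return run_study(vm_exp, vm_log.data, cohort.battery, cohort.covariates, config)


def _load_battery(cfg: PipelineConfig) -> OutcomeBattery:
    scores = pd.read_csv(cfg.scores, sep=None, engine="python", index_col=0)
    meta = pd.read_csv(cfg.measure_meta, sep=None, engine="python", index_col=0)
    cov = pd.read_csv(cfg.covariates, sep=None, engine="python", index_col=0)
    age_col = "age_years" if "age_years" in cov.columns else "age_at_assessment"
    common = scores.index.intersection(cov.index)
    return OutcomeBattery(
        scores=scores.loc[common],
        age_normed=meta["age_normed"].astype(bool),
        age_years=cov.loc[common, age_col],
    )


def run_pipeline(config: PipelineConfig) -> StudyResult:
    """File-based pipeline: load inputs per config, run the study, persist artifacts."""
    required = ("manifest", "mask", "scores", "measure_meta", "covariates")
    missing = [name for name in required if getattr(config, name) is None]
    if missing:
        raise ValueError(f"config is missing required paths: {', '.join(missing)}")
    for name in required:
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} path does not exist: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = pd.read_csv(config.manifest, sep=None, engine="python")
    maps = [
        volumes.load_map(row["path"], subject_id=str(row["subject_id"]))
        for _, row in manifest.iterrows()
    ]
    maps = volumes.preprocess_maps(maps, config.fwhm_mm, config.target_spacing_mm)
    mask = volumes.load_mask(config.mask, expected_grid=maps[0].shape)
    vm_exp = volumes.build_voxel_matrix(maps, mask, exponentiate=True)
    vm_log = volumes.build_voxel_matrix(maps, mask, exponentiate=False)
    vm_exp.save(out / "voxel_matrix.npz")

    battery = _load_battery(config)
    covariates = pd.read_csv(config.covariates, sep=None, engine="python", index_col=0)

    result = run_study(vm_exp, vm_log.data, battery, covariates, config)

    result.scn_volumes.to_csv(out / "scn_volumes.csv")
    result.components.loadings.to_csv(out / "pc_loadings.csv")
    result.components.scores.to_csv(out / "pc_scores.csv")
    pd.DataFrame(
        {
            "var_explained": result.components.var_explained,
            "perm_p": result.components.perm_p,
            "splithalf_r": result.components.splithalf_r,
            "retained": result.components.retained,
        }
    ).to_csv(out / "pc_retention.csv")
    if result.rank_report is not None:
        (out / "rank_selection.txt").write_text(result.rank_report.to_text())
    omn = pd.DataFrame(
        [
            {
                "predictor": r.predictor,
                "stat": r.omnibus_stat,
                "F": r.omnibus_F,
                "df1": r.omnibus_df[0],
                "df2": r.omnibus_df[1],
                "p": r.omnibus_p,
                "n": r.n_used,
            }
            for r in list(result.scn_results.values()) + [result.parenting_result]
        ]
    )
    omn.to_csv(out / "omnibus_tests.csv", index=False)
    follow = pd.concat(
        [r.component_table() for r in list(result.scn_results.values()) + [result.parenting_result] if r.per_component],
        ignore_index=True,
    ) if any(r.per_component for r in result.scn_results.values()) or result.parenting_result.per_component else pd.DataFrame()
    follow.to_csv(out / "followup_tests.csv", index=False)
    if result.interactions is not None:
        result.interactions.to_csv(out / "interaction_tests.csv", index=False)
    (out / "report.txt").write_text(result.report_text())
    (out / "config_used.json").write_text(json.dumps(asdict(config), indent=2, default=str))
    return result
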