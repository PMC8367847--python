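#!/usr/bin/env python
"""Generate the synthetic study cohort and summarize its demographics.

Writes the cohort's covariate table and a demographic summary (to compare
against the target distributions the generator emulates) under results/, and
the full cohort (NIfTI maps, mask, scores, metadata) under scratch/cohort/
for the later stages.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scnpipe import cohort, volumes

SEED = 7
N = 200
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohort"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    c = cohort.make_cohort(N=N, seed=SEED)

    cov = c.covariates
    summary = pd.DataFrame(
        {
            "GA_weeks_median": [cov.GA_weeks.median()],
            "GA_weeks_min": [cov.GA_weeks.min()],
            "GA_weeks_max": [cov.GA_weeks.max()],
            "PMA_weeks_median": [cov.PMA_weeks.median()],
            "female_pct": [100 * cov.sex.mean()],
            "IMD_mean": [cov.IMD.mean()],
            "IMD_sd": [cov.IMD.std(ddof=1)],
            "parenting_mean": [cov.parenting.mean()],
            "parenting_sd": [cov.parenting.std(ddof=1)],
            "minor_lesions_pct": [100 * cov.lesion_grade.mean()],
            "n_twin_pairs": [(cov.twin_group != "").sum() // 2],
            "mask_voxels": [c.mask.n_voxels],
        }
    ).T.rename(columns={0: "value"})
    summary.to_csv(RESULTS / "cohort_demographics.csv")
    cov.to_csv(SCRATCH / "covariates.csv")
    c.battery.scores.to_csv(SCRATCH / "scores.csv")
    cohort.measure_metadata().to_csv(SCRATCH / "measure_meta.csv")

    maps_dir = SCRATCH / "maps"
    maps_dir.mkdir(exist_ok=True)
    rows = []
    for m in c.maps:
        p = maps_dir / f"{m.subject_id}.nii.gz"
        volumes.save_map(m, p)
        rows.append({"subject_id": m.subject_id, "path": str(p)})
    pd.DataFrame(rows).to_csv(SCRATCH / "manifest.csv", index=False)
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(c.mask.labels.astype(np.int16), c.maps[0].affine),
        str(SCRATCH / "mask.nii.gz"),
    )
    np.savez(
        SCRATCH / "ground_truth.npz",
        W_true=c.truth.W_true,
        H_true=c.truth.H_true,
        factor_scores=c.truth.factor_scores,
        designated_network=c.truth.designated_network,
        cognitive_driver=c.truth.cognitive_driver,
    )
    print(f"Simulated N={N} cohort (seed {SEED}); mask has {c.mask.n_voxels} voxels.")
    print(summary.round(3))


if __name__ == "__main__":
    main()
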