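#!/usr/bin/env python
"""Association models: network volumes and parenting vs outcome components.

Per-network multivariate omnibus tests (Bonferroni across networks),
follow-up univariate regressions for networks passing correction, the
parenting omnibus, the combined additive model, interaction nested-model F
tests, and the sensitivity suite.  Writes all tables plus the combined
report under results/.
"""

from pathlib import Path

import pandas as pd

from scnpipe import cohort
from scnpipe.pipeline import PipelineConfig, run_cohort_study

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    c = cohort.make_cohort(N=200, seed=SEED)
    cfg = PipelineConfig(fixed_rank=None, n_perm=1000, n_splits=100, seed=SEED)
    res = run_cohort_study(c, cfg)

    omn = pd.DataFrame(
        [
            {
                "predictor": r.predictor,
                "pillai": r.omnibus_stat,
                "F": r.omnibus_F,
                "df1": r.omnibus_df[0],
                "df2": r.omnibus_df[1],
                "p": r.omnibus_p,
                "n": r.n_used,
            }
            for r in list(res.scn_results.values()) + [res.parenting_result]
        ]
    )
    omn.to_csv(RESULTS / "omnibus_tests.csv", index=False)

    follow = pd.concat(
        [
            r.component_table()
            for r in list(res.scn_results.values()) + [res.parenting_result]
            if r.per_component
        ],
        ignore_index=True,
    )
    follow.to_csv(RESULTS / "followup_tests.csv", index=False)

    if res.full_model is not None:
        pd.concat(
            [r.component_table() for r in res.full_model], ignore_index=True
        ).to_csv(RESULTS / "full_model_tests.csv", index=False)
    if res.interactions is not None:
        res.interactions.to_csv(RESULTS / "interaction_tests.csv", index=False)

    if res.sensitivity is not None:
        rows = []
        for variant, models in res.sensitivity.items():
            for name, r in models.items():
                rows.append(
                    {
                        "variant": variant,
                        "model": name,
                        "predictor": r.predictor,
                        "pillai": r.omnibus_stat,
                        "p": r.omnibus_p,
                        "n": r.n_used,
                    }
                )
        pd.DataFrame(rows).to_csv(RESULTS / "sensitivity_tests.csv", index=False)

    (RESULTS / "report.txt").write_text(res.report_text())
    print(res.report_text())


if __name__ == "__main__":
    main()
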