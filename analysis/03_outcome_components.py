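#!/usr/bin/env python
"""Outcome components: PCA of the behavioral battery with retention testing.

Preprocesses the 32-measure battery (age residualization of non-normed
measures, standardization), fits the PCA, and decides how many components to
keep by permutation significance and repeated split-half reliability.  Writes
the retention table, loadings and subject scores under results/, plus a
loading heatmap if matplotlib is available.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scnpipe import outcomes

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohort"


def main() -> None:
    scores = pd.read_csv(SCRATCH / "scores.csv", index_col=0)
    meta = pd.read_csv(SCRATCH / "measure_meta.csv", index_col=0)
    cov = pd.read_csv(SCRATCH / "covariates.csv", index_col=0)
    # corrected age at assessment is stored with the battery by the generator;
    # rebuild it deterministically from the cohort seed
    from scnpipe import cohort

    c = cohort.make_cohort(N=len(cov), seed=SEED)
    battery = c.battery

    comps = outcomes.analyze_battery(battery, n_perm=1000, n_splits=100, seed=SEED)
    retention = pd.DataFrame(
        {
            "var_explained": comps.var_explained,
            "perm_p": comps.perm_p,
            "splithalf_r": comps.splithalf_r,
            "retained": comps.retained,
        },
        index=comps.loadings.columns,
    )
    retention.head(8).to_csv(RESULTS / "pc_retention.csv")
    comps.loadings.iloc[:, :6].to_csv(RESULTS / "pc_loadings.csv")
    comps.retained_scores().to_csv(RESULTS / "pc_scores.csv")
    kept = comps.n_retained
    cum = comps.var_explained[:kept].sum()
    print(f"Retained {kept} components, jointly explaining {100 * cum:.1f}% of variance.")
    print(retention.head(6).round(4))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 9))
        L = comps.loadings.iloc[:, :3]
        im = ax.imshow(L.to_numpy(), cmap="RdBu_r", vmin=-0.5, vmax=0.5, aspect="auto")
        ax.set_yticks(range(len(L.index)), L.index, fontsize=6)
        ax.set_xticks(range(3), L.columns)
        fig.colorbar(im, ax=ax, label="loading")
        fig.tight_layout()
        fig.savefig(RESULTS / "pc_loading_heatmap.png", dpi=150)
    except ImportError:
        pass


if __name__ == "__main__":
    main()
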