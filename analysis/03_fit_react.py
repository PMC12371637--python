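"""Fit REACT on every subject: enriched-FC maps per molecular system.

Summarizes how well the dual regression recovers the generative
structure (spatial correlation of each recovered system map with its
truth template) and writes per-subject region-mean couplings.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, STUDY_CONFIG, enriched_stacks, study_cohort


def main():
    RESULTS.mkdir(exist_ok=True)
    cohort = study_cohort()
    stacks = enriched_stacks(cohort)
    cfg = STUDY_CONFIG

    rows = []
    for k, name in enumerate(cohort.system_names):
        truth = cohort.truth_templates[k].ravel()
        rs = [np.corrcoef(stacks[name][s].ravel(), truth)[0, 1]
              for s in range(cfg.n_subjects)]
        rows.append({"system": name, "median_recovery_r": round(float(np.median(rs)), 3)})
    recovery = pd.DataFrame(rows)
    recovery.to_csv(RESULTS / "react_recovery.tsv", sep="\t", index=False)
    print("Spatial correlation of recovered beta maps with truth templates:")
    print(recovery.to_string(index=False), "\n")

    region = cohort.effect_region
    means = pd.DataFrame(
        {name: stacks[name][:, region].mean(axis=1) for name in cohort.system_names}
    )
    means["fss"] = cohort.covariates["fss"].to_numpy()
    means.to_csv(RESULTS / "region_mean_betas.tsv", sep="\t", index=False)
    net = cohort.system_names[cfg.effect_system]
    r = np.corrcoef(means[net], means["fss"])[0, 1]
    print(f"Region-mean {net} coupling vs FSS: r = {r:.3f} "
          "(the planted negative dependence is visible before any inference).")


if __name__ == "__main__":
    main()
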