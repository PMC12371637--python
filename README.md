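# reactfc

Molecular-informed functional-connectivity analysis for resting-state
fMRI: from preprocessed 4D volumes and receptor/transporter density
templates to subject-specific **molecular-enriched FC maps** (REACT
dual regression), group-level **permutation inference with TFCE** and
familywise-error control, **atlas overlap labeling** of significant
clusters, and the accompanying clinical statistics. A synthetic-cohort
generator with planted ground truth makes every stage verifiable
without patient data.

Intended users: neuroimaging researchers studying how
neurotransmitter-specific circuits (dopamine, noradrenaline,
serotonin transporters; mGluR5) relate to clinical variables such as
fatigue severity in Parkinson's disease.

## The method

**REACT (receptor-enriched analysis of FC by targets).** Let
`m_k(v)` be K molecular density templates (rescaled to [0, 1], grey
matter at threshold 0.3, reference regions excised) and `y_v(t)` a
subject's BOLD data. Stage 1 regresses each demeaned volume on the
demeaned, unit-variance templates, giving system-specific time series
`x_k(t)`; stage 2 regresses each voxel's series on the demeaned,
unit-variance `x_k(t)`, giving K beta maps per subject — the
molecular-enriched FC maps.

**Inference.** Voxelwise GLM (e.g. FSS association adjusted for age,
gender, LEDD, eICV), Freedman-Lane permutation of nuisance-model
residuals, TFCE enhancement `Σ_h e_h^E · h^H · dh` (H = 2, E = 2,
C = 6), max-statistic FWE correction, and optional generalized-Pareto
refinement of the extreme tail for small permutation counts.

## Worked example

```python
import numpy as np
from reactfc import (SyntheticConfig, generate_cohort, mask_bold, react,
                     build_design, permutation_fwe)

cfg = SyntheticConfig(n_subjects=35, n_timepoints=100,
                      noise_sigma=0.5, effect_beta=-0.8, seed=1)
cohort = generate_cohort(cfg)             # 4 systems, planted NET effect
mask = np.ones(cfg.grid_dims, bool)
templates = cohort.truth_templates.reshape(4, -1).T

net = np.stack([react(mask_bold(cohort.bold[s], mask), templates)[0].volume(1)
                for s in range(35)])      # NET beta map per subject

spec = build_design(cohort.covariates, "fss",
                    ("age", "gender", "ledd", "eicv"), sign=-1)
res = permutation_fwe(net, spec, n_perm=500, seed=21)
sig = res.significant_mask()
print(res.min_p, int(sig.sum()))
```

prints

```
0.001996007984031936 282
```

a significant negative association (min FWE p ≈ 0.002) in a 282-voxel
cluster that covers the 115-voxel planted region; the cluster-mean
partial correlation with FSS (adjusted for the same covariates) is
−0.99 at this noise level. Running the same models on the
dopamine/serotonin analogues — where nothing was planted — yields no
significant voxels.

The numbered scripts under `analysis/` run this narrative end to end
(cohort generation → clinical tables → REACT fit → permutation
inference → cluster labeling) and write their tables to `results/`:

```bash
cd analysis && python 01_simulate_cohort.py && python 02_clinical_tables.py \
  && python 03_fit_react.py && python 04_permutation_inference.py \
  && python 05_label_clusters.py
```

There is also a CLI (`reactfc simulate | prepare-templates | preprocess |
react | infer | label | clinstats`) operating on NIfTI/TSV files; see
`reactfc --help`.

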