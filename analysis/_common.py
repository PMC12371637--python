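"""Shared configuration for the numbered analysis scripts.

One deterministic synthetic cohort at the emulated study's scale (35
patients, four molecular systems, a planted negative fatigue effect on
the noradrenaline analogue) is regenerated by each script; generation
is cheap and keeps every script runnable on its own.
"""

from pathlib import Path

import numpy as np

from reactfc import SyntheticConfig, generate_cohort, mask_bold, react

RESULTS = Path(__file__).resolve().parent.parent / "results"
NUISANCE = ("age", "gender", "ledd", "eicv")

STUDY_CONFIG = SyntheticConfig(
    grid_dims=(12, 12, 12),
    n_systems=4,
    n_subjects=35,
    n_timepoints=100,
    noise_sigma=0.5,
    effect_beta=-0.8,
    seed=1,
)


def study_cohort():
    return generate_cohort(STUDY_CONFIG)


def enriched_stacks(cohort):
    """Per-system (N, nx, ny, nz) stacks of REACT beta maps."""
    cfg = cohort.config
    mask = np.ones(cfg.grid_dims, dtype=bool)
    M = cohort.truth_templates.reshape(cfg.n_systems, -1).T
    maps = [react(mask_bold(cohort.bold[s], mask), M)[0] for s in range(cfg.n_subjects)]
    return {
        name: np.stack([m.volume(k) for m in maps])
        for k, name in enumerate(cohort.system_names)
    }
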