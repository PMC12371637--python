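# Methods

## The model

`reactfc` implements receptor-enriched analysis of functional
connectivity by targets (REACT): a two-step dual regression that uses
molecular density templates — population-average spatial maps of
transporter/receptor density (here DAT, NET, SERT, mGluR5 analogues) —
as priors to decompose resting-state BOLD data into
neurotransmitter-system-specific functional-connectivity maps.

**Stage 1 (spatial regression).** At every timepoint *t*, the demeaned
volume `y(·, t)` is regressed jointly on the K demeaned, unit-variance
templates plus an intercept. The K coefficients over time form the
subject's system-specific time series: the dominant BOLD fluctuation
associated with each system's spatial distribution.

**Stage 2 (temporal regression).** Every voxel's demeaned series is
regressed jointly on the K demeaned, unit-variance stage-1 series plus
an intercept. The K betas per voxel are the subject's
molecular-enriched FC maps — the coupling of that voxel to each
system's fluctuation, in units of signal per unit-variance regressor.

Normalization conventions matter and are pinned: responses are
demeaned, regressors are demeaned and scaled to unit variance
(sample SD, ddof = 1), and an intercept is present in both stages.
Consequences asserted by tests: stage-1 output is invariant to positive
rescaling of any template, and both stages agree with explicit
normal-equations solutions to 1e-8 relative. Solvers are QR-based
least squares; a design condition number above 1e6 raises a warning,
rank deficiency is an error that reports pairwise regressor
correlations. By default templates enter one joint regression (the
REACT convention); voxels excised from one template (reference
regions) contribute zeros to that regressor while remaining in the
analysis for the others, with a strict-intersection mode available.

## Template preparation

Raw density maps are prepared in a fixed order: restrict to grey
matter (probability strictly above 0.3), excise the tracer's
kinetic-model reference region (occipital cortex for DAT/NET,
cerebellum for SERT), then min-max rescale to [0, 1] over the
surviving voxels. Rescaling after masking guarantees both bounds are
attained on the analysis mask and that excluded extremes cannot
compress the range; masking steps commute with each other but not with
rescaling, which the tests pin down. Whether the original protocol
rescaled before or after excision is not documented anywhere we know
of; the mask-then-rescale order is this package's documented choice.
All grids must be voxelwise-aligned (2 mm standard space assumed); a
grid mismatch is an error, not an implicit resample.

## Denoising ("preprocess-lite")

The package starts from motion/distortion-corrected standard-space 4D
data and applies: (1) confound regression (six motion parameters,
mean CSF/WM signals, and one-hot spike regressors for frames whose
framewise displacement exceeds 0.4 mm), (2) discrete-cosine high-pass
filtering with a 1/128 Hz cutoff (basis size
`floor(2·T·TR·cutoff) + 1` non-constant cosines; projection, hence
idempotent), (3) isotropic Gaussian smoothing at 5 mm FWHM with
kernel renormalization at the volume edge, and (4) a mean-FD < 0.3 mm
quality gate. FD uses Power-style backward differences with rotations
converted to arc length on a 50 mm sphere — the dominant convention;
the source protocol names FD but not the variant. Spikes are handled
as scrub regressors rather than interpolation so that timing structure
is preserved and despiking commutes with the other confounds.

## Group inference

Subject-level enriched-FC maps enter a voxelwise OLS GLM (intercept +
predictor of interest + nuisance covariates; continuous covariates
mean-centered, binary covariates left 0/1). The model menu mirrors the
emulated study: fatigue-score association with age, gender, LEDD and
eICV as nuisance; a sensitivity variant adding apathy (AES); a
no-LEDD variant for the dopamine system; group (fatigued vs not) and
depression/anxiety models built the same way. Each direction of
association is tested as its own one-sided contrast with its own FWE
correction, since the emulated findings are directional.

Inference is nonparametric. Freedman-Lane permutation: fit the
nuisance-only model, permute its residual rows, add the nuisance fit
back, recompute the full-model contrast t. The identity permutation
reproduces the observed map exactly, and for N ≤ 8 the engine can
enumerate all N! permutations, where its p-values are provably exact
against full enumeration.

T-maps are enhanced with threshold-free cluster enhancement:
`TFCE(v) = Σ_h e_h(v)^E · h^H · dh`, with the component size `e_h(v)`
taken over face-connected (C = 6) voxels and defaults H = 2, E = 2 —
the emulated study's settings (E = 2 differs from the common
volumetric default of 0.5; it weighs extent quadratically and is kept
as the replication default, configurable in `TFCEParams`). The
threshold step is `max/100` by default. Numerical choice: thresholds
sit at midpoints `h_i = (i − ½)·dh`, which matches the single-voxel
closed form `h_max^(H+1)/(H+1)` to second order in dh (a left-endpoint
rule is biased +1.5% at 100 steps). The production implementation is a
union-find sweep over descending thresholds (numba-compiled); it is
exactly equivalent to per-threshold connected-component labeling,
which is kept as the reference path and asserted equal in tests.

Familywise error is controlled by the permutation distribution of the
image-wide maximum TFCE value; `p(v) = (1 + #{null ≥ obs(v)}) /
(1 + n_perm)` with ≥ ties (conservative). With few permutations
(500 in replication runs) the attainable p floor is 1/501, so the
extreme tail can optionally be refined by fitting a generalized Pareto
distribution (maximum likelihood, exceedances over the null's 90th
percentile) to p-values at or below 0.10; an Anderson-Darling
goodness-of-fit check (parametric bootstrap, alpha 0.05) gates the
refinement, falling back to the empirical p on rejection and for
degenerate nulls. Fitted tails with negative shape have bounded
support; p-values beyond the bound are clamped strictly positive.

## Cluster reporting

Significant clusters are labeled by normalized overlap with a label
atlas: the share of the cluster's atlas-covered voxels falling in each
label, summing to 100% — the percentage style used for
functional-network reporting; normalization by label size is available
as an alternative. Atlases are user-supplied NIfTI + TSV (none is
bundled, for licensing hygiene); the analysis scripts build a
synthetic nearest-anchor parcellation. Per-subject cluster means feed
a partial correlation with the symptom score (covariate-adjusted
residualize-then-correlate); this is reported as an effect size only,
never as inference — selecting voxels by significance and then testing
them would be circular.

## Clinical statistics

Group comparisons follow a normality-routing rule: Shapiro-Wilk per
group at alpha 0.05; pooled-variance Student t when both groups pass,
Mann-Whitney U otherwise (greater-than pair counting with half-ties;
exact enumeration when n1·n2 ≤ 400 and tie-free), chi-square without
continuity correction for gender (Yates behind a flag). Pooled rather
than Welch t is deliberate: the published group statistics are
reproduced from printed summaries only under pooling (FSS −8.67, age
−2.16, PDSS-2 −0.33, ESS −0.90, HDS −3.47 against printed −8.66,
−2.16, −0.33, −0.90, −3.46). Two published values resist
recomputation and are excluded from any assertion: the gender
chi-square (printed 1.52; the printed 7/10 vs 10/8 counts give 0.72
uncorrected, 0.26 with Yates) and the MoCA t (printed −1.51 vs −1.54
from summaries, suggesting missing data). Correlations are
pairwise-complete Pearson; group tests are listwise.

## The synthetic cohort generator

The generator produces data with exactly the structure REACT assumes:

    y_v(t) = Σ_k m_k(v) · c_sk(v) · x_sk(t) + ε_v(t)

with templates `m_k`, subject/system AR(1) time series `x_sk` (lag-1
coefficient 0.5, unit innovation variance — the simplest
serial-correlation model consistent with rs-fMRI), white Gaussian
noise, and regional coupling `c_sk(v) = 1` except for one system in
one region, where `c = 1 + β·z(FSS_s)`. The planted quantity is the
coupling — the stage-2 estimand — so recovery is a direct test of the
full chain. β defaults to −0.8 (a strong negative standardized slope
of regional coupling on the fatigue score, the structure of the
emulated finding).

Defaults mirror the emulated cohort where stated: 35 subjects
(17 non-fatigued / 18 fatigued), four systems, TR 1.1 s, 500 volumes.
The grid defaults to 12×12×12 — a desk-scale stand-in for 2 mm
standard space chosen so the full validation battery runs in minutes;
validation runs use 60-100 timepoints for the same reason. Covariates
are truncated Gaussians matching the published per-group means, SDs
and ranges (FSS truncated to each group's range so the FSS > 4 label
is consistent by construction); gender is Bernoulli(0.5); motion is a
small random walk (0.02 mm / 0.0004 rad per step) that keeps mean FD
well under the 0.3 mm gate.

**Template geometry.** Each synthetic system occupies a compact smooth
support: a truncated quadratic bump at a distinct anchor (the first
four anchors form a tetrahedral arrangement), modulated by smoothed
Gaussian noise and rescaled to [0, 1]; a pairwise correlation cap of
0.5 is enforced by redraw. The compact distinct supports are a
deliberate idealization. With heavily overlapping templates, a
coupling modulation planted in one system cross-projects onto the
other systems' spatial regressors; the contaminated stage-1 series
then redistribute the effect in the joint stage-2 partialling, so the
planted effect bleeds into other systems' maps and into the opposite
contrast — a genuine identifiability limit of dual regression, not an
implementation artifact (it vanishes for orthogonal templates, which
tests verify indirectly). Real density templates are anatomically
distinct but far from orthogonal; passing the planted-effect suite
therefore demonstrates that the chain is correct and selective when
systems are identifiable, not that collinear real templates cannot mix
effects across systems.

What the generator does not emulate: hemodynamic response shape,
physiological (cardiac/respiratory) noise, spatial noise correlation,
scanner artifacts, and real anatomy. Passing tests show the estimators
and inference engine are correct under the model's own assumptions;
they do not certify behavior under real-data violations of those
assumptions.

## Validation battery (what the acceptance script recomputes)

* Published group t-statistics from printed summaries (exact
  arithmetic, no simulation).
* TFCE single-voxel closed form and brute-force oracle equivalence.
* GPD tail behavior on an exponential null (true 99.9th-percentile
  tail probability 0.001; median fitted value over seeds).
* Familywise error calibration: 200 null cohorts (N = 20, 12³, four
  systems, 250 permutations each); the familywise false-positive rate
  must sit in the 95% binomial band around 0.05.
* Planted-effect recovery: 10 cohorts at study conditions (N = 35,
  β = −0.8, noise SD 0.5); detection of a significant negative
  NET-analogue cluster with Dice ≥ 0.3 against the planted region in
  ≥ 8/10 seeds, with DAT/SERT analogues at chance, plus the
  cluster-mean partial correlation with FSS as the effect-size
  readout.

## Known limitations

* The 12³ grid and ≤ 100-timepoint runs are scaled-down conditions;
  absolute TFCE magnitudes are not comparable to full-resolution runs.
* The GPD goodness-of-fit bootstrap uses a fixed internal seed for
  determinism; its power at 199 replicates is modest.
* Exhaustive permutation is limited to N ≤ 8 (40,320 orderings).
* `run_models` runs systems and models serially; large menus at high
  resolution would need chunking or parallelism not provided here.
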