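# Methods

This note documents the models implemented in `rtbimr`, the defaults
and the reasoning behind them, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Hyperpolarized ¹³C CSI quantification

A CSI acquisition yields one spectrum per voxel on a 16×16 grid
(256 points, 5000 Hz sweep, i.e. a 19.53 Hz grid). The pipeline works
on the dynamic series summed over time frames: AUC quantification is
linear, so the summed spectrum carries the same integral information,
and a per-frame path is unnecessary for the metrics computed here.

Per voxel:

1. **Noise level** — SD of the outermost 32 spectral points (16 per
   edge), a signal-free region for any sensible peak placement. The
   window is configurable; there is no canonical definition of the
   noise region for this kind of data.
2. **AUC** — trapezoidal integral over each metabolite window
   (default ±5σ around the peak center). Negative integrals, which
   arise only in near-empty voxels, are clamped to 0.
3. **Noise normalization** — AUCs divided by the noise SD.
4. **Pyruvate/lactate fractions** — each divided by their sum, which
   cancels polarization and delivery differences between animals.
5. **Urea normalization** — voxel urea over the summed urea of
   voxels labeled *surrounding* (perfusion reference outside the
   brain).
6. **Lac/Pyr** — the plain ratio of the two AUCs (both the noise and
   the fraction normalization cancel in this ratio, so the choice of
   normalization cannot affect it).

**Voxel exclusion.** A voxel enters the regional means only if its
lactate+pyruvate AUC exceeds 5× the *noise-equivalent AUC*. Comparing
an integral directly with the per-point noise SD would be
dimensionally wrong: integrating pure noise over a window of width
W Hz on an h-Hz grid produces values with SD ≈ σ·√(hW) (≈ 76 σ for the
default windows), so the threshold is defined as 5·σ·√(hW). This keeps
empty voxels out without touching brain voxels at realistic SNR. The
multiplier is configurable.

Regional means are unweighted over the labeled voxels — no
partial-volume weighting, matching how coarse CSI grids are read in
practice. Heatmaps use bilinear interpolation to the anatomical
resolution; voxel-center values are preserved exactly and non-finite
voxels propagate as masked pixels.

Out of scope by design: spectral line-shape fitting, baseline or B0
correction, and kinetic (k_PL) modeling.

## Inversion-recovery T1 mapping

The magnitude signal of a fast-spin-echo inversion-recovery
acquisition is modeled with three parameters:

    y(t) = | M0 − (M0 − M(0))·exp(−t/T1) |

where M0 is the equilibrium longitudinal magnetization and M(0) the
effective magnetization immediately after inversion (−M0 for a perfect
inversion). The absolute value is fitted directly — no polarity
restoration pass — because scanner data are magnitude images.

Fitting is nonlinear least squares (trust-region reflective, relative
tolerances 1e−8, T1 bounded positive) from 8 starts: T1 ∈ {100, 300,
1000, 3000} ms crossed with both signs of the initial magnetization.
The multi-start matters: the absolute value makes the objective
multimodal, and single-start fits can lock onto the wrong inversion
polarity. The returned solution is the lowest-residual start; flat or
all-zero series are reported non-converged. Regional T1 means use
converged pixels only, and a region with under 50% convergence is
flagged unreliable.

On the study's 8-TI schedule (100–5000 ms) the estimator is unbiased
(median error < 0.1% at SNR 50 over 500 simulated pixels) and
efficient: its per-pixel dispersion matches the numerical Cramér–Rao
bound of the schedule (≈ 1.8% relative at SNR 100) to within a few
percent. Any tighter per-pixel precision claim would be incompatible
with the information content of an 8-point schedule; validation tests
therefore check unbiasedness plus CRB-level dispersion rather than an
arbitrary spread figure.

No B1/flip-angle correction or slice-profile modeling is attempted.

## SWI phase-mask processing

The chain is: unwrap → high-pass → positive phase mask → apply.

- **Unwrapping** uses a reliability-sorted (quality-guided) 2-D
  algorithm (`skimage.restoration.unwrap_phase`). Output is correct up
  to a global 2πk offset per connected region, which the subsequent
  high-pass removes.
- **High-pass**: φ − G(φ) with G a Gaussian low-pass. The stated
  32×32-pixel window is interpreted as the kernel span, with
  σ = 32/6 px so the window covers ±3σ. A constant slice maps to 0.
- **Positive phase mask**: φ_pos = (φ_max − φ)/φ_max where φ > 0 and
  1 where φ ≤ 0, with φ_max the slice maximum of the filtered phase.
  φ = 0 maps to 1, the limit of the positive branch, making the mask
  continuous; a slice with no positive phase yields an all-ones mask.
- **Application**: SWI = magnitude × mask⁴. "Multiplied four times"
  is read as the standard fourth-power masking, not an iterated
  re-masking scheme.

Regional SWI intensities are reported relative to the Sham-group mean
of each region (Sham ≡ 1). Minimum-intensity projections, venography
and QSM are out of scope.

## Region statistics

T2-weighted regional intensities are normalized to the mean
ventricular CSF signal; volumes are voxel count × voxel volume; group
comparisons use the unpaired two-sided Student t-test with pooled
variance (the common default when Welch correction is not specified),
reporting means ± SD, a fold change ≥ 1 with a lower/higher direction
flag, and the raw p-value. No multiple-testing correction is applied
by default (per-region raw p-values are the study-report convention);
a Benjamini–Hochberg helper is available. Masks are inputs — no atlas
registration or segmentation.

## ML stage

All operations are deterministic given a seed.

- **Scaling**: per-variable standardization over observed entries
  (population SD). Zero-variance columns are set to 0 and flagged.
- **Imputation**: within each group, mice with complete measurements
  train one random-forest regressor (100 trees) per missing-valued
  variable, predictors being all other variables; incomplete mice
  receive predictions (their own remaining gaps are filled with
  training means for the prediction input only). Observed cells are
  never altered. A group without complete rows falls back to
  group-mean imputation, flagged.
- **Feature scoring**: six methods — a single-hidden-layer perceptron
  (8 units, L2 1e−3, ≤2000 iterations, **lbfgs** solver: at n = 20 a
  stochastic solver leaves the input weights at their random
  initialization, making weight-based importances meaningless),
  logistic regression (|coef|), RFE with a logistic base estimator,
  ANOVA-F SelectKBest, extra-trees importance, and LASSO with its
  penalty chosen by leave-one-out CV on a fixed log grid
  (10⁻³…1, 10 points). Each method's absolute importances are scaled
  to [0, 1]; pooling is by **mean midrank** (robust to the methods'
  incomparable score scales; ties share midranks).
- **Triplet ranking**: all triplets from the top-10 pooled variables
  (120 candidates; exhaustive search over all C(44,3) available behind
  a flag) scored by leave-one-out accuracy of a logistic classifier on
  the 3 variables, ties broken by summed pooled importance; top 5
  reported. LOO is the natural choice at n = 20 where a held-out split
  would be unstable.
- **Predictor selection**: four regressors (LASSO with LOO-CV penalty,
  random forest, ridge, linear SVR) score candidate predictors;
  pooling as above. Candidate subsets grow down the pooled ranking and
  are evaluated by LOO mean absolute error of a ridge regression whose
  penalty is chosen by internal cross-validation (a fixed penalty
  would cripple the all-variable reference model and make the
  "matches the full model" criterion vacuous). The smallest subset
  within 10% of the all-variable LOO error is taken, followed by a
  backward minimality pass: members whose removal keeps the error
  within the same budget are dropped, worst-ranked first. Without this
  pass a chance-correlated variable ranked above a true predictor
  would force a strict superset.

At the cohort's own size (20 subjects, 44 variables) exact recovery of
a planted 4-variable regression is not identifiable — chance
correlations between pure-noise variables and the target reach
|r| ≈ 0.5, exceeding weak true signals — so planted-recovery
validation uses constructions where the problem is well-posed
(40 samples, 20 variables); permutation-null calibration is checked at
the small-n regime.

## The synthetic generator

The generator produces every input with known ground truth, as a pure
function of (spec, seed):

- **Feature tables**: 20 mice × 44 variables. Enzyme activities (PDH,
  LDH) and transporter expressions (MCT1, MCT4; relative scale,
  Sham ≡ 1) use the study's printed group means and per-group SDs.
  Values are drawn Normal(group mean, group SD), independently across
  variables within a subject; within-subject correlation between
  modalities is not modeled beyond the shared group effect.
  Missingness is block-wise by assay, mirroring its physical cause:
  the same mice lose all PDH variables (2 rTBI + 2 Sham), the same
  mice lose the LDH/MCT block (3 + 3, rTBI count configurable to 4),
  and one rTBI mouse loses the HP imaging variables.
- **CSI phantoms**: Gaussian peaks (σ 30 Hz) at −1000/0/+1000 Hz for
  urea/pyruvate/lactate — arbitrary disjoint placements, configurable,
  since no chemical-shift axis is modeled — on the region layout
  cortex band / subcortical core / surrounding ring / background, plus
  additive Gaussian noise (SD 0.05 against cortical peak amplitudes
  summing to 6). The cortical group effect is encoded in the lactate
  fraction of the lactate+pyruvate amplitude: the configured folds
  (lactate 1.09 Sham/rTBI, pyruvate 1.05 rTBI/Sham) uniquely determine
  both groups' fractions because fractions must sum to 1, giving
  0.3772 (Sham) and 0.3460 (rTBI) and implying a Lac/Pyr fold of
  exactly 1.09 × 1.05 = 1.1445. A log-normal per-subject scale
  (σ = 0.2) emulates polarization/delivery variation and cancels in
  all normalized metrics; a small per-metabolite log-normal jitter
  (σ = 0.05) adds biological variability. Subcortical folds default
  to 1 (no effect). Risk-taking behavior (EPM open+center duration)
  defaults to 1.5× higher in rTBI with 20% CV; remaining behavioral,
  structural and relaxometric variables carry plausible preclinical
  values with no group effect.
- **IR stacks**: the three-parameter magnitude model evaluated on the
  8-TI schedule plus Gaussian noise, re-magnituded (absolute value) so
  emitted series are non-negative like scanner data. Rician noise is
  available but off by default — at the SNRs of interest the
  difference is negligible away from the null point.
- **SWI phantoms**: Gaussian phase bumps (σ = radius/2) on a magnitude
  image, optionally wrapped to (−π, π], with the unwrapped truth
  retained.

What the generator does **not** emulate: k-space acquisition, coil
sensitivities, Bloch dynamics, pyruvate delivery kinetics, spatial
noise correlation, motion, or partial-volume mixtures at region
boundaries. Passing tests therefore demonstrate that the analysis
chain is correct and calibrated under idealized signal models — not
that it is robust to every artifact of real scanner data.

## Validation problem sizes

The effect-recovery study uses 200 simulated cohorts of 10+10 mice
(seeds base…base+199); with per-cohort ratio SD ≈ 0.04 the standard
error of the reported mean fold is ≈ 0.003, an order of magnitude
inside the ±0.02 comparison band. T1 recovery uses 500 simulated
pixels; t-test calibration 10⁴ null draws; ML calibration 10 planted
seeds per task and 100 label permutations for the nulls. These sizes
were chosen so Monte-Carlo error is small against each check's
tolerance.

## Known limitations

- The 2-D unwrapper handles smooth phantom phase well; heavily aliased
  or low-SNR phase (where PRELUDE-class spatial unwrapping also
  struggles) is untested.
- Lac/Pyr ratios are mildly noise-biased (ratio of noisy quantities);
  at the default SNR the bias is ≪ the 0.02 validation band and
  cancels between groups.
- The triplet search space is the top-10 pooled variables; a variable
  useful only in combination (and invisible to every marginal scorer)
  could be missed unless the exhaustive flag is used.
- Fold changes of near-zero means are unstable; the study-report
  rounding (2 significant figures) is only applied to reported values,
  never to intermediate computation.
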