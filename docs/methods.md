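# Methods

This note documents the models, conventions and design choices behind
`adcsurv`: what each stage computes, which knobs matter, what the
synthetic cohorts do and do not emulate, and where the design was
genuinely open.

## ADC maps and preprocessing

The diffusion signal is modelled as monoexponential,
S_b = S₀·exp(−b·ADC), so the voxelwise estimate from a b=0 / b>0 pair is
ADC = ln(S₀/S_b)/b in mm²/s. Voxels where the pair is non-physical
(S_b > S₀, or a non-positive signal) are noise-dominated; they are set
to ADC = 0 and removed from the validity mask rather than left to
inflate the histogram tails. Their count is recorded in the map's
processing record.

Brain extraction is deliberately simple: threshold at a fraction
(default 0.5) of the robust maximum (99.5th percentile) of the b=0
volume, keep the largest 26-connected component, fill interior holes.
On synthetic phantoms this is exact; on real data users can supply
their own mask (provenance tag `supplied`), which is still eroded and
intersected with the validity mask. A surface-deformation extractor is
out of scope.

The mask is then eroded three times with a 3×3×3 box structuring
element — the default kernel of the standard FSL-style erosion — to
trim partial-volume voxels at the brain surface. Erosion is
anti-extensive and monotone in the iteration count; both properties are
tested.

"Standardization" is implemented as intensity/unit standardization
(method `physical`, the default): canonical units, exclusion of
non-finite voxels, clipping of in-mask values to [0, adc_max] with
adc_max = 4×10⁻³ mm²/s (free water at body temperature is ≈3×10⁻³; the
margin absorbs noise). The operation is idempotent and records its clip
counts. A `reference-scale` method (divide by a cohort reference value)
is provided for normalized-ADC workflows. Spatial (template)
standardization is a different reading of the term; it is deliberately
not implemented, and the method field keeps the choice explicit in
every output.

## Histogram metrics

Seven first-order statistics of the in-mask ADC sample per visit:

| metric | convention | default |
|---|---|---|
| skewness | Fisher–Pearson g₁ = m₃/m₂^{3/2} (biased moments) | — |
| kurtosis | Pearson m₄/m₂² (non-excess) | — |
| entropy | −Σ pᵢ ln pᵢ over a fixed-range histogram | 128 bins, [0, 4×10⁻³] |
| median, p15, p85 | linear-interpolation percentiles of the raw sample | — |
| mode | centre of the most populous bin, ties to the lower bin | same binning |

Percentiles are computed on the unbinned sample so the headline
median/p85 statistics carry no binning bias. The fixed histogram range
makes entropy comparable across visits and subjects; empty bins
contribute zero. Kurtosis is reported non-excess because the constant
−3 offset cannot change the sign of a fitted slope, which is the only
quantity consumed downstream; the convention is echoed in output
metadata rather than asserted as canonical. The minimum in-mask sample
size defaults to 1000 voxels; smaller samples and zero-variance samples
are rejected.

## Slopes and directionality

Per subject and metric, a simple OLS slope of metric value against days
from inclusion (closed form; at least three visits, strictly increasing
days). The regression slope directionality (RSD) is the slope's sign,
coded positive = 1 / negative = 0 as the Cox covariate — so a hazard
ratio above 1 reads "positive slope is worse". An exact-zero slope has
measure zero on continuous data; it is classified positive and counted
in a warning tally rather than given a third class. Directionality is
invariant to the time unit and to additive shifts of the metric; both
are property-tested. No robust or weighted regression is used: the
estimand is plain linear regression, unqualified.

## Survival chain

**Univariate Cox screening.** Each covariate is fit by Newton–Raphson
on the Cox partial likelihood with Efron tie handling (day-resolution
times produce ties; Efron is the default of the major survival
environments). Reported statistics are Wald: CI = exp(β ± 1.96·se),
two-sided normal p. Covariates with p strictly below the threshold
(default 0.1) are screened in, per endpoint. Monotone likelihood
(complete separation) is detected by coefficient divergence and raised
as an error naming the covariate. The engine is validated against
brute-force risk-set enumeration (≤8 subjects, 10⁻¹⁰), against an
independent implementation (lifelines) with and without ties, and by a
500-replicate null simulation (type-I error within binomial 99% bounds).

**Farrar–Glauber diagnostics.** On the n×p RSD design with correlation
matrix R: overall χ² = −[n−1−(2p+5)/6]·ln det R on p(p−1)/2 df;
per-variable Fᵢ = (R⁻¹ᵢᵢ−1)(n−p)/(p−1) on (p−1, n−p) df; partial
correlations rᵢⱼ = −R⁻¹ᵢⱼ/√(R⁻¹ᵢᵢR⁻¹ⱼⱼ) tested with
t = r√((n−p)/(1−r²)) on n−p df. A singular R (possible in noiseless
synthetic cohorts, where several RSDs are deterministic functions of
the same planted mechanism) is reported as a degenerate diagnostic with
the collinear columns named; the pipeline continues, because the test
is a diagnostic, not a gate.

**Adaptive LASSO.** Weights wⱼ = 1/|β̂ⱼ|^γ (γ = 1) come from a
ridge-stabilised Cox fit (default ridge 0.1): the screened RSDs are
collinear by construction, so the unpenalised MLE is too unstable to
weight with. The weighted-L1 problem is solved on the column-rescaled
design by proximal Newton with cyclic coordinate descent over a
40-point log-spaced λ grid (λ_max down to 10⁻³·λ_max) with warm starts.
λ is chosen to maximise the Verweij–van Houwelingen cross-validated
partial likelihood, cvl = Σ_k [l(β₋ₖ) − l₋ₖ(β₋ₖ)], over a seeded
5-fold split — 10-fold is unstable at n ≈ 43. Ties in cvl go to the
larger (sparser) λ. Nonzero coefficients define the selection; each
selected covariate is reported through an unpenalised univariate Cox
refit (penalised coefficients are biased toward zero and the selected
covariates are reported individually). The λ→0 limit equals the MLE to
solver tolerance (tested), and selection behaviour is benchmarked
against a brute-force all-subsets partial-likelihood-AIC oracle.
If every coefficient is shrunk to zero the selection is empty with a
warning, not an error.

**MGMT and treatment.** MGMT methylation and treatment arm are screened
univariately; MGMT is excluded from the multivariable selection
whenever it is missing for any subject (univariate fits use complete
cases), with the exclusion logged. Treatment enters screening like any
covariate.

**Kaplan–Meier.** Product-limit estimator per stratum; Greenwood
variance on the log-survival scale with the log-transformed CI
S·exp(±1.96·se), clipped to [0, 1] and collapsed to [0, 0] once S = 0;
median survival is the smallest event time with S ≤ 0.5, reported as
not-reached (NaN) otherwise. Checked against hand calculations, the
empirical survival function (no censoring), and lifelines.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets: 43
subjects, 3–10 visits at 60 ± 10 day intervals, paired b=0 / b=1000
volumes, MGMT missing in 7 subjects, 17 on TTFields.

**Anatomy.** A brain ellipsoid (semi-axes 0.45× the grid) with five
compartments as nested ellipsoids: white matter 0.70, grey matter 0.88,
tumor 1.05, edema 1.40, CSF 3.00 (×10⁻³ mm²/s), at core volume
fractions 0.52/0.25/0.05/0.12/0.06 with per-voxel Gaussian texture that
is fixed per subject. The outer ~4 voxels of the brain are a
sacrificial white-matter rind consumed by the triple erosion, so the
compartment fractions hold inside the analysed core at any grid
resolution. The fractions place the histogram median inside the
white/grey bulk and p85 inside the edema mass (cumulative fraction
below edema ≈ 0.82). Compartment means are jittered ±3% per subject.

**Signal and noise.** S_b = S₀·exp(−b·ADC) with b = 1000 s/mm²; Rician
noise (magnitude of the signal plus complex Gaussian noise, the MR
magnitude statistics) applied independently to both volumes at
σ = 0.03 × the median brain S₀ by default.

**Planted drift.** Three independent per-subject mechanisms, each a
random sign times a jittered rate:

- *tissue shift* — white+grey mean ADC ± 3×10⁻⁷ mm²/s per day; drives
  the median (and mode);
- *edema shift* — edema mean ± 1×10⁻⁶ per day; drives p85;
- *lower-tail stretch* — sub-mean white-matter texture scaled by
  exp(±0.006·day) (exponent capped at ±2.5); drives p15, skewness and
  entropy. Because it is a monotone transform of the sub-median values
  only, every quantile above the white peak — the median in
  particular — is exactly invariant under it.

Without the third mechanism the seven RSDs collapse onto two planted
bits, the RSD correlation matrix is singular and covariate selection is
unidentifiable; with it, the RSD correlation structure is strong but
full-rank, which is also what makes the multicollinearity diagnostics
meaningful.

**Survival.** PFS is exponential proportional hazards on the planted
median-drift sign and MGMT (defaults: log HR ln 3.3 and ln 0.42,
baseline median ≈ 350/ln2 days). OS = PFS plus a post-progression
exponential residual (mean 450 days) whose rate carries the p85-drift
sign and MGMT effects (ln 0.29, ln 0.30); the sum construction enforces
PFS ≤ OS, and at these defaults the *total*-OS univariate hazard ratio
for the p85 sign works out to ≈ 0.32. A single follow-up censoring time
per subject (exponential, scaled for a 15% censoring fraction) is
applied to both endpoints, which keeps observed PFS ≤ observed OS. The
planted sign proportions default to 20/43 positive-median and 32/43
positive-p85.

**Ground truth.** The manifest stores, per subject, the slope sign of
each metric computed from the noiseless ADC fields (true field, mask
extracted from the noiseless b=0 volume and triple-eroded), the planted
covariates, and the pre-censoring event times. With zero noise the
full pipeline — synthesis, reconstruction, masking, metrics, slopes —
reproduces the manifest signs exactly; this is an acceptance test.

**What the generator does not emulate.** Real anatomy and its
variability, inter-visit registration error, scanner/vendor effects,
motion/eddy artifacts, multi-b-value decay, non-proportional hazards,
informative censoring, and visit schedules coupled to progression.
Passing tests demonstrate that the statistical chain recovers planted
effects under the stated signal model — not that those effects exist in
any clinical population.

## Problem sizes and test conditions

Replicate studies (tests and the acceptance script) run on a
32×32×20 grid at 4×4×6 mm voxels: the smallest grid that leaves
comfortably more than the 1000-voxel minimum inside the triple-eroded
mask, chosen so 50-replicate end-to-end studies complete in minutes.
The single-cohort default is 48×48×24.

End-to-end selection recovery is evaluated on a dedicated
mechanism-validation configuration (`synthetic.recovery_condition`):
one prognostic metric per endpoint, balanced drift signs, hazard ratios
6 and 1/6, no censoring, a short progression timescale so OS is
dominated by its covariate-dependent phase, and a median drift kept
below ~1.5 histogram bins so the bin-quantised mode is not a
deterministic copy of the median mechanism. At the default study
condition (HR 3.3 at n = 43 with a 32/11 sign imbalance and censoring)
the selection problem is underpowered and partly unidentifiable, so
recovery *rates* are reported there as informative quantities
(`scripts/acceptance.py`) while the ≥90% recovery requirement is tested
under the identifiable design.

## Numerical choices

- Newton–Raphson with step halving; convergence on the max gradient
  component relative to |loglik|, tolerance 10⁻¹⁰; separation flagged
  at |β| > 15.
- The partial-likelihood evaluator uses reverse cumulative sums with a
  vectorised path when event times are untied (Efron = Breslow there)
  and an exact Efron group loop otherwise; the log-sum-exp shift guards
  overflow.
- Proximal-Newton L1 solver: coordinate-descent inner loop on the local
  quadratic model, line search on the true penalised objective,
  curvature regularised by 10⁻¹⁰·I; selection threshold 10⁻⁸ on the
  original coefficient scale; adaptive weights capped via
  |β̂| ≥ 10⁻⁸.
- Exact-zero slopes, empty-bin entropy terms, mode ties, S = 0 KM tails
  and all-censored strata each have a defined, tested behaviour (see
  the relevant sections above).
- All randomness flows from explicit integer seeds; cohort generation
  spawns per-subject substreams from a root `SeedSequence`, so cohorts
  are bit-reproducible and independent of evaluation order.

## Known limitations

- Brain extraction is threshold-based and untested on real heads; real
  studies should supply masks from a dedicated tool.
- The adaptive-LASSO CV criterion can legitimately return an empty
  selection on weak cohorts; callers must treat "nothing selected" as a
  valid outcome.
- Wald intervals at n ≈ 43 with few events are approximate;
  profile-likelihood intervals are not implemented.
- The generator's drift mechanisms are linear (or log-linear) in time;
  changepoint-like progression dynamics are out of scope, as is any
  per-timepoint prognostic evaluation.
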