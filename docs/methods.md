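# Methods

## Segmentation model

The volumetry rule is intentionally minimal: after voxelwise averaging of
the repeated measurements (inputs are assumed motion-corrected and
spatially aligned; registration is out of scope), signal intensity is
modelled only through the reference-region statistics.  Both
cerebral-peduncle ROIs are pooled into a single voxel set — the procedure
is described in terms of "the reference ROIs" without a per-side recipe,
and pooling is the simplest choice consistent with that.  The SD uses the
sample (n−1) estimator by default; a population option exists because the
estimator is not fixed by the procedure (at realistic reference sizes of
10³–10⁴ voxels the difference is far below every other noise source).

A voxel is labelled when its intensity is *strictly greater* than
μ_ref + k·σ_ref ("greater" read literally; ties at the exact threshold are
excluded, which matters only in degenerate synthetic images, e.g. σ_ref = 0,
where every mask voxel strictly above the mean counts).  Thresholding is
restricted to the anatomical mask binarised at probability ≥ 0.5 by
default (configurable; the gating of atlas probabilities is not specified
anywhere authoritative).  No connected-component or cluster-size filter is
applied: the rule is pure thresholding.  Intensities are arbitrary scanner
units and are never normalised; the segmented voxel *set* is invariant
under any positive affine intensity transform of the whole image because
the threshold transforms identically.

Consequences worth knowing: on pure noise the expected suprathreshold
fraction inside a mask of m voxels is the Gaussian tail 1 − Φ(k)
(≈ 0.00199 at k = 2.88, ≈ 0.00508 at k = 2.57), so a mask of ~10³ voxels
carries a false-positive "floor" of a few voxels; real volumes are always
measured above that floor.  The k multipliers are the established values
for this acquisition and are not re-derived here.

## Autonomic classification

All boundary comparisons are inclusive (≥), exactly as each criterion is
stated.  "Sustained fall within 3 minutes" is operationalised from the two
discrete readings as *any* qualifying fall at minute 1 or minute 3; the
stricter reading (must qualify at minute 3) is available as
`require_minute3`.  The neurogenic HR/SBP ratio is (mean of per-minute
ΔHR) / |mean of per-minute ΔSBP| — averaging the changes, not the
per-minute ratios, which are unstable when a minute's ΔSBP is near zero.
Under a pressor response (mean ΔSBP ≥ 0) the ratio is undefined and the
criterion is simply not met rather than an error: such subjects are
ordinary (−)OH.  MAP uses the standard clinical estimate (SBP + 2·DBP)/3.
Missing standing timepoints are excluded from averages; a subject with no
standing data cannot be labelled and is excluded from stratification with
a logged warning.

A useful consequence of the inclusive boundaries: with all three
timepoints present, a mean SBP fall ≥ 30 forces at least one per-minute
fall ≥ 30 ≥ 20 (pigeonhole), so the large-fall criterion can never hold in
a subject classified as having no OH.  This is asserted as a property test.

## Statistical battery

Implemented from first principles (scipy supplies only midranks and the
normal/χ²/t/F reference distributions):

* **Mann-Whitney U** — reported statistic is min(U₁, U₂), the common
  reporting convention.  In `auto` mode the p-value is exact by full
  enumeration of the U null distribution (classic two-index recurrence)
  when n₁·n₂ ≤ 400 and the data are tie-free; otherwise a tie-corrected
  normal approximation with continuity correction.  Two-tailed p is twice
  the lower-tail mass, capped at 1.
* **Kruskal-Wallis** — tie-corrected H against χ²(k−1); an all-tied sample
  carries no information and returns H = 0, p = 1.
* **Dunn post hoc** — pairwise z on pooled mean ranks with the pooled tie
  correction; both the mean-rank difference and z are reported, and the
  family-wise correction across the pairs tested is Bonferroni (no
  specific FWE method is prescribed by the plan being mirrored).
* **Quade's ANCOVA** — response and covariates are midranked across all N;
  response ranks are regressed (least squares with intercept) on covariate
  ranks; the residuals enter a one-way ANOVA with df (k−1, N−k), following
  Quade (1967).  Categorical covariates (scanner protocol, RBDSQ group)
  enter as ranked integer codes.  Constant covariates are dropped with a
  note (zero rank information); collinear covariate ranks are a hard
  error.  A numerically saturated regression (covariate ≡ response) is
  detected by comparing the residual sums of squares against 1e−12 of the
  total rank variation and returns F = 0.
* **Spearman** — Pearson correlation of midranks, two-tailed p from the t
  approximation on n−2 df (exact permutation p is not used; at the n of
  interest the approximation is standard), |rho| = 1 mapped to p = 0,
  constant input flagged undefined.
* **BH-FDR** — step-up with enforced monotonicity; Bonferroni as min(1, m·p).

Type-I calibration of the whole battery is measured, not assumed: under
seeded Gaussian nulls (2000 replicates, n = 60) each test's rejection rate
at α = 0.05 must land in [0.04, 0.06].

## Pipeline conventions

Post hoc Dunn tests run only when the omnibus is significant at α (the
plan's explicit handling of the null SNc omnibus); a config flag overrides
the gate.  The correlation battery's FDR family is *all* stratum × variable
pairs computed in a run — the family definition is otherwise open, and one
family is the conservative, reproducible choice.  Sensitivity analyses
re-run every fragment with tagged subjects censored and define a "flip" as
a raw p crossing α in either direction (or a comparison appearing/
disappearing, e.g. when censoring empties a stratum).  Empty or under-sized
strata always produce warnings and skips, never silent omission or a
crash.  A full run is deterministic for a fixed cohort and config; the
report carries no timestamps.

## Synthetic data: what it emulates and what it does not

**Phantoms** are Gaussian noise fields at NM-MRI geometry (0.39 × 0.39 ×
3 mm voxels) with constant-intensity ellipsoidal blobs at a stated contrast
in SD units.  Gaussian rather than Rician noise: at the signal levels of
brainstem tissue in this acquisition the Rician distribution is
indistinguishable from Gaussian.  Blob intensity has no partial-volume
ramp, which is what makes ground-truth voxel counts exact — the point of
the phantom is an exact oracle, not scanner realism.  Target masks are
binary (probability 1 on the blob dilated by a configurable margin) since
no atlas probabilities exist for an invented object; the segmentation
itself accepts fractional masks.  Half-integer blob centers are how exact
even-sized voxel counts are arranged (e.g. a 2 × 2 × 3 block of 12 voxels).
Phantoms do not emulate MT contrast physics, B1 inhomogeneity, motion, or
registration error.

**Cohorts** draw subgroup volumes from a lognormal family by default —
published subgroup summaries have SDs comparable to their means (LC
4.07 ± 3.53 mm³ and similar), which forces a nonnegative right-skewed
family; truncated-normal is available.  The default spec uses the four
published subgroup summaries at sizes 52/19/7/12.  (The printed PD
whole-group LC summary is mutually inconsistent with the printed subgroup
summaries; the defaults follow the subgroup values and treat neither as
ground truth.)  (+)OH subgroups stand with a mean SBP fall of 35 mmHg
(SD 5) and blunted HR response so the classifier recovers the designed
labels in expectation; (−)OH subgroups fall 5 mmHg with brisk HR.  Standing
minutes are i.i.d. around subgroup means — three timepoints give no
purchase for an autocorrelation model.  The volume-to-ΔMAP coupling shifts
standing SBP and DBP jointly by slope × (LC − subgroup location), which
shifts MAP by exactly that amount; it can be confined per subgroup.
Readings are clipped to physiological order (SBP > DBP > 0), which is only
active in extreme tails at the default parameters.

`headline_cohort_spec` encodes the designed qualitative pattern used for
end-to-end validation: LC elevated by 1.5 SD in PD(−)OH over a common base
(mean 3.0, SD 2.5 mm³), one common SNc distribution, and coupling slope
1.5 mmHg/mm³ in (+)OH subgroups only (chosen so that the induced
correlation is strong at n ≈ 12–20 without being deterministic).

Passing tests on these cohorts show the *pipeline* recovers effects of the
designed shape and size at the study's group sizes; they say nothing about
scanner-specific segmentation accuracy, real orthostatic physiology
(medication effects, measurement error, within-visit correlation), or the
clinical truth of any specific published estimate.

## Problem sizes and numerical choices

The validation suite uses 50 noise phantoms × 10,000-voxel masks for
false-positive calibration (99% binomial bounds), 100 phantoms for volume
recovery (mean absolute voxel error ≤ 1 at 6-SD contrast), 2000 null
replicates at n = 60 for type-I rates, and 100 simulated cohorts for
pattern recovery — sizes at which the measured quantities have comfortably
smaller Monte-Carlo error than the bounds they are checked against, while
the whole suite runs in seconds.  Exact identities (volume = count ×
voxel volume; enumeration vs recurrence Mann-Whitney p) are asserted to
machine precision (≤ 1e−12); algebraic identities routed through floating
point (H = z², Quade ↔ rank ANOVA) to 1e−10.

## Known limitations

* No registration, motion correction, or atlas construction: inputs must
  be pre-aligned, and mask/image shape mismatches are hard errors.
* The exact Mann-Whitney path requires tie-free data; tied samples always
  use the corrected normal approximation.
* Quade's residual ANOVA df (k−1, N−k) ignores the covariate degrees of
  freedom, as in the original procedure; its null calibration is verified
  empirically rather than claimed exactly.
* The cohort generator models neither missing vitals patterns nor
  medication effects; censor tags are assigned labels, not mechanisms.
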