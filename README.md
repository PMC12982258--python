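# nmoh

Neuromelanin-MRI brainstem volumetry and orthostatic-hypotension phenotyping
for parkinsonian-disorder cohorts.

Parkinson's disease (PD) and multiple system atrophy (MSA) both degrade the
locus coeruleus (LC), the pontine noradrenergic nucleus visible as a
hyperintensity on neuromelanin-sensitive MRI, and both can cause orthostatic
hypotension (OH).  Relating LC (and, as a specificity control, substantia
nigra pars compacta, SNc) volume to orthostatic hemodynamics requires three
pieces of machinery, which this package provides as a tested, reusable
pipeline for imaging and autonomic researchers:

1. **Reference-ROI threshold segmentation** (`nmoh.segmentation`): repeated
   gradient-echo measurements are averaged voxelwise; the mean μ and
   standard deviation σ of signal intensity are computed over two pooled
   cerebral-peduncle reference ROIs; voxels inside a probabilistic
   anatomical mask whose intensity exceeds μ + kσ are labelled target
   tissue (k = 2.88 for LC, k = 2.57 for SNc); volume = voxel count ×
   voxel volume (0.39 × 0.39 × 3 mm³ = 0.4563 mm³ by default).
2. **Rule-based autonomic classification** (`nmoh.autonomic`): from supine
   and minute-1/3/5 standing vitals, classic OH (SBP fall ≥ 20 and/or DBP
   fall ≥ 10 mmHg within 3 min), delayed OH (qualifying fall only at
   minute 5), neurogenic qualification (mean ΔHR/|mean ΔSBP| ≤ 0.5 or mean
   SBP fall ≥ 30 mmHg), supine hypertension (≥ 140/≥ 90 mmHg), and
   MAP = (SBP + 2·DBP)/3.
3. **A first-principles nonparametric battery** (`nmoh.stats`):
   Mann-Whitney U (exact by enumeration at small n), Kruskal-Wallis with
   Dunn post hoc z tests, Quade's rank ANCOVA, two-tailed Spearman,
   chi-squared, Welch's t, Bonferroni and Benjamini-Hochberg adjustment.

`nmoh.pipeline` chains these into the full analysis plan (primary PD vs MSA
comparisons, OH-stratified subgroup comparisons with gated post hoc tests,
covariate-adjusted sensitivity analyses, a FDR-controlled correlation
battery, and censoring-based sensitivity re-runs), and `nmoh.phantom` /
`nmoh.cohort` generate synthetic phantoms with exact ground-truth volumes
and simulated cohorts with configurable volume-to-ΔMAP coupling, so every
stage is testable without any imaging download.

## Worked example

Simulate a cohort at study-scale subgroup sizes (52/19/7/12 before label
noise) carrying a designed LC elevation in PD without OH, no SNc effect,
and LC-to-MAP coupling in the (+)OH subgroups only; then run the full plan:

```python
from nmoh import PipelineConfig, run_full_analysis
from nmoh.cohort import generate_cohort, headline_cohort_spec

cohort = generate_cohort(headline_cohort_spec(seed=42))
report = run_full_analysis(cohort, PipelineConfig(seed=42))

print("subgroup sizes:", report.subgroup_sizes)
lc = report.subgroup_comparisons["LC"]
print(f"LC omnibus H = {lc['omnibus'].statistic:.2f}, p = {lc['omnibus'].p_raw:.2e}")
for tr in sorted(lc["posthoc"], key=lambda t: t.p_raw)[:3]:
    print(f"  Dunn {tr.notes['pair'][0]} vs {tr.notes['pair'][1]}: z = {tr.statistic:.2f}, "
          f"p = {tr.p_raw:.4g}, Bonferroni p = {tr.p_adjusted:.4g}")
snc = report.subgroup_comparisons["SNc"]
print(f"SNc omnibus H = {snc['omnibus'].statistic:.2f}, p = {snc['omnibus'].p_raw:.3f} "
      f"(post hoc {'run' if snc['posthoc'] else 'skipped'})")
for cr in report.correlations:
    if cr.pair[1] == "avg_delta_map" and "(+)" in cr.pair[0]:
        print(f"rho(LC, avg dMAP) in {cr.pair[0]}: {cr.rho:.2f} "
              f"(FDR p = {cr.p_adjusted:.3f}, n = {cr.n})")
```

Output:

```text
subgroup sizes: {'PD(-)OH': 50, 'PD(+)OH': 21, 'MSA(-)OH': 7, 'MSA(+)OH': 12}
LC omnibus H = 39.95, p = 1.09e-08
  Dunn PD(-)OH vs PD(+)OH: z = 5.03, p = 4.785e-07, Bonferroni p = 2.871e-06
  Dunn PD(-)OH vs MSA(+)OH: z = 4.30, p = 1.679e-05, Bonferroni p = 0.0001007
  Dunn PD(-)OH vs MSA(-)OH: z = 3.37, p = 0.0007622, Bonferroni p = 0.004573
SNc omnibus H = 5.65, p = 0.130 (post hoc skipped)
rho(LC, avg dMAP) in PD(+)OH: 0.90 (FDR p = 0.000, n = 21)
rho(LC, avg dMAP) in MSA(+)OH: 0.50 (FDR p = 0.257, n = 12)
```

Reading: subgroup sizes are the classifier's labels, so they wobble around
the generating sizes; the LC Kruskal-Wallis omnibus is strongly significant
and the three smallest Dunn pairs are exactly the PD(-)OH contrasts; the
SNc omnibus is null, so its post hoc tests are skipped by the gate; the
designed positive volume-fall coupling is recovered in both (+)OH strata
(at n = 12 the MSA stratum shows the right sign but, as expected at that
size, does not always survive FDR).

The same run is available from the shell:

```sh
nmoh simulate cohort --seed 7 --out cohort.csv   # default: published subgroup summaries
nmoh classify --cohort cohort.csv --out labelled.csv
nmoh analyze --cohort cohort.csv --out report/
nmoh simulate phantom --config phantom.yaml --seed 1 --out phantom/
nmoh segment --image phantom/meas_00.nii.gz --ref-left phantom/ref_left.nii.gz \
  --ref-right phantom/ref_right.nii.gz --lc-mask phantom/lc_mask.nii.gz \
  --snc-mask phantom/snc_mask.nii.gz --out seg.csv
```

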