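# adcsurv

Longitudinal whole-brain ADC histogram analysis for survival studies in
glioblastoma.

Glioblastoma patients under standard therapy are followed by MRI every
couple of months until progression. Because the tumor infiltrates far
beyond its visible margins, region-of-interest measurements are
subjective and often infeasible late in treatment; a whole-brain summary
of the apparent diffusion coefficient (ADC) map sidesteps both problems.
`adcsurv` implements that analysis end to end, for researchers who have
paired b=0 / b=1000 s/mm² diffusion-weighted volumes at three or more
visits per subject and progression-free (PFS) / overall survival (OS)
outcomes:

1. **ADC maps** — voxelwise ADC = ln(S₀/S_b)/b, brain extraction on the
   b=0 volume, triple 3×3×3 box erosion of the mask, and intensity
   standardization with physical clipping to [0, 4×10⁻³ mm²/s].
2. **Histogram metrics** — seven first-order statistics of the in-mask
   ADC distribution per visit: skewness, kurtosis, entropy, median,
   mode, 15th and 85th percentiles (p15, p85).
3. **Regression slope directionality (RSD)** — per subject and metric,
   the sign of the OLS slope of the metric against days from inclusion;
   a binary biomarker (positive = 1, negative = 0).
4. **Survival chain** — univariate Cox screening of each RSD (Efron
   ties, Wald statistics, keep p < 0.1), the Farrar–Glauber
   multicollinearity test with partial correlations, adaptive-LASSO Cox
   selection (weights wⱼ = 1/|β̂ⱼ|ᵞ from a ridge-stabilised fit, λ by
   seeded 5-fold cross-validated partial likelihood), unpenalised refits
   of the selected covariates, and Kaplan–Meier curves with Greenwood
   95% CIs and median-survival markers.

Because no patient imaging is distributable, the package ships a
first-class synthetic-cohort generator (`adcsurv.synthetic`): seeded
longitudinal DWI volume pairs with compartmental ADC structure, Rician
magnitude noise, planted histogram-metric drifts, and survival outcomes
whose hazards depend on the planted drift directions — so every stage
of the pipeline can be validated against known ground truth.

## Worked example

```python
import numpy as np
from adcsurv import (CohortConfig, generate_cohort, preprocess_pair,
                     compute_metrics, SubjectSeries, SurvivalTimes,
                     rsd_table, run_endpoint_analysis, AnalysisConfig)

cfg = CohortConfig(n_subjects=43, grid_shape=(32, 32, 20), seed=5)
subjects, truth = generate_cohort(cfg)

cohort = []
for s in subjects:
    metrics = tuple(compute_metrics(preprocess_pair(p)) for p in s.pairs)
    cohort.append(SubjectSeries(
        subject_id=s.subject_id, days=s.days, metrics=metrics,
        survival=SurvivalTimes(s.pfs_days, s.pfs_event, s.os_days, s.os_event),
        mgmt=s.mgmt, treatment=s.treatment))

design = rsd_table(cohort)
report = run_endpoint_analysis(design, "PFS", AnalysisConfig(seed=1))
print("screened:", report.screened)
print("selected:", report.alasso.selected)
r = report.alasso.refits["median_rsd"]
print(f"median RSD: HR {r.hr:.2f} ({r.ci_lower:.2f}-{r.ci_upper:.2f}), "
      f"p = {r.p_value:.4f}")
```

Output from this exact script (seeds as shown):

```
screened: ('median_rsd', 'mode_rsd')
selected: ('median_rsd',)
median RSD: HR 3.31 (1.66-6.62), p = 0.0007
```

Reading: two of the seven RSD covariates pass the univariate p < 0.1
screen; the adaptive LASSO reduces them to the median-slope
directionality alone, and the unpenalised refit estimates that subjects
whose whole-brain median ADC drifts upward progress at ~3.3 times the
hazard of subjects whose median drifts down — the hazard ratio the
generator planted on exactly this covariate, so the chain recovers the
planted biomarker.

The same pipeline is available from the shell:

```bash
adcsurv simulate --out cohort/ --seed 5 --n-subjects 43
adcsurv run --out run/ --seed 5 --n-subjects 43
adcsurv survival --rsd run/rsd.csv --endpoint PFS --seed 1 --out run/pfs/
```

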