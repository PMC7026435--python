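# bdstaging

An empirically derived **clinical staging model for bipolar disorder**, packaged
as a reusable scoring and validation pipeline for clinicians and researchers
working with longitudinal cohorts of adults with bipolar disorder.

Clinical staging treats bipolar disorder as a life-course illness that
progresses from mild to severe presentations. This package implements a
five-stage model built on twelve patient-level **profilers** spanning five
life domains — clinical course (lifetime hospitalisations *HospN*, suicide
attempts *SuicAttN*, comorbid personality disorder *ComPD*), physical health
(*BMI*, metabolic syndrome *MetS*, comorbid physical illnesses *IllnessN*),
cognition (screening category *SCIP*), real-world functioning (permanent
disability *PD×BD*, *FAST* total and leisure subscale), and health-related
quality of life (SF-36 physical-functioning and mental-health z-scores).

Each profiler is normalised to the unit interval and enters a global severity
score with equal weight:

```
Severity = (10/12) · (PDxBD + MetS + ComPD + SCIP + IllnessN + SFPF + SFMH
                      + FAST_T + FAST_leisure + BMI + HospN + SuicAttN)
```

so severity ranges from 0 to 10. Four cutoffs — **1.70, 2.50, 4.50, 6.10**,
the 5th/25th/50th/75th percentile scores of the derivation cohort — partition
the severity axis into stages 1–5 (stage *s* covers the half-open interval
(c₍ₛ₋₁₎, cₛ]; severities above 6.10 are stage 5).

The package provides:

- `StagingModel` / `StagingResults` — score raw cohort tables, assign stages,
  summarise, recalibrate cutoffs from new samples;
- a **construct-validity battery** (stage-wise one-way ANOVA, Pearson
  chi-square, Tukey HSD, monotone-worsening trend flags, external validators:
  global functioning and prescribed-drug patterns);
- **longitudinal analysis** — 5×5 stage-transition matrices with shift
  aggregates and the sustained-euthymia subgroup analysis (paired t-tests on
  life-domain composites);
- a **synthetic cohort generator** emulating a 129-patient, 3-year validation
  cohort: stage-structured profiler distributions, a row-stochastic transition
  kernel, 32.2% sustained euthymia and 57.6% retention;
- a CLI (`bdstaging score | calibrate | validate | transitions | simulate | run`).

## Worked example

```python
from bdstaging import StagingModel, default_config, generate_baseline

patient = {
    "hosp_n": 3, "suic_att_n": 1, "com_pd": 0, "bmi": 31.2, "mets": 1,
    "illness_n": 2, "scip_cat": "moderate", "pd_x_bd": 1, "fast_total": 41,
    "fast_leisure": 4, "sf_pf": -0.8, "sf_mh": -1.1,
}
model = StagingModel()
print("severity:", round(model.severity(patient), 4))   # severity: 6.1551
print("stage:", model.stage(patient))                   # stage: 5

cohort = generate_baseline(default_config(129), seed=1)
print(model.fit(cohort).summary())
```

```
Clinical staging model — cohort summary
===========================================
Patients scored: 129
Severity mean (SD): 3.71 (1.51)
Severity min / max: 0.90 / 7.49
Cutoffs: 1.70, 2.50, 4.50, 6.10

Stage   n      %
  1     10    7.8
  2     24   18.6
  3     60   46.5
  4     28   21.7
  5      7    5.4
```

The single patient scores 6.16 — above the 6.10 boundary, hence stage 5 (the
most severe stratum). The simulated 129-patient cohort reproduces the staging
structure of the validation study: mean severity near 3.6 with roughly half
the cohort in the middle stage.

The same pipeline runs from the shell:

```bash
bdstaging simulate --out-dir sim --n 129 --seed 1
bdstaging score sim/baseline.csv --out scored.csv
bdstaging transitions sim/baseline.csv sim/followup.csv --out transitions.json
bdstaging run --out-dir staging_run --seed 1     # full report bundle
```

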