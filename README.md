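# katascore

Prognostic scoring and survival validation for patients with bone
metastases treated with palliative radiotherapy.

Radiation oncologists choose dose-fractionation schedules for bone
metastases (single-fraction, e.g. 8 Gy × 1, versus multi-fraction, e.g.
20 Gy/5 or 30 Gy/10) largely on predicted survival. The **modified Katagiri
score** estimates that survival from six routinely available factors:

| Component | Levels → points |
| --- | --- |
| Primary tumour growth class | slow 0 · moderate 2 · rapid 3 |
| Visceral/cerebral metastases | none 0 · nodular 1 · disseminated 2 |
| Laboratory category | normal 0 · abnormal 1 · critical 2 |
| ECOG performance status | 0–2 → 0 · 3–4 → 1 |
| Previous chemotherapy | no 0 · yes 1 |
| Multiple skeletal metastases | no 0 · yes 1 |

The total S = Σ points ∈ [0, 10] stratifies patients into **low (0–3)**,
**intermediate (4–6)** and **high (7–10)** risk groups; high-risk patients
are steered toward single-fraction palliation, the others toward
multi-fraction schedules. Laboratory tiers: *abnormal* = CRP ≥ 0.4 mg/dL,
LDH ≥ 250 IU/L or albumin < 3.7 g/dL; *critical* = platelets < 100,000/µL,
albumin-corrected calcium ≥ 10.3 mg/dL (Payne correction) or bilirubin
≥ 1.4 mg/dL, with the worst tier crossed dominating. The "modified" part
collapses all lung cancers into the rapid-growth class and all breast and
prostate cancers into the slow-growth class.

The package provides, for this setting:

- **`katascore.scoring`** — lab categorisation (with a two-month pre-RT
  validity window), growth classification from an editable site
  vocabulary, component points, totals, risk groups and fractionation
  recommendations; missing data makes a patient *non-scorable* rather than
  silently defaulting.
- **`katascore.survival`** — from-scratch survival machinery:
  Kaplan–Meier product-limit estimation, the k-sample log-rank test, and
  Cox proportional-hazards regression (`CoxPH(...).fit()` →
  `CoxPHResults` with `summary()`), maximising the partial likelihood by
  Newton–Raphson with Breslow tie handling (Efron behind a switch) and
  Wald inference.
- **`katascore.validation`** — `KatagiriValidation.from_dataframe(df).fit()`
  → `ValidationResults`: cohort characteristics, univariate log-rank
  screening, multivariate Cox models (sex and ECOG fitted separately, with
  declared reference levels reporting HR 1.000), and risk-group validation
  with survival percentages at 3/6/12/24 months plus KM step coordinates.
- **`katascore.simulate`** — a seeded synthetic cohort generator whose
  piecewise-exponential hazards are calibrated so each risk group's
  survival matches the published validation profile exactly at the
  3/6/12/24-month knots (see `docs/methods.md`).
- **`katascore.cli`** — `katascore score | simulate | validate | tables`.

## Worked example

```python
from katascore import CohortConfig, simulate_cohort, KatagiriValidation

df = simulate_cohort(CohortConfig(seed=1))        # replica validation cohort
res = KatagiriValidation.from_dataframe(df).fit()
print(res.summary())
```

prints

```
Prognostic-score validation
patients: 356 total, 356 scorable (0 excluded for missing components)
median follow-up of survivors: 43.7 months

Risk-group validation:
       group   n  median_months  median_rounded  surv_3m  surv_6m  surv_12m  surv_24m
         low  18      29.758590              30     88.9     77.8      72.2      72.2
intermediate 133       7.160543               7     71.4     53.4      35.3      21.1
        high 205       2.154014               2     41.0     24.9      12.7       3.9
3-group log-rank: chi2 = 55.91, df = 2, p < 0.001
[30 hypothesis tests performed; no multiplicity correction applied]
```

The cohort has the published group sizes (18/133/205); each patient's
covariates were decoded from a component-score combination and re-scored
through the scoring module, so the strata are exact while the survival
times are random draws from the calibrated hazards — the medians (here
30/7/2 months against calibration targets 27/5.8/2.2) wander within
sampling error, and the three curves separate decisively.

The same pipeline runs from the shell:

```bash
katascore simulate --mode replica_validation --seed 1 --out cohort.csv
katascore validate --input cohort.csv --out report/ --seed 1
katascore score    --input cohort.csv --out scores.csv
```

`report/` then contains `table2.csv` … `table5.csv`, `km_curves.csv`,
`report.json`, a run log and a `manifest.json` with input/output digests;
reruns with the same seed and input are byte-identical.

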