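# prosirs

Sepsis is the leading cause of death in intensive care units, and systemic
inflammatory response syndrome (SIRS) — the concurrent fulfilment of at
least two of four clinical criteria (tachycardia, tachypnea, abnormal body
temperature, abnormal leukocyte count) — remains a useful dynamic signal for
predicting and diagnosing it.  `prosirs` implements a **prospective,
ICU-tailored SIRS algorithm** and the analysis machinery around it, for
biostatisticians and intensive-care researchers working with minute-level
electronic chart data.

## What it computes

Each charted measurement is taken at face value: an out-of-range record
opens *criterion validity* at its chart minute for at most a
criterion-specific maximum length, and a subsequent in-range (or zero-dose /
zero-ventilation) record terminates validity.  The rules are tailored to the
ICU: ongoing catecholamine therapy (noradrenaline, adrenaline, dobutamine)
counts as tachycardia, and mechanical ventilation (positive expired minute
volume, EMV) counts as tachypnea while suppressing the spontaneous
respiratory-rate and PaCO2 sub-criteria.  The state at minute t depends only
on records charted at or before t, so the algorithm is streaming-capable.

| criterion | rule | max validity |
|---|---|---|
| TC | heart rate > 90 /min | 30 min |
| TC | any catecholamine dose > 0 μg/min | 1 h |
| TP | EMV > 0 L/min (ventilation) | 1 h |
| TP | respiratory rate > 20 /min (no EMV > 0 in the preceding hour) | 30 min |
| TP | PaCO2 < 32 mmHg (no EMV > 0 in the preceding hour) | 8 h |
| Tem | temperature ∉ [36, 38] °C | 4 h |
| Leu | leukocytes ∉ [4000, 12000] /μL | 24 h |

Per minute ℓ, the weighted SIRS level is

    λ_ℓ = w_TC·𝟙_TC + w_TP·𝟙_TP + w_Tem·𝟙_Tem + w_Leu·𝟙_Leu ∈ [0, 1],

with non-negative criterion weights summing to 1.  43 weighting schemes of
six composition types (equal, one-hot, pairs, triples, dominant-half,
permutations of 0.4/0.3/0.2/0.1) are enumerated with exact rational weights.
A 24-h window (L = 1440 min) is summarised by the descriptors

* **Λ** = mean level,  **Δ** = λ_L − λ_1,  **C** = number of minute-to-minute level changes,

which feed seven logistic models (every non-empty subset of {Λ, Δ, C}) for
two tasks: **prediction** (first 24 h after ICU admission, outcome =
sepsis ever) and **diagnosis** (last 24 h before sepsis onset, with controls
drawn by nested case-control risk sets matched on ICU length-of-stay).
Models are validated by stratified 10-fold cross-validation (pooled
out-of-fold AUROC, Youden-optimal sensitivity/specificity, calibration
slope/intercept) and compared with normalized-rank scores; a Cox
proportional-hazards model (T, S) ~ Λ + Δ + C covers time-to-event analysis.
A seeded synthetic ICU cohort generator replaces the study's non-public
patient data.

## Worked example

```python
from prosirs import (SimConfig, generate_cohort, apply_cohort_filters,
                     build_prediction_dataset, equal_weighting,
                     fit_logistic_cv, discrimination_metrics, ModelSpec)

manifest, events = generate_cohort(SimConfig(n_encounters=150, seed=7))
manifest, _ = apply_cohort_filters(manifest)
rows = build_prediction_dataset(manifest, events, equal_weighting())
res = fit_logistic_cv(rows, ModelSpec(("lambda_mean",)), seed=7)
auroc, cutoff, sens, spec = discrimination_metrics(res.probabilities, rows["outcome"])
print(f"S~Lambda prediction AUROC {auroc:.3f}  sens {sens:.3f}  spec {spec:.3f}")
```

which prints

```
S~Lambda prediction AUROC 0.617  sens 0.731  spec 0.561
```

— the cross-validated probability that a random septic encounter's first-day
mean SIRS level outranks a random non-septic one (0.617), plus the
sensitivity and specificity at the cutoff maximising their sum.

The same pipeline is scriptable from the shell:

```bash
sirs simulate --out data --seed 7 --n-encounters 150
sirs cohort --events data/events.csv --manifest data/manifest.csv \
            --out cohort --task prediction --scheme ws1
sirs evaluate --descriptors cohort/descriptors_prediction.csv --out eval --seed 7
sirs rank --results eval/results.csv --out rank
```

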