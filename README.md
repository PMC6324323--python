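# icurisk

Predicting in-hospital mortality for ICU patients from the first 24 hours
of routinely collected EHR data: irregular lab/vital-sign trajectories,
clinical note text, and a ridge-penalized logistic model, evaluated by
nested cross-validation and cross-site external validation. Everything
runs end to end on a built-in synthetic multi-site EHR generator, so the
whole pipeline is testable without access to protected health data.

## Who this is for

Researchers building or auditing ICU severity-of-illness models who want a
transparent, dependency-light reference implementation of the full
modeling chain — cohort selection, leakage-safe feature engineering, text
featurization, penalized fitting, and honest resampling-based evaluation —
plus a configurable cohort simulator for methods work.

## The model

Three nested predictor families are compared for the binary outcome
*died in hospital*:

1. **baseline** — for each of V labs/vitals, the minimum and maximum
   observed value in the first 24 h (2V predictors); a surrogate for
   classical worst-value severity scores.
2. **trajectory** — eight summary measures per variable over all
   observations: min, max, mean, SD, first, last, last−first, and the
   least-squares slope in units/hour (8V predictors).
3. **trajectory+nlp** — trajectory plus sublinear TF-IDF weights of each
   patient's pooled 24-h note set over the k most frequent training-corpus
   terms (8V + k predictors): w(t, d) = (1 + ln tf) · idf with
   idf = ln((1+N)/(1+df)) + 1.

All predictors enter linearly into a logistic regression fitted by IRLS on
the penalized log-likelihood ℓ(β₀, β) = Σᵢ [yᵢηᵢ − log(1+e^{ηᵢ})] −
(λ/2)‖β‖², intercept unpenalized, predictors z-standardized. λ is chosen
by stratified inner cross-validation on held-out AUC with the
one-standard-error rule. Missing derived measures are imputed with
training-fold medians. Evaluation reports Mann–Whitney AUC with bootstrap
CIs over R×K outer-fold values, average-precision AUPRC, a modified
Hosmer–Lemeshow calibration statistic, and sensitivity/PPV at the optimal
cut point. See `docs/methods.md` for the full specification.

## Worked example

```bash
icurisk simulate --n 2000 --seed 7 --out scratch/demo
icurisk nested-cv --data scratch/demo --repetitions 2 --vocab-k 200 \
    --seed 7 --out scratch/demo_cv.json
```

The second command prints, for each model mode, the mean outer-fold AUC
and its bootstrap CI, the AUPRC, the calibration statistic and p-value,
and the cut-point sensitivity/PPV, e.g.:

```
"baseline":       {"mean_auc": 0.858, "auc_ci": [0.834, 0.880], "auprc": 0.470, ...}
"trajectory":     {"mean_auc": 0.894, "auc_ci": [0.874, 0.911], "auprc": 0.582, ...}
"trajectory+nlp": {"mean_auc": 0.937, "auc_ci": [0.925, 0.950], "auprc": 0.691, ...}
```

Discrimination rises as trajectory measures and note terms are added — the
pipeline's headline structural result. AUPRC should be read against its
chance level, which equals the ~10% mortality prevalence.

The numbered scripts under `analysis/` run the full study arc on the
default three-site cohort: simulation and cohort characteristics,
construct validity of the trajectory measures, pooled nested CV, the
cross-site transfer matrix, and the alive-at-24-h sensitivity analysis.
Each writes a small table under `results/`.

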