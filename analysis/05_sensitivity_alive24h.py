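#!/usr/bin/env python
"""Sensitivity analysis: rerun the pooled CV on patients alive at 24 hours.

Terms and measurements recorded just before an early death could let a
model trivially predict deaths that have effectively already happened.
Restricting to patients alive at 24 h tests whether the discrimination
gains survive. Writes results/sensitivity_alive24h.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from icurisk import harness
from icurisk.harness import HarnessConfig, nested_cv, sensitivity_alive_24h
from icurisk.synthetic_ehr import default_config, default_variable_specs, generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main(n: int = 4000, repetitions: int = 3, seed: int = 0) -> None:
    specs = {v.name: v for v in default_variable_specs()}
    six = [specs[v] for v in ("gcs_total", "gcs_motor", "heart_rate",
                              "sbp", "lactate", "sodium")]
    cfg_gen = default_config(n_patients=n, seed=seed, variable_specs=six,
                             filler_vocab_size=200, tokens_per_note_mean=40.0)
    stays, obs, notes = generate_cohort(cfg_gen)
    prep = harness.prepare(stays, obs, notes, [v.name for v in six])
    cfg = HarnessConfig(repetitions=repetitions, outer_folds=10, inner_folds=3,
                        vocab_k=40, lambda_grid=(0.1, 1.0, 10.0), seed=seed)

    full = nested_cv(prep, cfg)
    restricted = sensitivity_alive_24h(prep, cfg)
    death = prep.stays["death_time_hours"]
    n_restricted = int((death.isna() | (death >= 24)).sum())

    rows = []
    for mode in cfg.model_modes:
        rows.append({
            "model": mode,
            "auc_full_cohort": round(full[mode].discrimination.auc, 4),
            "auc_alive_at_24h": round(restricted[mode].discrimination.auc, 4),
        })
    table = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    table.to_csv(ROOT / "results" / "sensitivity_alive24h.csv", index=False)
    print(f"full cohort n={len(prep.stays)}, alive at 24 h n={n_restricted}")
    print(table.to_string(index=False))
    print("\nSimilar AUCs in both cohorts indicate the models are not "
          "leaning on measurements recorded immediately before early deaths.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=4000)
    ap.add_argument("--repetitions", type=int, default=3)
    ap.add_argument("--seed", type=int, default=0)
    a = ap.parse_args()
    main(a.n, a.repetitions, a.seed)
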