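#!/usr/bin/env python
"""Generate the default three-site synthetic ICU cohort and summarize it.

Writes the full stay/observation/note tables under scratch/ (they are
large) and a compact cohort-characteristics table under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from icurisk.cohort import select_cohort, write_events
from icurisk.synthetic_ehr import default_config, generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main(n: int = 4000, seed: int = 0) -> None:
    cfg = default_config(n_patients=n, seed=seed)
    stays, obs, notes = generate_cohort(cfg)
    out = ROOT / "scratch" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    write_events(out / "stays.csv", stays)
    write_events(out / "observations.csv", obs)
    write_events(out / "notes.csv", notes)

    cohort = select_cohort(stays)
    dead = cohort[cohort["died_in_hospital"]]
    summary = pd.DataFrame([
        {"characteristic": "patients generated", "value": len(stays)},
        {"characteristic": "patients after cohort selection", "value": len(cohort)},
        {"characteristic": "in-hospital mortality (%)",
         "value": round(100 * cohort["died_in_hospital"].mean(), 1)},
        {"characteristic": "deaths within 24 h (% of deaths)",
         "value": round(100 * (dead["death_time_hours"] < 24).mean(), 1)},
        {"characteristic": "mean age (y)", "value": round(cohort["age"].mean(), 1)},
        {"characteristic": "male (%)",
         "value": round(100 * (cohort["sex"] == "male").mean(), 1)},
        {"characteristic": "observation rows", "value": len(obs)},
        {"characteristic": "note rows", "value": len(notes)},
    ])
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "cohort_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\nFull tables in {out}; summary in results/cohort_summary.csv")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=4000)
    ap.add_argument("--seed", type=int, default=0)
    a = ap.parse_args()
    main(a.n, a.seed)
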