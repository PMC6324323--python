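"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from icurisk import harness
from icurisk.synthetic_ehr import (GeneratorConfig, TermSpec, VariableSpec,
                                   default_config, generate_cohort)


def small_generator_config(n=300, seed=0, **overrides) -> GeneratorConfig:
    """A compact single-site configuration with signal in both trajectories
    and note terms, for fast pipeline tests."""
    cfg = GeneratorConfig(
        n_patients=n,
        sites={"site_a": 1.0},
        variable_specs=[
            VariableSpec("gcs_total", 12.5, 2.6, 0.9, trend_survivor=0.124,
                         trend_nonsurvivor=-0.034, trend_sd=0.22,
                         level_shift_nonsurvivor=-0.4, rate_per_hour=0.9,
                         missing_prob=0.03),
            VariableSpec("heart_rate", 86, 14, 6, trend_survivor=-0.03,
                         trend_nonsurvivor=0.09, trend_sd=0.22,
                         level_shift_nonsurvivor=1.5, rate_per_hour=1.5,
                         missing_prob=0.01),
            VariableSpec("lactate", 1.8, 1.1, 0.4, trend_survivor=-0.15,
                         trend_nonsurvivor=0.30, trend_sd=0.3,
                         level_shift_nonsurvivor=0.6, rate_per_hour=0.2,
                         missing_prob=0.4),
        ],
        term_specs=[
            TermSpec("shock", 0.8, 0.9), TermSpec("sepsis", 1.1, 0.6),
            TermSpec("pupils", 0.3, 1.4), TermSpec("awake", 2.0, -0.8),
            TermSpec("extubated", 1.2, -1.1), TermSpec("plan", 3.0, 0.0),
        ],
        filler_vocab_size=120,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_generator_config(n=300, seed=11)
    stays, obs, notes = generate_cohort(cfg)
    return cfg, stays, obs, notes


@pytest.fixture(scope="session")
def small_prep(small_cohort):
    cfg, stays, obs, notes = small_cohort
    variables = [v.name for v in cfg.variable_specs]
    return harness.prepare(stays, obs, notes, variables)


@pytest.fixture(scope="session")
def multisite_prep():
    """Two-site cohort (shared generative process apart from site labels)."""
    cfg = small_generator_config(
        n=700, seed=23, sites={"site_a": 0.5, "site_b": 0.5})
    stays, obs, notes = generate_cohort(cfg)
    variables = [v.name for v in cfg.variable_specs]
    return harness.prepare(stays, obs, notes, variables)


@pytest.fixture()
def toy_stays():
    return pd.DataFrame({
        "patient_id": ["a", "b", "c", "d", "e"],
        "site": ["s"] * 5,
        "age": [17.0, 40.0, 55.0, 70.0, 30.0],
        "sex": ["male"] * 5,
        "icu_type": ["medical"] * 5,
        "icu_admit_rank": [1, 1, 2, 1, 1],
        "icu_los_hours": [30.0, 3.0, 50.0, 4.0, 100.0],
        "died_in_hospital": [False, False, False, True, False],
        "death_time_hours": [np.nan, np.nan, np.nan, 60.0, np.nan],
    })
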