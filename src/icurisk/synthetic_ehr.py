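"""Synthetic multi-site ICU cohort generator.

Emits the three long-format tables the rest of the pipeline consumes —
stays, observations, notes — with the statistical structure an ICU
mortality model assumes: ~10% in-hospital mortality, outcome-dependent
trajectories of labs and vital signs (e.g. the Glasgow Coma Scale trending
up in survivors and down in nonsurvivors), outcome-dependent note-term
frequencies, per-site case mix / vocabulary / missingness shifts, and a
configurable fraction of deaths occurring inside the first 24 hours.

Observation times follow a homogeneous Poisson process per variable on
[0, 24) h; note tokens are multinomial over the configured clinical terms
plus a Zipf-weighted "filler" vocabulary of neutral words. Decedents dying
before 24 h stop generating data at their death time, which makes the
alive-at-24-h sensitivity analysis meaningful downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "TermSpec",
    "SiteEffect",
    "GeneratorConfig",
    "ConfigError",
    "default_variable_specs",
    "default_term_specs",
    "default_config",
    "generate_cohort",
    "sample_trajectory",
    "sample_note_set",
]

ICU_TYPES = ("med_surg", "medical", "surgical", "neurologic", "coronary")
# Table-1-like case mix: combined med/surg 31.8%, medical 18.9%, surgical
# 21.6%, neurologic 14.1%, coronary 13.6%.
ICU_TYPE_WEIGHTS = (0.318, 0.189, 0.216, 0.141, 0.136)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class VariableSpec:
    """One lab or vital sign and how it behaves over the first day.

    ``trend_survivor`` / ``trend_nonsurvivor`` are in units per hour;
    ``level_shift_nonsurvivor`` shifts the nonsurvivor baseline in units of
    the variable (sicker patients start off more deranged); ``rate_per_hour``
    is the Poisson sampling intensity; ``missing_prob`` is the probability
    the variable is never measured for a patient (elevated for blood-gas
    and lactate panels).
    """

    name: str
    baseline_mean: float
    baseline_sd: float
    noise_sd: float
    trend_survivor: float = 0.0
    trend_nonsurvivor: float = 0.0
    trend_sd: float = 0.0
    level_shift_nonsurvivor: float = 0.0
    rate_per_hour: float = 1.0
    missing_prob: float = 0.02
    lower: float = -math.inf
    upper: float = math.inf


@dataclass(frozen=True)
class TermSpec:
    """One clinical term: base note frequency and outcome log-odds shift.

    ``base_weight`` is the term's unnormalized multinomial weight in a
    survivor's note set; a nonsurvivor's weight is
    ``base_weight * exp(outcome_shift)``, so positive shifts make the term
    strictly more frequent in expectation among decedents.
    """

    term: str
    base_weight: float
    outcome_shift: float = 0.0


@dataclass(frozen=True)
class SiteEffect:
    """Per-site multiplicative shifts relative to the reference site."""

    mortality_odds_mult: float = 1.0
    missing_mult: float = 1.0
    term_mult: dict[str, float] = field(default_factory=dict)
    filler_offset: int = 0  # rotates the filler vocabulary -> site-specific top terms


@dataclass
class GeneratorConfig:
    n_patients: int = 1000
    sites: dict[str, float] = field(default_factory=lambda: {"site_a": 1.0})
    mortality_prevalence: float = 0.104
    frac_deaths_within_24h: float = 0.147
    variable_specs: list[VariableSpec] = field(default_factory=lambda: default_variable_specs())
    term_specs: list[TermSpec] = field(default_factory=lambda: default_term_specs())
    site_effects: dict[str, SiteEffect] = field(default_factory=dict)
    notes_per_patient_mean: float = 3.0
    tokens_per_note_mean: float = 55.0
    filler_vocab_size: int = 1600
    filler_zipf_exponent: float = 1.15
    filler_total_weight: float = 120.0
    frac_underage: float = 0.0
    frac_short_stay: float = 0.0
    frac_readmission: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for p, label in [
            (self.mortality_prevalence, "mortality_prevalence"),
            (self.frac_deaths_within_24h, "frac_deaths_within_24h"),
            (self.frac_underage, "frac_underage"),
            (self.frac_short_stay, "frac_short_stay"),
            (self.frac_readmission, "frac_readmission"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{label} must be in [0, 1], got {p}")
        if not self.sites:
            raise ConfigError("at least one site is required")
        total = sum(self.sites.values())
        if any(w < 0 for w in self.sites.values()) or not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError("site mixture weights must be non-negative and sum to 1")
        if not self.variable_specs:
            raise ConfigError("at least one variable spec is required")
        if not self.term_specs:
            raise ConfigError("at least one term spec is required")
        for v in self.variable_specs:
            if not 0.0 <= v.missing_prob <= 1.0:
                raise ConfigError(f"missing_prob for {v.name} must be in [0, 1]")
            if v.rate_per_hour < 0:
                raise ConfigError(f"rate_per_hour for {v.name} must be non-negative")
        for t in self.term_specs:
            if t.base_weight <= 0:
                raise ConfigError(f"base_weight for {t.term} must be positive")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# Default study conditions.
#
# 24 labs/vitals (2x24 = 48 baseline predictors, 8x24 = 192 trajectory
# predictors). GCS total and components carry the construct-validity trends
# (+0.124 vs -0.034 points/h for the total); blood-gas and lactate variables
# get elevated missingness. Level shifts encode that nonsurvivors arrive
# more physiologically deranged, which is what gives a min/max-only model
# its predictive power.
# --------------------------------------------------------------------------

def default_variable_specs() -> list[VariableSpec]:
    V = VariableSpec
    return [
        V("gcs_total", 12.5, 2.6, 0.9, trend_survivor=0.124, trend_nonsurvivor=-0.034,
          trend_sd=0.22, level_shift_nonsurvivor=-0.36, rate_per_hour=0.9,
          missing_prob=0.03),
        V("gcs_eye", 3.3, 0.8, 0.35, trend_survivor=0.031, trend_nonsurvivor=-0.012,
          trend_sd=0.07, level_shift_nonsurvivor=-0.1, rate_per_hour=0.9,
          missing_prob=0.03),
        V("gcs_verbal", 3.9, 1.1, 0.45, trend_survivor=0.049, trend_nonsurvivor=-0.016,
          trend_sd=0.10, level_shift_nonsurvivor=-0.128, rate_per_hour=0.9,
          missing_prob=0.03),
        V("gcs_motor", 5.3, 1.0, 0.4, trend_survivor=0.043, trend_nonsurvivor=-0.002,
          trend_sd=0.09, level_shift_nonsurvivor=-0.12, rate_per_hour=0.9,
          missing_prob=0.03),
        V("heart_rate", 86, 14, 6, trend_survivor=-0.03, trend_nonsurvivor=0.09,
          trend_sd=0.22, level_shift_nonsurvivor=1.4, rate_per_hour=2.0,
          missing_prob=0.005),
        V("resp_rate", 18, 4, 2.2, trend_survivor=-0.01, trend_nonsurvivor=0.04,
          trend_sd=0.07, level_shift_nonsurvivor=0.44, rate_per_hour=2.0,
          missing_prob=0.005),
        V("sbp", 122, 18, 9, trend_survivor=0.02, trend_nonsurvivor=-0.16,
          trend_sd=0.30, level_shift_nonsurvivor=-1.8, rate_per_hour=1.5,
          missing_prob=0.005),
        V("dbp", 68, 11, 6, trend_survivor=0.01, trend_nonsurvivor=-0.08,
          trend_sd=0.18, level_shift_nonsurvivor=-1, rate_per_hour=1.5,
          missing_prob=0.005),
        V("map", 86, 13, 7, trend_survivor=0.01, trend_nonsurvivor=-0.11,
          trend_sd=0.22, level_shift_nonsurvivor=-1.28, rate_per_hour=1.5,
          missing_prob=0.01),
        V("temperature", 37.0, 0.6, 0.25, trend_survivor=0.0, trend_nonsurvivor=-0.004,
          trend_sd=0.010, level_shift_nonsurvivor=-0.032, rate_per_hour=0.6,
          missing_prob=0.01),
        V("spo2", 96.5, 2.0, 1.2, trend_survivor=0.004, trend_nonsurvivor=-0.035,
          trend_sd=0.05, level_shift_nonsurvivor=-0.28, rate_per_hour=2.0,
          missing_prob=0.005),
        V("wbc", 10.5, 4.0, 1.1, trend_survivor=-0.005, trend_nonsurvivor=0.03,
          trend_sd=0.06, level_shift_nonsurvivor=0.48, rate_per_hour=0.15,
          missing_prob=0.02),
        V("hemoglobin", 11.6, 2.0, 0.5, trend_survivor=0.0, trend_nonsurvivor=-0.008,
          trend_sd=0.02, level_shift_nonsurvivor=-0.2, rate_per_hour=0.15,
          missing_prob=0.02),
        V("platelets", 225, 85, 18, trend_survivor=0.0, trend_nonsurvivor=-0.35,
          trend_sd=0.9, level_shift_nonsurvivor=-8.8, rate_per_hour=0.15,
          missing_prob=0.02),
        V("sodium", 139, 4.2, 1.5, trend_survivor=0.345 / 24, trend_nonsurvivor=0.990 / 24,
          trend_sd=0.05, level_shift_nonsurvivor=0.36, rate_per_hour=0.2,
          missing_prob=0.02),
        V("potassium", 4.1, 0.55, 0.25, trend_survivor=-0.074 / 24, trend_nonsurvivor=0.099 / 24,
          trend_sd=0.010, level_shift_nonsurvivor=0.056, rate_per_hour=0.2,
          missing_prob=0.02),
        V("bicarbonate", 24, 4.0, 1.3, trend_survivor=0.004, trend_nonsurvivor=-0.03,
          trend_sd=0.06, level_shift_nonsurvivor=-0.44, rate_per_hour=0.2,
          missing_prob=0.03),
        V("urea", 24, 14, 2.5, trend_survivor=-0.657 / 24, trend_nonsurvivor=0.308 / 24,
          trend_sd=0.05, level_shift_nonsurvivor=1.6, rate_per_hour=0.12,
          missing_prob=0.02),
        V("creatinine", 1.15, 0.8, 0.12, trend_survivor=-0.001, trend_nonsurvivor=0.002,
          trend_sd=0.004, level_shift_nonsurvivor=0.088, rate_per_hour=0.12,
          missing_prob=0.02),
        V("bilirubin", 0.9, 0.8, 0.15, trend_survivor=-0.035 / 24, trend_nonsurvivor=0.124 / 24,
          trend_sd=0.008, level_shift_nonsurvivor=0.088, rate_per_hour=0.08,
          missing_prob=0.08),
        V("glucose", 138, 42, 16, trend_survivor=-0.05, trend_nonsurvivor=0.10,
          trend_sd=0.35, level_shift_nonsurvivor=2.8, rate_per_hour=0.5,
          missing_prob=0.01),
        # Blood-gas / lactate panel: high missingness, per the reported pattern.
        V("lactate", 1.8, 1.1, 0.4, trend_survivor=-0.387 / 24 * 9.01, trend_nonsurvivor=0.802 / 24 * 9.01,
          trend_sd=0.30, level_shift_nonsurvivor=0.22, rate_per_hour=0.15,
          missing_prob=0.45),
        V("ph_arterial", 7.39, 0.06, 0.025, trend_survivor=0.0004, trend_nonsurvivor=-0.0022,
          trend_sd=0.0015, level_shift_nonsurvivor=-0.0088, rate_per_hour=0.25,
          missing_prob=0.40),
        V("pao2", 110, 40, 14, trend_survivor=0.04, trend_nonsurvivor=-0.22,
          trend_sd=0.5, level_shift_nonsurvivor=-2.8, rate_per_hour=0.25,
          missing_prob=0.40),
    ]


def default_term_specs() -> list[TermSpec]:
    """Clinical terms with outcome shifts whose signs follow the reported
    term-weight table: decompensation terms positive, recovery/routine
    terms negative."""
    T = TermSpec
    return [
        # markers of acute decompensation / poor prognosis -> more frequent in decedents
        T("pupils", 0.30, 0.75), T("fixed", 0.25, 0.75), T("gag", 0.25, 0.65),
        T("ecmo", 0.10, 0.6), T("coagulopathy", 0.20, 0.5), T("shock", 0.80, 0.45),
        T("intubated", 1.30, 0.4), T("pea", 0.12, 0.45), T("chemotherapy", 0.25, 0.35),
        T("ascites", 0.30, 0.35), T("cvvh", 0.15, 0.3), T("sepsis", 1.10, 0.3),
        T("meropenem", 0.35, 0.25), T("pressors", 0.60, 0.4), T("unresponsive", 0.35, 0.5),
        # markers of recovery / routine course -> more frequent in survivors
        T("etoh", 0.45, -0.15), T("ohns", 0.20, -0.175), T("alert", 2.20, -0.25),
        T("ebl", 0.70, -0.25), T("diet", 1.60, -0.3), T("awake", 2.00, -0.35),
        T("perrl", 1.10, -0.4), T("denies", 1.90, -0.4), T("pod", 1.30, -0.45),
        T("extubated", 1.20, -0.55), T("ambulating", 0.80, -0.375), T("stable", 2.40, -0.175),
        # outcome-neutral chart furniture
        T("plan", 3.0, 0), T("patient", 4.0, 0), T("continue", 2.5, 0),
        T("monitor", 2.2, 0), T("family", 1.4, 0), T("icu", 2.8, 0),
    ]


def default_config(**overrides) -> GeneratorConfig:
    """Three-site study configuration: two large academic sites and one
    smaller community site with its own documentation habits (rotated filler
    vocabulary, damped clinical-term usage) and higher lab missingness."""
    cfg = GeneratorConfig(
        sites={"ucsf_like": 0.4, "bidmc_like": 0.4, "community": 0.2},
        site_effects={
            "ucsf_like": SiteEffect(),
            "bidmc_like": SiteEffect(mortality_odds_mult=1.1, filler_offset=200,
                                     term_mult={"sepsis": 1.3, "cvvh": 1.5, "ohns": 0.5}),
            "community": SiteEffect(mortality_odds_mult=0.85, missing_mult=1.5, filler_offset=500,
                                    term_mult={"ecmo": 0.1, "cvvh": 0.2, "pod": 1.4, "diet": 1.3}),
        },
        frac_underage=0.02,
        frac_short_stay=0.02,
        frac_readmission=0.02,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# --------------------------------------------------------------------------
# Sampling primitives
# --------------------------------------------------------------------------

def sample_trajectory(
    spec: VariableSpec,
    died: bool,
    rng: np.random.Generator,
    *,
    missing_mult: float = 1.0,
    t_max: float = 24.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one patient's observation times and values for one variable.

    Returns ``(t, values)``; both empty if the variable is missing for this
    patient or the Poisson draw lands on zero observations. Values follow
    baseline + trend*t + noise, clipped to the plausible range.
    """
    p_miss = min(1.0, spec.missing_prob * missing_mult)
    if rng.random() < p_miss:
        return np.empty(0), np.empty(0)
    n_obs = rng.poisson(spec.rate_per_hour * t_max)
    if n_obs == 0:
        return np.empty(0), np.empty(0)
    t = np.sort(rng.uniform(0.0, t_max, size=n_obs))
    baseline = spec.baseline_mean + rng.normal(0.0, spec.baseline_sd)
    if died:
        baseline += spec.level_shift_nonsurvivor
        trend = spec.trend_nonsurvivor
    else:
        trend = spec.trend_survivor
    if spec.trend_sd > 0:
        trend = trend + rng.normal(0.0, spec.trend_sd)
    values = baseline + trend * t
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=n_obs)
    return t, np.clip(values, spec.lower, spec.upper)


def _filler_tokens(size: int, offset: int) -> list[str]:
    return [f"w{(i + offset) % (size * 4):04d}" for i in range(size)]


def _filler_weights(size: int, exponent: float, total: float) -> np.ndarray:
    w = 1.0 / np.arange(1, size + 1, dtype=float) ** exponent
    return w * (total / w.sum())


def sample_note_set(
    term_specs: Sequence[TermSpec],
    died: bool,
    rng: np.random.Generator,
    *,
    site_effect: SiteEffect | None = None,
    n_notes_mean: float = 3.0,
    tokens_per_note_mean: float = 55.0,
    filler_vocab_size: int = 1600,
    filler_zipf_exponent: float = 1.15,
    filler_total_weight: float = 120.0,
    t_max: float = 24.0,
) -> list[tuple[float, str]]:
    """Draw one patient's notes as ``(time, text)`` pairs.

    Token counts are multinomial over the clinical terms (outcome log-odds
    shift applied multiplicatively to the weight of each term for
    nonsurvivors, site multipliers on top) plus a Zipf-weighted filler
    vocabulary. At least one note is always produced.
    """
    eff = site_effect or SiteEffect()
    weights = []
    tokens = []
    for s in term_specs:
        w = s.base_weight * eff.term_mult.get(s.term, 1.0)
        if died:
            w *= math.exp(s.outcome_shift)
        weights.append(w)
        tokens.append(s.term)
    fw = _filler_weights(filler_vocab_size, filler_zipf_exponent, filler_total_weight)
    tokens.extend(_filler_tokens(filler_vocab_size, eff.filler_offset))
    weights = np.concatenate([np.asarray(weights, dtype=float), fw])
    probs = weights / weights.sum()

    n_notes = max(1, rng.poisson(n_notes_mean))
    out = []
    for _ in range(n_notes):
        t = rng.uniform(0.0, t_max)
        n_tok = max(1, rng.poisson(tokens_per_note_mean))
        counts = rng.multinomial(n_tok, probs)
        idx = np.repeat(np.arange(len(tokens)), counts)
        rng.shuffle(idx)
        out.append((t, " ".join(tokens[i] for i in idx)))
    return out


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (stays, observations, notes) tables. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    site_names = list(config.sites)
    site_probs = np.array([config.sites[s] for s in site_names], dtype=float)

    # Per-site mortality via odds multipliers, renormalized so the marginal
    # prevalence equals mortality_prevalence exactly.
    base_odds = config.mortality_prevalence / max(1e-12, 1.0 - config.mortality_prevalence)
    mults = np.array([
        (config.site_effects.get(s, SiteEffect()).mortality_odds_mult) for s in site_names
    ])
    site_p = (base_odds * mults) / (1.0 + base_odds * mults)
    marginal = float(site_p @ site_probs)
    if marginal > 0:
        site_p = site_p * (config.mortality_prevalence / marginal)
    site_p = np.clip(site_p, 0.0, 1.0)

    stay_rows, note_rows = [], []
    obs_pid, obs_var, obs_t, obs_val = [], [], [], []
    for i in range(config.n_patients):
        pid = f"p{i:06d}"
        s_idx = int(rng.choice(len(site_names), p=site_probs))
        site = site_names[s_idx]
        eff = config.site_effects.get(site, SiteEffect())
        died = bool(rng.random() < site_p[s_idx])

        underage = rng.random() < config.frac_underage
        age = float(rng.uniform(14, 17.9)) if underage else float(np.clip(rng.normal(61.3, 17.1), 18, 100))
        sex = "male" if rng.random() < 0.513 else "female"
        icu_type = ICU_TYPES[int(rng.choice(len(ICU_TYPES), p=np.array(ICU_TYPE_WEIGHTS) / sum(ICU_TYPE_WEIGHTS)))]
        rank = 2 if rng.random() < config.frac_readmission else 1

        if rng.random() < config.frac_short_stay:
            los = float(rng.uniform(0.5, 3.9))
        else:
            los = float(4.0 + rng.lognormal(3.3, 0.9))  # median ~ 1.3 d

        death_time = None
        if died:
            if rng.random() < config.frac_deaths_within_24h:
                death_time = float(rng.uniform(max(4.0, min(4.0, los)), 24.0))
            else:
                death_time = float(24.0 + rng.exponential(120.0))
            los = min(los, death_time) if death_time < los else los
            if los < 4.0 and rng.random() >= config.frac_short_stay:
                los = max(los, 4.0)

        t_max = 24.0 if death_time is None else min(24.0, death_time)
        t_max = min(t_max, max(los, 0.5))

        for spec in config.variable_specs:
            t, vals = sample_trajectory(spec, died, rng, missing_mult=eff.missing_mult, t_max=t_max)
            if len(t):
                obs_pid.extend([pid] * len(t))
                obs_var.extend([spec.name] * len(t))
                obs_t.append(t)
                obs_val.append(vals)

        for t_note, text in sample_note_set(
            config.term_specs, died, rng, site_effect=eff,
            n_notes_mean=config.notes_per_patient_mean,
            tokens_per_note_mean=config.tokens_per_note_mean,
            filler_vocab_size=config.filler_vocab_size,
            filler_zipf_exponent=config.filler_zipf_exponent,
            filler_total_weight=config.filler_total_weight,
            t_max=t_max,
        ):
            note_rows.append((pid, float(t_note), text))

        stay_rows.append((pid, site, age, sex, icu_type, rank, los, died,
                          death_time if death_time is not None else np.nan))

    stays = pd.DataFrame(stay_rows, columns=[
        "patient_id", "site", "age", "sex", "icu_type", "icu_admit_rank",
        "icu_los_hours", "died_in_hospital", "death_time_hours"])
    observations = pd.DataFrame({
        "patient_id": obs_pid,
        "variable": obs_var,
        "t": np.concatenate(obs_t) if obs_t else np.empty(0),
        "value": np.concatenate(obs_val) if obs_val else np.empty(0),
    })
    notes = pd.DataFrame(note_rows, columns=["patient_id", "t", "text"])
    return stays, observations, notes
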