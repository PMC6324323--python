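"""Validation harness: pooled nested cross-validation, the cross-site
train/test matrix, the alive-at-24-h sensitivity analysis, and the
construct-validity comparisons.

Three model modes are evaluated: ``baseline`` (min/max per variable),
``trajectory`` (8 measures per variable), and ``trajectory+nlp``
(trajectory plus sublinear TF-IDF weights over a training-fitted
vocabulary). Every fit-time artifact — imputation medians, standardization,
vocabulary and idf, and the ridge penalty selected by the inner loop — is a
pure function of the training partition, so the outer-fold AUCs are
honest out-of-sample estimates. Repetition and fold seeds derive from the
master seed through numpy SeedSequence([master, repetition, fold]).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortWindow, clip_window, select_cohort
from .evaluation import (CalibrationResult, CutpointResult, DiscriminationResult,
                         auprc, auc, bootstrap_ci, hosmer_lemeshow, optimal_cutpoint)
from .ridge_logistic import FittedModel, RidgeConfig, fit, select_lambda, stratified_folds
from .text_features import Vocabulary, build_note_sets, fit_vocabulary, tfidf_matrix
from .trajectory_features import (apply_impute, build_feature_matrix,
                                  build_raw_summaries, FeatureMatrix)

__all__ = ["HarnessConfig", "PreparedData", "FittedPipeline", "CrossSiteMatrix",
           "prepare", "fit_pipeline", "predict_pipeline", "nested_cv",
           "cross_site", "sensitivity_alive_24h", "construct_validity",
           "MODEL_MODES"]

MODEL_MODES = ("baseline", "trajectory", "trajectory+nlp")


@dataclass
class HarnessConfig:
    model_modes: tuple[str, ...] = MODEL_MODES
    outer_folds: int = 10
    repetitions: int = 100
    inner_folds: int = 5
    bootstrap: int = 1000
    vocab_k: int = 1000
    lambda_grid: tuple[float, ...] = tuple(float(x) for x in np.logspace(-3, 3, 7))
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        bad = set(self.model_modes) - set(MODEL_MODES)
        if bad:
            raise ValueError(f"unknown model modes: {sorted(bad)}")


@dataclass
class PreparedData:
    """A cohort with precomputed per-patient summaries and note sets.

    Per-patient trajectory summaries and token multisets involve no
    cross-patient statistics, so precomputing them once is leak-free; all
    fitted artifacts are learned per training partition downstream.
    """

    stays: pd.DataFrame
    raw: pd.DataFrame
    note_sets: dict[str, Counter]
    variables: list[str]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.stays["patient_id"])

    @property
    def y(self) -> np.ndarray:
        return self.stays["died_in_hospital"].to_numpy().astype(int)

    def subset(self, mask) -> "PreparedData":
        stays = self.stays.loc[mask]
        return PreparedData(stays=stays.reset_index(drop=True), raw=self.raw,
                            note_sets=self.note_sets, variables=self.variables)


def prepare(stays: pd.DataFrame, observations: pd.DataFrame, notes: pd.DataFrame,
            variables, rules: CohortWindow = CohortWindow()) -> PreparedData:
    """Apply cohort rules and the 24-h window, then precompute summaries."""
    cohort = select_cohort(stays, rules).reset_index(drop=True)
    keep = set(cohort["patient_id"])
    obs = observations[observations["patient_id"].isin(keep)]
    nts = notes[notes["patient_id"].isin(keep)]
    obs, nts = clip_window(obs, nts, rules)
    raw = build_raw_summaries(obs, variables)
    note_sets = build_note_sets(nts, patient_ids=cohort["patient_id"])
    return PreparedData(stays=cohort, raw=raw, note_sets=note_sets,
                        variables=list(variables))


# --------------------------------------------------------------------------
# One modeling pipeline = structured features (+ optional text) + ridge fit
# --------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    mode: str
    columns: list[str]
    medians: np.ndarray          # structured-feature imputation medians
    vocab: Vocabulary | None
    model: FittedModel
    lam: float
    dropped_columns: list[str] = field(default_factory=list)


def _structured_matrix(prep: PreparedData, stays: pd.DataFrame, mode: str) -> FeatureMatrix:
    base_mode = "baseline" if mode == "baseline" else "trajectory"
    return build_feature_matrix(stays, None, prep.variables,
                                mode=base_mode, raw=prep.raw)


def fit_pipeline(prep: PreparedData, train_ids, mode: str, config: HarnessConfig,
                 seed: int = 0, ridge: RidgeConfig | None = None) -> FittedPipeline:
    """Fit every artifact of one model mode on the training patients only."""
    train_ids = list(train_ids)
    stays_tr = prep.stays.set_index("patient_id", drop=False).loc[train_ids].reset_index(drop=True)
    fm = _structured_matrix(prep, stays_tr, mode)

    X = fm.X
    columns = list(fm.columns)
    all_missing = np.isnan(X).all(axis=0)
    dropped = [c for c, m in zip(columns, all_missing) if m]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} all-missing training predictor(s)")
        keep = ~all_missing
        X = X[:, keep]
        columns = [c for c, m in zip(columns, all_missing) if not m]
    medians = np.nanmedian(X, axis=0)
    mask = np.isnan(X)
    X = X.copy()
    X[mask] = np.broadcast_to(medians, X.shape)[mask]

    vocab = None
    if mode == "trajectory+nlp":
        vocab = fit_vocabulary({pid: prep.note_sets[pid] for pid in train_ids},
                               k=config.vocab_k)
        T = tfidf_matrix(prep.note_sets, train_ids, vocab)
        X = np.hstack([X, T])
        columns = columns + [f"term__{t}" for t in vocab.terms]

    y = stays_tr["died_in_hospital"].to_numpy().astype(int)
    base = ridge or RidgeConfig(tol=1e-6, lambda_grid=config.lambda_grid,
                                inner_folds=config.inner_folds)
    lam = select_lambda(X, y, grid=base.lambda_grid, inner_folds=config.inner_folds,
                        seed=seed, config=base)
    model = fit(X, y, replace(base, lam=lam), columns=columns)
    return FittedPipeline(mode=mode, columns=columns, medians=medians,
                          vocab=vocab, model=model, lam=lam, dropped_columns=dropped)


def predict_pipeline(pipe: FittedPipeline, prep: PreparedData, patient_ids) -> np.ndarray:
    """Predicted in-hospital mortality risk for the listed patients."""
    patient_ids = list(patient_ids)
    stays = prep.stays.set_index("patient_id", drop=False).loc[patient_ids].reset_index(drop=True)
    fm = _structured_matrix(prep, stays, pipe.mode)
    struct_cols = [c for c in fm.columns if c not in set(pipe.dropped_columns)]
    keep_idx = [fm.columns.index(c) for c in struct_cols]
    fm = replace(fm, X=fm.X[:, keep_idx], columns=struct_cols)
    fm = apply_impute(fm, pipe.medians)
    X = fm.X
    if pipe.vocab is not None:
        X = np.hstack([X, tfidf_matrix(prep.note_sets, patient_ids, pipe.vocab)])
    return pipe.model.predict_risk(X)


# --------------------------------------------------------------------------
# Pooled nested cross-validation
# --------------------------------------------------------------------------

@dataclass
class NestedCVResult:
    mode: str
    fold_aucs: list[float]
    discrimination: DiscriminationResult
    calibration: CalibrationResult
    cutpoint: CutpointResult
    oof_risks: np.ndarray          # out-of-fold risks, first repetition
    first_rep_pipelines: list[FittedPipeline] | None = None


def _fold_seed(master: int, rep: int, fold: int) -> int:
    return int(np.random.SeedSequence([master, rep, fold]).generate_state(1)[0] % (2**31 - 1))


def nested_cv(prep: PreparedData, config: HarnessConfig,
              keep_pipelines: bool = False) -> dict[str, NestedCVResult]:
    """R repetitions of stratified K-fold nested CV per model mode.

    Yields R*K outer-fold AUCs per mode; the point estimate is their mean
    and the 95% CI a percentile bootstrap of that mean. AUPRC, calibration
    and the optimal cut point are computed on the out-of-fold risks of the
    first repetition (every patient scored exactly once by a model that
    never saw them).
    """
    y = prep.y
    pids = np.array(prep.patient_ids)
    out: dict[str, NestedCVResult] = {}
    fold_aucs: dict[str, list[float]] = {m: [] for m in config.model_modes}
    oof: dict[str, np.ndarray] = {m: np.full(len(y), np.nan) for m in config.model_modes}
    pipelines: dict[str, list[FittedPipeline]] = {m: [] for m in config.model_modes}

    for r in range(config.repetitions):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, r]))
        folds = stratified_folds(y, config.outer_folds, rng)
        for k, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            seed = _fold_seed(config.seed, r, k)
            for mode in config.model_modes:
                pipe = fit_pipeline(prep, pids[train_idx], mode, config, seed=seed)
                risks = predict_pipeline(pipe, prep, pids[test_idx])
                fold_aucs[mode].append(auc(risks, y[test_idx]))
                if r == 0:
                    oof[mode][test_idx] = risks
                    if keep_pipelines:
                        pipelines[mode].append(pipe)

    boot_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 987654321]))
    for mode in config.model_modes:
        vals = fold_aucs[mode]
        ci = bootstrap_ci(vals, B=config.bootstrap, seed=boot_rng)
        risks = oof[mode]
        disc = DiscriminationResult(auc=float(np.mean(vals)), auc_ci=ci,
                                    auprc=auprc(risks, y), fold_aucs=vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calib = hosmer_lemeshow(risks, y)
        cut = optimal_cutpoint(risks, y)
        out[mode] = NestedCVResult(mode=mode, fold_aucs=vals, discrimination=disc,
                                   calibration=calib, cutpoint=cut, oof_risks=risks,
                                   first_rep_pipelines=pipelines[mode] or None)
    return out


# --------------------------------------------------------------------------
# Cross-site external validation
# --------------------------------------------------------------------------

@dataclass
class CrossSiteMatrix:
    """Per-mode site x site grid of transfer AUCs; diagonal absent."""

    sites: list[str]
    aucs: dict[str, dict[tuple[str, str], float]]

    def table(self, mode: str) -> pd.DataFrame:
        t = pd.DataFrame(index=self.sites, columns=self.sites, dtype=float)
        for (a, b), v in self.aucs[mode].items():
            t.loc[a, b] = v
        return t


def cross_site(preps: dict[str, PreparedData], config: HarnessConfig) -> CrossSiteMatrix:
    """Fit on all of one site (inner lambda selection there), test on each
    other site with the training site's vocabulary and idf; out-of-
    vocabulary test-site tokens contribute nothing."""
    sites = list(preps)
    if len(sites) < 2:
        raise ValueError("cross-site validation needs at least 2 sites")
    aucs: dict[str, dict[tuple[str, str], float]] = {m: {} for m in config.model_modes}
    for i, train_site in enumerate(sites):
        prep_tr = preps[train_site]
        seed = _fold_seed(config.seed, 10_000 + i, 0)
        for mode in config.model_modes:
            pipe = fit_pipeline(prep_tr, prep_tr.patient_ids, mode, config, seed=seed)
            for test_site in sites:
                if test_site == train_site:
                    continue
                prep_te = preps[test_site]
                risks = predict_pipeline(pipe, prep_te, prep_te.patient_ids)
                aucs[mode][(train_site, test_site)] = auc(risks, prep_te.y)
    return CrossSiteMatrix(sites=sites, aucs=aucs)


def split_by_site(prep: PreparedData) -> dict[str, PreparedData]:
    return {site: prep.subset((prep.stays["site"] == site).to_numpy())
            for site in prep.stays["site"].unique()}


# --------------------------------------------------------------------------
# Sensitivity analysis and construct validity
# --------------------------------------------------------------------------

def sensitivity_alive_24h(prep: PreparedData, config: HarnessConfig,
                          window_hours: float = 24.0) -> dict[str, NestedCVResult]:
    """Rerun nested CV keeping only patients alive at 24 hours."""
    death = prep.stays["death_time_hours"]
    alive = death.isna() | (death >= window_hours)
    return nested_cv(prep.subset(alive.to_numpy()), config)


def construct_validity(fm: FeatureMatrix) -> pd.DataFrame:
    """Survivor vs nonsurvivor comparison of every derived measure.

    Returns one row per predictor with group means, a Welch t p-value and a
    Wilcoxon rank-sum p-value (missing cells excluded pairwise).
    """
    y = fm.y
    rows = []
    for j, col in enumerate(fm.columns):
        x = fm.X[:, j]
        s = x[(y == 0) & ~np.isnan(x)]
        d = x[(y == 1) & ~np.isnan(x)]
        mean_s = float(np.mean(s)) if len(s) else float("nan")
        mean_d = float(np.mean(d)) if len(d) else float("nan")
        if len(s) >= 2 and len(d) >= 2:
            vs, vd = s.var(ddof=1), d.var(ddof=1)
            se2 = vs / len(s) + vd / len(d)
            if se2 > 0:
                t = (mean_s - mean_d) / np.sqrt(se2)
                df = se2**2 / ((vs / len(s))**2 / (len(s) - 1)
                               + (vd / len(d))**2 / (len(d) - 1))
                t_p = float(2 * stats.t.sf(abs(t), df))
            else:
                t_p = 1.0
            w_stat, w_p = stats.ranksums(s, d)
            if np.all(s == s[0]) and np.all(d == d[0]) and s[0] == d[0]:
                w_p = 1.0
        else:
            t_p, w_p = float("nan"), float("nan")
        rows.append({"predictor": col, "mean_survivor": mean_s,
                     "mean_nonsurvivor": mean_d, "t_p": t_p, "wilcoxon_p": float(w_p)
                     if w_p == w_p else float("nan")})
    return pd.DataFrame(rows)
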