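"""Structured-feature engineering over first-24-hour observations.

For each lab/vital the baseline representation keeps only the highest and
lowest observed values (a surrogate for classical worst-value severity
scores); the clinical-trajectory representation adds measures of
distribution, variability and time course. Eight per-variable measures are
produced:

    min, max, mean, sd, first, last, delta (= last - first),
    slope (ordinary least-squares slope in units per hour)

so a V-variable panel yields 2V baseline or 8V trajectory predictors.
Conventions: sample (n-1) SD; "first"/"last" by ascending time with ties
broken by input order; with a single observation SD, slope and delta are
missing (not zero) and are later median-imputed; with no observations all
eight are missing. Imputation medians are learned on training rows only and
reapplied unchanged to test rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASELINE_MEASURES",
    "TRAJECTORY_MEASURES",
    "FeatureMatrix",
    "ls_slope",
    "summarize_variable",
    "build_raw_summaries",
    "build_feature_matrix",
    "fit_impute",
    "apply_impute",
]

BASELINE_MEASURES = ("min", "max")
TRAJECTORY_MEASURES = ("min", "max", "mean", "sd", "first", "last", "delta", "slope")


@dataclass
class FeatureMatrix:
    """Patients x named predictors, with the outcome and fit-time artifacts."""

    patient_ids: list[str]
    columns: list[str]
    X: np.ndarray                       # float, NaN = missing
    y: np.ndarray                       # 0/1 in-hospital death
    imputation_medians: np.ndarray | None = None   # per-column, set by fit_impute
    standardization: tuple[np.ndarray, np.ndarray] | None = None  # (means, sds)
    extra: dict = field(default_factory=dict)

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]


def ls_slope(points: Sequence[tuple[float, float]]) -> float:
    """Ordinary least-squares slope of value on time, units per hour.

    Returns NaN (missing) with fewer than two points or when all times
    coincide.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        return float("nan")
    t, v = pts[:, 0], pts[:, 1]
    dt = t - t.mean()
    denom = float(dt @ dt)
    if denom <= 0.0:
        return float("nan")
    return float(dt @ (v - v.mean()) / denom)


def summarize_variable(t: Sequence[float], values: Sequence[float]) -> dict[str, float]:
    """The 8 trajectory measures for one patient x variable.

    ``t`` and ``values`` are paired observations, not necessarily sorted;
    first/last are taken by ascending t with ties broken by input order.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(values, dtype=float)
    nan = float("nan")
    if len(v) == 0:
        return {m: nan for m in TRAJECTORY_MEASURES}
    order = np.argsort(t, kind="stable")
    v_sorted = v[order]
    out = {
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if len(v) >= 2 else nan,
        "first": float(v_sorted[0]),
        "last": float(v_sorted[-1]),
        "delta": float(v_sorted[-1] - v_sorted[0]) if len(v) >= 2 else nan,
        "slope": ls_slope(np.column_stack([t, v])),
    }
    return out


def build_raw_summaries(observations: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """All 8 measures for every patient x variable, vectorized.

    Returns a frame indexed by patient_id with columns ``{var}__{measure}``
    (variable-major, measure-minor), NaN where undefined. Patients appear in
    first-occurrence order of the observation table.
    """
    var_set = set(variables)
    obs = observations[observations["variable"].isin(var_set)] if len(observations) else observations

    patients = list(dict.fromkeys(observations["patient_id"])) if len(observations) else []
    columns = [f"{v}__{m}" for v in variables for m in TRAJECTORY_MEASURES]
    frame = pd.DataFrame(np.nan, index=pd.Index(patients, name="patient_id"), columns=columns)
    if not len(obs):
        return frame

    df = obs.reset_index(drop=True)
    # stable sort by t within group keeps input order among ties
    df = df.sort_values(["patient_id", "variable", "t"], kind="stable")
    g = df.groupby(["patient_id", "variable"], sort=False)
    t = df["t"].to_numpy()
    v = df["value"].to_numpy()
    agg = g.agg(
        n=("value", "size"),
        vmin=("value", "min"),
        vmax=("value", "max"),
        vmean=("value", "mean"),
        vsd=("value", lambda s: s.std(ddof=1)),
        first=("value", "first"),
        last=("value", "last"),
        t_sum=("t", "sum"),
        t2_sum=("t", lambda s: float(np.dot(s, s))),
    )
    tv = pd.Series(t * v, index=df.index)
    agg["tv_sum"] = tv.groupby([df["patient_id"], df["variable"]], sort=False).sum()

    n = agg["n"].to_numpy(dtype=float)
    denom = n * agg["t2_sum"].to_numpy() - agg["t_sum"].to_numpy() ** 2
    v_sum = agg["vmean"].to_numpy() * n
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (n * agg["tv_sum"].to_numpy() - agg["t_sum"].to_numpy() * v_sum) / denom
    slope[(n < 2) | (denom <= 1e-12)] = np.nan

    measures = {
        "min": agg["vmin"], "max": agg["vmax"], "mean": agg["vmean"],
        "sd": agg["vsd"].where(agg["n"] >= 2),
        "first": agg["first"], "last": agg["last"],
        "delta": (agg["last"] - agg["first"]).where(agg["n"] >= 2),
        "slope": pd.Series(slope, index=agg.index),
    }
    for m, series in measures.items():
        wide = series.unstack("variable")
        for var in wide.columns:
            frame.loc[wide.index, f"{var}__{m}"] = wide[var]
    return frame


def build_feature_matrix(
    stays: pd.DataFrame,
    observations: pd.DataFrame | None,
    variables: Sequence[str],
    mode: str = "trajectory",
    raw: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Assemble the structured design matrix for the selected cohort.

    ``mode='baseline'`` emits min/max only (2 columns per variable);
    ``mode='trajectory'`` emits all 8. Column order is variable-major,
    measure-minor and stable. Rows follow the stay table. ``raw`` may carry
    precomputed per-patient summaries (from :func:`build_raw_summaries`) to
    avoid recomputation across folds; summaries are per-patient statistics
    and involve no cross-patient fitting, so sharing them leaks nothing.
    """
    if mode not in ("baseline", "trajectory"):
        raise ValueError(f"unknown mode {mode!r}")
    if raw is None:
        if observations is None:
            raise ValueError("either observations or precomputed raw summaries required")
        known = set(observations["variable"].unique()) if len(observations) else set()
        unknown = [v for v in variables if known and v not in known]
        if unknown:
            raise ValueError(f"unknown variable(s) in list: {unknown}")
        raw = build_raw_summaries(observations, variables)
    measures = BASELINE_MEASURES if mode == "baseline" else TRAJECTORY_MEASURES
    columns = [f"{v}__{m}" for v in variables for m in measures]
    pids = list(stays["patient_id"])
    aligned = raw.reindex(pids)
    X = aligned[columns].to_numpy(dtype=float)
    y = stays["died_in_hospital"].to_numpy().astype(int)
    return FeatureMatrix(patient_ids=pids, columns=columns, X=X, y=y)


def fit_impute(matrix: FeatureMatrix) -> FeatureMatrix:
    """Learn per-predictor training medians and fill missing cells.

    Must be called on training rows only. A predictor missing in every
    training row cannot be imputed; the caller is told to drop it.
    """
    X = matrix.X
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [matrix.columns[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(
            f"predictor(s) {bad} have no non-missing training values; drop them before fitting")
    medians = np.nanmedian(X, axis=0)
    return apply_impute(matrix, medians)


def apply_impute(matrix: FeatureMatrix, medians: np.ndarray) -> FeatureMatrix:
    """Replace missing cells with the supplied (training) medians."""
    medians = np.asarray(medians, dtype=float)
    if medians.shape[0] != matrix.X.shape[1]:
        raise ValueError("median vector length does not match predictor count")
    X = matrix.X.copy()
    mask = np.isnan(X)
    X[mask] = np.broadcast_to(medians, X.shape)[mask]
    return replace(matrix, X=X, imputation_medians=medians)
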