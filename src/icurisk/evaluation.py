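"""Discrimination, calibration, and cut-point metrics with resampling CIs.

AUC is the Mann-Whitney estimator (ties counted half); AUPRC is the
average-precision step form of the precision-recall curve, whose chance
level equals the outcome prevalence; calibration uses a modified
Hosmer-Lemeshow statistic over risk-sorted equal-count groups,

    C = sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g)),

referred to chi-square with G degrees of freedom for externally supplied
risks (G - 2 for a development sample). Uncertainty for
cross-validated AUCs comes from a percentile bootstrap of the mean of
fold-level values, and model comparisons use Welch's unpaired t test on
those same fold AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DiscriminationResult", "CalibrationResult", "CutpointResult",
    "auc", "auprc", "hosmer_lemeshow", "bootstrap_ci", "optimal_cutpoint",
    "compare_auc", "ci_separated",
]


@dataclass
class DiscriminationResult:
    auc: float
    auc_ci: tuple[float, float] | None = None
    auprc: float | None = None
    fold_aucs: list[float] | None = None


@dataclass
class CalibrationResult:
    statistic: float
    groups: int
    df: int
    p_value: float


@dataclass
class CutpointResult:
    threshold: float
    sensitivity: float
    ppv: float
    method: str


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(float).ravel()
    if not np.all(np.isin(np.unique(labels), [0.0, 1.0])):
        raise ValueError("labels must be binary 0/1")
    return labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied) / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_binary(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = float(ranks[labels == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def auprc(scores, labels) -> float:
    """Average precision: sum over recall steps of precision at each step."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPRC requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate at distinct-threshold boundaries only
    distinct = np.flatnonzero(np.append(np.diff(s) != 0, True))
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


def hosmer_lemeshow(risks, labels, groups: int = 10,
                    df: int | None = None) -> CalibrationResult:
    """Modified Hosmer-Lemeshow goodness-of-fit test.

    Rows are sorted by predicted risk and cut into ``groups`` equal-count
    groups (tied risks at a boundary fall to the lower group); degenerate
    groups (expected count 0 or n_g) are merged into a neighbor with a
    warning. P > .05 is read as adequate calibration.

    Degrees of freedom default to G, the reference distribution of C when
    the risks are externally supplied (a validation sample, as in
    out-of-fold evaluation); pass ``df=G - 2`` for the classical
    development-sample convention where the model was fitted by maximum
    likelihood on the same rows.
    """
    risks = np.asarray(risks, dtype=float).ravel()
    labels = _check_binary(labels)
    n = len(risks)
    if groups < 3:
        raise ValueError("need at least 3 groups")
    if n < groups * 5:
        warnings.warn(f"only {n} rows for {groups} groups; test may be unreliable")

    order = np.argsort(risks, kind="stable")
    r, y = risks[order], labels[order]
    edges = [len(chunk) for chunk in np.array_split(np.arange(n), groups)]
    bounds = np.cumsum(edges)[:-1]
    # push boundary ties into the lower group
    bounds = list(bounds)
    for b_i in range(len(bounds)):
        b = bounds[b_i]
        while b < n and b > 0 and r[b] == r[b - 1]:
            b += 1
        bounds[b_i] = b
    bounds = sorted(set(b for b in bounds if 0 < b < n))
    starts = [0] + bounds
    stops = bounds + [n]

    grp = []
    for a, b in zip(starts, stops):
        if a == b:
            continue
        grp.append((b - a, float(y[a:b].sum()), float(r[a:b].sum())))
    # merge degenerate groups (E = 0 or E = n_g) into the neighbor above
    merged = []
    for g in grp:
        if merged and (merged[-1][2] <= 0 or merged[-1][2] >= merged[-1][0]):
            warnings.warn("merging degenerate risk group")
            n_g, o, e = merged.pop()
            g = (g[0] + n_g, g[1] + o, g[2] + e)
        merged.append(g)
    if len(merged) >= 2 and (merged[-1][2] <= 0 or merged[-1][2] >= merged[-1][0]):
        warnings.warn("merging degenerate risk group")
        n2, o2, e2 = merged.pop()
        n1_, o1, e1 = merged.pop()
        merged.append((n1_ + n2, o1 + o2, e1 + e2))

    C = 0.0
    for n_g, o_g, e_g in merged:
        denom = e_g * (1.0 - e_g / n_g)
        if denom <= 0:
            continue
        C += (o_g - e_g) ** 2 / denom
    G = len(merged)
    dof = max(1, G if df is None else df)
    p = float(stats.chi2.sf(C, dof)) if C > 0 else 1.0
    return CalibrationResult(statistic=float(C), groups=G, df=dof, p_value=p)


def bootstrap_ci(values, B: int = 1000, level: float = 0.95,
                 seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of fold-level values."""
    values = np.asarray(values, dtype=float).ravel()
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(B, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def ci_separated(ci_a: tuple[float, float], est_a: float,
                 ci_b: tuple[float, float], est_b: float) -> bool:
    """The study's significance rule: each model's 95% CI excludes the
    other's point estimate."""
    a_excludes_b = not (ci_a[0] <= est_b <= ci_a[1])
    b_excludes_a = not (ci_b[0] <= est_a <= ci_b[1])
    return a_excludes_b and b_excludes_a


def optimal_cutpoint(scores, labels, method: str = "youden") -> CutpointResult:
    """Best threshold over observed scores by Youden's J or F1.

    Rows scoring at or above the threshold are called positive; reports
    sensitivity (recall) and positive predictive value (precision) at the
    chosen cut.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    thresholds = np.unique(scores)
    best = None
    for thr in thresholds:
        call = scores >= thr
        tp = float(np.sum(call & (labels == 1)))
        fp = float(np.sum(call & (labels == 0)))
        sens = tp / n_pos
        spec = 1.0 - fp / n_neg
        ppv = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        if method == "youden":
            crit = sens + spec - 1.0
        elif method == "f1":
            crit = 2 * ppv * sens / (ppv + sens) if (ppv + sens) > 0 else 0.0
        else:
            raise ValueError(f"unknown method {method!r}")
        if best is None or crit > best[0] + 1e-15:
            best = (crit, thr, sens, ppv)
    return CutpointResult(threshold=float(best[1]), sensitivity=float(best[2]),
                          ppv=float(best[3]), method=method)


def compare_auc(values_a, values_b) -> tuple[float, float]:
    """Welch's unpaired t test on two sets of fold AUCs; returns (t, p)."""
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, 1.0
    t = float((a.mean() - b.mean()) / np.sqrt(se2))
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p
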