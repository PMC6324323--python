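"""L2-penalized (ridge) logistic regression via iteratively reweighted
least squares.

The fitted objective is the penalized log-likelihood

    l(b0, b) = sum_i [ y_i eta_i - log(1 + exp(eta_i)) ] - (lambda/2) ||b||^2

with eta = b0 + X b, the intercept unpenalized, and the penalty applied on
the z-standardized predictor scale (default) so one lambda is coherent
across structured and text predictors. Newton/IRLS steps with step-halving
guarantee a monotone objective; convergence is declared when the max-norm
of the penalized gradient falls below ``tol``. The penalty parameter is
selected by stratified inner cross-validation on held-out AUC under the
one-standard-error rule: the most regularized model statistically
indistinguishable from the best wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import auc

__all__ = ["RidgeConfig", "FittedModel", "ConvergenceError", "fit",
           "predict_risk", "select_lambda", "stratified_folds"]


class ConvergenceError(RuntimeError):
    """IRLS failed to reach the gradient tolerance; carries diagnostics."""

    def __init__(self, message: str, n_iter: int, grad_norm: float):
        super().__init__(f"{message} (iterations={n_iter}, grad_max_norm={grad_norm:.3e})")
        self.n_iter = n_iter
        self.grad_norm = grad_norm


@dataclass
class RidgeConfig:
    lam: float = 1.0
    lambda_grid: tuple[float, ...] = tuple(float(x) for x in np.logspace(-3, 3, 7))
    max_iter: int = 100
    tol: float = 1e-8
    standardize: bool = True
    inner_folds: int = 5

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FittedModel:
    """A fitted ridge-logistic model.

    ``coef_`` and ``intercept_`` live on the standardized scale used for
    fitting (the scale the penalty is defined on); ``coefficients`` maps
    predictor names to original-scale slopes for interpretation.
    """

    intercept_: float
    coef_: np.ndarray
    lam: float
    means_: np.ndarray
    sds_: np.ndarray
    columns: list[str] | None = None
    n_iter_: int = 0
    grad_norm_: float = float("nan")
    converged_: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> dict[str, float]:
        names = self.columns or [f"x{j}" for j in range(len(self.coef_))]
        return {n: float(b / s) for n, b, s in zip(names, self.coef_, self.sds_)}

    @property
    def intercept(self) -> float:
        return float(self.intercept_ - np.sum(self.coef_ * self.means_ / self.sds_))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.means_) / self.sds_
        return self.intercept_ + Z @ self.coef_

    def predict_risk(self, X: np.ndarray) -> np.ndarray:
        return _expit(self.linear_predictor(X))


def _expit(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def penalized_loglik(beta0: float, beta: np.ndarray, Z: np.ndarray, y: np.ndarray,
                     lam: float) -> float:
    """Objective value on the (standardized) fitting scale."""
    eta = beta0 + Z @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return ll - 0.5 * lam * float(beta @ beta)


def fit(X: np.ndarray, y: np.ndarray, config: RidgeConfig | None = None,
        columns: list[str] | None = None) -> FittedModel:
    """Fit by IRLS with step-halving. Deterministic given inputs.

    ``X`` must be fully imputed (no NaN) and ``y`` binary with both classes
    present.
    """
    config = config or RidgeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute before fitting")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("y must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("y contains a single class; cannot fit")
    n, p = X.shape

    if config.standardize:
        means = X.mean(axis=0)
        sds = X.std(axis=0)
        sds = np.where(sds > 0, sds, 1.0)
    else:
        means = np.zeros(p)
        sds = np.ones(p)
    Z = (X - means) / sds
    lam = config.lam

    beta0 = float(np.log(y.mean() / (1.0 - y.mean())))
    beta = np.zeros(p)
    obj = penalized_loglik(beta0, beta, Z, y, lam)

    for it in range(1, config.max_iter + 1):
        eta = beta0 + Z @ beta
        mu = _expit(eta)
        resid = y - mu
        grad0 = float(resid.sum())
        grad = Z.T @ resid - lam * beta
        gnorm = max(abs(grad0), float(np.abs(grad).max()) if p else 0.0)
        if gnorm <= config.tol:
            return FittedModel(beta0, beta, lam, means, sds, columns,
                               n_iter_=it - 1, grad_norm_=gnorm)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        Zw = Z * w[:, None]
        H = np.empty((p + 1, p + 1))
        H[0, 0] = w.sum()
        H[0, 1:] = H[1:, 0] = Zw.sum(axis=0)
        H[1:, 1:] = Z.T @ Zw
        H[1:, 1:][np.diag_indices(p)] += lam
        g_full = np.concatenate([[grad0], grad])
        try:
            step = np.linalg.solve(H, g_full)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g_full, rcond=None)[0]
        # step-halving keeps the objective monotone
        scale = 1.0
        for _ in range(50):
            b0_new = beta0 + scale * step[0]
            b_new = beta + scale * step[1:]
            obj_new = penalized_loglik(b0_new, b_new, Z, y, lam)
            if obj_new >= obj - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError("step-halving failed to improve objective", it, gnorm)
        beta0, beta, obj = b0_new, b_new, obj_new

    eta = beta0 + Z @ beta
    resid = y - _expit(eta)
    gnorm = max(abs(float(resid.sum())),
                float(np.abs(Z.T @ resid - lam * beta).max()) if p else 0.0)
    if gnorm <= config.tol:
        return FittedModel(beta0, beta, lam, means, sds, columns,
                           n_iter_=config.max_iter, grad_norm_=gnorm)
    raise ConvergenceError("IRLS did not converge", config.max_iter, gnorm)


def predict_risk(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Per-row event probability; inverse logit of the linear predictor."""
    return model.predict_risk(X)


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Outcome-stratified fold assignment; returns k index arrays."""
    y = np.asarray(y).ravel()
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def select_lambda(X: np.ndarray, y: np.ndarray, grid=None, inner_folds: int = 5,
                  seed: int = 0, config: RidgeConfig | None = None) -> float:
    """Pick the penalty by inner-fold held-out AUC with the one-SE rule.

    The selected lambda is the largest grid value whose mean inner-fold AUC
    lies within one standard error of the best mean — the conventional
    "one-standard-error" tie-break that prefers the more regularized model
    whenever the data cannot distinguish the candidates (exact ties also
    resolve to the larger lambda). Folds are outcome-stratified; if a split
    still yields a single-class training fold, the split is retried with
    fresh shuffles before erroring.
    """
    base = config or RidgeConfig()
    grid = sorted(set(float(g) for g in (grid if grid is not None else base.lambda_grid)))
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if len(grid) == 1:
        return grid[0]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    for attempt in range(5):
        folds = stratified_folds(y, inner_folds, rng)
        ok = all(len(np.unique(y[np.setdiff1d(np.arange(len(y)), f)])) == 2
                 and len(f) > 0 for f in folds)
        if ok:
            break
    else:
        raise ValueError("could not build inner folds with both classes present")

    fold_scores: list[list[float]] = []
    for lam in grid:
        cfg = RidgeConfig(lam=lam, max_iter=base.max_iter, tol=max(base.tol, 1e-7),
                          standardize=base.standardize)
        scores = []
        for f in folds:
            train = np.setdiff1d(np.arange(len(y)), f)
            model = fit(X[train], y[train], cfg)
            held = y[f]
            if len(np.unique(held)) < 2:
                continue  # AUC undefined on a single-class held-out fold
            scores.append(auc(model.predict_risk(X[f]), held))
        fold_scores.append(scores)

    means = [float(np.mean(s)) if s else -np.inf for s in fold_scores]
    j_best = max(range(len(grid)), key=lambda j: (means[j], grid[j]))
    best_scores = fold_scores[j_best]
    se = (float(np.std(best_scores, ddof=1)) / np.sqrt(len(best_scores))
          if len(best_scores) >= 2 else 0.0)
    eligible = [g for g, m in zip(grid, means) if m >= means[j_best] - se]
    return max(eligible)
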