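"""Stability models: logistic regression on FASA_p, LASSO descriptor fit, CV.

The experimental target is binary: a drug–excipient pair either forms a
stable nanosuspension at some excipient:drug ratio ("success", with a
recorded minimum weight percentage) or fails at every ratio. The logistic
models are parameterised on the log-odds-of-failure scale,

    log(P_f / P_s) = b0 + b1 · x,        P_s = 1 / (1 + exp(b0 + b1·x)),

with x the (simulated or 2-D-predicted) polar surface fraction. Two
reference coefficient sets are shipped: :data:`REF_SIM` = (6.14, −26.1) on
simulated FASA_p and :data:`REF_2D` = (13.5, −58.0) on the 2-D-predicted
FASA_p, both fitted to a 16-pair milling dataset (8 successes, 8 failures).
The negative slope means a more polar complex surface is more likely to
stabilise.

Fitting is maximum likelihood by Newton–Raphson; predictive accuracy is
estimated by repeated k-fold cross validation (100 rounds of 4-fold by
default). The LASSO step for the 2-D model uses scikit-learn's
coordinate-descent solver with the penalty chosen by cross-validated MSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .descriptors2d import Fasa2DModel


@dataclass
class LogisticModel:
    """Coefficients on the log(P_f/P_s) scale: intercept b0 and slope b1.

    ``separation`` flags a fit whose likelihood had no finite maximiser
    (perfectly separated data); the returned coefficients are then the large
    values at which iteration stopped.
    """

    b0: float
    b1: float
    separation: bool = False

    def predict_ps(self, x) -> np.ndarray | float:
        """Probability of success, strictly increasing in x when b1 < 0."""
        x = np.asarray(x, dtype=float)
        eta = np.clip(self.b0 + self.b1 * x, -500, 500)
        out = 1.0 / (1.0 + np.exp(eta))
        return float(out) if out.ndim == 0 else out


#: Logistic model on simulated FASA_p (16 drug–excipient pairs).
REF_SIM = LogisticModel(b0=6.14, b1=-26.1)
#: Logistic model on 2-D-predicted FASA_p (same 16 pairs).
REF_2D = LogisticModel(b0=13.5, b1=-58.0)


@dataclass
class CvReport:
    """Repeated k-fold classification accuracy (mean, std over rounds×folds)."""

    mean_accuracy: float
    std_accuracy: float
    k: int
    rounds: int
    seed: int
    n_folds_scored: int = 0
    n_folds_skipped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_accuracy <= 1.0) or self.std_accuracy < 0:
            raise ValueError("invalid accuracy summary")


@dataclass
class StabilityRecord:
    """One drug–excipient pair: min wt.% when stable, else a failure."""

    drug: str
    excipient: str
    min_wt_pct: Optional[float] = None
    success: Optional[bool] = None

    def __post_init__(self) -> None:
        present = self.min_wt_pct is not None
        if self.success is None:
            self.success = present
        elif self.success != present:
            raise ValueError(
                f"record ({self.drug}, {self.excipient}): success flag "
                "contradicts min wt.% presence"
            )


def predict_ps(model: LogisticModel, x) -> np.ndarray | float:
    """P_s(x) under a log(P_f/P_s) = b0 + b1·x model."""
    return model.predict_ps(x)


def fit_logistic(
    x: Sequence[float],
    labels: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood logistic fit, reported on the log(P_f/P_s) scale.

    Newton–Raphson on the standard log-odds-of-success parameterisation,
    converged when the gradient norm drops below ``tol``; the returned
    (b0, b1) are the negated coefficients so that
    P_s = 1/(1+exp(b0+b1·x)). Perfect separation is detected (coefficients
    diverging without gradient convergence) and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matching x/labels with n >= 2")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [0.0, 1.0]):
        raise ValueError("labels must contain both classes 0 and 1")

    X = np.column_stack([np.ones_like(x), x])
    w = np.zeros(2)
    separation = False
    for _ in range(max_iter):
        eta = X @ w
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        g = X.T @ (y - p)
        if np.linalg.norm(g) < tol:
            # a "converged" fit whose probabilities are all saturated and
            # label-perfect means the likelihood has no finite maximiser
            if np.all(np.where(y == 1, p > 1 - 1e-6, p < 1e-6)):
                separation = True
            break
        s = np.maximum(p * (1.0 - p), 1e-12)
        H = X.T @ (X * s[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            separation = True
            break
        w = w + step
        if np.abs(w).max() > 1e4:
            separation = True
            break
    else:
        if np.linalg.norm(g) >= tol:
            separation = True
    return LogisticModel(b0=float(-w[0]), b1=float(-w[1]), separation=separation)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matching vectors with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    return float(stats.pearsonr(x, y).statistic)


def fit_lasso(
    features,
    y: Sequence[float],
    lambda_grid: Optional[Sequence[float]] = None,
    cv_folds: int = 4,
    seed: int = 0,
    use_cv: bool = True,
) -> tuple[Fasa2DModel, dict]:
    """L1-penalised linear fit of FASA_p on the six descriptor ratios.

    Coordinate-descent LASSO (scikit-learn) over a log-spaced penalty grid;
    the penalty minimising k-fold cross-validated MSE is selected, then the
    model is refit on all data at that penalty. ``lambda_grid`` entries are
    the sklearn ``alpha`` (objective (1/2n)·RSS + alpha·||w||1); an entry of
    0 falls back to ordinary least squares. With ``use_cv=False`` the
    training MSE picks the penalty instead (which degenerates to the
    smallest grid value).

    Returns the fitted :class:`Fasa2DModel` and a diagnostics dict.
    """
    import pandas as pd
    from sklearn.linear_model import Lasso, LinearRegression
    from sklearn.model_selection import KFold

    X = np.asarray(
        features.values if isinstance(features, pd.DataFrame) else features, float
    )
    y = np.asarray(y, float)
    n = y.size
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError("features must be (n, p) matching y")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate (constant) features")
    if lambda_grid is None:
        lambda_grid = np.concatenate([[0.0], np.logspace(-6, 0, 25)])
    lambda_grid = np.asarray(list(lambda_grid), float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    if not (2 <= cv_folds < n):
        raise ValueError("need n > cv_folds >= 2")

    def _fit(alpha: float, Xf, yf):
        if alpha == 0.0:
            return LinearRegression().fit(Xf, yf)
        return Lasso(alpha=alpha, max_iter=50000, tol=1e-10).fit(Xf, yf)

    scores = np.zeros(lambda_grid.size)
    if use_cv:
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        for i, lam in enumerate(lambda_grid):
            mse = []
            for tr, te in kf.split(X):
                est = _fit(lam, X[tr], y[tr])
                mse.append(float(np.mean((est.predict(X[te]) - y[te]) ** 2)))
            scores[i] = np.mean(mse)
    else:
        for i, lam in enumerate(lambda_grid):
            est = _fit(lam, X, y)
            scores[i] = float(np.mean((est.predict(X) - y) ** 2))

    best = int(np.argmin(scores))
    est = _fit(lambda_grid[best], X, y)
    coef = np.asarray(est.coef_, float)
    model = Fasa2DModel(
        ha_drug=float(coef[0]),
        hd_drug=float(coef[1]),
        ha_exc=float(coef[2]),
        hd_exc=float(coef[3]),
        q_drug=float(coef[4]),
        q_exc=float(coef[5]),
        intercept=float(est.intercept_),
    )
    info = {
        "lambda": float(lambda_grid[best]),
        "cv_mse": float(scores[best]),
        "lambda_grid": lambda_grid.tolist(),
        "mse_path": scores.tolist(),
        "seed": seed,
    }
    return model, info


def repeated_kfold_accuracy(
    x: Sequence[float],
    labels: Sequence[int],
    k: int = 4,
    rounds: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
) -> CvReport:
    """Repeated k-fold cross-validated classification accuracy.

    Each round partitions the data uniformly at random into k folds, fits the
    logistic model on k−1 folds, and classifies the held-out fold at
    P_s ≥ ``threshold``. Accuracies are pooled over every round × fold; folds
    whose *training* set is single-class are skipped with a warning
    (single-class test folds are still scored).
    """
    x = np.asarray(x, float)
    y = np.asarray(labels, int)
    n = x.size
    if n < k:
        raise ValueError("need n >= k")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    rng = np.random.default_rng(seed)
    accs: list[float] = []
    skipped = 0
    for _ in range(rounds):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fold in folds:
            test = fold
            train = np.setdiff1d(perm, fold, assume_unique=True)
            if np.unique(y[train]).size < 2:
                skipped += 1
                warnings.warn("skipping fold with single-class training set")
                continue
            model = fit_logistic(x[train], y[train])
            pred = (np.atleast_1d(model.predict_ps(x[test])) >= threshold).astype(int)
            accs.append(float(np.mean(pred == y[test])))
    if not accs:
        raise ValueError("no scorable folds")
    return CvReport(
        mean_accuracy=float(np.mean(accs)),
        std_accuracy=float(np.std(accs)),
        k=k,
        rounds=rounds,
        seed=seed,
        n_folds_scored=len(accs),
        n_folds_skipped=skipped,
    )


def label_outcomes(records: Sequence[StabilityRecord]) -> np.ndarray:
    """Binary success vector from stability records (1 = min wt.% recorded)."""
    labels = np.array([1 if r.success else 0 for r in records], dtype=int)
    if labels.size and labels.sum() == 0:
        warnings.warn("all records are failures; downstream fits are impossible")
    return labels
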