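"""Per-feature genetic predictors: dual-form ridge and elastic net.

Brain features are extremely polygenic, so ridge — which spreads weight
over all variants — is the default model. With P variants >> n samples the
primal ridge solve is infeasible; the matrix push-through identity turns it
into an n x n solve on the GRM:

    w(theta) = (theta / P) * X' (theta * Sigma + (1 - theta) * I)^{-1} B,

where Sigma = X X' / P and theta = P / (P + lambda) in (0, 1) replaces the
raw penalty. The n x n system is solved once per training set via an
eigendecomposition of Sigma shared across the whole theta grid, so scanning
the grid is nearly free.

Elastic net (mixing alpha, default 0.1) is the sparse alternative; it wins
when a feature's genetic basis concentrates on few variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import GenotypeSet

logger = logging.getLogger(__name__)

#: Default theta grid for ridge hyperparameter search.
DEFAULT_THETA_GRID = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95)


@dataclass
class RidgeSpec:
    """Ridge model search space over theta = P / (P + lambda)."""

    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID

    def __post_init__(self) -> None:
        g = tuple(self.theta_grid)
        if not all(0.0 < t < 1.0 for t in g):
            raise ValueError("all theta must be in (0, 1)")
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("theta grid must be strictly increasing")
        self.theta_grid = g


@dataclass
class EnetSpec:
    """Elastic-net search space: fixed mixing alpha, lambda path length,
    and the validation fraction of the 80/20 selection split."""

    alpha: float = 0.1
    n_lambda: int = 50
    validation_fraction: float = 0.2
    lambda_min_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class PerformanceRecord:
    """Aggregated out-of-fold prediction performance for one feature."""

    feature_id: str
    model_type: str
    cv_R2: float
    cv_pearson: float
    cv_spearman: float
    selected_hyperparameter: float
    seed: int


def fit_ridge(
    B: np.ndarray,
    X_std: np.ndarray,
    theta: float,
    sigma: np.ndarray | None = None,
) -> np.ndarray:
    """Dual-form ridge weights at a single theta.

    ``B`` must be mean-centered and ``X_std`` column-standardized; ``sigma``
    is the n x n GRM X X' / P (computed if omitted). Equivalent to the
    primal solution (X'X + lambda I)^{-1} X'B with lambda = P(1-theta)/theta.
    """
    B = np.asarray(B, dtype=float)
    n, P = X_std.shape
    if sigma is None:
        sigma = (X_std @ X_std.T) / P
    A = theta * sigma + (1.0 - theta) * np.eye(n)
    try:
        alpha = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"dual ridge system singular at theta={theta}: {e}")
    return (theta / P) * (X_std.T @ alpha)


def _ridge_path_weights(
    B: np.ndarray, X_std: np.ndarray, thetas: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Dual coefficients alpha(theta) for every theta via one shared
    eigendecomposition of Sigma; returns the n x len(thetas) matrix of
    dual solutions (weights are (theta/P) X' alpha)."""
    n, P = X_std.shape
    if eig is None:
        sigma = (X_std @ X_std.T) / P
        vals, vecs = np.linalg.eigh(sigma)
    else:
        vals, vecs = eig
    Bt = vecs.T @ B
    out = np.empty((n, len(thetas)))
    for i, t in enumerate(thetas):
        out[:, i] = vecs @ (Bt / (t * vals + (1.0 - t)))
    return out


def _soft_threshold(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def fit_elastic_net(
    B: np.ndarray, X_std: np.ndarray, spec: EnetSpec | None = None, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Elastic-net weights with lambda chosen on a held-out split.

    Minimizes (1/2N)||B - Xw||^2 + lambda * (alpha ||w||_1 +
    (1-alpha)/2 ||w||^2) along a decreasing 50-point lambda path from
    lambda_max = max_j |x_j'B| / (N alpha). Lambda is selected by Pearson
    correlation between prediction and truth on a random
    ``validation_fraction`` hold-out, then the model is refit on all
    samples at the chosen lambda. Returns (weights, selected lambda).
    """
    from sklearn.linear_model import ElasticNet
    from sklearn.exceptions import ConvergenceWarning

    if spec is None:
        spec = EnetSpec()
    B = np.asarray(B, dtype=float)
    n, P = X_std.shape
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(int(round(n * spec.validation_fraction)), 1)
    val, train = perm[:n_val], perm[n_val:]

    Bc = B - B[train].mean()
    lam_max = np.max(np.abs(X_std[train].T @ Bc[train])) / (len(train) * spec.alpha)
    if lam_max <= 0:
        warnings.warn("all-zero elastic-net model (degenerate response)")
        return np.zeros(P), 0.0
    path = np.geomspace(lam_max, lam_max * spec.lambda_min_ratio, spec.n_lambda)

    best_lam, best_r = None, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = ElasticNet(l1_ratio=spec.alpha, fit_intercept=True, warm_start=True,
                           max_iter=2000)
        for lam in path:
            model.set_params(alpha=lam)
            model.fit(X_std[train], B[train])
            pred = model.predict(X_std[val])
            if np.std(pred) == 0 or np.std(B[val]) == 0:
                r = -np.inf
            else:
                r = float(np.corrcoef(pred, B[val])[0, 1])
            if r > best_r:
                best_r, best_lam = r, float(lam)
        if best_lam is None or not np.isfinite(best_r):
            warnings.warn("elastic net: all-zero model wins; returning zero weights")
            return np.zeros(P), float(path[0])
        final = ElasticNet(alpha=best_lam, l1_ratio=spec.alpha, fit_intercept=True,
                           max_iter=5000)
        final.fit(X_std, B)
    if not np.any(final.coef_):
        warnings.warn("elastic net: all-zero model wins; returning zero weights")
    return final.coef_.copy(), best_lam


def _standardize_split(X_train: np.ndarray, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize with training-split moments only (no leakage)."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"monomorphic variant in training fold at columns "
                         f"{np.flatnonzero(sd == 0).tolist()}")
    return (X_train - mu) / sd, (X_test - mu) / sd


def _select_theta_cv(
    B: np.ndarray, X: np.ndarray, thetas: np.ndarray, k: int, rng: np.random.Generator
) -> float:
    """Inner k-fold CV over the theta grid, maximizing out-of-fold Pearson."""
    n = X.shape[0]
    folds = rng.permutation(n) % k
    preds = np.zeros((n, len(thetas)))
    for f in range(k):
        tr, te = folds != f, folds == f
        Xtr, Xte = _standardize_split(X[tr], X[te])
        Btr = B[tr] - B[tr].mean()
        P = Xtr.shape[1]
        dual = _ridge_path_weights(Btr, Xtr, thetas)
        # predict held-out: Xte @ w = (theta/P) * Xte @ Xtr' @ alpha
        cross = Xte @ Xtr.T
        for i, t in enumerate(thetas):
            preds[te, i] = (t / P) * (cross @ dual[:, i])
    rs = np.array([
        np.corrcoef(preds[:, i], B)[0, 1] if np.std(preds[:, i]) > 0 else -np.inf
        for i in range(len(thetas))
    ])
    return float(thetas[int(np.argmax(rs))])


def cross_validate(
    feature: np.ndarray,
    genotypes: GenotypeSet,
    model: RidgeSpec | EnetSpec,
    k: int = 5,
    seed: int = 0,
    feature_id: str = "feature",
) -> PerformanceRecord:
    """k-fold cross-validated prediction performance for one feature.

    Fold assignment is a seeded permutation. Within each outer training
    set, hyperparameters are selected using only that set (ridge: inner
    k-fold CV over the theta grid; elastic net: 80/20 split), the model is
    refit, and the held-out fold is predicted. Out-of-fold predictions are
    concatenated and R^2, Pearson, and Spearman computed once on the
    aggregate. Standardization moments come from each training split only.
    """
    y = np.asarray(feature, dtype=float)
    X = genotypes.dosages
    n = X.shape[0]
    if n < 2 * k:
        raise ValueError(f"need at least {2*k} samples for {k}-fold CV")
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % k
    pred = np.zeros(n)
    selected: list[float] = []

    for f in range(k):
        tr, te = folds != f, folds == f
        Xtr, Xte = _standardize_split(X[tr], X[te])
        ytr = y[tr]
        ytr_c = ytr - ytr.mean()
        if isinstance(model, RidgeSpec):
            theta = _select_theta_cv(ytr_c, X[tr], np.asarray(model.theta_grid), k, rng)
            w = fit_ridge(ytr_c, Xtr, theta)
            pred[te] = Xte @ w + ytr.mean()
            selected.append(theta)
        else:
            w, lam = fit_elastic_net(ytr, Xtr, model, seed=int(rng.integers(2**31)))
            pred[te] = Xte @ w + ytr.mean()
            selected.append(lam)

    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    pearson = float(np.corrcoef(pred, y)[0, 1]) if np.std(pred) > 0 else 0.0
    spearman = float(stats.spearmanr(pred, y).statistic) if np.std(pred) > 0 else 0.0
    return PerformanceRecord(
        feature_id=feature_id,
        model_type="ridge" if isinstance(model, RidgeSpec) else "enet",
        cv_R2=r2,
        cv_pearson=pearson,
        cv_spearman=spearman,
        selected_hyperparameter=float(np.median(selected)),
        seed=seed,
    )


def filter_predictors(perf: "pd.DataFrame", threshold: float = 0.1) -> list[str]:
    """Feature ids whose cross-validated Spearman correlation strictly
    exceeds ``threshold`` (poorly predicted features are dropped from the
    exported weight database)."""
    import pandas as pd  # noqa: F811

    if len(perf) == 0:
        return []
    keep = perf.loc[perf["cv_spearman"] > threshold, "feature_id"]
    return list(keep)
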