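"""Single-response partial least squares (NIPALS) with VIP scores.

PLS1 finds latent directions in the predictor block that maximize covariance
with a single response — here leaf delta13C, the integrative intrinsic-WUE
proxy — and the Variable-Importance-in-Projection (VIP) score summarizes how
much each predictor trait contributes to the response variance explained
across components.  Predictors with VIP > 1 are conventionally deemed
influential; the squared VIPs average to exactly 1 by construction.

Algorithm (per component, after autoscaling X and y to zero mean / unit sd):

    w_k = X'y / ||X'y||         (unit-norm weight vector)
    t_k = X w_k                 (score)
    p_k = X't_k / (t_k't_k)     (X loading)
    q_k = y't_k / (t_k't_k)     (y loading)
    X <- X - t_k p_k' ; y <- y - t_k q_k   (deflation of X and y)

For a single response this NIPALS form needs no inner iteration and is fully
deterministic.  VIP_j = sqrt( p * sum_k SSY_k w_jk^2 / sum_k SSY_k ) with
SSY_k = q_k^2 t_k't_k the response sum of squares captured by component k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError


@dataclass
class PLSModel:
    """Fitted PLS1 model on autoscaled data.

    ``weights`` (W), ``x_loadings`` (P) are predictors x components;
    ``y_loadings`` (q) has one entry per component; ``scores`` (T) is
    samples x components with mutually orthogonal columns;
    ``explained_y_variance`` is the fraction of (scaled) response variance
    captured per component.
    """

    n_components: int
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float
    y_sd: float
    explained_y_variance: np.ndarray
    predictor_names: list[str] = field(default_factory=list)

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients on the autoscaled data,
        B = W (P'W)^-1 q."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict the response on the original scale."""
        Xs = (np.asarray(X, dtype=float) - self.x_means) / self.x_sds
        return self.y_mean + self.y_sd * (Xs @ self.coefficients)


@dataclass
class VIPResult:
    scores: dict[str, float]
    selected: list[str]
    threshold: float


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{j + 1}" for j in range(arr.shape[1])]


def fit_pls1(X, y, n_components: int = 2) -> PLSModel:
    """Fit single-response PLS by NIPALS with X- and y-deflation.

    X is samples x predictors (DataFrame keeps trait names), y a vector.
    Both blocks are autoscaled so trait units are immaterial.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if yv.size != n:
        raise ConfigError("X row count must match length of y")
    if not 1 <= n_components <= min(n - 1, p):
        raise ConfigError(
            f"n_components must lie in [1, min(samples-1, predictors)] = "
            f"[1, {min(n - 1, p)}]"
        )
    x_sds = Xm.std(axis=0, ddof=1)
    if np.any(x_sds == 0):
        bad = [names[j] for j in np.flatnonzero(x_sds == 0)]
        raise DegenerateDataError(f"constant predictor(s): {', '.join(bad)}")
    y_sd = yv.std(ddof=1)
    if y_sd == 0:
        raise DegenerateDataError("constant response")
    x_means = Xm.mean(axis=0)
    y_mean = yv.mean()
    Xc = (Xm - x_means) / x_sds
    yc = (yv - y_mean) / y_sd
    ssy_total = float(yc @ yc)

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    explained = np.zeros(n_components)

    Xd, yd = Xc.copy(), yc.copy()
    for k in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            raise DegenerateDataError(
                f"no covariance left between X and y at component {k + 1}"
            )
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise DegenerateDataError(f"degenerate score at component {k + 1}")
        pk = (Xd.T @ t) / tt
        qk = float(yd @ t) / tt
        Xd -= np.outer(t, pk)
        yd -= qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, pk, qk, t
        explained[k] = qk**2 * tt / ssy_total

    return PLSModel(
        n_components=n_components,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        x_means=x_means,
        x_sds=x_sds,
        y_mean=float(y_mean),
        y_sd=float(y_sd),
        explained_y_variance=explained,
        predictor_names=names,
    )


def vip_scores(model: PLSModel, threshold: float = 1.0) -> VIPResult:
    """Variable importance in projection for every predictor.

    VIP_j = sqrt( p * sum_k SSY_k (w_jk / ||w_k||)^2 / sum_k SSY_k );
    sum_j VIP_j^2 = p exactly.  ``selected`` holds predictors with
    VIP > ``threshold`` (default 1, the conventional cutoff).
    """
    ssy = model.explained_y_variance
    total = ssy.sum()
    if total <= 0:
        raise DegenerateDataError("model explains no response variance")
    p = model.weights.shape[0]
    w_norm2 = (model.weights**2) / (model.weights**2).sum(axis=0)
    vip = np.sqrt(p * (w_norm2 @ ssy) / total)
    scores = {name: float(v) for name, v in zip(model.predictor_names, vip)}
    selected = [name for name, v in scores.items() if v > threshold]
    return VIPResult(scores=scores, selected=selected, threshold=threshold)


def choose_components(
    X,
    y,
    max_components: int | None = None,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Pick the component count by cross-validated prediction error.

    K-fold cross-validation with a seeded shuffle scores each candidate
    count; the one-standard-error rule then returns the smallest count whose
    mean CV error lies within one standard error (across folds) of the
    minimum, breaking effective ties toward fewer components.
    ``max_components`` defaults to the largest admissible count.
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    if folds > n:
        raise ConfigError(f"folds ({folds}) cannot exceed samples ({n})")
    min_train = n - (n // folds + (1 if n % folds else 0))
    kmax_allowed = min(min_train - 1, p)
    kmax = kmax_allowed if max_components is None else min(max_components, kmax_allowed)
    if kmax < 1:
        raise ConfigError("too few samples for cross-validation")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, folds)
    fold_mse = np.zeros((folds, kmax))
    for f, test_idx in enumerate(fold_ids):
        train_idx = np.setdiff1d(order, test_idx)
        for k in range(1, kmax + 1):
            model = fit_pls1(Xm[train_idx], yv[train_idx], n_components=k)
            resid = yv[test_idx] - model.predict(Xm[test_idx])
            fold_mse[f, k - 1] = float(resid @ resid) / test_idx.size
    mean_mse = fold_mse.mean(axis=0)
    se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_mse))
    cutoff = mean_mse[best] + se_mse[best]
    return int(np.flatnonzero(mean_mse <= cutoff)[0]) + 1
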