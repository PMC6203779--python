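"""Mixture models and partial correlations for directionality analysis.

Three pieces: (i) a 1-D Gaussian mixture with BIC component selection for
log forward/reverse initiation ratios, (ii) Spearman partial correlations
over directional feature tables via the precision matrix of the rank
correlation, and (iii) a two-component mixture of linear regressions
(EM / clusterwise regression) that predicts the initiation log-ratio from
the core-promoter sequence-score ratio and the H3K4me3 ratio, with
ten-fold cross-validation over feature subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm, rankdata

# ---------------------------------------------------------------------------
# 1-D Gaussian mixture + BIC


@dataclass
class Gmm1d:
    K: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    bic: float
    n: int


def fit_gmm_1d(values: np.ndarray, K: int, n_init: int = 5, seed: int = 0) -> Gmm1d:
    """Unequal-variance 1-D Gaussian mixture fitted by EM.

    BIC = -2 log L + p ln n with p = 3K - 1 free parameters (K means,
    K variances, K-1 weights); smaller is better.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float).reshape(-1, 1)
    n = values.shape[0]
    if K > n:
        raise ValueError("more components than observations")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        n_init=n_init,
        random_state=seed,
        reg_covar=1e-6,
    ).fit(values)
    loglik = float(gm.score(values) * n)
    p = 3 * K - 1
    bic = -2.0 * loglik + p * np.log(n)
    order = np.argsort(gm.means_.ravel())
    return Gmm1d(
        K=K,
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        variances=gm.covariances_.reshape(K)[order],
        loglik=loglik,
        bic=float(bic),
        n=n,
    )


def select_k(
    values: np.ndarray, K_range: range | list[int], n_init: int = 5, seed: int = 0
) -> tuple[int, dict[int, Gmm1d]]:
    """Pick the mixture size minimizing BIC; ties go to the smaller K."""
    fits = {K: fit_gmm_1d(values, K, n_init=n_init, seed=seed) for K in K_range}
    best = min(fits, key=lambda K: (round(fits[K].bic, 9), K))
    return best, fits


# ---------------------------------------------------------------------------
# Spearman partial correlation


def partial_correlation(features: pd.DataFrame) -> pd.DataFrame:
    """Spearman partial correlation of every pair given all other columns.

    Columns are rank-transformed (average ranks on ties); the partial
    correlation is read off the precision matrix P of the rank correlation
    matrix as -P_ij / sqrt(P_ii P_jj), diagonal 1.  A singular correlation
    matrix falls back to the pseudoinverse with a warning.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    if features.shape[0] <= features.shape[1] + 2:
        raise ValueError("need n > #columns + 2 observations")
    ranks = np.column_stack([rankdata(features[c]) for c in features.columns])
    R = np.corrcoef(ranks, rowvar=False)
    try:
        P = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("rank correlation matrix singular; using pseudoinverse")
        P = np.linalg.pinv(R)
    d = np.sqrt(np.diag(P))
    pcorr = -P / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    return pd.DataFrame(pcorr, index=features.columns, columns=features.columns)


# ---------------------------------------------------------------------------
# Mixture of linear regressions


@dataclass
class MixtureLinearModel:
    """K sets of linear-regression coefficients over standardized predictors.

    ``coef`` has shape (K, n_features + 1) with the intercept first;
    predictors are standardized internally with the training moments stored
    in ``x_mean``/``x_std`` (the response is left on its original scale).
    """

    K: int
    coef: np.ndarray
    sigma2: np.ndarray
    weights: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    loglik: float
    responsibilities: np.ndarray
    assignment: np.ndarray
    skewed_component: int
    loglik_history: list[float] = field(default_factory=list)

    def _design(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        return np.column_stack([np.ones(len(Z)), Z])

    def component_predictions(self, X: np.ndarray) -> np.ndarray:
        """(n, K) linear predictions of every component."""
        return self._design(X) @ self.coef.T

    def responsibilities_for(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        preds = self.component_predictions(X)
        log_r = np.log(self.weights)[None, :] + norm.logpdf(
            np.asarray(y, dtype=float)[:, None], preds, np.sqrt(self.sigma2)[None, :]
        )
        return np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))


def _em_once(
    D: np.ndarray, y: np.ndarray, K: int, rng: np.random.Generator,
    max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, list[float]]:
    n, p = D.shape
    resp = rng.dirichlet(np.ones(K), size=n)
    coef = np.zeros((K, p))
    sigma2 = np.ones(K)
    weights = np.full(K, 1.0 / K)
    history: list[float] = []
    loglik = -np.inf
    for _ in range(max_iter):
        # M-step: weighted least squares per component
        for k in range(K):
            w = resp[:, k]
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(D * sw[:, None], y * sw, rcond=None)
            coef[k] = beta
            res = y - D @ beta
            sigma2[k] = max((w * res**2).sum() / max(w.sum(), 1e-12), 1e-8)
        weights = resp.mean(axis=0)
        if (weights < 1.0 / n).any():
            raise _ComponentCollapse
        # E-step
        log_r = np.log(weights)[None, :] + norm.logpdf(
            y[:, None], D @ coef.T, np.sqrt(sigma2)[None, :]
        )
        norm_c = logsumexp(log_r, axis=1)
        new_loglik = float(norm_c.sum())
        resp = np.exp(log_r - norm_c[:, None])
        history.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol * max(1.0, abs(loglik)):
            loglik = new_loglik
            break
        loglik = new_loglik
    return coef, sigma2, weights, resp, loglik, history


class _ComponentCollapse(Exception):
    pass


def fit_mixture_linear(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 2,
    n_init: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MixtureLinearModel:
    """EM over K Gaussian-error linear regressions; best of ``n_init`` restarts.

    Features are standardized internally (mean 0, sd 1 on the training
    data); the response is not.  A restart whose smallest mixing weight
    collapses below 1/n is abandoned with a warning and re-drawn.  K=1
    reduces exactly to ordinary least squares.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) != 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in predictors or response")
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    x_std[x_std == 0] = 1.0
    D = np.column_stack([np.ones(len(y)), (X - x_mean) / x_std])

    rng = np.random.default_rng(seed)
    best = None
    attempts = 0
    done = 0
    while done < n_init and attempts < 5 * n_init:
        attempts += 1
        try:
            result = _em_once(D, y, K, rng, max_iter, tol)
        except _ComponentCollapse:
            warnings.warn("mixture component collapsed; restarting")
            continue
        done += 1
        if best is None or result[4] > best[4]:
            best = result
    if best is None:
        raise RuntimeError("all EM restarts collapsed")
    coef, sigma2, weights, resp, loglik, history = best
    assignment = resp.argmax(axis=1)
    preds = D @ coef.T
    comp_mean_abs = np.array(
        [
            np.abs(preds[assignment == k, k]).mean() if (assignment == k).any() else 0.0
            for k in range(K)
        ]
    )
    return MixtureLinearModel(
        K=K,
        coef=coef,
        sigma2=sigma2,
        weights=weights,
        x_mean=x_mean,
        x_std=x_std,
        loglik=loglik,
        responsibilities=resp,
        assignment=assignment,
        skewed_component=int(comp_mean_abs.argmax()),
        loglik_history=history,
    )


def predict_directionality(
    model: MixtureLinearModel, X: np.ndarray, y: np.ndarray | None = None
) -> pd.DataFrame:
    """Predicted ratio and skewed/balanced class per region.

    Each region is assigned to the mixture component with the higher
    posterior probability (using the measured ratio ``y`` when available,
    otherwise the mixing weights alone) and receives that component's linear
    prediction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    preds = model.component_predictions(X)
    if y is not None:
        resp = model.responsibilities_for(X, y)
        assignment = resp.argmax(axis=1)
    else:
        assignment = np.full(len(X), int(model.weights.argmax()))
    predicted = preds[np.arange(len(X)), assignment]
    klass = np.where(
        assignment == model.skewed_component, "skewed", "balanced"
    )
    return pd.DataFrame(
        {"predicted_ratio": predicted, "component": assignment, "class": klass}
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    K: int = 2,
    n_init: int = 5,
    feature_sets: dict[str, list[int]] | None = None,
) -> pd.DataFrame:
    """Ten-fold CV of the mixture-linear predictor over feature subsets.

    For each fold the model is fitted on the remaining data and held-out
    regions are predicted (component assignment uses the held-out measured
    ratios, mirroring the fitting procedure); the per-fold score is the
    Pearson correlation between predicted and measured ratios.  By default
    three feature sets are compared when two predictors are given: both,
    first only, second only.
    """
    from sklearn.model_selection import KFold

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    if len(y) < 10 * folds:
        raise ValueError("need at least 10 observations per fold")
    if feature_sets is None:
        if X.shape[1] == 2:
            feature_sets = {"both": [0, 1], "feature0_only": [0], "feature1_only": [1]}
        else:
            feature_sets = {"all": list(range(X.shape[1]))}
    rows = []
    for name, cols in feature_sets.items():
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        for fold, (train_idx, test_idx) in enumerate(kf.split(X)):
            if len(test_idx) < 3:
                raise ValueError("fold with fewer than 3 points")
            model = fit_mixture_linear(
                X[np.ix_(train_idx, cols)], y[train_idx], K=K, n_init=n_init,
                seed=seed + 1000 * fold,
            )
            pred = predict_directionality(
                model, X[np.ix_(test_idx, cols)], y=y[test_idx]
            )["predicted_ratio"].to_numpy()
            with np.errstate(invalid="ignore"):
                r = float(np.corrcoef(pred, y[test_idx])[0, 1])
            rows.append({"feature_set": name, "fold": fold, "correlation": r})
    return pd.DataFrame(rows)
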