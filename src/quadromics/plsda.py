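"""Partial least squares discriminant analysis (PLS-DA) with VIP scores.

PLS-DA projects the feature matrix onto latent components that maximise
covariance with a two-class response, then scores each feature's influence
with the variable importance in projection (VIP).  Components are extracted
sequentially (NIPALS for a univariate response): for component *a*

    w_a ∝ X_a' y,   ||w_a|| = 1
    t_a = X_a w_a
    p_a = X_a' t_a / (t_a' t_a)
    b_a = y' t_a / (t_a' t_a)
    X_{a+1} = X_a - t_a p_a',   y (response residual) deflated by b_a t_a

and the Wold VIP of feature j over A components is

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

with p the number of features and SSY_a = b_a^2 t_a't_a the response sum
of squares explained by component a.  This normalisation gives the exact
identity sum_j VIP_j^2 = p for every fit.

The estimator follows scikit-learn conventions (fit / transform / predict,
``get_params``/``set_params``, fitted attributes with trailing underscores)
and composes with sklearn pipelines.  Sign convention: the first non-zero
entry of each weight vector is positive, so fits are deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["PLSDiscriminantAnalysis", "vip_scores"]


class PLSDiscriminantAnalysis(TransformerMixin, BaseEstimator):
    """Two-class PLS-DA via sequential NIPALS extraction.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent components requested.  Extraction stops early
        (with a warning) if the residual rank is exhausted.
    scale : bool, default True
        Mean-centre and unit-variance scale columns of X before fitting.
        Constant columns are left centred (scale divisor 1).

    Attributes
    ----------
    x_weights_ : (n_features, A) unit-norm weight vectors w_a.
    x_scores_ : (n_samples, A) score vectors t_a.
    x_loadings_ : (n_features, A) loadings p_a.
    y_loadings_ : (A,) regression coefficients b_a of y on t_a.
    explained_ssy_ : (A,) response sum of squares explained per component.
    vip_ : (n_features,) variable importance in projection.
    classes_ : the two class labels, sorted.
    """

    def __init__(self, n_components: int = 2, scale: bool = True) -> None:
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y) -> "PLSDiscriminantAnalysis":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent sample counts")
        classes = np.unique(y)
        if classes.shape[0] != 2:
            raise ValueError(f"PLS-DA requires exactly 2 classes, got {classes.shape[0]}")
        for cls in classes:
            if (y == cls).sum() < 2:
                raise ValueError("each class needs at least 2 samples")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.classes_ = classes
        # dummy response: -1 / +1, then centred
        yv = np.where(y == classes[1], 1.0, -1.0)
        yv = yv - yv.mean()

        self._x_mean = X.mean(axis=0)
        Xc = X - self._x_mean
        if self.scale:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self._x_scale = sd
        else:
            self._x_scale = np.ones(X.shape[1])
        Xc = Xc / self._x_scale

        n, p = Xc.shape
        max_rank = min(n - 1, p)
        A = min(self.n_components, max_rank)

        weights, scores, loadings, betas, ssy = [], [], [], [], []
        Xr = Xc.copy()
        yr = yv.copy()
        eps = np.finfo(float).eps
        for _ in range(A):
            w = Xr.T @ yr
            norm = np.linalg.norm(w)
            if norm <= 1e3 * eps * max(1.0, np.abs(Xr).max()):
                break  # residual carries no covariance with the response
            w = w / norm
            # deterministic sign: first non-zero entry positive
            nz = np.flatnonzero(np.abs(w) > 1e-12)
            if nz.size and w[nz[0]] < 0:
                w = -w
            t = Xr @ w
            tt = t @ t
            if tt <= 1e3 * eps:
                break
            pl = Xr.T @ t / tt
            b = yr @ t / tt
            Xr = Xr - np.outer(t, pl)
            yr = yr - b * t
            weights.append(w)
            scores.append(t)
            loadings.append(pl)
            betas.append(b)
            ssy.append(b * b * tt)

        if not weights:
            raise ValueError("no PLS component could be extracted (X carries no class signal)")
        if len(weights) < self.n_components:
            warnings.warn(
                f"requested {self.n_components} components, extracted {len(weights)} "
                "(rank exhausted)",
                UserWarning,
                stacklevel=2,
            )
        self.x_weights_ = np.column_stack(weights)
        self.x_scores_ = np.column_stack(scores)
        self.x_loadings_ = np.column_stack(loadings)
        self.y_loadings_ = np.asarray(betas)
        self.explained_ssy_ = np.asarray(ssy)
        self.n_components_ = self.x_weights_.shape[1]
        self.n_features_in_ = p
        self.vip_ = vip_scores(self)
        return self

    def transform(self, X) -> np.ndarray:
        """Project new samples onto the latent components."""
        check_is_fitted(self, "x_weights_")
        X = np.asarray(X, dtype=float)
        Xc = (X - self._x_mean) / self._x_scale
        # R = W (P'W)^-1 maps X to scores accounting for deflation
        PW = self.x_loadings_.T @ self.x_weights_
        R = self.x_weights_ @ np.linalg.inv(PW)
        return Xc @ R

    def decision_function(self, X) -> np.ndarray:
        scores = self.transform(X)
        return scores @ self.y_loadings_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes_[1], self.classes_[0])


def vip_scores(model: PLSDiscriminantAnalysis) -> np.ndarray:
    """Wold VIP over all extracted components of a fitted PLS-DA model.

    Raises if the model explains no response variance.
    """
    check_is_fitted(model, "x_weights_")
    ssy = model.explained_ssy_
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains zero response variance; VIP undefined")
    W = model.x_weights_
    # columns are unit norm already; normalise defensively
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    p = W.shape[0]
    return np.sqrt(p * (wn**2 @ ssy) / total)
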