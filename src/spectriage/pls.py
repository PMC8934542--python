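"""Partial-least-squares discriminant analysis with a logistic probability link.

This is the per-spectrum classifier of the pipeline: PLS1 regression of a
binary class indicator on the preprocessed spectra, computed by NIPALS with
deflation, followed by a univariate logistic calibration mapping the latent
regression score to a cancer probability. The fit is fully deterministic —
for a univariate response the NIPALS weight update has the closed form
w = X'y / ||X'y||, the dominant direction of the covariance X'y y'X — and a
sign convention (largest-magnitude weight element positive) fixes the
remaining ambiguity.

Components are nested: the model fitted with k_max components contains the
model for every k <= k_max, which the tuner exploits to sweep a component
grid from a single fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

#: probabilities are clipped into this open interval
_PROB_EPS = 1e-12
_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class PlsModel:
    """Fitted PLS-DA model (coefficients on the *full* input feature space).

    Zero-variance features are excluded from the fit and carry zero regression
    coefficient, so their values never influence predictions.
    """

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray        # (n_features, k), zero rows at dropped features
    loadings: np.ndarray       # (n_features, k)
    y_loadings: np.ndarray     # (k,)
    coefficients_path: np.ndarray = field(repr=False)  # (k, n_features)
    link_intercept: float = 0.0
    link_slope: float = 1.0
    train_scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def regression_coefficients(self) -> np.ndarray:
        """Per-feature regression vector at the model's component count."""
        return self.coefficients_path[self.n_components - 1]

    def latent_score(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        """Raw regression prediction y_mean + (X - x_mean)/x_scale @ B_k."""
        k = self.n_components if k is None else k
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"feature length {X.shape[1]} does not match model "
                f"({self.x_mean.size})")
        Xc = (X - self.x_mean) / self.x_scale
        return self.y_mean + Xc @ self.coefficients_path[k - 1]

    def truncated(self, k: int) -> "PlsModel":
        """The nested sub-model using only the first `k` components.

        The logistic link is *not* refitted; callers that need a calibrated
        sub-model should refit the link on training scores at `k`.
        """
        if not 1 <= k <= self.coefficients_path.shape[0]:
            raise ValueError(f"k={k} outside fitted component range")
        return PlsModel(
            n_components=k, x_mean=self.x_mean, x_scale=self.x_scale,
            y_mean=self.y_mean, weights=self.weights[:, :k],
            loadings=self.loadings[:, :k], y_loadings=self.y_loadings[:k],
            coefficients_path=self.coefficients_path,
            link_intercept=self.link_intercept, link_slope=self.link_slope)


def _encode_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        y = (y == "positive").astype(float)
    y = y.astype(float)
    classes = np.unique(y)
    if classes.size != 2 or not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError(
            "labels must contain exactly the two classes 0/negative and "
            f"1/positive; got {classes}")
    return y


def fit_pls(X: np.ndarray, y, n_components: int,
            fit_link: bool = True) -> PlsModel:
    """Fit PLS-DA by NIPALS with deflation.

    Parameters
    ----------
    X : (n_samples, n_features) array
        Preprocessed spectra; must be finite.
    y : array of {0,1} or {"negative","positive"}
        Per-spectrum class labels; both classes must be present.
    n_components : int
        Number of latent components, ``1 <= k <= min(n_samples-1, n_features)``.
    fit_link : bool
        Fit the logistic calibration on the training latent scores (maximum
        likelihood); disable when the caller calibrates separately.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    yv = _encode_labels(y)
    if yv.size != X.shape[0]:
        raise ValueError("X and y lengths differ")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} outside [1, {min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    variances = X.var(axis=0)
    keep = variances > 1e-24  # exact zeros plus accumulation fuzz of constants
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature(s) from the "
            "PLS fit", stacklevel=2)
    x_scale = np.ones(p)

    Xc = (X[:, keep] - x_mean[keep])
    y_mean = float(yv.mean())
    yc = yv - y_mean

    k = n_components
    pk = int(keep.sum())
    W = np.zeros((pk, k))
    P = np.zeros((pk, k))
    Q = np.zeros(k)
    T = np.zeros((n, k))
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(k):
        # NIPALS with univariate response: iterate w <- X'u/||.||, t = Xw,
        # u staying equal to the (deflated) response; converges in one pass
        # but is iterated to tolerance for fidelity to the general algorithm.
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-300:
            raise ValueError(
                f"residual covariance vanished at component {a + 1}; "
                "reduce n_components")
        w /= norm
        for _ in range(_NIPALS_MAX_ITER):
            t = Xd @ w
            q = float(yd @ t / (t @ t))
            u = yd * q  # univariate y: u direction fixed
            w_new = Xd.T @ yd
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        # sign convention: largest-magnitude weight element positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        p_load = Xd.T @ t / tt
        q = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p_load)
        yd = yd - q * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_load, q, t

    # regression coefficients for every component count 1..k
    coef_path = np.zeros((k, p))
    R = W @ np.linalg.inv(np.triu(P.T @ W))  # W (P'W)^{-1}, exploiting structure
    for a in range(k):
        coef_path[a, keep] = R[:, : a + 1] @ Q[: a + 1]

    model = PlsModel(
        n_components=k, x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
        weights=_expand(W, keep, p), loadings=_expand(P, keep, p),
        y_loadings=Q, coefficients_path=coef_path)
    model.train_scores = model.latent_score(X)
    if fit_link:
        model.link_intercept, model.link_slope = fit_logistic_link(
            model.train_scores, yv)
    return model


def _expand(M: np.ndarray, keep: np.ndarray, p: int) -> np.ndarray:
    out = np.zeros((p, M.shape[1]))
    out[keep] = M
    return out


def fit_logistic_link(scores: np.ndarray, y: np.ndarray,
                      C: float = 1000.0) -> tuple[float, float]:
    """Maximum-likelihood logistic calibration of 1-D scores.

    A weak ridge penalty (C=1000) keeps the slope finite on separable data;
    probabilities therefore never reach exactly 0 or 1.
    """
    yv = _encode_labels(y)
    lr = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
    lr.fit(np.asarray(scores, dtype=float).reshape(-1, 1), yv)
    return float(lr.intercept_[0]), float(lr.coef_[0, 0])


def predict_proba(model: PlsModel, X: np.ndarray,
                  k: int | None = None) -> np.ndarray:
    """Per-spectrum cancer probability in (0, 1), monotone in the latent score."""
    s = model.latent_score(X, k=k)
    z = model.link_intercept + model.link_slope * s
    return np.clip(1.0 / (1.0 + np.exp(-z)), _PROB_EPS, 1.0 - _PROB_EPS)
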