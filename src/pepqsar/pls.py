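"""Partial least squares regression (single response, NIPALS).

The calibration engine behind the QSAR model: X and y are autoscaled
(column mean-centred, unit variance; constant columns get scale 1 and
therefore zero weight), latent components are extracted by the NIPALS
deflation recursion, and regression coefficients are back-transformed to
the original units so prediction is a single affine map.

Validation statistics follow chemometrics convention:

* R² (calibration): 1 - SS_res / SS_tot over the fitted set.
* Q² (leave-one-out): 1 - PRESS / SS_tot, PRESS accumulating squared
  prediction errors of models refit without each sample in turn, with
  the autoscaling recomputed inside every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS regression model.

    Attributes
    ----------
    n_components : int
        Number of latent components A actually extracted (may be fewer
        than requested when the response is fit exactly early).
    x_mean, x_std, y_mean, y_std :
        Autoscaling parameters estimated from the training data.
    weights : (p, A) ndarray
        NIPALS weight vectors W (unit norm, per component).
    x_loadings : (p, A) ndarray
        Loadings P of the deflated X blocks.
    y_loadings : (A,) ndarray
        Response loadings q.
    scores : (n, A) ndarray
        Training-set score vectors T (mutually orthogonal columns).
    coef : (p,) ndarray
        Regression coefficients in original units.
    intercept : float
        Intercept in original units.
    """

    n_components: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray = field(default=None, repr=False)
    coef: np.ndarray = field(default=None)
    intercept: float = field(default=None)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def coef_for(self, a: int) -> tuple[np.ndarray, float]:
        """Coefficients/intercept of the nested sub-model with ``a`` components."""
        a = min(a, self.n_components)
        W, P, q = self.weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:a]
        # B = W (P'W)^-1 q in autoscaled space
        b_scaled = W @ np.linalg.solve(P.T @ W, q)
        coef = b_scaled * self.y_std / self.x_std
        intercept = self.y_mean - float(self.x_mean @ coef)
        return coef, intercept


def _autoscale(X: np.ndarray, y: np.ndarray):
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    x_std = np.where(x_std < _EPS, 1.0, x_std)  # constant columns -> zero weight
    y_mean = float(y.mean())
    y_std = float(y.std(ddof=1))
    if y_std < _EPS:
        raise ValueError("response has zero variance; PLS is undefined")
    return (X - x_mean) / x_std, (y - y_mean) / y_std, x_mean, x_std, y_mean, y_std


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a single-response PLS model by NIPALS.

    Parameters
    ----------
    X : (n, p) array_like
    y : (n,) array_like
    n_components : int
        Requested number of latent components A; must satisfy
        ``1 <= A <= min(n - 1, p)``.  Extraction stops early if the
        response residual or the candidate weight vector vanishes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} values")
    a_max = min(n - 1, p)
    if not 1 <= n_components <= a_max:
        raise ValueError(f"n_components must be in [1, {a_max}], got {n_components}")

    Xc, yc, x_mean, x_std, y_mean, y_std = _autoscale(X, y)
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xd, yd = Xc.copy(), yc.copy()
    a_used = 0
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break  # response residual orthogonal to X residual
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        P[:, a] = Xd.T @ t / tt
        q[a] = float(yd @ t) / tt
        W[:, a] = w
        T[:, a] = t
        Xd -= np.outer(t, P[:, a])
        yd -= q[a] * t
        a_used += 1

    if a_used == 0:
        raise ValueError("no PLS component could be extracted (X uncorrelated with y)")
    model = PLSModel(
        n_components=a_used,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        weights=W[:, :a_used],
        x_loadings=P[:, :a_used],
        y_loadings=q[:a_used],
        scores=T[:, :a_used],
    )
    model.coef, model.intercept = model.coef_for(a_used)
    return model


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses for new rows: ``y = intercept + X_new @ coef``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_features}"
        )
    return model.intercept + X_new @ model.coef


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    d = np.asarray(y_true, dtype=float) - np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean(d**2)))


def loo_predictions_sweep(X: np.ndarray, y: np.ndarray, a_max: int) -> np.ndarray:
    """Leave-one-out predictions for every component count 1..a_max.

    Each fold is fit once with ``a_max`` components (autoscaling
    recomputed on the retained rows); the nested sub-models share the
    fold's weight/loading sequence, so predictions for all smaller A
    come out of the same fit.

    Returns
    -------
    (a_max, n) ndarray
        Row ``a-1`` holds the LOO predictions using ``a`` components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out validation needs n >= 3")
    if a_max > min(n - 2, X.shape[1]):
        raise ValueError(
            f"a_max={a_max} infeasible for folds of {n - 1} samples and {X.shape[1]} features"
        )
    preds = np.empty((a_max, n))
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_pls(X[keep], y[keep], a_max)
        for a in range(1, a_max + 1):
            coef, intercept = model.coef_for(a)
            preds[a - 1, i] = intercept + X[i] @ coef
    return preds


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[float, float]:
    """Leave-one-out Q² and PRESS at a fixed component count.

    Q² = 1 - PRESS / SS_tot with PRESS = Σ (y_i - ŷ_(-i))² and
    SS_tot = Σ (y_i - ȳ)²; every fold refits the model (including the
    autoscaling) without sample i.
    """
    y = np.asarray(y, dtype=float).ravel()
    preds = loo_predictions_sweep(X, y, n_components)[n_components - 1]
    press = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot, press


def select_components(X: np.ndarray, y: np.ndarray, a_max: int = 10) -> tuple[int, np.ndarray]:
    """Choose the component count maximising LOO Q².

    ``a_max`` is capped at ``min(a_max, n - 2, p)``.  Ties break to the
    smallest A.

    Returns
    -------
    (int, ndarray)
        The selected A and the Q² value for every candidate 1..A_cap.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    a_cap = min(a_max, X.shape[0] - 2, X.shape[1])
    if a_cap < 1:
        raise ValueError("not enough samples/features to select components")
    preds = loo_predictions_sweep(X, y, a_cap)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - np.sum((y[None, :] - preds) ** 2, axis=1) / ss_tot
    best = int(np.argmax(q2)) + 1  # argmax returns first maximum -> smallest A on ties
    return best, q2
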