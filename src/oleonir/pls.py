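"""NIPALS PLS1 regression with PRESS cross-validation and F-test factor selection.

The number of latent variables is chosen by computing the prediction error
sum of squares (PRESS) in cross-validation for each candidate count h,
locating the minimum (h*), and then taking the smallest h whose PRESS is not
significantly larger than PRESS(h*) by an F-test at alpha = 0.25 with (n, n)
degrees of freedom — the parsimony criterion of Haaland and Thomas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PLSModel",
    "CVResult",
    "nipals_pls1_fit",
    "pls_predict",
    "cross_validate_press",
    "select_components_haaland_thomas",
    "regression_coefficients",
    "explained_x_variance",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class PLSModel:
    """A fitted NIPALS PLS1 model.

    W are loading weights (unit-norm columns), P the x-loadings, q the
    y-loadings and T the calibration scores (mutually orthogonal columns).
    ``coef``/``intercept`` give predictions directly on the pretreated
    wavelength scale: yhat = intercept + X @ coef.
    """

    h: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    coef: np.ndarray
    intercept: float
    explained_x_variance: np.ndarray


@dataclass(frozen=True)
class CVResult:
    """PRESS per candidate component count and the two selected counts."""

    press: np.ndarray          # PRESS(h) for h = 1..h_max
    h_star: int                # argmin of PRESS
    selected_h: int            # Haaland-Thomas choice, <= h_star
    alpha: float = 0.25
    scheme: str = "leave-one-out"
    n: int = 0


def nipals_pls1_fit(X: np.ndarray, y: np.ndarray, h: int) -> PLSModel:
    """Fit PLS1 by classical NIPALS deflation with mean-centering.

    For a single response the weight of each factor is the (normalised)
    covariance direction X'y, so no inner iteration is needed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("PLS needs at least 2 samples")
    if y.size != n:
        raise ValueError(f"y has {y.size} values for {n} spectra")
    if h < 1 or h > min(n - 1, p):
        raise ValueError(f"h={h} outside valid range 1..{min(n - 1, p)}")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to calibrate")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    total_x_ss = float(np.sum(E * E))

    W = np.zeros((p, h))
    P = np.zeros((p, h))
    q = np.zeros(h)
    T = np.zeros((n, h))
    explained = np.zeros(h)
    kept = 0
    for j in range(h):
        w = E.T @ f
        norm_w = np.linalg.norm(w)
        if norm_w < 1e-14:
            warnings.warn(
                f"NIPALS stopped early at {kept} components (zero-norm weight)",
                stacklevel=2,
            )
            break
        w /= norm_w
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-28:
            warnings.warn(
                f"NIPALS stopped early at {kept} components (degenerate score)",
                stacklevel=2,
            )
            break
        pj = E.T @ t / tt
        qj = float(f @ t) / tt
        E = E - np.outer(t, pj)
        f = f - qj * t
        W[:, j], P[:, j], q[j], T[:, j] = w, pj, qj, t
        explained[j] = tt * float(pj @ pj) / total_x_ss if total_x_ss > 0 else 0.0
        kept += 1

    W, P, q, T, explained = W[:, :kept], P[:, :kept], q[:kept], T[:, :kept], explained[:kept]
    # coef = W (P'W)^-1 q maps centered X to centered yhat
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        h=kept, x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q, T=T,
        coef=coef, intercept=intercept, explained_x_variance=explained,
    )


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations: yhat = intercept + X_new @ coef."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coef.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} wavelengths, model expects {model.coef.size}"
        )
    return model.intercept + X_new @ model.coef


def _fold_indices(n: int, scheme: str, n_folds: int | None) -> list[np.ndarray]:
    if scheme in ("loo", "leave-one-out"):
        return [np.array([i]) for i in range(n)]
    if scheme == "kfold":
        if not n_folds or n_folds < 2 or n_folds > n:
            raise ValueError(f"k-fold needs 2 <= n_folds <= {n}")
        # contiguous (systematic) segments, deterministic
        return [f for f in np.array_split(np.arange(n), n_folds) if f.size]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate_press(
    X: np.ndarray,
    y: np.ndarray,
    h_max: int,
    scheme: str = "leave-one-out",
    n_folds: int | None = None,
    alpha: float = 0.25,
    pretreat=None,
) -> CVResult:
    """Cross-validated PRESS(h) for h = 1..h_max plus factor selection.

    Each fold refits the model (including re-centering) on the remaining
    samples. ``pretreat``, if given, is a callable ``(X_train, X_test) ->
    (X_train, X_test)`` applied per fold — the strict mode in which scatter
    correction is refitted inside each fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if h_max < 1:
        raise ValueError("h_max must be >= 1")
    folds = _fold_indices(n, scheme, n_folds)
    if any(f.size >= n for f in folds):
        raise ValueError("a CV fold leaves no training samples")
    h_max = min(h_max, n - max(f.size for f in folds) - 1, X.shape[1])
    if h_max < 1:
        raise ValueError("too few samples for any latent variable")

    press = np.zeros(h_max)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold, assume_unique=True)
        X_tr, X_te = X[train], X[fold]
        if pretreat is not None:
            X_tr, X_te = pretreat(X_tr, X_te)
        model = nipals_pls1_fit(X_tr, y[train], h_max)
        # accumulate predictions for every truncation 1..h_max in one pass
        E_te = X_te - model.x_mean
        yhat = np.full(X_te.shape[0], model.y_mean)
        press_increment = float(np.sum((y[fold] - yhat) ** 2))
        for j in range(h_max):
            if j >= model.h:  # early NIPALS stop: reuse the last valid model
                press[j] += press_increment
                continue
            t = E_te @ model.W[:, j]
            E_te = E_te - np.outer(t, model.P[:, j])
            yhat = yhat + model.q[j] * t
            press_increment = float(np.sum((y[fold] - yhat) ** 2))
            press[j] += press_increment

    h_star = int(np.argmin(press)) + 1
    cv = CVResult(press=press, h_star=h_star, selected_h=h_star, alpha=alpha,
                  scheme=scheme, n=n)
    selected = select_components_haaland_thomas(cv, n, alpha=alpha)
    return CVResult(press=press, h_star=h_star, selected_h=selected, alpha=alpha,
                    scheme=scheme, n=n)


def select_components_haaland_thomas(cv: CVResult, n: int, alpha: float = 0.25) -> int:
    """Smallest h whose PRESS is statistically indistinguishable from the minimum.

    F(h) = PRESS(h)/PRESS(h*) is compared against the upper-alpha quantile
    of F with (n, n) degrees of freedom; the first h <= h* with
    F(h) < F_{1-alpha}(n, n) is selected, else h* itself.
    """
    press = np.asarray(cv.press, dtype=float)
    if press.size == 0:
        raise ValueError("empty PRESS curve")
    h_star = int(np.argmin(press)) + 1
    press_min = press[h_star - 1]
    if press_min == 0.0:
        return int(np.argmax(press == 0.0)) + 1
    f_crit = stats.f.ppf(1.0 - alpha, n, n)
    for h in range(1, h_star + 1):
        if press[h - 1] / press_min < f_crit:
            return h
    return h_star


def regression_coefficients(model: PLSModel, wavelengths: np.ndarray | None = None):
    """Regression-coefficient vector, optionally labelled by wavelength.

    Returns ``coef`` (and ``(wavelengths, coef)`` when a grid is given) for
    interpretation plots; equals W (P'W)^-1 q on the centered scale.
    """
    if wavelengths is None:
        return model.coef.copy()
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != model.coef.size:
        raise ValueError("wavelength axis does not match coefficient vector")
    return wavelengths, model.coef.copy()


def explained_x_variance(model: PLSModel) -> np.ndarray:
    """Fraction of centered-X Frobenius energy captured by each factor."""
    return model.explained_x_variance.copy()


def save_model(model: PLSModel, path) -> None:
    """Serialise a model to JSON with full float precision."""
    payload = {
        "h": model.h,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "T": model.T.tolist(),
        "coef": model.coef.tolist(),
        "intercept": model.intercept,
        "explained_x_variance": model.explained_x_variance.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PLSModel:
    with open(path) as fh:
        d = json.load(fh)
    return PLSModel(
        h=d["h"], x_mean=np.array(d["x_mean"]), y_mean=d["y_mean"],
        W=np.array(d["W"]), P=np.array(d["P"]), q=np.array(d["q"]),
        T=np.array(d["T"]), coef=np.array(d["coef"]), intercept=d["intercept"],
        explained_x_variance=np.array(d["explained_x_variance"]),
    )
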