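"""PLSR core: SIMPLS fits, 10-fold cross-validation, R/RMSE/RPD metrics.

The selection stages evaluate thousands of sub-models, each scored by its
cross-validated RMSE (RMSE_CV) minimized over the latent-variable count.  The
SIMPLS implementation therefore returns the full coefficient path: one
decomposition per training fold yields predictions for every component count
at once.

Conventions: mean-centering only (no unit-variance scaling; preprocessing
already handles scale); the latent-variable count is capped at 10 throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "PLSRModel",
    "MetricsReport",
    "fit_plsr",
    "predict",
    "rmsecv",
    "subset_rmsecv",
    "cv_select_components",
    "evaluate",
    "MAX_COMPONENTS",
]

#: Global latent-variable cap used by every selection stage.
MAX_COMPONENTS = 10


def _simpls_path(Xc: np.ndarray, yc: np.ndarray, k_max: int) -> np.ndarray:
    """Coefficient paths for centered data: column k-1 = coefficients at k LVs.

    SIMPLS (de Jong 1993) for a single response.  Stops early if the score
    norm collapses (rank exhausted); remaining columns repeat the last one.
    """
    n, p = Xc.shape
    k_max = int(min(k_max, p, max(n - 1, 1)))
    R = np.zeros((p, k_max))
    Q = np.zeros(k_max)
    V = np.zeros((p, k_max))
    s = Xc.T @ yc
    tol = 0.0
    for a in range(k_max):
        r = s.copy()
        t = Xc @ r
        normt = np.linalg.norm(t)
        if a == 0:
            tol = max(normt, 1.0) * 1e-12
        if normt <= tol:
            # rank exhausted: freeze the path
            for b in range(a, k_max):
                R[:, b] = 0.0
                Q[b] = 0.0
            k_max = a
            break
        t /= normt
        r /= normt
        pl = Xc.T @ t
        q = float(yc @ t)
        v = pl.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pl)
        nv = np.linalg.norm(v)
        if nv <= 1e-14:
            k_max = a
            break
        v /= nv
        V[:, a] = v
        R[:, a] = r
        Q[a] = q
        s = s - v * (v @ s)
    paths = np.cumsum(R * Q, axis=1)
    if k_max == 0:
        raise ValueError("degenerate input: no predictive component found")
    # freeze columns past the effective rank at the last valid path
    if k_max < paths.shape[1]:
        paths[:, k_max:] = paths[:, [k_max - 1]]
    return paths


@dataclass
class PLSRModel:
    """Fitted PLSR model on a channel subset.

    ``channels`` are column indices into the modeling-window matrix the model
    was trained on; ``coef``/``intercept`` act on raw (preprocessed but
    uncentered) reflectance at those channels.
    """

    coef: np.ndarray
    intercept: float
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    channels: np.ndarray
    wavelengths_nm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float).ravel()
        self.channels = np.asarray(self.channels, dtype=int).ravel()
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("non-finite regression coefficients")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "channels": self.channels.tolist(),
            "wavelengths_nm": (
                None if self.wavelengths_nm is None else list(map(float, self.wavelengths_nm))
            ),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            coef=np.array(d["coef"]),
            intercept=float(d["intercept"]),
            n_components=int(d["n_components"]),
            x_mean=np.array(d["x_mean"]),
            y_mean=float(d["y_mean"]),
            channels=np.array(d["channels"], dtype=int),
            wavelengths_nm=None
            if d.get("wavelengths_nm") is None
            else np.array(d["wavelengths_nm"]),
        )


@dataclass
class MetricsReport:
    """R / RMSE / RPD for one evaluation set.

    R is the Pearson correlation between predictions and references, RMSE the
    root mean squared error in analyte units, and RPD the sample SD of the
    references divided by the RMSE (> 2 conventionally marks a usable model).
    A perfect fit yields RPD = inf; a constant prediction yields R = nan.
    """

    label: str
    r: float
    rmse: float
    rpd: float
    n: int

    def as_dict(self) -> dict:
        return {"set": self.label, "R": self.r, "RMSE": self.rmse, "RPD": self.rpd, "n": self.n}


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    channels: Optional[np.ndarray] = None,
    wavelengths_nm: Optional[np.ndarray] = None,
) -> PLSRModel:
    """Deterministic SIMPLS fit on mean-centered data.

    ``channels`` records which modeling-window columns ``X`` corresponds to
    (defaults to 0..p-1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per response value")
    n, p = X.shape
    if n <= n_components:
        raise ValueError("need more samples than components")
    if np.ptp(y) == 0:
        raise ValueError("constant response: PLSR undefined")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    paths = _simpls_path(X - x_mean, y - y_mean, n_components)
    k = min(n_components, paths.shape[1])
    coef = paths[:, k - 1]
    intercept = y_mean - float(x_mean @ coef)
    if channels is None:
        channels = np.arange(p)
    return PLSRModel(
        coef=coef,
        intercept=intercept,
        n_components=k,
        x_mean=x_mean,
        y_mean=y_mean,
        channels=channels,
        wavelengths_nm=wavelengths_nm,
    )


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Predict responses; X columns must match the model's training columns."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.coef.size:
        raise ValueError(
            f"X has {X.shape[-1]} channels, model expects {model.coef.size}"
        )
    return X @ model.coef + model.intercept


def _fold_blocks(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks of a seeded shuffle: deterministic fold assignment."""
    if folds > n:
        raise ValueError("more folds than samples")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    perm = np.random.default_rng(seed).permutation(n)
    return np.array_split(perm, folds)


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = MAX_COMPONENTS,
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """RMSE_CV for every component count 1..k_eff in one pass per fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("constant response: cross-validation undefined")
    blocks = _fold_blocks(n, folds, seed)
    k_eff = int(min(max_components, p, n - max(len(b) for b in blocks) - 1))
    k_eff = max(k_eff, 1)
    sq = np.zeros(k_eff)
    for val_idx in blocks:
        train = np.setdiff1d(np.arange(n), val_idx, assume_unique=False)
        Xt, yt = X[train], y[train]
        xm, ym = Xt.mean(axis=0), yt.mean()
        paths = _simpls_path(Xt - xm, yt - ym, k_eff)[:, :k_eff]
        pred = (X[val_idx] - xm) @ paths + ym  # n_val x k_eff
        sq += ((pred - y[val_idx, None]) ** 2).sum(axis=0)
    return np.sqrt(sq / n)


def subset_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    max_components: int = MAX_COMPONENTS,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, int]:
    """(min RMSE_CV, best component count) for a channel subset."""
    idx = np.asarray(idx, dtype=int)
    curve = rmsecv(X[:, idx], y, max_components=max_components, folds=folds, seed=seed)
    k = int(np.argmin(curve))  # first minimum on ties
    return float(curve[k]), k + 1


def cv_select_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = MAX_COMPONENTS,
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Best latent-variable count by 10-fold CV (first minimum on ties)."""
    curve = rmsecv(X, y, max_components=max_components, folds=folds, seed=seed)
    return int(np.argmin(curve)) + 1, curve


def evaluate(model: PLSRModel, X: np.ndarray, y: np.ndarray, label: str) -> MetricsReport:
    """R / RMSE / RPD of the model on one evaluation set.

    RMSE uses the population formula sqrt(sum((yhat-y)^2)/n); RPD divides the
    sample (n-1) SD of the references by that RMSE.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("R and RPD need at least 2 samples")
    yhat = predict(model, X)
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    if np.ptp(yhat) == 0:
        r = float("nan")  # constant prediction: correlation undefined
    else:
        r = float(np.corrcoef(yhat, y)[0, 1])
    sd = float(np.std(y, ddof=1))
    rpd = math.inf if rmse == 0 else sd / rmse
    return MetricsReport(label=label, r=r, rmse=rmse, rpd=rpd, n=y.size)
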