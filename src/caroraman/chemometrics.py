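"""PLSR concentration calibration and PCA differentiation.

The calibration maps preprocessed, self-absorption-corrected Raman
spectra (the X matrix) to analyte concentration (the target y) with a
PLS1 model (Y = XB + E), mean-centered internally.  Model quality is
assessed by repeated random K-fold cross-validation (default 10-fold,
100 repeats): RMSECV per latent-variable count, cross-validated R^2
(squared Pearson correlation of averaged held-out predictions against
the targets) and the limit of detection LOD = 3.3 * RMSECV.

PCA (vector normalization, mean centering, SVD) differentiates the
three carotenoid classes; a deterministic sign convention (largest
|loading| element positive) keeps score plots reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression


def _fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        # expected on exactly low-rank data once y is fully explained
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls.fit(X, y)
    return pls

from .spectra import SpectrumSet


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectrumSet):
        return X.matrix
    return np.atleast_2d(np.asarray(X, dtype=float))


def lod(rmsecv: float) -> float:
    """Limit of detection, LOD = 3.3 * RMSECV (mg/mL)."""
    if rmsecv < 0:
        raise ValueError("RMSECV must be >= 0")
    return 3.3 * rmsecv


# ---------------------------------------------------------------------------
# PLSR calibration
# ---------------------------------------------------------------------------

def _coefficient_path(pls: PLSRegression) -> np.ndarray:
    """Coefficient vectors for every truncation 1..K of a fitted PLS1.

    NIPALS components are computed sequentially, so the k-component
    regression vector is x_rotations[:, :k] @ y_loadings[:, :k].T.
    Returns an (n_features, K) array, column k-1 for k components.
    """
    rot = pls.x_rotations_          # (p, K)
    yl = pls.y_loadings_            # (1, K)
    return np.cumsum(rot * yl[0][None, :], axis=1)


@dataclass
class PLSRModel:
    """Fitted PLS1 calibration plus (optional) cross-validation figures."""

    n_lv: int
    coefficients: np.ndarray            # (n_channels,)
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    x_loadings: np.ndarray              # (n_channels, n_lv)
    y_loadings: np.ndarray              # (1, n_lv)
    cumulative_variance: np.ndarray     # % of y-variance, per LV count
    cumulative_x_variance: np.ndarray   # % of X-variance, per LV count
    rmsecv_per_lv: np.ndarray | None = None
    rmsecv: float | None = None
    r_squared: float | None = None
    cv_predictions: np.ndarray | None = None
    _pls: PLSRegression = field(default=None, repr=False)

    @property
    def lod(self) -> float | None:
        return None if self.rmsecv is None else lod(self.rmsecv)

    def predict(self, X) -> np.ndarray:
        Xc = _as_matrix(X) - self.x_mean
        return Xc @ self.coefficients + self.y_mean

    def summary(self) -> str:
        lines = [
            "PLS1 concentration calibration",
            f"  latent variables : {self.n_lv}",
            f"  cum. Y-variance  : {self.cumulative_variance[self.n_lv - 1]:.2f} %",
        ]
        if self.rmsecv is not None:
            lines += [
                f"  RMSECV           : {self.rmsecv:.4g} mg/mL",
                f"  LOD (3.3*RMSECV) : {self.lod:.4g} mg/mL",
            ]
        if self.r_squared is not None:
            lines.append(f"  CV R^2           : {self.r_squared:.4f}")
        return "\n".join(lines)


def fit_plsr(X, y: Sequence[float], n_lv: int) -> PLSRModel:
    """Fit a PLS1 calibration with ``n_lv`` latent variables.

    X must already be preprocessed (EMSC-corrected, water-normalized,
    self-absorption-corrected); centering is internal, no scaling.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if y.size != n:
        raise ValueError("X and y row counts differ")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(
            f"n_lv must be in [1, min(n_samples-1, n_channels)] = "
            f"[1, {min(n - 1, p)}], got {n_lv}"
        )
    pls = _fit_pls(Xm, y, n_lv)
    path = _coefficient_path(pls)
    y_mean = float(np.ravel(pls._y_mean)[0])
    Xc = Xm - pls._x_mean
    yc = y - y_mean
    ss_tot = float(np.sum(yc**2))
    cum_y = np.array(
        [100.0 * (1.0 - np.sum((yc - Xc @ path[:, k]) ** 2) / ss_tot) for k in range(n_lv)]
    )
    ss_x = float(np.sum(Xc**2))
    per_lv_x = np.array(
        [
            np.sum(pls.x_scores_[:, k] ** 2) * np.sum(pls.x_loadings_[:, k] ** 2)
            for k in range(n_lv)
        ]
    )
    cum_x = 100.0 * np.cumsum(per_lv_x) / ss_x
    coef = path[:, -1]
    return PLSRModel(
        n_lv=n_lv,
        coefficients=coef,
        intercept=float(y_mean - pls._x_mean @ coef),
        x_mean=pls._x_mean.copy(),
        y_mean=y_mean,
        x_loadings=pls.x_loadings_.copy(),
        y_loadings=pls.y_loadings_.copy(),
        cumulative_variance=cum_y,
        cumulative_x_variance=cum_x,
        _pls=pls,
    )


@dataclass
class CVResult:
    """Repeated K-fold cross-validation of a PLS1 calibration."""

    rmsecv_per_lv: np.ndarray       # (n_lv_max,), LV count k at index k-1
    rmsecv_se_per_lv: np.ndarray    # spread of per-repeat RMSECV
    mean_predictions: np.ndarray    # (n_samples, n_lv_max) averaged over repeats
    y: np.ndarray
    k: int
    repeats: int
    seed: int

    def r_squared(self, n_lv: int) -> float:
        """Squared Pearson correlation of averaged CV predictions vs y."""
        pred = self.mean_predictions[:, n_lv - 1]
        return float(np.corrcoef(pred, self.y)[0, 1] ** 2)

    def bias(self, n_lv: int) -> float:
        """Mean signed error of averaged CV predictions."""
        return float(np.mean(self.mean_predictions[:, n_lv - 1] - self.y))


def cross_validate(
    X,
    y: Sequence[float],
    n_lv_max: int,
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
) -> CVResult:
    """Repeated random K-fold CV; RMSECV per LV count 1..n_lv_max.

    Folds are drawn by a seeded random partition into ``k`` near-equal
    parts, redrawn each repeat; deterministic for a fixed seed.  Each
    fold is fitted once at ``n_lv_max`` components and the nested
    NIPALS coefficient path supplies predictions for all smaller LV
    counts.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = Xm.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of samples ({n})")
    if k < 2:
        raise ValueError("k must be >= 2")
    max_train = n - int(np.ceil(n / k))
    if not 1 <= n_lv_max <= min(max_train - 1, Xm.shape[1]):
        raise ValueError(f"n_lv_max must be in [1, {min(max_train - 1, Xm.shape[1])}]")
    rng = np.random.default_rng(seed)
    sq_err = np.zeros((repeats, n, n_lv_max))
    pred_sum = np.zeros((n, n_lv_max))
    for rep in range(repeats):
        order = rng.permutation(n)
        for fold in np.array_split(order, k):
            train = np.setdiff1d(order, fold, assume_unique=True)
            pls = _fit_pls(Xm[train], y[train], n_lv_max)
            path = _coefficient_path(pls)
            pred = (Xm[fold] - pls._x_mean) @ path + float(np.ravel(pls._y_mean)[0])
            sq_err[rep, fold, :] = (pred - y[fold, None]) ** 2
            pred_sum[fold] += pred
    per_repeat = np.sqrt(sq_err.mean(axis=1))            # (repeats, n_lv_max)
    return CVResult(
        rmsecv_per_lv=np.sqrt(sq_err.mean(axis=(0, 1))),
        rmsecv_se_per_lv=per_repeat.std(axis=0, ddof=1) if repeats > 1 else np.zeros(n_lv_max),
        mean_predictions=pred_sum / repeats,
        y=y,
        k=k,
        repeats=repeats,
        seed=seed,
    )


def select_n_lv(
    cumulative_variance: Sequence[float] | None = None,
    rmsecv_per_lv: Sequence[float] | None = None,
    policy: str = "variance_saturation",
    rmsecv_se: Sequence[float] | None = None,
    variance_threshold: float = 99.9,
    rel_tol: float = 0.05,
) -> int:
    """Choose the latent-variable count.

    ``variance_saturation``: first LV whose cumulative variance reaches
    ``variance_threshold`` (default 99.9%).  ``rmsecv_min``: smallest LV
    whose RMSECV is within one SE (when supplied) or ``rel_tol`` of the
    minimum.
    """
    if policy == "variance_saturation":
        cv = np.asarray(cumulative_variance, dtype=float)
        if cv.size == 0:
            raise ValueError("cumulative_variance is empty")
        hits = np.nonzero(cv >= variance_threshold)[0]
        return int(hits[0]) + 1 if hits.size else int(cv.size)
    if policy == "rmsecv_min":
        r = np.asarray(rmsecv_per_lv, dtype=float)
        if r.size == 0:
            raise ValueError("rmsecv_per_lv is empty")
        i_min = int(np.argmin(r))
        band = r[i_min] + (
            np.asarray(rmsecv_se, float)[i_min] if rmsecv_se is not None else rel_tol * max(r[i_min], 1e-300)
        )
        return int(np.nonzero(r <= band)[0][0]) + 1
    raise ValueError(f"unknown policy {policy!r}")


def calibrate(
    X,
    y: Sequence[float],
    n_lv: int | None = None,
    n_lv_max: int = 8,
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
    policy: str = "variance_saturation",
) -> PLSRModel:
    """Full calibration: fit, cross-validate, attach RMSECV/R^2/LOD."""
    cv = cross_validate(X, y, n_lv_max=n_lv_max, k=k, repeats=repeats, seed=seed)
    full = fit_plsr(X, y, n_lv_max)
    if n_lv is None:
        n_lv = select_n_lv(full.cumulative_variance, cv.rmsecv_per_lv, policy,
                           rmsecv_se=cv.rmsecv_se_per_lv)
    model = fit_plsr(X, y, n_lv)
    model.rmsecv_per_lv = cv.rmsecv_per_lv
    model.rmsecv = float(cv.rmsecv_per_lv[n_lv - 1])
    model.r_squared = cv.r_squared(n_lv)
    model.cv_predictions = cv.mean_predictions[:, n_lv - 1]
    return model


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Scores, loadings (orthonormal rows) and explained variance (%)."""

    scores: np.ndarray                  # (n_samples, n_pc)
    loadings: np.ndarray                # (n_pc, n_channels)
    explained_variance_pct: np.ndarray  # per PC
    mean: np.ndarray
    labels: pd.DataFrame | None = None

    def reconstruct(self) -> np.ndarray:
        """Normalized, centered matrix rebuilt from all retained PCs."""
        return self.scores @ self.loadings

    def class_centroids(self, column: str = "analyte") -> pd.DataFrame:
        if self.labels is None or column not in self.labels:
            raise ValueError(f"no {column!r} labels attached")
        df = pd.DataFrame(self.scores[:, :2], columns=["PC1", "PC2"])
        df[column] = self.labels[column].values
        return df.groupby(column).mean()


def fit_pca(
    X,
    vector_normalize: bool = True,
    n_pc: int | None = None,
    labels: pd.DataFrame | None = None,
) -> PCAResult:
    """PCA with vector normalization, mean centering and SVD.

    Each row is scaled to unit Euclidean norm (when flagged), columns
    are mean-centered, and the SVD taken.  Signs are fixed by making the
    largest-magnitude element of each loading positive.
    """
    if isinstance(X, SpectrumSet) and labels is None:
        labels = X.labels
    Xm = _as_matrix(X).copy()
    n = Xm.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if vector_normalize:
        norms = np.linalg.norm(Xm, axis=1)
        zero = np.nonzero(norms == 0)[0]
        if zero.size:
            raise ValueError(f"row {zero[0]} has zero norm; cannot vector-normalize")
        Xm /= norms[:, None]
    mean = Xm.mean(axis=0)
    Xc = Xm - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, vt.shape[0]) if n_pc is None else min(n_pc, vt.shape[0])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = u * s * flip[None, :]
    total_var = float(np.sum(Xc**2))
    explained = 100.0 * s**2 / total_var if total_var > 0 else np.zeros(k)
    return PCAResult(scores, vt, explained, mean,
                     labels.reset_index(drop=True) if labels is not None else None)


def pairwise_pca(
    X: SpectrumSet,
    pair: tuple[str, str],
    label_column: str = "analyte",
    vector_normalize: bool = True,
) -> PCAResult:
    """PCA restricted to two labelled classes."""
    if label_column not in X.labels:
        raise ValueError(f"SpectrumSet has no {label_column!r} label column")
    values = X.labels[label_column].astype(str)
    for cls in pair:
        if not (values == cls).any():
            raise ValueError(f"label {cls!r} absent from the set")
    rows = np.nonzero(values.isin([str(p) for p in pair]).values)[0]
    return fit_pca(X.subset(rows), vector_normalize=vector_normalize)
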