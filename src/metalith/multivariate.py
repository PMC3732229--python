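"""NIPALS PCA and PLS-DA with unit-variance scaling and k-fold Q².

The latent models are computed with the nonlinear iterative partial least
squares (NIPALS) algorithm: components are extracted one at a time by
alternating score/loading regressions and deflating the data matrix, rather
than by a full decomposition. Defaults follow the study settings: unit
standard deviation (autoscaling) of each metabolite, at most 50 iterations
per component with a 1e-4 relative convergence criterion on the score
vector, and stratified 7-fold cross-validation of the PLS-DA class
predictions (Q² = 1 − PRESS/SS).

Classes for PLS-DA are dummy-coded into a centered indicator matrix (PLS2).
Missing values are mean-substituted (zero on the autoscaled scale) inside
latent fits only; univariate statistics elsewhere never impute.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LatentModel",
    "MultivariateError",
    "autoscale",
    "nipals_pca",
    "nipals_pls",
    "cross_validate",
    "dummy_code",
]


class MultivariateError(Exception):
    pass


@dataclass
class LatentModel:
    """A fitted NIPALS PCA or PLS(-DA) model."""

    kind: str  # "PCA" | "PLS"
    n_components: int
    scores: np.ndarray  # samples x components
    x_loadings: np.ndarray  # features x components
    x_variance_explained: np.ndarray  # fraction of total X SS per component
    x_weights: np.ndarray | None = None  # PLS only, features x components
    y_loadings: np.ndarray | None = None  # PLS only, classes x components
    y_variance_explained: np.ndarray | None = None
    q2: np.ndarray | None = None
    scaling_record: pd.DataFrame | None = None
    converged: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)
    class_levels: list = field(default_factory=list)
    y_mean: np.ndarray | None = None

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"v{i + 1}" for i in range(self.n_components)]
        idx = self.sample_ids or range(self.scores.shape[0])
        return pd.DataFrame(self.scores, index=idx, columns=cols)


# ---------------------------------------------------------------------------
# scaling


def autoscale(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center each column to mean 0 and scale to unit sample SD (ddof=1).

    Columns that are entirely MISSING or have zero SD are dropped with a
    warning. MISSING entries become 0 after scaling (mean substitution on
    the scaled scale), which is the least-informative fill for a latent fit.
    Returns (scaled matrix, scaling record with per-column center/scale).
    """
    center = values.mean(axis=0, skipna=True)
    scale = values.std(axis=0, ddof=1, skipna=True)
    n_obs = values.notna().sum(axis=0)
    bad = values.columns[(n_obs < 2) | (scale == 0) | scale.isna()]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} constant or all-missing metabolite(s) "
            f"before scaling: {list(bad[:5])}..."
            if len(bad) > 5
            else f"dropping constant or all-missing metabolite(s): {list(bad)}",
            stacklevel=2,
        )
    keep = [c for c in values.columns if c not in set(bad)]
    X = (values[keep] - center[keep]) / scale[keep]
    X = X.fillna(0.0)
    record = pd.DataFrame({"center": center[keep], "scale": scale[keep]})
    return X, record


def inverse_scale(X: pd.DataFrame, record: pd.DataFrame) -> pd.DataFrame:
    """Undo :func:`autoscale` (MISSING entries come back as the column mean)."""
    return X * record["scale"] + record["center"]


def dummy_code(classes: Sequence) -> tuple[np.ndarray, list, np.ndarray]:
    """Class labels -> centered indicator matrix; returns (Y, levels, column means)."""
    levels = sorted(set(classes))
    if len(levels) < 2:
        raise MultivariateError("need at least 2 classes")
    raw = np.zeros((len(classes), len(levels)))
    for i, c in enumerate(classes):
        raw[i, levels.index(c)] = 1.0
    mean = raw.mean(axis=0)
    return raw - mean, levels, mean


# ---------------------------------------------------------------------------
# NIPALS PCA


def _as_array(X) -> tuple[np.ndarray, list, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def nipals_pca(
    X, n_components: int, max_iter: int = 50, tol: float = 1e-4
) -> LatentModel:
    """Iterative NIPALS principal component extraction on a centered matrix.

    Each component: the score vector starts from the column of largest
    variance; then loading <- X't/(t't) normalized to unit length, score
    <- X.loading, until the relative L2 change of the score falls below
    ``tol`` or ``max_iter`` is reached (non-convergence keeps the component
    and records a False flag). X is deflated by the rank-1 fit and the
    variance explained is the relative drop in total sum of squares.
    """
    Xa, sample_ids, feature_ids = _as_array(X)
    n, m = Xa.shape
    rank_bound = min(n - 1, m)
    if not 1 <= n_components <= rank_bound:
        raise MultivariateError(
            f"n_components must be in [1, {rank_bound}] for a {n}x{m} matrix"
        )
    E = Xa.copy()
    ss_total = float((Xa**2).sum())
    if ss_total == 0:
        raise MultivariateError("zero matrix")
    T = np.zeros((n, n_components))
    P = np.zeros((m, n_components))
    varx = np.zeros(n_components)
    converged: list[bool] = []
    for c in range(n_components):
        ss_before = float((E**2).sum())
        if ss_before == 0:  # exhausted rank
            converged.append(True)
            continue
        t = E[:, int(np.argmax(E.var(axis=0)))].copy()
        if not t.any():
            t = E[:, int(np.argmax((E**2).sum(axis=0)))].copy()
        ok = False
        for _ in range(max_iter):
            p = E.T @ t / (t @ t)
            p /= np.linalg.norm(p)
            t_new = E @ p
            denom = np.linalg.norm(t_new)
            if denom == 0:
                break
            if np.linalg.norm(t_new - t) / denom < tol:
                t = t_new
                ok = True
                break
            t = t_new
        if not ok:
            warnings.warn(f"PCA component {c + 1} did not converge in {max_iter} iterations",
                          stacklevel=2)
        converged.append(ok)
        p = E.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t = E @ p
        E = E - np.outer(t, p)
        T[:, c] = t
        P[:, c] = p
        varx[c] = (ss_before - float((E**2).sum())) / ss_total
    return LatentModel(
        kind="PCA",
        n_components=n_components,
        scores=T,
        x_loadings=P,
        x_variance_explained=varx,
        converged=converged,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
    )


# ---------------------------------------------------------------------------
# NIPALS PLS2 (discriminant analysis via dummy-coded classes)


def _nipals_pls_core(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    max_iter: int,
    tol: float,
) -> dict:
    n, m = X.shape
    E, F = X.copy(), Y.copy()
    ssx_total = float((X**2).sum())
    ssy_total = float((Y**2).sum())
    T = np.zeros((n, n_components))
    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    C = np.zeros((Y.shape[1], n_components))
    varx = np.zeros(n_components)
    vary = np.zeros(n_components)
    converged: list[bool] = []
    for c in range(n_components):
        ssx_before = float((E**2).sum())
        ssy_before = float((F**2).sum())
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if not u.any():
            u = F[:, 0].copy()
        t = np.zeros(n)
        ok = False
        for _ in range(max_iter):
            w = E.T @ u / (u @ u)
            norm_w = np.linalg.norm(w)
            if norm_w == 0:
                break
            w /= norm_w
            t_new = E @ w
            q = F.T @ t_new / (t_new @ t_new)
            norm_q = np.linalg.norm(q)
            if norm_q == 0:
                break
            q /= norm_q
            u = F @ q
            denom = np.linalg.norm(t_new)
            if denom > 0 and np.linalg.norm(t_new - t) / denom < tol:
                t = t_new
                ok = True
                break
            t = t_new
        if not ok:
            warnings.warn(
                f"PLS component {c + 1} did not converge in {max_iter} iterations",
                stacklevel=3,
            )
        converged.append(ok)
        tt = t @ t
        if tt == 0:
            break
        p = E.T @ t / tt
        cvec = F.T @ t / tt
        E = E - np.outer(t, p)
        F = F - np.outer(t, cvec)
        T[:, c] = t
        W[:, c] = w
        P[:, c] = p
        C[:, c] = cvec
        varx[c] = (ssx_before - float((E**2).sum())) / ssx_total
        vary[c] = (ssy_before - float((F**2).sum())) / ssy_total if ssy_total else 0.0
    return {
        "T": T,
        "W": W,
        "P": P,
        "C": C,
        "varx": varx,
        "vary": vary,
        "converged": converged,
    }


def pls_coefficients(W: np.ndarray, P: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Regression coefficients B with Y_hat = X @ B for a fitted PLS2 model."""
    A = P.T @ W
    return W @ np.linalg.solve(A, C.T)


def nipals_pls(
    X,
    classes: Sequence,
    n_components: int,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> LatentModel:
    """NIPALS PLS2 discriminant analysis of an autoscaled matrix.

    Classes are dummy-coded into a centered indicator matrix Y. Per
    component: u starts from a Y column; w <- X'u (normalized), t <- Xw,
    q <- Y't (normalized), u <- Yq, iterated to the score-vector tolerance;
    X and Y are then deflated on t. Variance explained is reported for both
    blocks from the deflation sum-of-squares drop.
    """
    Xa, sample_ids, feature_ids = _as_array(X)
    if len(classes) != Xa.shape[0]:
        raise MultivariateError("classes length must match sample count")
    levels = sorted(set(classes))
    counts = {lv: list(classes).count(lv) for lv in levels}
    if len(levels) < 2:
        raise MultivariateError("need at least 2 classes")
    small = [lv for lv, k in counts.items() if k < 2]
    if small:
        raise MultivariateError(f"class(es) with fewer than 2 samples: {small}")
    Y, levels, y_mean = dummy_code(classes)
    rank_bound = min(Xa.shape[0] - 1, Xa.shape[1])
    if not 1 <= n_components <= rank_bound:
        raise MultivariateError(f"n_components must be in [1, {rank_bound}]")
    fit = _nipals_pls_core(Xa, Y, n_components, max_iter, tol)
    return LatentModel(
        kind="PLS",
        n_components=n_components,
        scores=fit["T"],
        x_loadings=fit["P"],
        x_weights=fit["W"],
        y_loadings=fit["C"],
        x_variance_explained=fit["varx"],
        y_variance_explained=fit["vary"],
        converged=fit["converged"],
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        class_levels=levels,
        y_mean=y_mean,
    )


# ---------------------------------------------------------------------------
# cross-validation


def stratified_folds(classes: Sequence, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per sample)."""
    classes = list(classes)
    n = len(classes)
    if k > n:
        raise MultivariateError(f"k={k} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    offset = 0
    for lv in sorted(set(classes)):
        idx = np.array([i for i, c in enumerate(classes) if c == lv])
        idx = idx[rng.permutation(len(idx))]
        # round-robin with a rotating offset so folds stay balanced overall
        folds[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx) % k
    return folds


def cross_validate(
    X,
    classes: Sequence,
    n_components: int,
    k: int = 7,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> np.ndarray:
    """Per-component Q² from stratified k-fold cross-validation.

    For each fold, a PLS2 model is fitted on the training samples (columns
    re-centered on the training means) and the held-out class indicators are
    predicted with 1..n_components components. Q²_c = 1 − PRESS_c / SS(Y)
    where SS(Y) accumulates the held-out centered indicator sum of squares.
    Fold assignment is deterministic given the seed.
    """
    Xa, _, _ = _as_array(X)
    classes = list(classes)
    folds = stratified_folds(classes, k, seed)
    Yraw = np.zeros((len(classes), len(sorted(set(classes)))))
    levels = sorted(set(classes))
    for i, c in enumerate(classes):
        Yraw[i, levels.index(c)] = 1.0

    press = np.zeros(n_components)
    ss = 0.0
    for f in range(k):
        test = folds == f
        train = ~test
        if train.sum() < 3 or test.sum() == 0:
            continue
        x_mean = Xa[train].mean(axis=0)
        Xtr = Xa[train] - x_mean
        Xte = Xa[test] - x_mean
        y_mean = Yraw[train].mean(axis=0)
        Ytr = Yraw[train] - y_mean
        Yte = Yraw[test] - y_mean
        ncomp = min(n_components, train.sum() - 1, Xa.shape[1])
        fit = _nipals_pls_core(Xtr, Ytr, ncomp, max_iter, tol)
        ss += float((Yte**2).sum())
        for c in range(n_components):
            cc = min(c + 1, ncomp)
            B = pls_coefficients(fit["W"][:, :cc], fit["P"][:, :cc], fit["C"][:, :cc])
            resid = Yte - Xte @ B
            press[c] += float((resid**2).sum())
    if ss == 0:
        raise MultivariateError("no held-out variance; check folds/classes")
    return 1.0 - press / ss
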