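"""Correspondence analysis and constrained ordination of codon-usage tables.

Three ordinations over the genes x codons matrix Y:

* CA — unconstrained correspondence analysis: SVD of the chi-square
  standardized residuals of Y from its row/column margins.
* RDA — redundancy analysis: Y and the explanatory index matrix X are
  column-centered, Y is projected onto X through the hat matrix
  ``Yhat = X (X'X)^-1 X' Y`` and the covariance ``M = Yhat'Yhat/(n-1)``
  is eigen-decomposed; eigenvalues are the variance of Y captured along
  each constrained axis.
* CCA — canonical correspondence analysis: the chi-square residual
  transform of CA followed by a row-weighted regression on X (ter Braak's
  construction), i.e. RDA in the chi-square metric.

Explained fractions are reported against the method's total inertia
(CA/CCA: total chi-square inertia; RDA: total variance of centered Y),
which is how constrained axis percentages are conventionally quoted.
Axis signs are arbitrary in any SVD; they are fixed by forcing the
largest-|loading| variable positive on each axis so outputs are
reproducible run to run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Eigenvalues below this fraction of the largest are treated as zero.
EIGEN_CUTOFF = 1e-12


class PreparationError(ValueError):
    """Input matrix cannot be ordinated (zero margins, shape mismatch...)."""


@dataclass
class OrdinationResult:
    """Eigenvalues, explained fractions and scores of one ordination.

    site_scores are genes x axes (principal coordinates); feature_scores
    are the Y-columns (codons) x axes; variable_scores are the biplot
    arrows for the explanatory variables (for CA, identical to
    feature_scores since there is no X).
    """

    method: str
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    total_inertia: float
    site_scores: pd.DataFrame
    feature_scores: pd.DataFrame
    variable_scores: pd.DataFrame


def _as_array(df: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(df, dtype=float)
    if not np.isfinite(arr).all():
        raise PreparationError("matrix contains missing or non-finite values")
    return arr


def drop_collinear(X: pd.DataFrame, weights: np.ndarray | None = None,
                   tol: float = 1e-10) -> pd.DataFrame:
    """Drop collinear columns, preferring to keep leftmost ones.

    Columns are scanned left to right on the (weighted-)centered matrix;
    a column linearly dependent on those already kept is dropped with a
    warning. Constant columns are dropped too.
    """
    arr = _as_array(X)
    n = arr.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else weights / weights.sum()
    centered = arr - w @ arr
    centered = np.sqrt(w)[:, None] * centered
    kept: list[int] = []
    basis = np.empty((n, 0))
    for j in range(arr.shape[1]):
        col = centered[:, [j]]
        if basis.shape[1]:
            col = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(col)
        scale = np.linalg.norm(centered[:, j]) or 1.0
        if norm > tol * max(scale, 1.0):
            kept.append(j)
            basis = np.hstack([basis, col / norm])
        else:
            logger.warning("dropping collinear/constant column %r", X.columns[j])
    return X.iloc[:, kept]


def _fix_signs(loadings: np.ndarray, *score_sets: np.ndarray) -> None:
    """Flip axes in place so the largest-|loading| entry is positive."""
    for ax in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, ax])))
        if loadings[j, ax] < 0:
            loadings[:, ax] *= -1
            for s in score_sets:
                s[:, ax] *= -1


def _result(method, eigvals, total, site, feats, varscores,
            row_ids, col_ids, var_ids, n_axes) -> OrdinationResult:
    keep = eigvals > EIGEN_CUTOFF * (eigvals[0] if eigvals.size else 1.0)
    k = min(int(keep.sum()), n_axes)
    axes = [f"axis{i + 1}" for i in range(k)]
    eigvals = eigvals[:k]
    site, feats, varscores = site[:, :k], feats[:, :k], varscores[:, :k]
    _fix_signs(varscores, site, feats)
    return OrdinationResult(
        method=method,
        eigenvalues=eigvals,
        explained_fraction=eigvals / total if total > 0 else np.zeros(k),
        total_inertia=float(total),
        site_scores=pd.DataFrame(site, index=row_ids, columns=axes),
        feature_scores=pd.DataFrame(feats, index=col_ids, columns=axes),
        variable_scores=pd.DataFrame(varscores, index=var_ids, columns=axes),
    )


def _chi_square_residuals(Y: np.ndarray, label: pd.DataFrame):
    if (Y < 0).any():
        raise PreparationError("CA/CCA require a non-negative matrix")
    rows = Y.sum(axis=1)
    cols = Y.sum(axis=0)
    if (rows == 0).any():
        bad = list(np.asarray(label.index)[rows == 0])
        raise PreparationError(f"all-zero row(s) in Y: {bad}")
    if (cols == 0).any():
        bad = list(np.asarray(label.columns)[cols == 0])
        raise PreparationError(f"all-zero column(s) in Y: {bad}")
    P = Y / Y.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    return Q, r, c


def ca(Y: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Correspondence analysis of a non-negative genes x codons matrix."""
    arr = _as_array(Y)
    Q, r, c = _chi_square_residuals(arr, Y)
    U, sv, Vt = np.linalg.svd(Q, full_matrices=False)
    eig = sv ** 2
    total = float((Q ** 2).sum())
    site = (U * sv) / np.sqrt(r)[:, None]
    feats = (Vt.T * sv) / np.sqrt(c)[:, None]
    return _result("CA", eig, total, site, feats, feats.copy(),
                   Y.index, Y.columns, Y.columns, n_axes)


def rda(Y: pd.DataFrame, X: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Redundancy analysis: eigen-decomposition of the covariance of the
    X-fitted codon-usage matrix."""
    if len(Y) != len(X):
        raise PreparationError("Y and X must have the same rows")
    n = len(Y)
    if n < 2:
        raise PreparationError("need at least 2 rows")
    Yc = _as_array(Y)
    Yc = Yc - Yc.mean(axis=0)
    Xk = drop_collinear(X)
    Xc = _as_array(Xk)
    Xc = Xc - Xc.mean(axis=0)
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ B
    M = Yhat.T @ Yhat / (n - 1)
    eigvals, U = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    U = U[:, order]
    total = float(np.trace(Yc.T @ Yc)) / (n - 1)
    site = Yhat @ U
    varscores = _correlation_scores(Xc, site)
    return _result("RDA", eigvals, total, site, U.copy(), varscores,
                   Y.index, Y.columns, Xk.columns, n_axes)


def cca(Y: pd.DataFrame, X: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Canonical correspondence analysis (row-weighted RDA on chi-square
    residuals)."""
    if len(Y) != len(X):
        raise PreparationError("Y and X must have the same rows")
    arr = _as_array(Y)
    Q, r, c = _chi_square_residuals(arr, Y)
    Xk = drop_collinear(X, weights=r)
    Xc = _as_array(Xk)
    Xc = Xc - r @ Xc  # weighted centering
    Xw = np.sqrt(r)[:, None] * Xc
    B, *_ = np.linalg.lstsq(Xw, Q, rcond=None)
    Qhat = Xw @ B
    U, sv, Vt = np.linalg.svd(Qhat, full_matrices=False)
    eig = sv ** 2
    total = float((Q ** 2).sum())
    site = (U * sv) / np.sqrt(r)[:, None]
    feats = (Vt.T * sv) / np.sqrt(c)[:, None]
    varscores = _correlation_scores(Xc, site, weights=r)
    return _result("CCA", eig, total, site, feats, varscores,
                   Y.index, Y.columns, Xk.columns, n_axes)


def _correlation_scores(Xc: np.ndarray, site: np.ndarray,
                        weights: np.ndarray | None = None) -> np.ndarray:
    """(Weighted) Pearson correlation of each X column with each axis."""
    n = Xc.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else weights / weights.sum()
    Xm = Xc - w @ Xc
    Sm = site - w @ site
    xsd = np.sqrt(w @ Xm ** 2)
    ssd = np.sqrt(w @ Sm ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xm * w[:, None]).T @ Sm / np.outer(xsd, ssd)
    corr[~np.isfinite(corr)] = 0.0
    return corr


def correlate_axes(result: OrdinationResult, X: pd.DataFrame,
                   n_axes: int = 2) -> pd.DataFrame:
    """Pearson correlation of each explanatory index with the leading axes.

    Returns one row per index with columns ``axis1 .. axisK`` and boolean
    ``top3_axisK`` flags marking the three indices with the largest |r| on
    each axis. Zero-variance indices get an undefined (NaN) correlation
    and are never flagged.
    """
    site = result.site_scores
    if len(site) != len(X):
        raise PreparationError("site scores and X must share rows")
    k = min(n_axes, site.shape[1])
    out = pd.DataFrame(index=X.columns)
    for ax in range(k):
        name = site.columns[ax]
        s = site.iloc[:, ax].to_numpy()
        vals = []
        for col in X.columns:
            x = X[col].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(s) == 0:
                vals.append(np.nan)
            else:
                vals.append(float(np.corrcoef(x, s)[0, 1]))
        out[name] = vals
        ranked = out[name].abs().sort_values(ascending=False)
        top = set(ranked.index[:3][ranked.iloc[:3].notna()])
        out[f"top3_{name}"] = [ix in top for ix in out.index]
    return out
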