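"""Variation partitioning of codon-usage variance.

Decomposes the total variance of the codon-usage matrix Y into the
fraction explained only by mutational-pressure indices (R1), only by
natural-selection indices (R2), jointly by both (R_shared, possibly
negative under suppression), and by neither (R0):

    S        = trace((Y - Ybar)'(Y - Ybar)) / (n - 1)
    R1       = trace var of the fit of Y|X2-residuals on X1|X2-residuals, / S
    R2       =                 symmetric in X1, X2
    R12      = trace var of the fit of Y on [X1 X2], / S
    R0       = 1 - R12
    R_shared = R12 - R1 - R2

The default variable grouping follows the codon-usage convention:
nucleotide-content indices (GC, GC3s, A3s, T3s, C3s, G3s) proxy
mutational pressure; CAI and the protein properties GRAVY and AROMO
proxy natural selection. ENC belongs to neither group by default.

Fractions are computed on the plain (unadjusted) multivariate R²; the
predictor-count-adjusted variant used by some ecology software is
available behind ``adjusted=True`` but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ordination import PreparationError, drop_collinear

#: Default explanatory groups for the mutation-vs-selection partition.
DEFAULT_MUTATION_VARS = ("GC", "GC3s", "A3s", "T3s", "C3s", "G3s")
DEFAULT_SELECTION_VARS = ("CAI", "GRAVY", "AROMO")


class GroupingError(ValueError):
    """Invalid explanatory-variable grouping."""


@dataclass(frozen=True)
class VariableGrouping:
    """Disjoint index-name groups for the two explanatory matrices."""

    mutation_vars: tuple[str, ...] = DEFAULT_MUTATION_VARS
    selection_vars: tuple[str, ...] = DEFAULT_SELECTION_VARS

    def __post_init__(self):
        m, s = set(self.mutation_vars), set(self.selection_vars)
        if not m or not s:
            raise GroupingError("both variable groups must be non-empty")
        if m & s:
            raise GroupingError(f"groups overlap: {sorted(m & s)}")

    def split(self, indices: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        missing = (set(self.mutation_vars) | set(self.selection_vars)) \
            - set(indices.columns)
        if missing:
            raise GroupingError(f"index table lacks column(s): {sorted(missing)}")
        return indices[list(self.mutation_vars)], indices[list(self.selection_vars)]


@dataclass(frozen=True)
class VarPartResult:
    """The four variance fractions plus the combined fit R12 and total S."""

    S: float
    R1: float
    R2: float
    R12: float
    R_shared: float
    R0: float

    def to_dict(self) -> dict[str, float]:
        return {"S": self.S, "R1": self.R1, "R2": self.R2,
                "R_shared": self.R_shared, "R0": self.R0, "R12": self.R12}


def _centered(df: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(df, dtype=float)
    if not np.isfinite(arr).all():
        raise PreparationError("matrix contains missing or non-finite values")
    return arr - arr.mean(axis=0)


def total_variation(Y: pd.DataFrame) -> float:
    """Mean-centered trace variance S of Y."""
    n = len(Y)
    if n < 2:
        raise PreparationError("total variation needs at least 2 rows")
    Yc = _centered(Y)
    return float(np.trace(Yc.T @ Yc)) / (n - 1)


def _fit_trace(Yc: np.ndarray, Xc: np.ndarray) -> float:
    """Trace variance of the least-squares fit of centered Y on centered X."""
    n = Yc.shape[0]
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ B
    Yhat = Yhat - Yhat.mean(axis=0)
    return float(np.trace(Yhat.T @ Yhat)) / (n - 1)


def _r2_adjust(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise PreparationError(f"too few rows ({n}) to adjust R2 for {p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def partial_fraction(Y: pd.DataFrame, X_target: pd.DataFrame,
                     X_condition: pd.DataFrame | None = None) -> float:
    """Fraction of S explained by X_target after removing X_condition.

    Y and X_target are residualized on X_condition, the residual Y is
    regressed on the residual X_target, and the trace variance of the
    fit is reported as a fraction of the total variance of the original
    Y. With an empty condition this is the plain multivariate R² of
    X_target alone.
    """
    if len(Y) != len(X_target):
        raise PreparationError("Y and X_target must share rows")
    S = total_variation(Y)
    if S == 0:
        raise PreparationError("Y has zero total variation")
    Yc = _centered(Y)
    Xt = _centered(drop_collinear(X_target))
    if X_condition is None or X_condition.shape[1] == 0:
        return _fit_trace(Yc, Xt) / S
    if len(X_condition) != len(Y):
        raise PreparationError("Y and X_condition must share rows")
    Xc = _centered(drop_collinear(X_condition))
    Bc, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Y_res = Yc - Xc @ Bc
    Bx, *_ = np.linalg.lstsq(Xc, Xt, rcond=None)
    Xt_res = Xt - Xc @ Bx
    # columns fully absorbed by the condition leave only round-off; a
    # projection onto that noise would fabricate explained variance
    norms = np.linalg.norm(Xt_res, axis=0)
    ref = np.maximum(np.linalg.norm(Xt, axis=0), 1.0)
    Xt_res = Xt_res[:, norms > 1e-8 * ref]
    if Xt_res.shape[1] == 0:
        return 0.0
    return _fit_trace(Y_res, Xt_res) / S


def variation_partition(Y: pd.DataFrame, X1: pd.DataFrame, X2: pd.DataFrame,
                        adjusted: bool = False) -> VarPartResult:
    """Partition the variance of Y between predictor groups X1 and X2.

    R1 and R2 are the unique (semipartial) fractions, R12 the combined
    fit, R0 = 1 - R12 the unexplained remainder and
    R_shared = R12 - R1 - R2 the jointly explained fraction. The
    identities R0 + R12 = 1 and R1 + R2 + R_shared = R12 hold exactly by
    construction; R_shared can be negative (suppression) and is reported
    as-is.
    """
    overlap = set(X1.columns) & set(X2.columns)
    if overlap:
        raise GroupingError(f"predictor groups overlap: {sorted(overlap)}")
    n = len(Y)
    Yc = _centered(Y)
    S = total_variation(Y)
    if S == 0:
        raise PreparationError("Y has zero total variation")
    X1k = drop_collinear(X1)
    X2k = drop_collinear(X2)
    X12 = drop_collinear(pd.concat([X1k, X2k], axis=1))
    R12 = _fit_trace(Yc, _centered(X12)) / S
    if not adjusted:
        R1 = partial_fraction(Y, X1k, X2k)
        R2 = partial_fraction(Y, X2k, X1k)
    else:
        R12 = _r2_adjust(R12, n, X12.shape[1])
        r1_full = _r2_adjust(_fit_trace(Yc, _centered(X1k)) / S, n, X1k.shape[1])
        r2_full = _r2_adjust(_fit_trace(Yc, _centered(X2k)) / S, n, X2k.shape[1])
        R1 = R12 - r2_full
        R2 = R12 - r1_full
    return VarPartResult(
        S=S, R1=R1, R2=R2, R12=R12,
        R_shared=R12 - R1 - R2, R0=1.0 - R12,
    )


def partition_indices(Y: pd.DataFrame, indices: pd.DataFrame,
                      grouping: VariableGrouping | None = None,
                      adjusted: bool = False) -> VarPartResult:
    """Convenience wrapper: split the index table by grouping and partition."""
    grouping = grouping or VariableGrouping()
    X1, X2 = grouping.split(indices)
    return variation_partition(Y, X1, X2, adjusted=adjusted)
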