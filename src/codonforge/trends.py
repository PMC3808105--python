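"""Neutrality plot and GC-composition trend regressions.

The neutrality plot regresses GC12 (mean G+C at codon positions 1 and 2)
on GC3s (G+C at synonymous third positions). Under pure mutational
pressure all three positions drift together and the slope approaches 1;
selection on protein-coding positions 1-2 flattens it. The slope b gives
the relative strength of mutation pressure on positions 1-2, and
``b / (1 - b)`` quantifies mutation relative to selection there.

The trend suite fits the standard composition regressions: GC against
gene length (raw and log-log), GC against GRAVY, and GC against AROMO.
P-values are two-sided t-tests on the slope; no multiple-testing
correction is applied across the suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class FitError(ValueError):
    """Regression cannot be fitted (degenerate input)."""


@dataclass(frozen=True)
class RegressionFit:
    """An ordinary least-squares line y = slope*x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class NeutralityResult:
    """GC12 ~ GC3s fit and the implied mutation/selection ratio.

    The ratio is ``None`` (undefined) when the fitted slope falls
    outside [0, 1), where slope/(1 - slope) has no interpretation.
    """

    fit: RegressionFit
    mutation_selection_ratio: float | None


def fit_ols(x, y) -> RegressionFit:
    """OLS fit of y on x with a two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise FitError(f"need at least 3 points, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise FitError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise FitError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2), p_value=float(res.pvalue), n=len(x),
    )


def mutation_selection_ratio(slope: float) -> float:
    """Mutation-to-selection ratio slope/(1 - slope) for a neutrality slope.

    Defined for slopes in [0, 1); a slope at or above 1 would imply
    mutation pressure alone and the ratio is undefined.
    """
    s = float(slope)
    if not 0.0 <= s < 1.0:
        raise ValueError(f"neutrality slope must lie in [0, 1), got {s}")
    return s / (1.0 - s)


def neutrality_plot(indices: pd.DataFrame) -> NeutralityResult:
    """Fit GC12 ~ GC3s on a per-gene index table."""
    sub = indices[["GC3s", "GC12"]].dropna()
    dropped = len(indices) - len(sub)
    if dropped:
        logger.warning("neutrality_plot: dropped %d rows with undefined values", dropped)
    fit = fit_ols(sub["GC3s"], sub["GC12"])
    ratio = mutation_selection_ratio(fit.slope) if 0.0 <= fit.slope < 1.0 else None
    return NeutralityResult(fit=fit, mutation_selection_ratio=ratio)

#: relation name -> (x column, y column, transform)
TREND_RELATIONS = {
    "GC~length": ("length_nt", "GC", None),
    "logGC~loglength": ("length_nt", "GC", "log"),
    "GC~GRAVY": ("GRAVY", "GC", None),
    "GC~AROMO": ("AROMO", "GC", None),
}


def gc_trend_suite(indices: pd.DataFrame) -> dict[str, RegressionFit]:
    """Fit the GC trend regressions on a per-gene index table."""
    out: dict[str, RegressionFit] = {}
    for name, (xcol, ycol, transform) in TREND_RELATIONS.items():
        sub = indices[[xcol, ycol]].dropna()
        dropped = len(indices) - len(sub)
        if dropped:
            logger.warning("%s: dropped %d rows with undefined values", name, dropped)
        x = sub[xcol].to_numpy(dtype=float)
        y = sub[ycol].to_numpy(dtype=float)
        if transform == "log":
            bad = (x <= 0) | (y <= 0)
            if bad.any():
                rows = list(sub.index[bad])
                raise FitError(f"{name}: non-positive values in rows {rows[:10]}")
            x, y = np.log(x), np.log(y)
        out[name] = fit_ols(x, y)
    return out


def trends_table(fits: dict[str, RegressionFit]) -> pd.DataFrame:
    rows = [
        {"relation": name, "slope": f.slope, "intercept": f.intercept,
         "r_squared": f.r_squared, "p_value": f.p_value, "n": f.n}
        for name, f in fits.items()
    ]
    return pd.DataFrame(rows).set_index("relation")
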