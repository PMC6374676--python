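"""Temporal trends of reference points and range-change pattern rules.

Each informative landmark series is tested with a weighted linear regression
of elevation on calendar year, using the yearly number of sampling units as
weight.  A species' pattern of elevational range change follows from which
landmarks moved significantly:

1. both extremes (OBL and OBR) significant with the same sign -> compare the
   slopes (normal z-test on independent fits): the boundary moving
   significantly faster decides between contraction (lower boundary catching
   up) and expansion (upper boundary pulling away); slopes not significantly
   different -> a shift of the whole range;
2. only OBL significant -> lower boundary contraction;
3. only OBR significant -> upper boundary expansion;
4. otherwise any central landmark (CBL, OPT, CBR) significant -> upward shift;
5. nothing significant -> none.

The rules are written for upward (positive-slope) changes, the only direction
observed in the study system; significant downward trends are handled by the
mirror-image labels.  The Durbin-Watson statistic is attached as a residual
autocorrelation diagnostic only — it never alters a classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .response_curves import CENTRAL_LANDMARKS, EXTREME_LANDMARKS, RefPointSeries

__all__ = [
    "TrendFit",
    "SimpleTrend",
    "SlopeComparison",
    "PatternCall",
    "fit_weighted_trend",
    "compare_slopes",
    "durbin_watson",
    "classify_pattern",
]


@dataclass
class TrendFit:
    """Weighted linear regression of landmark elevation on year."""

    slope: float  # m/yr
    se: float
    p: float  # two-sided t-test on n-2 df
    intercept: float
    n: int
    years: np.ndarray
    residuals: np.ndarray  # response-scale residuals in year order
    weights: np.ndarray

    @property
    def dw(self) -> float:
        return durbin_watson(self.residuals)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return self.slope - t * self.se, self.slope + t * self.se


@dataclass(frozen=True)
class SimpleTrend:
    """A (slope, p) record without standard error — e.g. a transcribed table."""

    slope: float
    p: float
    se: Optional[float] = None


@dataclass(frozen=True)
class SlopeComparison:
    z: float
    p: float
    different: bool
    higher: Optional[str] = None  # "a"/"b" when different


@dataclass
class PatternCall:
    """Range-change pattern with its supporting evidence."""

    pattern: str
    significant: tuple[str, ...]
    comparison: Optional[SlopeComparison] = None


def fit_weighted_trend(
    series: RefPointSeries | tuple[np.ndarray, np.ndarray, np.ndarray],
) -> TrendFit:
    """WLS of elevation on year with sampling effort as weight."""
    if isinstance(series, RefPointSeries):
        years, values, weights = series.years, series.values, series.weights
    else:
        years, values, weights = series
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(years) < 3:
        raise ValueError("a trend test needs at least three years")
    if (weights <= 0).any():
        raise ValueError("weights must be positive")
    if np.ptp(years) == 0:
        raise ValueError("year vector has zero variance")
    order = np.argsort(years)
    years, values, weights = years[order], values[order], weights[order]
    X = sm.add_constant(years)
    res = sm.WLS(values, X, weights=weights).fit()
    return TrendFit(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        p=float(res.pvalues[1]),
        intercept=float(res.params[0]),
        n=len(years),
        years=years.astype(int),
        residuals=np.asarray(res.resid, dtype=float),
        weights=weights,
    )


def compare_slopes(a: TrendFit, b: TrendFit, alpha: float = 0.05) -> SlopeComparison:
    """Two-sided normal z-test on the slope difference of independent fits."""
    if a.se is None or b.se is None or not np.isfinite(a.se * b.se):
        raise ValueError("both fits need a finite standard error")
    denom = np.hypot(a.se, b.se)
    if denom == 0:  # both fits exact: identical slopes are not different
        if a.slope == b.slope:
            return SlopeComparison(z=0.0, p=1.0, different=False)
        higher = "a" if a.slope > b.slope else "b"
        return SlopeComparison(z=np.inf * np.sign(a.slope - b.slope), p=0.0,
                               different=True, higher=higher)
    z = (a.slope - b.slope) / denom
    p = 2 * stats.norm.sf(abs(z))
    different = p <= alpha
    higher = None
    if different:
        higher = "a" if a.slope > b.slope else "b"
    return SlopeComparison(z=float(z), p=float(p), different=different, higher=higher)


def durbin_watson(residuals: np.ndarray) -> float:
    """d = sum((e_t - e_{t-1})^2) / sum(e_t^2); NaN when residuals are all zero."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 3:
        raise ValueError("Durbin-Watson needs at least three residuals")
    denom = (e**2).sum()
    if denom == 0:
        return float("nan")
    return float(_sm_dw(e))


def _sig(fit, alpha: float) -> bool:
    return fit is not None and np.isfinite(fit.p) and fit.p <= alpha


def classify_pattern(
    fits: Mapping[str, TrendFit | SimpleTrend | None],
    alpha: float = 0.05,
    slope_comparison: Optional[SlopeComparison] = None,
) -> PatternCall:
    """Classify a species' pattern of elevational range change.

    ``fits`` maps landmark names to trend fits; landmarks that were truncated
    or non-informative are absent or None and count as non-significant.
    ``slope_comparison`` (keyed as fit "a" = OBL, "b" = OBR) can inject a
    known extreme-slope comparison when standard errors are unavailable.
    """
    known = {lm: f for lm, f in fits.items() if f is not None}
    if not known:
        raise ValueError("no landmark trends supplied")
    sig = {lm for lm, f in known.items() if _sig(f, alpha)}
    signs = {lm: np.sign(known[lm].slope) for lm in sig}

    obl, obr = (known.get(lm) for lm in EXTREME_LANDMARKS)
    obl_sig, obr_sig = "OBL" in sig, "OBR" in sig

    if obl_sig and obr_sig and signs["OBL"] == signs["OBR"]:
        up = signs["OBL"] > 0
        comp = slope_comparison or compare_slopes(obl, obr, alpha)
        if not comp.different:
            pattern = "upward shift" if up else "downward shift"
        elif (comp.higher == "a") == up:
            # the lower boundary moves faster toward the range interior
            pattern = "lower boundary contraction" if up else "lower boundary expansion"
        else:
            pattern = "upper boundary expansion" if up else "upper boundary contraction"
        return PatternCall(pattern, tuple(sorted(sig)), comp)
    if obl_sig and obr_sig:  # opposite signs: both boundaries move outward/inward
        pattern = "range expansion" if signs["OBL"] < 0 else "range contraction"
        return PatternCall(pattern, tuple(sorted(sig)))
    if obl_sig:
        pattern = "lower boundary contraction" if signs["OBL"] > 0 else "lower boundary expansion"
        return PatternCall(pattern, tuple(sorted(sig)))
    if obr_sig:
        pattern = "upper boundary expansion" if signs["OBR"] > 0 else "upper boundary contraction"
        return PatternCall(pattern, tuple(sorted(sig)))
    central_sig = [lm for lm in CENTRAL_LANDMARKS if lm in sig]
    if central_sig:
        mean_sign = np.sign(np.mean([known[lm].slope for lm in central_sig]))
        return PatternCall(
            "upward shift" if mean_sign >= 0 else "downward shift", tuple(sorted(sig))
        )
    return PatternCall("none", ())
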