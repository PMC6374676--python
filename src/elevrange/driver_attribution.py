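"""Climate vs. habitat driver attribution for significant reference points.

Each significantly trending landmark series is regressed (weighted least
squares, yearly sampling effort as weight) on the belt's May-June minimum
temperature series (tn, degC) and shrub+forest cover series (SF, km^2).  The
explained variation is partitioned into four additive fractions from the
weighted R-squared of the three nested models (tn only: R2_T; SF only: R2_S;
both: R2_TS):

    partial_tn  = R2_TS - R2_S        (net temperature contribution)
    partial_SF  = R2_TS - R2_T        (net habitat contribution)
    shared      = R2_T + R2_S - R2_TS (joint, collinearity-borne part)
    unexplained = 1 - R2_TS

Negative components (suppression) are floored at zero and the remainder is
absorbed into the shared fraction so the four always sum to one.  The driver
call then follows threshold rules on the fractions: shared > 0.9 -> not
distinguishable (nd); both nets >= 0.1 -> tn+SF; one net >= 0.1 -> that
driver; unexplained > 0.9 -> none; anything else falls through as nd.

Two relabelling rules act on raw nd calls.  Under near-collinearity
(shared > 0.9) a temperature coefficient that is individually significant
while the habitat one is not marks temperature as the separable driver.  When
no threshold fired at all, the call goes to the individually significant
covariate with the larger net contribution (nd if neither is significant).
Finally, a negative habitat coefficient at an upper landmark (CBR/OBR) with a
final SF or nd call is ecologically spurious — cover decreases with elevation
— and is flagged as a density-dependent effect, dde: dense populations lower
down spilling into suboptimal higher habitat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol

import numpy as np
import statsmodels.api as sm

__all__ = [
    "DriverRegression",
    "DeviancePartition",
    "RawDriverCall",
    "DriverCall",
    "fit_driver_regression",
    "variation_partition",
    "independent_effects",
    "classify_driver",
    "finalize_driver_call",
]

UPPER_LANDMARKS = ("CBR", "OBR")


class _HasCoefficients(Protocol):
    beta_tn: float
    p_tn: float
    beta_sf: float
    p_sf: float


@dataclass
class DriverRegression:
    """Weighted multiple linear regression of elevation on (tn, SF)."""

    beta_tn: float  # m per degC
    p_tn: float
    beta_sf: float  # m per km^2
    p_sf: float
    r2: float
    r2_adj: float
    n: int
    residuals: np.ndarray
    weights: np.ndarray
    collinear: bool = False  # |corr(tn, SF)| beyond tolerance; fit kept


@dataclass(frozen=True)
class DriverStats:
    """Coefficient summary sufficient for the relabelling rules (e.g. when
    re-classifying a printed table without refitting)."""

    beta_tn: float
    p_tn: float
    beta_sf: float
    p_sf: float


@dataclass(frozen=True)
class DeviancePartition:
    """Four additive fractions of the total weighted variation."""

    partial_tn: float
    shared: float
    partial_sf: float
    unexplained: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.partial_tn, self.shared, self.partial_sf, self.unexplained)

    def check(self, tol: float = 1e-9) -> None:
        t = self.as_tuple()
        if any(not (-tol <= v <= 1 + tol) for v in t):
            raise ValueError("partition components must lie in [0, 1]")
        if abs(sum(t) - 1) > tol:
            raise ValueError("partition components must sum to 1")


@dataclass(frozen=True)
class RawDriverCall:
    """Threshold-rule class before relabelling; carries its partition."""

    cls: str  # nd | tn+SF | SF | tn | none
    fallback: bool  # True when no threshold rule fired
    partition: DeviancePartition


@dataclass(frozen=True)
class DriverCall:
    raw: str
    final: str  # underlying class after overrides: nd | tn+SF | SF | tn | none
    dde: bool

    @property
    def label(self) -> str:
        pretty = "tn + SF" if self.final == "tn+SF" else self.final
        return f"dde ({pretty})" if self.dde else pretty

    @property
    def level(self) -> str:
        """Factor level for the contingency analysis (dde is its own level)."""
        return "dde" if self.dde else ("tn + SF" if self.final == "tn+SF" else self.final)


def _weighted_r2(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> float:
    res = sm.WLS(y, X, weights=w).fit()
    ybar = np.average(y, weights=w)
    tss = float(w @ (y - ybar) ** 2)
    rss = float(w @ (y - res.fittedvalues) ** 2)
    return 1.0 - rss / tss


def _validate_xy(y, tn, sf, weights):
    y = np.asarray(y, dtype=float)
    tn = np.asarray(tn, dtype=float)
    sf = np.asarray(sf, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if not (len(y) == len(tn) == len(sf) == len(w)):
        raise ValueError("misaligned series: y, tn, SF and weights differ in length")
    if len(y) < 5:
        raise ValueError("driver regression needs at least five aligned years")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    for name, v in (("tn", tn), ("SF", sf)):
        if np.ptp(v) == 0:
            raise ValueError(f"zero-variance predictor: {name}")
    return y, tn, sf, w


def fit_driver_regression(
    y: np.ndarray,
    tn: np.ndarray,
    sf: np.ndarray,
    weights: np.ndarray | None = None,
    collinearity_tol: float = 0.999,
) -> DriverRegression:
    """WLS of landmark elevation on (tn, SF) with coefficient t-tests."""
    y, tn, sf, w = _validate_xy(y, tn, sf, weights)
    X = sm.add_constant(np.column_stack([tn, sf]))
    res = sm.WLS(y, X, weights=w).fit()
    collinear = abs(np.corrcoef(tn, sf)[0, 1]) > collinearity_tol
    return DriverRegression(
        beta_tn=float(res.params[1]),
        p_tn=float(res.pvalues[1]),
        beta_sf=float(res.params[2]),
        p_sf=float(res.pvalues[2]),
        r2=_weighted_r2(y, X, w),
        r2_adj=float(res.rsquared_adj),
        n=len(y),
        residuals=np.asarray(res.resid, dtype=float),
        weights=w,
        collinear=collinear,
    )


def variation_partition(
    y: np.ndarray,
    tn: np.ndarray,
    sf: np.ndarray,
    weights: np.ndarray | None = None,
) -> DeviancePartition:
    """Unique/shared/unexplained decomposition from the three nested models."""
    y, tn, sf, w = _validate_xy(y, tn, sf, weights)
    ones = np.ones_like(y)
    r2_t = _weighted_r2(y, np.column_stack([ones, tn]), w)
    r2_s = _weighted_r2(y, np.column_stack([ones, sf]), w)
    r2_ts = _weighted_r2(y, np.column_stack([ones, tn, sf]), w)
    partial_tn = r2_ts - r2_s
    partial_sf = r2_ts - r2_t
    shared = r2_t + r2_s - r2_ts
    unexplained = 1.0 - r2_ts
    # floor suppression-induced negatives; absorb the remainder into shared
    partial_tn, partial_sf, unexplained = (max(v, 0.0) for v in (partial_tn, partial_sf, unexplained))
    shared = 1.0 - partial_tn - partial_sf - unexplained
    if shared < 0:  # pathological suppression: renormalize the floored parts
        total = partial_tn + partial_sf + unexplained
        partial_tn, partial_sf, unexplained = (v / total for v in (partial_tn, partial_sf, unexplained))
        shared = 0.0
    part = DeviancePartition(partial_tn, shared, partial_sf, unexplained)
    part.check(tol=1e-9)
    return part


def independent_effects(
    y: np.ndarray,
    tn: np.ndarray,
    sf: np.ndarray,
    weights: np.ndarray | None = None,
) -> dict[str, float]:
    """Hierarchical-partitioning independent/joint effects (order-averaged).

    Provided as the alternative decomposition; the additive four-fraction
    partition above is the default used by the driver rules.
    """
    y, tn, sf, w = _validate_xy(y, tn, sf, weights)
    ones = np.ones_like(y)
    r2_t = _weighted_r2(y, np.column_stack([ones, tn]), w)
    r2_s = _weighted_r2(y, np.column_stack([ones, sf]), w)
    r2_ts = _weighted_r2(y, np.column_stack([ones, tn, sf]), w)
    ind_tn = 0.5 * (r2_t + (r2_ts - r2_s))
    ind_sf = 0.5 * (r2_s + (r2_ts - r2_t))
    return {
        "independent_tn": ind_tn,
        "independent_sf": ind_sf,
        "joint_tn": r2_t - ind_tn,
        "joint_sf": r2_s - ind_sf,
        "unexplained": 1.0 - r2_ts,
    }


def classify_driver(
    partition: DeviancePartition,
    nd_threshold: float = 0.9,
    net_threshold: float = 0.1,
) -> RawDriverCall:
    """Threshold rules on the partition, in order; ties fall through as nd."""
    p = partition
    if p.shared > nd_threshold:
        return RawDriverCall("nd", False, p)
    if p.partial_tn >= net_threshold and p.partial_sf >= net_threshold:
        return RawDriverCall("tn+SF", False, p)
    if p.partial_sf >= net_threshold:
        return RawDriverCall("SF", False, p)
    if p.partial_tn >= net_threshold:
        return RawDriverCall("tn", False, p)
    if p.unexplained > nd_threshold:
        return RawDriverCall("none", False, p)
    return RawDriverCall("nd", True, p)


def finalize_driver_call(
    raw: RawDriverCall,
    regression: _HasCoefficients,
    landmark: str,
    alpha: float = 0.05,
) -> DriverCall:
    """Apply the nd relabelling rules and the density-dependent-effect flag."""
    final = raw.cls
    if raw.cls == "nd":
        tn_sig = regression.p_tn <= alpha
        sf_sig = regression.p_sf <= alpha
        if raw.fallback:
            if tn_sig and sf_sig:
                final = "tn" if raw.partition.partial_tn >= raw.partition.partial_sf else "SF"
            elif tn_sig:
                final = "tn"
            elif sf_sig:
                final = "SF"
        elif tn_sig and not sf_sig:
            # collinear series: only a temperature-specific signal is separable
            final = "tn"
    dde = landmark in UPPER_LANDMARKS and regression.beta_sf < 0 and final in ("SF", "nd")
    return DriverCall(raw=raw.cls, final=final, dde=dde)
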