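"""Yearly presence-probability curves along elevation and their landmarks.

For one species and one survey year the presence/absence records are fit with
a binomial additive model (logit link): an elevation smooth capped at 3
effective df so only unimodal or monotone shapes are representable — by
default the classical Gaussian response curve, i.e. a quadratic on the logit
scale (2 df), whose optimum estimate is location-equivariant; a natural
cubic regression spline basis is available as an alternative — plus a
low-order polynomial surface in the geographic coordinates (<= 15 df)
absorbing spatial autocorrelation.  The
curve is predicted along a dense elevation grid with the spatial surface held
at its average over the year's survey locations, which makes curves
comparable across years with different spatial coverage.

Five landmarks summarize each curve: the optimum OPT and, left/right of it,
the central borders (CBL/CBR) where the probability falls to p_max*exp(-0.5)
and the outer borders (OBL/OBR) where it falls to p_max*exp(-2).  Landmarks
whose defining feature lies at or beyond the surveyed elevation window are
reported as truncated (missing).  Reliability of each landmark is assessed by
bootstrapping the year's records (default 200 replicates): a landmark is
reliable when refit-and-extract succeeds in at least half of the replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import build_design_matrices, dmatrix

__all__ = [
    "LANDMARKS",
    "CENTRAL_LANDMARKS",
    "EXTREME_LANDMARKS",
    "CurveSettings",
    "FittedCurve",
    "ReferencePoints",
    "RefPointSeries",
    "fit_year_curve",
    "extract_reference_points",
    "bootstrap_reliability",
    "build_series",
]

LANDMARKS = ("OBL", "CBL", "OPT", "CBR", "OBR")
CENTRAL_LANDMARKS = ("CBL", "OPT", "CBR")
EXTREME_LANDMARKS = ("OBL", "OBR")

_CB_LEVEL = np.exp(-0.5)
_OB_LEVEL = np.exp(-2.0)


@dataclass(frozen=True)
class CurveSettings:
    """Tunables of the curve stage (defaults follow the study design)."""

    elev_df: int = 3  # max effective df of the elevation smooth
    spatial_df: int = 15  # max effective df of the spatial surface
    n_boot: int = 200  # bootstrap replicates per species-year
    bounds: tuple[float, float] = (600.0, 2700.0)
    grid_step: float = 1.0  # prediction grid step (m)
    min_rows: int = 30  # minimum records to attempt a fit
    reliability_threshold: float = 0.5  # "at least 50% of replicates"
    #: "quadratic-logit" fits the classical Gaussian response curve (a
    #: quadratic on the logit scale, 2 df, location-equivariant so curve
    #: optima are not pulled toward the window centre); "spline" uses a
    #: natural cubic regression spline with elev_df basis functions.
    elev_basis: str = "quadratic-logit"

    def __post_init__(self) -> None:
        if self.elev_df < 2 or self.spatial_df < 0:
            raise ValueError("elevation df must be >= 2 (spatial may be 0)")
        if self.elev_basis not in ("quadratic-logit", "spline"):
            raise ValueError("elev_basis must be 'quadratic-logit' or 'spline'")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("elevation bounds must be ordered")
        if not 0 < self.reliability_threshold <= 1:
            raise ValueError("reliability threshold must be in (0, 1]")

    def grid(self) -> np.ndarray:
        lo, hi = self.bounds
        n = int(np.floor((hi - lo) / self.grid_step))
        return lo + np.arange(n + 1) * self.grid_step


@dataclass
class FittedCurve:
    """Predicted presence probability along the elevation grid."""

    species: str
    year: int
    grid: np.ndarray
    probability: np.ndarray
    converged: bool
    degenerate: bool = False
    n_obs: int = 0

    @property
    def ok(self) -> bool:
        return self.converged and not self.degenerate


@dataclass
class ReferencePoints:
    """The five landmarks of one species-year curve with reliability."""

    species: str
    year: int
    points: dict = field(default_factory=dict)  # landmark -> elevation or None
    success: dict = field(default_factory=dict)  # landmark -> bootstrap fraction
    reliable: dict = field(default_factory=dict)  # landmark -> bool
    n_y: int = 0  # sampling units this year (downstream regression weight)

    def present(self, landmark: str) -> bool:
        return self.points.get(landmark) is not None


@dataclass
class RefPointSeries:
    """Time series of one landmark's elevation with per-year weights."""

    species: str
    landmark: str
    years: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    informative: bool

    def __len__(self) -> int:
        return len(self.years)


# ---------------------------------------------------------------------------
# model matrix / fitting engine
# ---------------------------------------------------------------------------


def _spatial_terms(x: np.ndarray, y: np.ndarray, max_df: int) -> np.ndarray:
    """Polynomial surface in standardized coordinates, up to cubic (9 df)."""
    cols = [x, y, x * y, x**2, y**2, x**3, x**2 * y, x * y**2, y**3]
    k = min(max_df, len(cols))
    if k == 0:
        return np.empty((x.size, 0))
    return np.column_stack(cols[:k])


class _CurveDesign:
    """Design matrices for one species-year, reusable across bootstrap draws."""

    def __init__(self, rows: pd.DataFrame, settings: CurveSettings):
        self.settings = settings
        elev = np.asarray(rows["elevation"], dtype=float)
        east = np.asarray(rows["easting"], dtype=float)
        north = np.asarray(rows["northing"], dtype=float)
        self.y = np.asarray(rows["presence"], dtype=float)
        self.n = len(self.y)

        if settings.elev_basis == "quadratic-logit":
            self._e0, self._es = elev.mean(), elev.std() or 1.0
            elev_basis = self._poly(elev)
            self._elev_info = None
        else:
            dm = dmatrix(f"cr(elev, df={settings.elev_df}) - 1", {"elev": elev})
            self._elev_info = dm.design_info
            elev_basis = np.asarray(dm)
        xs = (east - east.mean()) / (east.std() or 1.0)
        ys = (north - north.mean()) / (north.std() or 1.0)
        spatial = _spatial_terms(xs, ys, settings.spatial_df)
        self.X = np.column_stack([np.ones(self.n), elev_basis, spatial])
        # spatial surface averaged over this year's survey locations
        self._mean_spatial = spatial.mean(axis=0) if spatial.shape[1] else np.empty(0)

        grid = settings.grid()
        if self._elev_info is None:
            grid_basis = self._poly(grid)
        else:
            grid_basis = np.asarray(build_design_matrices([self._elev_info], {"elev": grid})[0])
        self.grid = grid
        self.X_grid = np.column_stack(
            [np.ones(len(grid)), grid_basis, np.tile(self._mean_spatial, (len(grid), 1))]
        )

    def _poly(self, elev: np.ndarray) -> np.ndarray:
        z = (np.asarray(elev, dtype=float) - self._e0) / self._es
        return np.column_stack([z, z**2])

    def fit(self, idx: np.ndarray | None = None, start_params: np.ndarray | None = None):
        """Return fitted params or None on failure/degeneracy."""
        X = self.X if idx is None else self.X[idx]
        y = self.y if idx is None else self.y[idx]
        if y.min() == y.max():  # all-presence or all-absence: degenerate response
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    maxiter=50, start_params=start_params
                )
            except Exception:
                return None
        params = np.asarray(res.params)
        if not (res.converged and np.isfinite(params).all()):
            return None
        return params

    def predict(self, params: np.ndarray) -> np.ndarray:
        eta = self.X_grid @ params
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def fit_year_curve(rows: pd.DataFrame, settings: CurveSettings | None = None) -> FittedCurve:
    """Fit one species-year presence curve.

    ``rows`` needs columns elevation, easting, northing, presence (one species,
    one year).  Degenerate inputs (too few rows, single response class) and
    non-convergence are flagged on the returned curve, never raised.
    """
    settings = settings or CurveSettings()
    species = str(rows["species"].iloc[0]) if "species" in rows and len(rows) else ""
    year = int(rows["year"].iloc[0]) if "year" in rows and len(rows) else 0
    grid = settings.grid()
    n = len(rows)
    if n < settings.min_rows or rows["presence"].nunique() < 2:
        return FittedCurve(species, year, grid, np.full(grid.shape, np.nan), False, True, n)
    design = _CurveDesign(rows, settings)
    params = design.fit()
    if params is None:
        return FittedCurve(species, year, grid, np.full(grid.shape, np.nan), False, False, n)
    return FittedCurve(species, year, grid, design.predict(params), True, False, n)


# ---------------------------------------------------------------------------
# landmark extraction
# ---------------------------------------------------------------------------


def _crossing(grid, p, i_max, level, direction):
    """Nearest crossing of ``level`` scanning from the maximum; None if the
    curve runs off the grid before dropping below the level."""
    i = i_max
    step = -1 if direction == "left" else 1
    while 0 <= i + step < len(grid):
        j = i + step
        if p[j] <= level:
            # linear interpolation between grid[i] and grid[j]
            if p[i] == p[j]:
                return float(grid[j])
            frac = (p[i] - level) / (p[i] - p[j])
            return float(grid[i] + frac * (grid[j] - grid[i]))
        i = j
    return None


def extract_reference_points(
    curve: FittedCurve, bounds: tuple[float, float] | None = None
) -> ReferencePoints:
    """Locate OPT/CB/OB landmarks on a fitted curve; truncated ones are None.

    The optimum must be an interior maximum: a maximum within one grid step of
    either bound means the curve is monotone over the window, so OPT and the
    landmarks on that side are reported missing.  Border crossings are located
    by linear interpolation between grid points.
    """
    rp = ReferencePoints(curve.species, curve.year, n_y=curve.n_obs)
    rp.points = {lm: None for lm in LANDMARKS}
    rp.success = {lm: 0.0 for lm in LANDMARKS}
    rp.reliable = {lm: False for lm in LANDMARKS}
    if not curve.ok:
        return rp
    grid, p = curve.grid, curve.probability
    lo, hi = bounds if bounds is not None else (grid[0], grid[-1])
    step = grid[1] - grid[0]
    i_max = int(np.argmax(p))
    p_max = p[i_max]
    at_lower = grid[i_max] <= lo + step
    at_upper = grid[i_max] >= hi - step
    if not (at_lower or at_upper):
        rp.points["OPT"] = float(grid[i_max])
    for lm, level, direction in (
        ("CBL", p_max * _CB_LEVEL, "left"),
        ("OBL", p_max * _OB_LEVEL, "left"),
        ("CBR", p_max * _CB_LEVEL, "right"),
        ("OBR", p_max * _OB_LEVEL, "right"),
    ):
        if (direction == "left" and at_lower) or (direction == "right" and at_upper):
            continue  # curve truncated on this side
        x = _crossing(grid, p, i_max, level, direction)
        if x is not None and lo < x < hi:  # a crossing AT a bound is truncated
            rp.points[lm] = x
    return rp


# ---------------------------------------------------------------------------
# bootstrap reliability
# ---------------------------------------------------------------------------


def bootstrap_reliability(
    rows: pd.DataFrame, settings: CurveSettings | None = None, seed: int | None = None
) -> ReferencePoints:
    """Full-data landmarks plus bootstrap success fractions.

    The year's records are resampled with replacement ``n_boot`` times; a
    replicate counts as a success for a landmark when the refit converges and
    the landmark is extractable (inside the bounds).  A landmark is reliable
    when its success fraction reaches the threshold (default 0.5) and it is
    present in the full-data fit, whose elevation is the reported value.
    """
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    settings = settings or CurveSettings()
    species = str(rows["species"].iloc[0]) if "species" in rows and len(rows) else ""
    year = int(rows["year"].iloc[0]) if "year" in rows and len(rows) else 0
    n = len(rows)
    curve = fit_year_curve(rows, settings)
    rp = extract_reference_points(curve, settings.bounds)
    rp.n_y = n
    if not curve.ok:
        return rp

    design = _CurveDesign(rows, settings)
    full_params = design.fit()
    rng = np.random.default_rng(seed)
    counts = {lm: 0 for lm in LANDMARKS}
    boot_curve = FittedCurve(species, year, design.grid, np.empty(0), True, False, n)
    for _ in range(settings.n_boot):
        idx = rng.integers(0, n, size=n)
        params = design.fit(idx, start_params=full_params)
        if params is None:
            continue
        boot_curve.probability = design.predict(params)
        boot_rp = extract_reference_points(boot_curve, settings.bounds)
        for lm in LANDMARKS:
            if boot_rp.present(lm):
                counts[lm] += 1
    for lm in LANDMARKS:
        frac = counts[lm] / settings.n_boot
        rp.success[lm] = frac
        rp.reliable[lm] = frac >= settings.reliability_threshold and rp.present(lm)
    return rp


def build_series(
    yearly: list[ReferencePoints], min_informative: int = 10
) -> dict[str, RefPointSeries]:
    """Assemble per-landmark time series from reliable yearly values.

    Each series carries the year's sampling effort as regression weight and
    is marked informative when it holds at least ``min_informative`` reliable
    values; non-informative series are excluded from the trend analysis.
    """
    if not yearly:
        raise ValueError("at least one year of reference points is required")
    species = yearly[0].species
    out: dict[str, RefPointSeries] = {}
    for lm in LANDMARKS:
        yrs, vals, wts = [], [], []
        for rp in sorted(yearly, key=lambda r: r.year):
            if rp.reliable.get(lm) and rp.present(lm):
                yrs.append(rp.year)
                vals.append(rp.points[lm])
                wts.append(rp.n_y)
        out[lm] = RefPointSeries(
            species=species,
            landmark=lm,
            years=np.asarray(yrs, dtype=int),
            values=np.asarray(vals, dtype=float),
            weights=np.asarray(wts, dtype=float),
            informative=len(yrs) >= min_informative,
        )
    return out
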