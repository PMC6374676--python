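"""Per-landmark covariate series: belt temperature (tn) and habitat cover (SF).

Each informative reference point defines an elevational belt — the [min, max]
interval of elevations it occupied across the time series.  Within that belt
two yearly series are built: the overall mean of daily minimum temperatures
over May 1 - June 30 (tn, degC) and the shrub+forest cover (SF, km^2)
interpolated from the sparse cartography years with a year-smooth capped at
4 df.

Coarse daily temperature grids are brought to the fine climatology grid with
the anomaly (delta) method: fine value = fine climatology + (coarse daily -
coarse climatology) of the enclosing coarse cell.  The interface is
grid-in/grid-out, so a more elaborate downscaling procedure can be swapped in
without touching the belt aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import build_design_matrices, dmatrix

from .response_curves import RefPointSeries
from .synthetic_data import ElevationGrid, TemperatureCube

__all__ = [
    "Belt",
    "belt_from_series",
    "downscale_temperature",
    "belt_temperature_series",
    "belt_habitat_survey",
    "interpolate_habitat_cover",
]


@dataclass(frozen=True)
class Belt:
    """Elevational belt [lower, upper] in m asl."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("belt bounds must be finite")
        if self.lower >= self.upper:
            raise ValueError("belt lower bound must be below the upper bound")

    def contains(self, elevation: np.ndarray) -> np.ndarray:
        e = np.asarray(elevation, dtype=float)
        return (e >= self.lower) & (e <= self.upper)  # inclusive bounds


def belt_from_series(series: RefPointSeries) -> Belt:
    """Belt spanned by a reference point's reliable values over the years."""
    if len(series) == 0:
        raise ValueError("cannot build a belt from an empty series")
    lo, hi = float(series.values.min()), float(series.values.max())
    if lo == hi:  # a constant landmark still needs a non-degenerate belt
        lo, hi = lo - 0.5, hi + 0.5
    return Belt(lo, hi)


def downscale_temperature(
    coarse: TemperatureCube,
    coarse_climatology: ElevationGrid,
    fine_climatology: ElevationGrid,
) -> TemperatureCube:
    """Delta-method downscaling of daily grids onto the fine climatology grid.

    Every fine cell takes its enclosing coarse cell's daily anomaly (coarse
    daily minus coarse climatology) added to the fine climatology.  Fine cells
    outside the coarse coverage are an error.
    """
    if coarse.data.shape[2:] != coarse_climatology.shape:
        raise ValueError("coarse cube and coarse climatology shapes differ")
    xs, ys = fine_climatology.cell_centers()
    xg, yg = np.meshgrid(xs, ys)
    try:
        ci, cj = coarse_climatology.cell_index(xg.ravel(), yg.ravel())
    except ValueError as exc:
        raise ValueError("fine grid extends outside the coarse coverage") from exc
    anomaly = coarse.data - coarse_climatology.elevation[None, None, :, :]
    ny, nx = fine_climatology.shape
    fine = fine_climatology.elevation[None, None, :, :] + anomaly[:, :, ci, cj].reshape(
        anomaly.shape[0], anomaly.shape[1], ny, nx
    )
    return TemperatureCube(
        years=coarse.years,
        data=fine,
        cell_size=fine_climatology.cell_size,
        x0=fine_climatology.x0,
        y0=fine_climatology.y0,
    )


def belt_temperature_series(
    cube: TemperatureCube, elevation: ElevationGrid, belt: Belt
) -> pd.Series:
    """Yearly mean of all window days over all cells inside the belt (tn, degC)."""
    if cube.grid_shape != elevation.shape:
        raise ValueError("temperature cube and elevation grid shapes differ")
    mask = belt.contains(elevation.elevation)
    if not mask.any():
        raise ValueError("empty elevational belt: no grid cell inside the belt")
    means = cube.data[:, :, mask].mean(axis=(1, 2))
    return pd.Series(means, index=list(cube.years), name="tn_C")


def belt_habitat_survey(habitat: pd.DataFrame, belt: Belt) -> tuple[np.ndarray, np.ndarray]:
    """Reduce banded cover surveys to per-year totals within the belt.

    Band cover is assumed uniform in elevation, so each band contributes in
    proportion to its overlap with the belt.
    """
    needed = {"year", "band_lo", "band_hi", "sf_km2"}
    if not needed.issubset(habitat.columns):
        raise ValueError(f"habitat surveys need columns {sorted(needed)}")
    lo = habitat["band_lo"].to_numpy(float)
    hi = habitat["band_hi"].to_numpy(float)
    overlap = np.clip(
        np.minimum(hi, belt.upper) - np.maximum(lo, belt.lower), 0.0, None
    ) / (hi - lo)
    contrib = habitat["sf_km2"].to_numpy(float) * overlap
    per_year = pd.Series(contrib).groupby(habitat["year"].to_numpy()).sum()
    return per_year.index.to_numpy(int), per_year.to_numpy(float)


def interpolate_habitat_cover(
    survey_years: Sequence[int],
    survey_values: Sequence[float],
    target_years: Sequence[int],
    max_df: int = 4,
) -> pd.Series:
    """Smooth the sparse cover surveys over year and predict every target year.

    A natural cubic regression spline of the year with effective df capped at
    ``max_df`` (and at n_surveys - 1) is fit by least squares; predictions are
    floored at zero.  At least two survey years are required.
    """
    yrs = np.asarray(survey_years, dtype=float)
    vals = np.asarray(survey_values, dtype=float)
    if len(yrs) < 2:
        raise ValueError("habitat interpolation needs at least two survey years")
    if len(yrs) != len(vals):
        raise ValueError("survey year/value lengths differ")
    tgt = np.asarray(target_years, dtype=float)
    df_eff = int(min(max_df, len(yrs) - 1))
    if df_eff <= 1:
        coef = np.polyfit(yrs, vals, 1)
        pred = np.polyval(coef, tgt)
    else:
        dm = dmatrix(f"cr(year, df={df_eff}) - 1", {"year": yrs})
        X = sm.add_constant(np.asarray(dm))
        fit = sm.OLS(vals, X).fit()
        basis = np.asarray(build_design_matrices([dm.design_info], {"year": tgt})[0])
        pred = sm.add_constant(basis, has_constant="add") @ fit.params
    pred = np.maximum(pred, 0.0)
    return pd.Series(pred, index=np.asarray(target_years, dtype=int), name="sf_km2")
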