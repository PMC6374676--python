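"""Synthetic alpine world: terrain, covariate truth, and point-count surveys.

The generator emulates the structure of a long-term mountain breeding-bird
monitoring scheme: 28 survey years spread over 1982-2017 (with the historical
gap years), point counts scattered over a 600-2,700 m asl gradient with yearly
effort varying between ~67 and ~782 points, a warming trend in May-June daily
minimum temperatures (~0.46 degC per decade by default), and shrub+forest
encroachment that is stronger below 1,200 m asl.  Every species has a known
unimodal presence-probability curve along elevation,

    p(e) = p_max * exp(-(e - mu)^2 / (2 * sigma^2)),

with side-specific scale (sigma_L below the optimum, sigma_U above), so the
analytic reference points OPT = mu, CB = mu -/+ sigma_side and
OB = mu -/+ 2*sigma_side are available as ground truth for every year.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElevationGrid",
    "SpeciesTruth",
    "TemperatureCube",
    "CovariateTruth",
    "DEFAULT_SURVEY_YEARS",
    "MAY_JUNE_DAYS",
    "default_effort",
    "generate_landscape",
    "generate_covariate_truth",
    "habitat_survey_table",
    "simulate_surveys",
]

#: The 28 years with bird surveys (1982-1987, 1992, 1995-96, 1999-2017);
#: 1988-1991, 1993-94 and 1997-98 are gap years without data.
DEFAULT_SURVEY_YEARS: tuple[int, ...] = tuple(range(1982, 1988)) + (
    1992,
    1995,
    1996,
) + tuple(range(1999, 2018))

#: Number of days in the May 1 - June 30 window (31 + 30).
MAY_JUNE_DAYS = 61


# ---------------------------------------------------------------------------
# terrain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElevationGrid:
    """Single-band elevation raster (m asl) on a regular grid.

    ``elevation[i, j]`` is the cell-center value of the cell in row ``i``
    (northing) and column ``j`` (easting); ``(x0, y0)`` is the lower-left
    corner of the raster.
    """

    elevation: np.ndarray
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        elev = np.asarray(self.elevation, dtype=float)
        if elev.ndim != 2 or elev.size == 0:
            raise ValueError("elevation must be a non-empty 2-D array")
        if not np.isfinite(elev).all():
            raise ValueError("elevation must be finite everywhere")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "elevation", elev)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the raster footprint."""
        ny, nx = self.shape
        return (self.x0, self.x0 + nx * self.cell_size, self.y0, self.y0 + ny * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each (x, y); errors outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        j = np.floor((x - self.x0) / self.cell_size).astype(int)
        i = np.floor((y - self.y0) / self.cell_size).astype(int)
        ny, nx = self.shape
        if ((i < 0) | (i >= ny) | (j < 0) | (j >= nx)).any():
            raise ValueError("coordinates fall outside the raster extent")
        return i, j

    def elevation_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        i, j = self.cell_index(x, y)
        return self.elevation[i, j]

    # -- plain-text friendly IO: .npy array + .json geotransform sidecar ----

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.elevation)
        meta = {"cell_size": self.cell_size, "x0": self.x0, "y0": self.y0}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "ElevationGrid":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(np.load(path.with_suffix(".npy")), **meta)


def generate_landscape(
    seed: int,
    *,
    shape: tuple[int, int] = (30, 30),
    cell_size: float = 1000.0,
    model: str = "random",
    elev_range: tuple[float, float] = (600.0, 2700.0),
    constant: float = 1500.0,
    roughness: float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ElevationGrid:
    """Build a reproducible synthetic terrain.

    ``model="random"`` (default) draws cell elevations uniformly over
    ``elev_range`` — a deliberately rugged terrain in which elevation varies
    within every neighbourhood and is therefore identifiable next to the
    smooth spatial surface of the curve models (a monotone ramp would be
    perfectly confounded with northing).  ``model="plane"`` produces a
    south-to-north linear ramp whose cell-center values span ``elev_range``
    exactly; ``roughness`` (m) adds a smooth, seeded sinusoidal perturbation
    (clipped back into ``elev_range``).  ``model="constant"`` fills the grid
    with ``constant``.
    """
    ny, nx = shape
    if ny <= 0 or nx <= 0 or cell_size <= 0:
        raise ValueError("grid shape and cell size must be positive")
    lo, hi = elev_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
        raise ValueError("elev_range must be an ordered finite interval")
    rng = np.random.default_rng(seed)
    x0, y0 = origin
    if model == "constant":
        elev = np.full(shape, float(constant))
    elif model == "random":
        elev = rng.uniform(lo, hi, size=shape)
    elif model == "plane":
        rows = np.arange(ny, dtype=float)
        ramp = lo + (hi - lo) * (rows / max(ny - 1, 1))
        elev = np.repeat(ramp[:, None], nx, axis=1)
        if roughness > 0:
            xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
            phase = rng.uniform(0, 2 * np.pi, size=4)
            wobble = np.sin(2 * np.pi * xs / max(nx, 1) + phase[0]) * np.cos(
                2 * np.pi * ys / max(ny, 1) + phase[1]
            ) + 0.5 * np.sin(4 * np.pi * xs / max(nx, 1) + phase[2]) * np.sin(
                4 * np.pi * ys / max(ny, 1) + phase[3]
            )
            elev = np.clip(elev + roughness * wobble, lo, hi)
    else:
        raise ValueError(f"unknown elevation model {model!r}")
    return ElevationGrid(elev, cell_size=cell_size, x0=x0, y0=y0)


# ---------------------------------------------------------------------------
# species truth
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTruth:
    """Per-year true presence curve parameters for one species.

    Arrays are aligned with ``years``.  The curve is an asymmetric Gaussian:
    scale ``sigma_l`` applies below the optimum ``mu`` and ``sigma_u`` above,
    so lower-boundary contraction scenarios (sigma_l shrinking while sigma_u
    is stable) are representable with analytic reference points.
    """

    species: str
    years: np.ndarray
    p_max: np.ndarray
    mu: np.ndarray
    sigma_l: np.ndarray
    sigma_u: np.ndarray
    habitat: str = "forest"
    migration: str = "res"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for name in ("p_max", "mu", "sigma_l", "sigma_u"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), self.years.shape).copy()
            setattr(self, name, arr)
        # p_max = 0 is tolerated as the degenerate never-present species
        if not ((self.p_max >= 0) & (self.p_max <= 1)).all():
            raise ValueError("p_max must lie in [0, 1]")
        if not ((self.sigma_l > 0) & (self.sigma_u > 0)).all():
            raise ValueError("curve scales must be positive")

    def _year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"species {self.species!r} has no truth for year {year}")
        return int(idx[0])

    def probability(self, elevation: np.ndarray, year: int) -> np.ndarray:
        """True presence probability at ``elevation`` (m asl) in ``year``."""
        k = self._year_index(year)
        e = np.asarray(elevation, dtype=float)
        sigma = np.where(e < self.mu[k], self.sigma_l[k], self.sigma_u[k])
        return self.p_max[k] * np.exp(-((e - self.mu[k]) ** 2) / (2.0 * sigma**2))

    def reference_point(self, landmark: str, year: int) -> float:
        """Analytic landmark elevation (OPT, CBL, CBR, OBL, OBR)."""
        k = self._year_index(year)
        mu, sl, su = self.mu[k], self.sigma_l[k], self.sigma_u[k]
        table = {
            "OPT": mu,
            "CBL": mu - sl,
            "OBL": mu - 2 * sl,
            "CBR": mu + su,
            "OBR": mu + 2 * su,
        }
        return table[landmark]

    @classmethod
    def from_linear_drift(
        cls,
        species: str,
        years: Sequence[int],
        *,
        p_max: float = 0.5,
        mu0: float = 1500.0,
        mu_trend: float = 0.0,
        sigma_l0: float = 300.0,
        sigma_l_trend: float = 0.0,
        sigma_u0: float = 300.0,
        sigma_u_trend: float = 0.0,
        base_year: int | None = None,
        habitat: str = "forest",
        migration: str = "res",
    ) -> "SpeciesTruth":
        years = np.asarray(years, dtype=int)
        t = years - (base_year if base_year is not None else years.min())
        return cls(
            species=species,
            years=years,
            p_max=np.full(years.shape, p_max),
            mu=mu0 + mu_trend * t,
            sigma_l=np.maximum(sigma_l0 + sigma_l_trend * t, 1.0),
            sigma_u=np.maximum(sigma_u0 + sigma_u_trend * t, 1.0),
            habitat=habitat,
            migration=migration,
        )

    @classmethod
    def from_covariates(
        cls,
        species: str,
        years: Sequence[int],
        temperature: Mapping[int, float],
        habitat_cover: Mapping[int, float],
        *,
        p_max: float = 0.5,
        mu0: float = 1500.0,
        mu_per_degree: float = 0.0,
        mu_per_km2: float = 0.0,
        sigma_l0: float = 300.0,
        sigma_l_per_km2: float = 0.0,
        sigma_u0: float = 300.0,
        habitat: str = "forest",
        migration: str = "res",
    ) -> "SpeciesTruth":
        """Tie the curve parameters to temperature/habitat series.

        Anomalies are taken relative to the first year, so ``mu0`` is the
        optimum in the first year.
        """
        years = np.asarray(years, dtype=int)
        tn = np.array([temperature[y] for y in years], dtype=float)
        sf = np.array([habitat_cover[y] for y in years], dtype=float)
        d_tn, d_sf = tn - tn[0], sf - sf[0]
        return cls(
            species=species,
            years=years,
            p_max=np.full(years.shape, p_max),
            mu=mu0 + mu_per_degree * d_tn + mu_per_km2 * d_sf,
            sigma_l=np.maximum(sigma_l0 + sigma_l_per_km2 * d_sf, 1.0),
            sigma_u=np.full(years.shape, sigma_u0),
            habitat=habitat,
            migration=migration,
        )


# ---------------------------------------------------------------------------
# covariate truth (temperature cubes + habitat surveys)
# ---------------------------------------------------------------------------


@dataclass
class TemperatureCube:
    """Daily minimum temperatures for the May 1 - June 30 window.

    ``data[k, d, i, j]`` is the daily minimum (degC) for year ``years[k]``,
    window day ``d`` (0 = May 1), grid cell ``(i, j)`` on a raster sharing the
    geometry convention of :class:`ElevationGrid`.
    """

    years: tuple[int, ...]
    data: np.ndarray
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[0] != len(self.years):
            raise ValueError("data must be (years, days, rows, cols)")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    def year(self, year: int) -> np.ndarray:
        try:
            k = self.years.index(year)
        except ValueError as exc:
            raise KeyError(f"no temperatures for year {year}") from exc
        return self.data[k]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        meta = {
            "years": list(self.years),
            "cell_size": self.cell_size,
            "x0": self.x0,
            "y0": self.y0,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "TemperatureCube":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        meta["years"] = tuple(meta["years"])
        return cls(years=meta.pop("years"), data=np.load(path.with_suffix(".npy")), **meta)


@dataclass
class CovariateTruth:
    """Everything the covariate stages consume, with known ground truth."""

    coarse_daily: TemperatureCube
    coarse_climatology: ElevationGrid  # raster of degC, reusing the grid container
    fine_climatology: ElevationGrid
    habitat_surveys: pd.DataFrame
    anomalies: pd.Series  # true yearly anomaly (degC) added to the climatology
    trend_per_year: float


def habitat_survey_table(
    *,
    survey_years: Sequence[int] = (1980, 1999, 2007, 2009, 2012, 2015),
    bands: Sequence[tuple[float, float]] = ((600.0, 1200.0), (1200.0, 2700.0)),
    start_total: float = 4140.0,
    end_total: float = 4364.0,
    start_shares: Sequence[float] = (0.62, 0.38),
    gain_shares: Sequence[float] = (0.714, 0.286),
    period: tuple[int, int] = (1980, 2015),
) -> pd.DataFrame:
    """Sparse-year shrub+forest cover surveys per elevational band (km^2).

    Defaults follow the study system: six cartography years, total cover
    rising linearly from 4,140 km^2 (1980) to 4,364 km^2 (2015), i.e.
    +224 km^2, with most of the gain in the 600-1,200 m band.
    """
    if abs(sum(start_shares) - 1) > 1e-9 or abs(sum(gain_shares) - 1) > 1e-9:
        raise ValueError("band shares must each sum to 1")
    y0, y1 = period
    gain = end_total - start_total
    rows = []
    for year in survey_years:
        frac = (year - y0) / (y1 - y0)
        for (lo, hi), s0, sg in zip(bands, start_shares, gain_shares):
            rows.append(
                {
                    "year": int(year),
                    "band_lo": lo,
                    "band_hi": hi,
                    "sf_km2": start_total * s0 + gain * sg * frac,
                }
            )
    return pd.DataFrame(rows)


def generate_covariate_truth(
    years: Sequence[int],
    *,
    seed: int,
    fine_grid: ElevationGrid,
    coarse_factor: int = 10,
    trend_per_year: float = 0.046,
    base_temp: float = 4.7,
    base_year: int = 1982,
    lapse_rate: float = 0.0065,
    interannual_sd: float = 0.35,
    daily_sd: float = 1.5,
    habitat_kwargs: Mapping | None = None,
) -> CovariateTruth:
    """Simulate coarse daily minimum-temperature grids and habitat surveys.

    Daily temperature is climatology + yearly anomaly + daily white noise;
    the yearly anomaly carries the warming trend (``trend_per_year`` degC/yr,
    default 0.046 ~ 0.46 degC per decade).  The climatology follows a lapse
    rate off the fine elevation grid, so belt means differ by elevation while
    the trend is elevation-invariant.  Only May 1 - June 30 days are produced,
    the only window used downstream.
    """
    years = tuple(int(y) for y in years)
    if len(years) == 0:
        raise ValueError("years must be non-empty")
    if not np.isfinite(trend_per_year):
        raise ValueError("trend must be finite")
    ny, nx = fine_grid.shape
    if ny % coarse_factor or nx % coarse_factor:
        raise ValueError("fine grid shape must be divisible by coarse_factor")
    rng = np.random.default_rng(seed)

    mean_elev = float(fine_grid.elevation.mean())
    fine_clim_vals = base_temp + lapse_rate * (mean_elev - fine_grid.elevation)
    fine_clim = ElevationGrid(
        fine_clim_vals, cell_size=fine_grid.cell_size, x0=fine_grid.x0, y0=fine_grid.y0
    )
    # coarse climatology = block mean of the fine climatology
    cf = coarse_factor
    coarse_vals = fine_clim_vals.reshape(ny // cf, cf, nx // cf, cf).mean(axis=(1, 3))
    coarse_clim = ElevationGrid(
        coarse_vals, cell_size=fine_grid.cell_size * cf, x0=fine_grid.x0, y0=fine_grid.y0
    )

    anomalies = trend_per_year * (np.array(years) - base_year) + rng.normal(
        0.0, interannual_sd, size=len(years)
    )
    daily = rng.normal(0.0, daily_sd, size=(len(years), MAY_JUNE_DAYS))
    cube = coarse_vals[None, None, :, :] + anomalies[:, None, None, None] + daily[:, :, None, None]
    coarse_daily = TemperatureCube(
        years=years,
        data=cube,
        cell_size=coarse_clim.cell_size,
        x0=coarse_clim.x0,
        y0=coarse_clim.y0,
    )
    habitat = habitat_survey_table(**(habitat_kwargs or {}))
    return CovariateTruth(
        coarse_daily=coarse_daily,
        coarse_climatology=coarse_clim,
        fine_climatology=fine_clim,
        habitat_surveys=habitat,
        anomalies=pd.Series(anomalies, index=list(years), name="anomaly_C"),
        trend_per_year=trend_per_year,
    )


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------


def default_effort(
    years: Sequence[int] = DEFAULT_SURVEY_YEARS,
    seed: int = 0,
    low: int = 67,
    high: int = 782,
) -> dict[int, int]:
    """Yearly number of point counts, drawn uniformly over the observed range."""
    rng = np.random.default_rng(seed)
    return {int(y): int(n) for y, n in zip(years, rng.integers(low, high + 1, size=len(years)))}


def simulate_surveys(
    grid: ElevationGrid,
    truths: Sequence[SpeciesTruth],
    effort: Mapping[int, int],
    seed: int,
    *,
    stratified: bool = False,
    n_strata: int = 10,
) -> pd.DataFrame:
    """Simulate presence/absence point counts.

    Each year draws ``effort[year]`` point locations (shared by all species,
    as in a real point-count scheme); presence is an independent Bernoulli
    draw of the species' true curve at the point elevation.  ``stratified``
    balances the points across ``n_strata`` equal-width elevation bands
    instead of sampling uniformly over the map.

    Returns a tidy table: year, easting, northing, elevation, species,
    presence (0/1).
    """
    if not truths:
        raise ValueError("at least one species truth is required")
    for year, n in effort.items():
        if n < 1:
            raise ValueError(f"effort must be >= 1 (year {year})")
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = grid.extent
    frames = []
    for year in sorted(effort):
        n = int(effort[year])
        if stratified:
            edges = np.linspace(grid.elevation.min(), grid.elevation.max(), n_strata + 1)
            band = np.digitize(grid.elevation.ravel(), edges[1:-1])
            cells = []
            targets = rng.integers(0, n_strata, size=n)
            flat = np.arange(grid.elevation.size)
            by_band = [flat[band == b] for b in range(n_strata)]
            occupied = [b for b in range(n_strata) if by_band[b].size]
            for t in targets:
                b = t if by_band[t].size else occupied[t % len(occupied)]
                cells.append(rng.choice(by_band[b]))
            cells = np.asarray(cells)
            ny_, nx_ = grid.shape
            i, j = cells // nx_, cells % nx_
            x = grid.x0 + (j + rng.random(n)) * grid.cell_size
            y = grid.y0 + (i + rng.random(n)) * grid.cell_size
        else:
            x = rng.uniform(xmin, xmax, size=n)
            y = rng.uniform(ymin, ymax, size=n)
        # clamp onto the grid (uniform draws can hit the upper edge exactly)
        x = np.clip(x, xmin, np.nextafter(xmax, -np.inf))
        y = np.clip(y, ymin, np.nextafter(ymax, -np.inf))
        elev = grid.elevation_at(x, y)
        for truth in truths:
            try:
                p = truth.probability(elev, year)
            except KeyError:
                raise KeyError(
                    f"species {truth.species!r} has no truth for survey year {year}"
                ) from None
            frames.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "easting": x,
                        "northing": y,
                        "elevation": elev,
                        "species": truth.species,
                        "presence": rng.random(n) < p,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out["presence"] = out["presence"].astype(int)
    return out
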