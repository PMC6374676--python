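"""Log-linear association of pattern x habitat x migration x driver.

Species with a significant range change are crossed into a four-way
contingency table — pattern of range change (3 levels), breeding habitat
(open/edge/forest), migration habit (ldm/sdm/res) and driver class (tn, SF,
tn + SF, nd, dde; 5 levels) — giving 135 cells when every level set is
complete.  Sequential Poisson log-linear models are then fit, each row of the
deviance table reporting the deviance drop of one added term against a
chi-square reference.

The counting unit is configurable because a species has one pattern but may
carry several per-landmark driver calls: the default counts one record per
species x distinct final driver class; the alternative counts every
significant reference point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "PATTERN_LEVELS",
    "HABITAT_LEVELS",
    "MIGRATION_LEVELS",
    "DRIVER_LEVELS",
    "DEFAULT_TERMS",
    "ContingencyTable",
    "build_contingency",
    "loglinear_deviance_table",
    "saturated_residual_deviance",
]

PATTERN_LEVELS = ("lower boundary contraction", "upper boundary expansion", "upward shift")
HABITAT_LEVELS = ("open", "edge", "forest")
MIGRATION_LEVELS = ("ldm", "sdm", "res")
DRIVER_LEVELS = ("tn", "SF", "tn + SF", "nd", "dde")

_FACTORS = ("pattern", "habitat", "migration", "driver")
_LEVELS = {
    "pattern": PATTERN_LEVELS,
    "habitat": HABITAT_LEVELS,
    "migration": MIGRATION_LEVELS,
    "driver": DRIVER_LEVELS,
}

#: Four main effects then the three pattern interactions.
DEFAULT_TERMS = (
    "pattern",
    "habitat",
    "migration",
    "driver",
    "pattern:habitat",
    "pattern:migration",
    "pattern:driver",
)


@dataclass
class ContingencyTable:
    """Cell counts over the full cartesian of factor levels."""

    cells: pd.DataFrame  # columns: pattern, habitat, migration, driver, count
    mode: str

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total(self) -> int:
        return int(self.cells["count"].sum())


def build_contingency(records: pd.DataFrame, mode: str = "species_driver") -> ContingencyTable:
    """Cross-tabulate classified records into the 4-way table.

    ``records`` needs columns species, pattern, habitat, migration, driver.
    ``mode="species_driver"`` counts one record per species x distinct driver
    class; ``mode="reference_point"`` counts every row.
    """
    needed = {"species", *_FACTORS}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns {sorted(missing)}")
    for factor in _FACTORS:
        bad = set(records[factor]) - set(_LEVELS[factor])
        if bad:
            raise ValueError(f"unknown {factor} level(s): {sorted(bad)}")
    if mode == "species_driver":
        records = records.drop_duplicates(subset=["species", "driver"])
    elif mode != "reference_point":
        raise ValueError(f"unknown counting mode {mode!r}")
    counts = records.groupby(list(_FACTORS), observed=True).size()
    full = pd.MultiIndex.from_product([_LEVELS[f] for f in _FACTORS], names=_FACTORS)
    cells = counts.reindex(full, fill_value=0).rename("count").reset_index()
    return ContingencyTable(cells=cells, mode=mode)


def _formula(terms: tuple[str, ...]) -> str:
    rhs = ["1"]
    for term in terms:
        rhs.append(":".join(f"C({f})" for f in term.split(":")))
    return "count ~ " + " + ".join(rhs)


def loglinear_deviance_table(
    table: ContingencyTable, terms: tuple[str, ...] = DEFAULT_TERMS
) -> pd.DataFrame:
    """Sequential Poisson log-linear fits over a nested term sequence.

    Returns one row per model starting from the null (intercept-only): term
    added, its df, the deviance drop, residual df, residual deviance, and the
    chi-square p-value of the drop.
    """
    if len(set(terms)) != len(terms):
        raise ValueError("term sequence must not repeat terms (non-nested)")
    for term in terms:
        for f in term.split(":"):
            if f not in _FACTORS:
                raise ValueError(f"unknown factor {f!r} in term {term!r}")
    data = table.cells.copy()
    rows = []
    prev = None
    for k in range(len(terms) + 1):
        res = smf.glm(
            _formula(tuple(terms[:k])), data=data, family=sm.families.Poisson()
        ).fit()
        if k == 0:
            rows.append(
                {
                    "term": "Null",
                    "df": np.nan,
                    "deviance": np.nan,
                    "resid_df": int(res.df_resid),
                    "resid_deviance": float(res.deviance),
                    "p": np.nan,
                }
            )
        else:
            d_df = prev["resid_df"] - int(res.df_resid)
            drop = prev["resid_deviance"] - float(res.deviance)
            if d_df <= 0:
                raise ValueError(f"term {terms[k-1]!r} adds no df: sequence not nested")
            rows.append(
                {
                    "term": terms[k - 1],
                    "df": d_df,
                    "deviance": drop,
                    "resid_df": int(res.df_resid),
                    "resid_deviance": float(res.deviance),
                    "p": float(stats.chi2.sf(drop, d_df)),
                }
            )
        prev = rows[-1]
    return pd.DataFrame(rows)


def saturated_residual_deviance(table: ContingencyTable) -> float:
    """Residual deviance of the saturated model (0 up to numerical noise).

    Fit with one free parameter per non-zero cell; zero cells have their
    Poisson MLE on the boundary (fitted mean 0) and contribute exactly zero
    deviance, so they are excluded from the numerical fit.
    """
    o = table.cells["count"].to_numpy(float)
    o_nz = o[o > 0]
    if o_nz.size == 0:
        return 0.0
    res = sm.GLM(o_nz, np.eye(o_nz.size), family=sm.families.Poisson()).fit()
    return float(res.deviance)
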