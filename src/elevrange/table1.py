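"""Published landmark table: loading and rule-based re-classification.

The packaged fixture ``data/table1_landmarks.csv`` transcribes, one row per
species x reference point, the published trend statistics (slope on year and
its p-value), the driver regression coefficients, the four-fraction deviance
partition and the printed pattern/driver labels for 29 mountain-breeding bird
species (125 landmark records, 49 of them with a significant positive trend).
It gives the classification rules a download-free surface to run against: the
pattern and driver rules are re-applied to the printed numeric columns and
compared with the printed labels.

Printed p-values such as "<0.001" are parsed to their bound (all decisions
happen at alpha = 0.05, far above it).  The ``extremes_comparison`` column
carries the published slope-comparison outcome for the two species whose
extreme landmarks were both significant (standard errors are not printed, so
the z-test cannot be recomputed); the ``dw`` column flags rows with
significant residual autocorrelation at the Durbin-Watson test (diagnostic
only).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .driver_attribution import (
    DeviancePartition,
    DriverStats,
    classify_driver,
    finalize_driver_call,
)
from .trend_classification import SimpleTrend, SlopeComparison, classify_pattern

__all__ = [
    "load_table1",
    "significant_landmarks",
    "classify_table_patterns",
    "classify_table_drivers",
    "driver_records",
]

_NUMERIC = [
    "beta_y",
    "p_y",
    "beta_tn",
    "p_tn",
    "beta_sf",
    "p_sf",
    "r_adj",
    "partial_tn",
    "shared",
    "partial_sf",
    "unexplained",
]


def _parse_p(col: pd.Series) -> pd.Series:
    return pd.to_numeric(col.astype(str).str.lstrip("<"), errors="coerce")


def load_table1() -> pd.DataFrame:
    """Load the packaged landmark table (125 rows, 29 species)."""
    with resources.files("elevrange.data").joinpath("table1_landmarks.csv").open() as fh:
        df = pd.read_csv(fh)
    for col in _NUMERIC:
        df[col] = _parse_p(df[col])
    df["dw"] = df["dw"].astype(bool)
    expected = {"species", "habitat", "migration", "landmark", "pattern"}
    if not expected.issubset(df.columns):
        raise ValueError("landmark table fixture is malformed")
    return df


def significant_landmarks(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with a significant positive trend (p_y <= alpha, slope > 0)."""
    return df[(df["p_y"] <= alpha) & (df["beta_y"] > 0)]


def classify_table_patterns(df: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Re-apply the pattern rules per species to the printed trend columns."""
    out = {}
    for species, grp in df.groupby("species", sort=False):
        fits = {
            row.landmark: SimpleTrend(slope=row.beta_y, p=row.p_y)
            for row in grp.itertuples()
        }
        comp = None
        declared = grp["extremes_comparison"].dropna()
        if not declared.empty and declared.iloc[0] == "obl_steeper":
            comp = SlopeComparison(z=np.nan, p=np.nan, different=True, higher="a")
        out[species] = classify_pattern(fits, alpha=alpha, slope_comparison=comp).pattern
    return pd.Series(out, name="pattern")


def classify_table_drivers(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Re-apply the driver rules to every significant row's printed columns.

    Returns the significant rows with raw/final driver class, the dde flag
    and the resulting label alongside the printed one.
    """
    sig = significant_landmarks(df, alpha).copy()
    raws, finals, ddes, labels = [], [], [], []
    for row in sig.itertuples():
        partition = DeviancePartition(
            partial_tn=row.partial_tn,
            shared=row.shared,
            partial_sf=row.partial_sf,
            unexplained=row.unexplained,
        )
        raw = classify_driver(partition)
        stats_ = DriverStats(
            beta_tn=row.beta_tn, p_tn=row.p_tn, beta_sf=row.beta_sf, p_sf=row.p_sf
        )
        call = finalize_driver_call(raw, stats_, row.landmark, alpha=alpha)
        raws.append(call.raw)
        finals.append(call.final)
        ddes.append(call.dde)
        labels.append(call.label)
    sig["raw_class"] = raws
    sig["final_class"] = finals
    sig["dde_flag"] = ddes
    sig["computed_driver"] = labels
    return sig


def driver_records(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-landmark records (species, traits, pattern, driver level) for the
    contingency analysis, with pattern and driver re-derived by the rules."""
    calls = classify_table_drivers(df, alpha)
    patterns = classify_table_patterns(df, alpha)
    level = np.where(
        calls["dde_flag"],
        "dde",
        calls["final_class"].str.replace("tn+SF", "tn + SF", regex=False),
    )
    return pd.DataFrame(
        {
            "species": calls["species"].to_numpy(),
            "landmark": calls["landmark"].to_numpy(),
            "pattern": patterns.loc[calls["species"]].to_numpy(),
            "habitat": calls["habitat"].to_numpy(),
            "migration": calls["migration"].to_numpy(),
            "driver": level,
        }
    )
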