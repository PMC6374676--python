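#!/usr/bin/env python
"""Build per-landmark covariate series within elevational belts.

Each informative reference point defines a belt (the [min, max] of its
reliable elevations); within it the May-June daily-minimum temperature is
averaged per year from the downscaled grids, and shrub+forest cover is
interpolated from the sparse cartography years (year-smooth capped at 4 df)."""

from common import CONFIG, RUN_DIR, publish
from elevrange.pipeline import stage_covariates


def main() -> None:
    covs = stage_covariates(CONFIG, RUN_DIR)
    n_belts = covs.groupby(["species", "landmark"]).ngroups
    print(f"covariate series for {n_belts} informative reference points")
    summary = covs.groupby(["species", "landmark"]).agg(
        tn_min=("tn_C", "min"), tn_max=("tn_C", "max"),
        sf_min=("sf_km2", "min"), sf_max=("sf_km2", "max"),
    ).round(2)
    print(summary.to_string())
    publish(covs, "covariate_series.csv")


if __name__ == "__main__":
    main()
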