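#!/usr/bin/env python
"""Fit yearly presence curves and bootstrap their reference points.

Each species-year gets a binomial Gaussian-logit curve along elevation (with
a spatial surface held at its yearly average), the five landmarks (OPT,
CBL/CBR, OBL/OBR) are extracted, and each landmark's reliability is the
fraction of bootstrap refits in which it could be re-located."""

from common import CONFIG, RUN_DIR, publish
from elevrange.pipeline import stage_curves


def main() -> None:
    refs = stage_curves(CONFIG, RUN_DIR)
    ok = refs[refs["reliable"]]
    print(f"{len(ok)} reliable landmark values out of {len(refs)} "
          f"({CONFIG.n_boot} bootstrap replicates each)")
    per_lm = ok.groupby("landmark").size()
    print("reliable values per landmark:")
    print(per_lm.to_string())
    publish(refs, "reference_points.csv")


if __name__ == "__main__":
    main()
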