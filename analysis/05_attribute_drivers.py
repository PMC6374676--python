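#!/usr/bin/env python
"""Attribute each significant landmark trend to temperature and/or habitat.

Each significantly trending series is regressed on its belt's temperature
(tn) and shrub+forest cover (SF); the explained variation is split into net
tn, net SF, shared and unexplained fractions, and the threshold rules (plus
the nd override and the density-dependent-effect flag) yield the final
driver call."""

from common import CONFIG, RUN_DIR, publish
from elevrange.pipeline import stage_drivers


def main() -> None:
    drivers = stage_drivers(CONFIG, RUN_DIR)
    print(f"driver calls for {len(drivers)} significant reference points:")
    cols = ["species", "landmark", "beta_tn", "p_tn", "beta_SF", "p_SF",
            "partial_tn", "shared", "partial_SF", "unexplained", "driver"]
    print(drivers[cols].round(3).to_string(index=False))
    print("\ntallies:", dict(drivers["driver"].value_counts()))
    publish(drivers, "drivers.csv")


if __name__ == "__main__":
    main()
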