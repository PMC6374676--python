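#!/usr/bin/env python
"""Cross pattern x habitat x migration x driver and run the log-linear
analysis on the synthetic study's classified species."""

from common import CONFIG, RUN_DIR, publish
from elevrange.pipeline import stage_associate


def main() -> None:
    cells, dev = stage_associate(CONFIG, RUN_DIR)
    occupied = cells[cells["count"] > 0] if len(cells) else cells
    print(f"contingency: {len(cells)} cells, {len(occupied)} occupied")
    if len(occupied):
        print(occupied.to_string(index=False))
    if len(dev):
        print("\nsequential log-linear deviance table:")
        print(dev.round(3).to_string(index=False))
        publish(dev, "deviance_table.csv")
    publish(cells, "contingency.csv")


if __name__ == "__main__":
    main()
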