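#!/usr/bin/env python
"""Test each reference-point series for a temporal trend and classify the
per-species pattern of elevational range change.

A weighted linear regression of landmark elevation on year (yearly effort as
weight) is fit for every informative series; the pattern rules then combine
the significant landmarks into lower-boundary contraction, upper-boundary
expansion, upward shift, or none."""

from common import CONFIG, RUN_DIR, publish
from elevrange.pipeline import stage_trends


def main() -> None:
    trends, patterns = stage_trends(CONFIG, RUN_DIR)
    sig = trends[trends["p_y"] <= CONFIG.alpha]
    print(f"{len(sig)} of {len(trends)} informative series trend "
          f"significantly (alpha = {CONFIG.alpha})")
    print(trends.round(4).to_string(index=False))
    print("\npattern calls:")
    print(patterns.to_string(index=False))
    publish(trends, "trends.csv")
    publish(patterns, "patterns.csv")


if __name__ == "__main__":
    main()
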