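"""Shared paths and configuration for the analysis scripts.

The synthetic study runs in ``scratch/analysis_run`` (rasters and large
intermediates live there); small summary tables are copied to ``results/``.
"""

from pathlib import Path

from elevrange.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"

#: One seeded world shared by scripts 01-06: three archetypal species
#: surveyed over the 28 study years with realistic effort variation.
CONFIG = PipelineConfig(seed=42, n_species=3, n_boot=100)


def publish(df, name: str) -> Path:
    """Write a small summary table under results/."""
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, index=False)
    return path
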