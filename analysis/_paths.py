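"""Shared locations and the study configuration for the numbered analyses.

Per-trial intermediates (trial tables, segmentations, kept trials) are large
and go under scratch/analysis/; participant-level summaries and the stats
report go under results/.
"""

from pathlib import Path

from selftouch.config import PipelineConfig

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parent.parent / "results"

DEFAULT_SEED = 2026


def study_config(seed: int = DEFAULT_SEED) -> PipelineConfig:
    return PipelineConfig(n_participants=28, seed=seed)
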