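"""Shared run configuration for the numbered analysis drivers.

All drivers operate on one pipeline run directory under scratch/ (large,
regenerable) and write their small summary tables under results/. Each
driver resumes the shared run, so they can be executed in order or
individually.
"""

from pathlib import Path

from pedmeth import SimulationConfig
from pedmeth.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"
SEED = 0


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(
        out_dir=str(RUN_DIR),
        seed=SEED,
        simulate=SimulationConfig(seed=SEED),
    )


def ensure_stage(stage: str):
    """Run the shared pipeline up to `stage`, reusing existing outputs."""
    RESULTS.mkdir(exist_ok=True)
    run_pipeline(pipeline_config(), resume=True, until=stage)
    return RUN_DIR
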