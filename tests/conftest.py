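import pytest

from exomir.config import PipelineConfig
from exomir.pipeline import run_pipeline
from exomir.simulate import load_toy_ncrna, simulate_dataset


@pytest.fixture(scope="session")
def small_run():
    """A seeded small simulation plus a full pipeline run over it.

    Shared across unit tests so the (relatively) expensive discovery
    stage runs once per session.
    """
    cfg = PipelineConfig(rng_seed=7)
    genome, truth, reads, provenance = simulate_dataset(
        n_precursors=10, total_reads=8_000, rng_seed=7, config=cfg
    )
    result = run_pipeline(genome, reads, load_toy_ncrna(), config=cfg)
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "reads": reads,
        "provenance": provenance,
        "result": result,
    }
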