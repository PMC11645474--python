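import numpy as np
import pytest

from rarecascade import PipelineConfig, SimConfig, run_pipeline
from rarecascade.config import PlantedEffect, PlantedGene


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full cascade run on the default demo cohort, shared across tests."""
    out = tmp_path_factory.mktemp("demo_run")
    report = run_pipeline(PipelineConfig(), str(out))
    return report, out


@pytest.fixture()
def small_config():
    return SimConfig(
        n_cases=30,
        n_controls=30,
        n_genes=10,
        variants_per_gene=2,
        planted_burden_genes=[PlantedGene("CABP1", 0.4, 0.0)],
        planted_phenotype_effects=[PlantedEffect("CABP1", "LDL_C", 30.0)],
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
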