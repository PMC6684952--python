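import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oncohub as oh

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> oh.PipelineConfig:
    return oh.PipelineConfig()


@pytest.fixture(scope="session")
def default_study(default_config) -> oh.SyntheticStudy:
    """The default synthetic study (2,000 genes, 8 modules, 300 samples, seed 1)."""
    return oh.simulate_all(default_config.sim)


@pytest.fixture(scope="session")
def pipeline_result(default_config, default_study) -> oh.PipelineResult:
    """One full pipeline run on the default study, shared across tests."""
    return oh.run_all(default_config, study=default_study)


@pytest.fixture(scope="session")
def small_config() -> oh.PipelineConfig:
    """Reduced study for fast pipeline-level tests."""
    sim = oh.SimConfig(
        seed=7,
        n_genes=400,
        n_modules=3,
        module_sizes=(40, 40, 40),
        trait_effect=(0.6, 0.0, 0.4),
        samples_per_phenotype={p: 20 for p in oh.SimConfig().phenotypes},
        n_datasets=3,
        extra_regulated_count=30,
        control_artifact_count=10,
        n_strains=60,
        n_interactors=10,
        n_essential=2,
        n_decoy_edges=50,
        n_hub_genes=3,
        n_patients=100,
    )
    return oh.PipelineConfig(sim=sim)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
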