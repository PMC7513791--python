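import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import methylstab as ms

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study_config() -> ms.StudyConfig:
    """The default synthetic study conditions at a fixed seed."""
    return ms.StudyConfig().with_seed(STUDY_SEED)


@pytest.fixture(scope="session")
def study_report(study_config) -> ms.StudyReport:
    """One full end-to-end run, shared by the slower integration checks."""
    return ms.run_study(study_config)


@pytest.fixture(scope="session")
def small_sim() -> tuple[ms.SimulationConfig, dict, "object"]:
    """A small genome with planted structure for unit-level checks."""
    cfg = ms.SimulationConfig(
        seed=5,
        n_contigs=4,
        contig_length=30_000,
        n_planted={
            "habitat_divergent_stable": 3,
            "habitat_divergent_responsive": 2,
            "site_specific": 1,
        },
    )
    contigs, windows = ms.generate_reference(cfg)
    return cfg, contigs, windows


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
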