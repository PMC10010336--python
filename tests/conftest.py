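import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coexmod.datatypes import AbundanceMatrix
from coexmod.simulate import SimulationConfig, SurvivalConfig, generate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_dataset():
    """Five planted modules, three groups, batch effects, linked survival."""
    cfg = SimulationConfig(
        n_proteins=600,
        n_samples=60,
        module_sizes=[150, 120, 100, 80, 60],
        kme_target=0.85,
        survival=SurvivalConfig(linked_module=2, log_hazard_per_unit=1.2,
                                baseline_scale=24.0, censor_rate=0.2),
        seed=7,
    )
    matrix, clinical, truth = generate_dataset(cfg)
    return cfg, matrix, clinical, truth


@pytest.fixture()
def small_matrix():
    """Deterministic 10x8 matrix, two batches."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(size=(10, 8)),
        index=[f"P{i}" for i in range(10)],
        columns=[f"S{j}" for j in range(8)],
    )
    batch = pd.Series(["B1"] * 4 + ["B2"] * 4, index=values.columns)
    return AbundanceMatrix(values, batch)
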