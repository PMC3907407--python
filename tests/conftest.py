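import numpy as np
import pandas as pd
import pytest

from ffpesig import ExpressionMatrix, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Paired FC/AS cohort at the shipped default configuration."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort for fast functional tests."""
    cfg = SimulationConfig(
        n_genes=1200,
        n_controls=60,
        n_samples=40,
        markers_per_class=20,
        effect_size=3.0,
        seed=5,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    """50 genes + 25 controls x 5 samples of positive raw signal."""
    rng = np.random.default_rng(17)
    genes = [f"G{i:02d}" for i in range(50)] + [f"NEG_{i:02d}" for i in range(25)]
    vals = pd.DataFrame(
        rng.lognormal(5.0, 1.0, (75, 5)),
        index=genes,
        columns=[f"s{j}" for j in range(5)],
    )
    return ExpressionMatrix(values=vals)
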