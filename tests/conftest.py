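import numpy as np
import pandas as pd
import pytest

from m6asig.cohort_io import REGULATOR_GENES, ExpressionMatrix
from m6asig.synthetic import SimulationParams, generate_cohort


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """Seven regulators + two extra genes over six samples, all positive."""
    rng = np.random.default_rng(42)
    genes = list(REGULATOR_GENES) + ["GENE1", "GENE2"]
    samples = [f"S{i}" for i in range(6)]
    vals = pd.DataFrame(rng.uniform(1, 10, (len(genes), len(samples))),
                        index=genes, columns=samples)
    return ExpressionMatrix(vals)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default study design (n = 600)."""
    return generate_cohort(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for pipeline-level tests."""
    return generate_cohort(SimulationParams(
        seed=11, n_samples=150, n_background_genes=60, n_enriched_genes=20))
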