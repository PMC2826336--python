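import numpy as np
import pandas as pd
import pytest

from chillregnet.expression_calls import TimeCourseMatrix
from chillregnet.synthetic_data import SimulationConfig, generate_study

CHILL_HOURS = (0.5, 2, 4, 6, 12, 18, 24, 36, 48, 96)


def make_matrix(profiles: dict, pvalues: dict | float = 0.01, hours=CHILL_HOURS):
    """Build a TimeCourseMatrix from gene -> ratio-vector mappings."""
    ratios = pd.DataFrame.from_dict(profiles, orient="index", columns=hours)
    if isinstance(pvalues, dict):
        pvals = pd.DataFrame.from_dict(pvalues, orient="index", columns=hours)
    else:
        pvals = pd.DataFrame(pvalues, index=ratios.index, columns=hours)
    return TimeCourseMatrix(hours, ratios, pvals)


def random_matrix(rng: np.random.Generator, n_genes=1000, hours=CHILL_HOURS):
    """Random profiles spanning both thresholds, for oracle comparisons."""
    ratios = rng.uniform(-3.0, 3.0, size=(n_genes, len(hours)))
    pvals = rng.uniform(0.0, 1.0, size=(n_genes, len(hours)))
    idx = [f"g{i:04d}" for i in range(n_genes)]
    return TimeCourseMatrix(
        hours,
        pd.DataFrame(ratios, index=idx, columns=hours),
        pd.DataFrame(pvals, index=idx, columns=hours),
    )


SMALL_CONFIG = SimulationConfig(
    n_genes=600,
    n_clusters=6,
    cluster_phase_counts=(4, 1, 1),
    per_cluster_h2o2_fraction=(0.39, 0.16, 0.6, 0.7, 0.3, 0.2),
    seed=42,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced study bundle shared across integration tests."""
    return generate_study(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_config():
    return SMALL_CONFIG
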