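import numpy as np
import pandas as pd
import pytest

from sclc_subtyper import MethylationMatrix
from sclc_subtyper.synthetic_cohort import CohortSpec, simulate_tissue


@pytest.fixture(scope="session")
def small_cohort():
    """Light synthetic cohort for unit tests (10 samples/subtype)."""
    spec = CohortSpec(
        n_per_subtype=10,
        n_sites_null=300,
        n_sites_differential_per_subtype=12,
        n_genes_null=60,
        n_marker_genes_per_subtype=8,
        missing_frac=0.05,
        rng_seed=123,
    )
    return simulate_tissue(spec)


@pytest.fixture()
def random_matrix():
    """Seeded random methylation matrix with missing values."""
    rng = np.random.default_rng(99)
    beta = rng.uniform(0, 100, size=(40, 12))
    beta[rng.random(beta.shape) < 0.15] = np.nan
    sites = [f"chr{1 + i % 3}:{100 + 10 * i}" for i in range(40)]
    samples = [f"S{j:02d}" for j in range(12)]
    return MethylationMatrix(pd.DataFrame(beta, index=sites, columns=samples))
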