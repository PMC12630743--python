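import numpy as np
import pytest

from snpmon.genotype_io import GenotypeTable
from snpmon.synthetic_data import SimConfig, simulate_reference_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_dataset():
    """Clean five-population reference genotypes at default divergence."""
    cfg = SimConfig(seed=42)
    table, markers, pop_of, sex_of, freqs = simulate_reference_dataset(cfg)
    return {
        "table": table,
        "markers": markers,
        "pop_of": pop_of,
        "sex_of": sex_of,
        "freqs": freqs,
        "config": cfg,
    }


def table_from_rows(sample_ids, marker_ids, rows):
    """Build a GenotypeTable from nested lists of canonical call strings."""
    return GenotypeTable(sample_ids, marker_ids, np.array(rows, dtype=object))
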