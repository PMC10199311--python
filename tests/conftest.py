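import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sgabund as sg

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_catalog() -> sg.SimulatedCatalog:
    """3 entities x 300 genes x 20 samples with planted strain-specific
    genes; small enough for per-test refinement runs."""
    config = sg.SimConfig(
        n_entities=3,
        genes_per_entity=300,
        n_samples=20,
        reads_per_sample=(10_000, 30_000),
        seed=7,
    )
    return sg.simulate_catalog(config)


@pytest.fixture(scope="session")
def null_catalog() -> sg.SimulatedCatalog:
    """No planted pathologies and mild overdispersion: a catalog where the
    initial signature sets are already close to ideal."""
    config = sg.SimConfig(
        n_entities=2,
        genes_per_entity=300,
        n_samples=20,
        strain_fraction=0.0,
        bias_fraction=0.0,
        dispersion_range=(50.0, 100.0),
        reads_per_sample=(10_000, 30_000),
        seed=11,
    )
    return sg.simulate_catalog(config)


@pytest.fixture(scope="session")
def small_model(small_catalog) -> sg.SignatureGeneModel:
    return sg.SignatureGeneModel(
        small_catalog.raw_counts, small_catalog.gene_entities, small_catalog.gene_lengths
    )


@pytest.fixture(scope="session")
def small_fit(small_model) -> sg.SignatureGeneResults:
    return small_model.fit()


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    """Hand-sized normalized count matrix: 5 genes x 4 samples."""
    return pd.DataFrame(
        {
            "s1": [10, 9, 11, 0, 10],
            "s2": [20, 22, 18, 0, 20],
            "s3": [5, 4, 6, 0, 5],
            "s4": [40, 39, 41, 0, 40],
        },
        index=pd.Index([f"g{i}" for i in range(1, 6)], name="gene_id"),
    )
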