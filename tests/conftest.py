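import numpy as np
import pytest

import asvnet as av


@pytest.fixture(scope="session")
def default_run():
    """One full default-design pipeline run shared across tests."""
    design = av.default_design(seed=0)
    counts, taxonomy = av.simulate_counts(design)
    metadata = av.simulate_env_and_traits(design)
    retained = av.filter_taxa(counts)
    edges = av.spearman_edges(retained)
    net = av.build_network(edges, taxonomy)
    return {
        "design": design,
        "counts": counts,
        "taxonomy": taxonomy,
        "metadata": metadata,
        "retained": retained,
        "edges": edges,
        "net": net,
    }


@pytest.fixture
def small_design():
    """A fast, scaled-down study: 72 retained taxa in 4 modules."""
    return av.default_design(
        n_modules=4,
        seed=7,
        n_bacteria=60,
        n_fungi=12,
        n_background=200,
        sequencing_depth=20_000,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
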