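import networkx as nx
import numpy as np
import pytest

from melanet.synthetic_data import (
    ExpressionSimSpec,
    plant_articulation_structure,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_expression():
    """60-gene, 20+15-sample matrix with 5 strongly shifted informative genes."""
    return simulate_expression(
        ExpressionSimSpec(
            n_genes=60, n_informative=5, n_control=20, n_case=15,
            effect_size=3.0, noise_sd=1.0, seed=42,
        )
    )


@pytest.fixture(scope="session")
def separable_expression():
    """Noiseless, large-effect matrix: classes perfectly separable."""
    return simulate_expression(
        ExpressionSimSpec(
            n_genes=30, n_informative=5, n_control=20, n_case=15,
            effect_size=4.0, noise_sd=0.0, seed=3,
        )
    )


@pytest.fixture(scope="session")
def clique_chain():
    """Chain of four K5 cliques: three junction articulation points."""
    return plant_articulation_structure([5, 5, 5, 5], topology="chain")


@pytest.fixture(scope="session")
def random_graph_suite():
    """Small random graphs of varied density for oracle cross-checks."""
    rng = np.random.default_rng(2024)
    graphs = []
    for i in range(40):
        n = int(rng.integers(4, 31))
        p = float(rng.uniform(0.05, 0.5))
        graphs.append(nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31))))
    return graphs
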