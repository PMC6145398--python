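import numpy as np
import pandas as pd
import pytest

import maxmif as mx


@pytest.fixture
def toy_matrix() -> mx.MutationMatrix:
    # s1 mutates gA,gB (N=2); s2 mutates gA (N=1); s3 mutates gA,gB,gC,gD (N=4)
    data = pd.DataFrame(
        {
            "s1": [1, 1, 0, 0],
            "s2": [1, 0, 0, 0],
            "s3": [1, 1, 1, 1],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    return mx.MutationMatrix(data)


@pytest.fixture
def toy_network() -> mx.WeightedNetwork:
    return mx.build_network(
        [("gA", "gB", 2.0), ("gB", "gC", 4.0), ("gC", "gD", 1.0), ("gD", "gE", 0.5)]
    )


def random_instance(
    rng: np.random.Generator, n_genes: int = 30, n_samples: int = 12, p_edge: float = 0.15
):
    """Small random matrix + network sharing a gene namespace, for oracle tests."""
    genes = [f"g{i:02d}" for i in range(n_genes)]
    while True:
        mat = (rng.random((n_genes, n_samples)) < 0.2).astype(int)
        if mat.any():
            break
    samples = [f"s{j:02d}" for j in range(n_samples)]
    m = mx.MutationMatrix(pd.DataFrame(mat, index=genes, columns=samples))
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p_edge:
                edges.append((genes[i], genes[j], float(rng.uniform(0.05, 5.0))))
    if not edges:
        edges.append((genes[0], genes[1], 1.0))
    return m, mx.build_network(edges)


@pytest.fixture(scope="session")
def bench():
    """One planted-driver benchmark instance, shared across evaluation tests."""
    spec = mx.SyntheticSpec(seed=11)
    return spec, mx.gen_mutation_matrix(spec), mx.gen_network(spec), mx.gen_reference_set(spec)
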