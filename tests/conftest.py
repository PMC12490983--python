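from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hyperad import GeneSet, Hypergraph, build_hypergraph

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_gene_sets(
    rng: np.random.Generator,
    n_genes: int,
    n_sets: int,
    size_range: tuple[int, int] = (2, 6),
) -> list[GeneSet]:
    """Random gene sets over a pool of ``n_genes`` symbols."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    sets = []
    for b in range(n_sets):
        size = int(rng.integers(size_range[0], min(size_range[1], n_genes) + 1))
        members = tuple(rng.choice(genes, size=size, replace=False))
        sets.append(GeneSet(f"s{b:03d}", "random", members))
    return sets


def random_hypergraph(rng: np.random.Generator, n_genes: int = 20, n_sets: int = 10) -> Hypergraph:
    return build_hypergraph(random_gene_sets(rng, n_genes, n_sets), min_size=2)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_hypergraph() -> Hypergraph:
    """Tiny fixed hypergraph: 5 genes, 3 sets (deterministic)."""
    sets = [
        GeneSet("SET1", "d", ("a", "b", "c")),
        GeneSet("SET2", "d", ("b", "c", "d")),
        GeneSet("SET3", "d", ("d", "e")),
    ]
    return build_hypergraph(sets)
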