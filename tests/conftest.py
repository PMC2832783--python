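import numpy as np
import pytest
from hypothesis import settings

from pogf import (
    GeneList,
    ModularNetworkSpec,
    PPINetwork,
    generate_network,
)

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def path_net() -> PPINetwork:
    """A--B--C path: A and C share neighbour B."""
    return PPINetwork([("A", "B"), ("B", "C")])


@pytest.fixture
def two_components_net() -> PPINetwork:
    return PPINetwork([("A", "B"), ("C", "D")])


@pytest.fixture
def star_net() -> PPINetwork:
    """Hub H with four leaves; every leaf pair shares H."""
    return PPINetwork([("H", f"L{i}") for i in range(1, 5)])


def random_network(
    rng: np.random.Generator, n_nodes: int = 20, p: float = 0.15
) -> PPINetwork:
    """Erdos-Renyi network over symbols N00..; may contain isolated nodes."""
    symbols = [f"N{i:02d}" for i in range(n_nodes)]
    iu, ju = np.triu_indices(n_nodes, k=1)
    keep = rng.random(len(iu)) < p
    edges = [(symbols[a], symbols[b]) for a, b in zip(iu[keep], ju[keep])]
    return PPINetwork(edges, nodes=symbols)


def random_gene_list(
    rng: np.random.Generator, net: PPINetwork, size: int, name: str = "L"
) -> GeneList:
    picks = rng.choice(net.node_list, size=size, replace=False)
    return GeneList(name, tuple(picks))


@pytest.fixture(scope="session")
def default_synthetic():
    """Default planted-module network (seed 1) shared across tests."""
    spec = ModularNetworkSpec(seed=1)
    net, module_map = generate_network(spec)
    return spec, net, module_map


def module_gene_list(module_map: dict, module: int, name: str | None = None) -> GeneList:
    genes = tuple(sorted(g for g, m in module_map.items() if m == module))
    return GeneList(name or f"module{module}", genes)
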