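"""Synthetic planted-module networks and gene-list samplers.

A planted-partition (stochastic-block-style) graph stands in for a real
PPI network: dense modules emulate the few key pathways that different
gene-discovery efforts sample from, over a sparse background.  Gene lists
drawn from shared or disjoint modules reproduce, on demand, the regime of
interest — near-zero gene overlap with high functional consistency — and
its negative control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .io import GeneList
from .network import PPINetwork

logger = logging.getLogger(__name__)

__all__ = ["ModularNetworkSpec", "generate_network", "sample_lists"]


@dataclass(frozen=True)
class ModularNetworkSpec:
    """Parameters of the planted-module network generator.

    Defaults give a 1000-gene network with 10 modules of 40 genes each
    (the remaining 600 genes are unstructured background), within-module
    edge probability 0.3 and background edge probability 0.005.
    """

    n_genes: int = 1000
    n_modules: int = 10
    module_size: int = 40
    p_in: float = 0.3
    p_out: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ParameterError(
                "modules do not fit: n_modules * module_size > n_genes"
            )
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ParameterError("require 0 <= p_out < p_in <= 1")
        if self.n_genes < 2:
            raise ParameterError("need at least two genes")


def _symbols(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def generate_network(
    spec: ModularNetworkSpec,
) -> tuple[PPINetwork, dict[str, int]]:
    """Generate a planted-module PPI network.

    Edges are independent Bernoulli draws: probability ``p_in`` between
    genes of the same module, ``p_out`` otherwise.  Returns the network
    and the module map (symbol -> module index, module genes only);
    genes outside every module are background.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    symbols = _symbols(n)
    module_of = np.full(n, -1, dtype=np.int64)
    for m in range(spec.n_modules):
        module_of[m * spec.module_size : (m + 1) * spec.module_size] = m
    iu, ju = np.triu_indices(n, k=1)
    same = (module_of[iu] == module_of[ju]) & (module_of[iu] >= 0)
    prob = np.where(same, spec.p_in, spec.p_out)
    keep = rng.random(len(prob)) < prob
    edges = [(symbols[a], symbols[b]) for a, b in zip(iu[keep], ju[keep])]
    net = PPINetwork(edges, nodes=symbols)
    module_map = {
        symbols[i]: int(module_of[i]) for i in range(n) if module_of[i] >= 0
    }
    logger.info(
        "synthetic network: %d genes, %d edges, %d modules of %d",
        n, net.n_edges, spec.n_modules, spec.module_size,
    )
    return net, module_map


def sample_lists(
    module_map: dict[str, int],
    modules_a: set[int],
    modules_b: set[int],
    size: int,
    overlap: int,
    seed: int | None = None,
    names: tuple[str, str] = ("listA", "listB"),
) -> tuple[GeneList, GeneList]:
    """Draw two gene lists of *size* genes from chosen module sets.

    The lists share exactly *overlap* genes (drawn from modules common to
    both sets) and are otherwise disjoint.

    Raises
    ------
    ParameterError
        When the requested sizes/overlap are infeasible for the chosen
        modules.
    """
    if not 0 <= overlap <= size:
        raise ParameterError("overlap must satisfy 0 <= overlap <= size")
    rng = np.random.default_rng(seed)
    pool_a = sorted(g for g, m in module_map.items() if m in modules_a)
    pool_b = sorted(g for g, m in module_map.items() if m in modules_b)
    common = sorted(set(pool_a) & set(pool_b))
    if overlap > len(common):
        raise ParameterError(
            f"overlap {overlap} exceeds the {len(common)} genes shared by "
            "the chosen module sets"
        )
    shared = list(rng.choice(common, size=overlap, replace=False)) if overlap else []
    rest_a_pool = [g for g in pool_a if g not in shared]
    if size - overlap > len(rest_a_pool):
        raise ParameterError(
            f"cannot draw {size - overlap} unshared genes for {names[0]} "
            f"from a pool of {len(rest_a_pool)}"
        )
    rest_a = list(rng.choice(rest_a_pool, size=size - overlap, replace=False))
    taken = set(shared) | set(rest_a)
    rest_b_pool = [g for g in pool_b if g not in taken]
    if size - overlap > len(rest_b_pool):
        raise ParameterError(
            f"cannot draw {size - overlap} unshared genes for {names[1]} "
            f"from a pool of {len(rest_b_pool)} (after excluding {names[0]})"
        )
    rest_b = list(rng.choice(rest_b_pool, size=size - overlap, replace=False))
    list_a = GeneList(names[0], tuple(shared + rest_a))
    list_b = GeneList(names[1], tuple(shared + rest_b))
    return list_a, list_b
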