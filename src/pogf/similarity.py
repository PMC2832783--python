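"""Hypergeometric PPI-link enrichment and functional similarity of a gene to a list.

A gene with ``n`` PPI-link partners among the ``N`` other network genes is
functionally similar to a list of ``M`` network genes when its observed
number ``k`` of links into the list is improbably large under random
draws: ``p = P(X >= k)``, ``X ~ Hypergeometric(N, M, n)``, with strict
``p < alpha`` (default 0.05).  Selection against a benchmark list applies
Benjamini–Hochberg FDR control to these per-gene p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .exceptions import ParameterError
from .io import GeneList
from .network import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "LinkTest",
    "link_enrichment_pvalue",
    "functionally_similar",
    "link_test_table",
    "select_by_benchmark",
    "prioritize",
    "significance_k_threshold",
]


@dataclass(frozen=True)
class LinkTest:
    """One per-gene link-enrichment test record.

    k: links into the list; n: PPI-link degree of the gene; M: list genes
    on the network (query gene excluded); N: possible partners; p: upper
    tail hypergeometric probability; q: BH-adjusted value when computed.
    """

    gene: str
    k: int
    n: int
    M: int
    N: int
    p: float
    q: float | None = None


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha!r}")


def _upper_tail(k, N, M, n):
    """P(X >= k) for X ~ Hypergeometric(population N, successes M, draws n)."""
    return np.clip(stats.hypergeom.sf(np.asarray(k) - 1, N, M, n), 0.0, 1.0)


def link_enrichment_pvalue(
    net: PPINetwork, gene: str, gene_list: GeneList
) -> LinkTest:
    """Test whether *gene* has more PPI links into *gene_list* than chance.

    The query gene is excluded from the list (so membership never inflates
    ``k``).  ``M = 0`` — a list disjoint from the network — yields ``p = 1``
    rather than an error, so batch runs survive degenerate lists.
    """
    k, M = net.count_links_to_list(gene, gene_list)
    n = int(net.link_degree[net.index_of(gene)])
    N = net.n_nodes - 1
    if M == 0:
        logger.debug("gene %s: list has no network members, p = 1", gene)
        return LinkTest(gene=gene, k=0, n=n, M=0, N=N, p=1.0)
    p = float(_upper_tail(k, N, M, n))
    assert k <= min(n, M), "impossible link count"
    return LinkTest(gene=gene, k=k, n=n, M=M, N=N, p=p)


def functionally_similar(
    net: PPINetwork, gene: str, gene_list: GeneList, alpha: float = 0.05
) -> bool:
    """True iff the gene's link enrichment into the list has ``p < alpha``."""
    _check_alpha(alpha)
    return link_enrichment_pvalue(net, gene, gene_list).p < alpha


def link_test_table(
    net: PPINetwork, genes: GeneList, target: GeneList
) -> list[LinkTest]:
    """Vectorized link-enrichment tests of each query gene against a target list.

    Query genes absent from the network get ``k = n = 0`` and ``p = 1``
    (logged); a query gene that belongs to the target list is excluded
    from its own ``M``.
    """
    target_on_net = [g for g in target if g in net]
    target_idx = net.indices_of(target_on_net)
    target_set = set(target_on_net)
    N = net.n_nodes - 1

    on_net = [g for g in genes if g in net]
    off_net = [g for g in genes if g not in net]
    if off_net:
        logger.info(
            "%d of %d query genes absent from the network (p = 1)",
            len(off_net), len(genes),
        )
    tests: dict[str, LinkTest] = {
        g: LinkTest(gene=g, k=0, n=0, M=len(target_set), N=N, p=1.0)
        for g in off_net
    }
    if on_net:
        q_idx = net.indices_of(on_net)
        k = net.links_into(q_idx, target_idx)
        n = net.link_degree[q_idx]
        in_target = np.array([g in target_set for g in on_net])
        # the link matrix has an empty diagonal, so k never counts a
        # self-link; members of the target list only need M reduced by one
        M = np.where(in_target, len(target_set) - 1, len(target_set))
        p = np.where(M > 0, _upper_tail(k, N, M, n), 1.0)
        for g, ki, ni, Mi, pi in zip(on_net, k, n, M, p):
            tests[g] = LinkTest(
                gene=g, k=int(ki), n=int(ni), M=int(Mi), N=N, p=float(pi)
            )
    return [tests[g] for g in genes]


def select_by_benchmark(
    net: PPINetwork,
    candidates: GeneList,
    benchmark: GeneList,
    fdr_level: float = 0.05,
) -> tuple[GeneList, GeneList, list[LinkTest]]:
    """FDR-controlled selection of candidates functionally linked to a benchmark.

    Each candidate is tested for link enrichment against the benchmark
    list; Benjamini–Hochberg adjusted values ``q`` are attached and the
    candidates split into (selected: ``q <= fdr_level``, remaining).

    Returns ``(selected, remaining, tests)``.
    """
    _check_alpha(fdr_level)
    if len(candidates) == 0:
        return (
            GeneList(f"{candidates.name}:selected", ()),
            GeneList(f"{candidates.name}:remaining", ()),
            [],
        )
    if not (benchmark.gene_set & net.nodes):
        raise ParameterError(
            f"benchmark list {benchmark.name!r} has no genes on the network"
        )
    tests = link_test_table(net, candidates, benchmark)
    pvals = np.array([t.p for t in tests])
    qvals = stats.false_discovery_control(pvals, method="bh")
    tests = [replace(t, q=float(q)) for t, q in zip(tests, qvals)]
    keep = qvals <= fdr_level
    selected = GeneList(
        f"{candidates.name}:selected",
        tuple(g for g, s in zip(candidates.genes, keep) if s),
    )
    remaining = GeneList(
        f"{candidates.name}:remaining",
        tuple(g for g, s in zip(candidates.genes, keep) if not s),
    )
    logger.info(
        "selected %d / %d candidates at FDR %g against %s",
        len(selected), len(candidates), fdr_level, benchmark.name,
    )
    return selected, remaining, tests


def prioritize(
    net: PPINetwork, candidates: GeneList, benchmark: GeneList
) -> list[LinkTest]:
    """Rank candidates by functional similarity to a benchmark list.

    Ascending p, ties broken by descending ``k`` then symbol.
    """
    tests = link_test_table(net, candidates, benchmark)
    return sorted(tests, key=lambda t: (t.p, -t.k, t.gene))


def significance_k_threshold(
    N: int, M: int, n_max: int, alpha: float = 0.05
) -> np.ndarray:
    """Minimal significant link count per link-degree.

    Returns an array ``kmin`` of length ``n_max + 1`` where ``kmin[n]`` is
    the smallest ``k`` with ``P(X >= k) < alpha`` for
    ``X ~ Hypergeometric(N, M, n)`` — or ``M + 1`` (unreachable) when no
    ``k <= min(n, M)`` is significant.  Lets permutation loops replace
    per-gene tail evaluations by an integer comparison.
    """
    _check_alpha(alpha)
    kmin = np.full(n_max + 1, M + 1, dtype=np.int64)
    if M == 0:
        return kmin
    ns = np.arange(n_max + 1)
    ks = np.arange(1, M + 2)
    # tail[j, i] = P(X >= ks[i]) at degree ns[j]
    tail = stats.hypergeom.sf(ks[None, :] - 1, N, M, ns[:, None])
    sig = tail < alpha
    has = sig.any(axis=1)
    first = np.argmax(sig, axis=1)
    kmin[has] = ks[first[has]]
    # a gene cannot have more links into the list than min(n, M)
    kmin = np.where(kmin > np.minimum(ns, M), M + 1, kmin)
    return kmin
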