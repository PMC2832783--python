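"""Overlap (POG) and functional (POGF) consistency scores between gene lists.

For lists of lengths ``l1`` and ``l2`` sharing ``m`` genes, the directional
overlap scores are ``POG12 = m / l1`` and ``POG21 = m / l2``.  The
functional scores extend the shared count ``O`` by genes not shared but
functionally similar (significant PPI-link enrichment) to the other list:
``POGF12 = (O + Of12) / l1``.  Chance expectations are Monte-Carlo means
over random list pairs of the same lengths, and each score is normalized
as ``(score - E) / (1 - E)`` so that chance maps to 0 and perfect
consistency to 1.  Permutation p-values count the fraction of random
scores strictly larger than the observed one.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .io import GeneList
from .network import PPINetwork
from .similarity import _check_alpha, significance_k_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "ConsistencyResult",
    "pog",
    "pogf",
    "expected_score",
    "normalize",
    "permutation_pvalue",
    "compare_lists",
    "compare_many",
]


@dataclass(frozen=True)
class ConsistencyResult:
    """Both-direction consistency scores for one pair of gene lists."""

    list1: str
    list2: str
    l1: int                # raw list lengths
    l2: int
    l1_net: int            # network-restricted lengths (POGF denominators)
    l2_net: int
    m: int                 # shared genes (raw lists)
    pog12: float
    pog21: float
    O: int                 # shared genes on the network
    of12: int              # non-shared but functionally similar counts
    of21: int
    pogf12: float
    pogf21: float
    e_pog12: float
    e_pog21: float
    e_pogf12: float
    e_pogf21: float
    npog12: float
    npog21: float
    npogf12: float
    npogf21: float
    p_pog12: float
    p_pog21: float
    p_pogf12: float
    p_pogf21: float
    R: int                 # Monte-Carlo repetitions
    alpha: float           # similarity threshold
    seed: int | None


# ---------------------------------------------------------------------------
# observed scores

def pog(list1: GeneList, list2: GeneList) -> tuple[float, float, int]:
    """Directional overlap scores ``(m/l1, m/l2, m)``."""
    if len(list1) == 0 or len(list2) == 0:
        raise ParameterError("POG requires two non-empty gene lists")
    m = len(list1.gene_set & list2.gene_set)
    return m / len(list1), m / len(list2), m


def pogf(
    net: PPINetwork,
    list1: GeneList,
    list2: GeneList,
    alpha: float = 0.05,
) -> tuple[float, float, int, int, int]:
    """Directional functional consistency scores over the PPI network.

    Lists are restricted to network genes; denominators are the restricted
    lengths.  Returns ``(pogf12, pogf21, O, of12, of21)``.

    Raises
    ------
    ParameterError
        If either list has no gene on the network (the missing genes are
        named in the message).
    """
    _check_alpha(alpha)
    for gl in (list1, list2):
        if not (gl.gene_set & net.nodes):
            missing = ", ".join(gl.genes[:10])
            raise ParameterError(
                f"gene list {gl.name!r} has no members on the network "
                f"(genes: {missing}{'...' if len(gl) > 10 else ''})"
            )
    r1 = list1.restrict_to(net.nodes)
    r2 = list2.restrict_to(net.nodes)
    idx1 = net.indices_of(r1.genes)
    idx2 = net.indices_of(r2.genes)
    s12, s21, O, of12, of21 = _pogf_from_indices(
        net, idx1, idx2, alpha=alpha
    )
    return s12, s21, O, of12, of21


def _pogf_from_indices(
    net: PPINetwork,
    idx1: np.ndarray,
    idx2: np.ndarray,
    alpha: float,
    kmin1: np.ndarray | None = None,
    kmin2: np.ndarray | None = None,
) -> tuple[float, float, int, int, int]:
    """POGF in both directions from node-index arrays.

    ``kmin1``/``kmin2`` are optional precomputed significance thresholds
    (per link-degree) for target-list sizes ``len(idx2)`` / ``len(idx1)``;
    permutation loops pass them to avoid re-evaluating hypergeometric
    tails.
    """
    N = net.n_nodes - 1
    deg = net.link_degree
    shared = np.isin(idx1, idx2, assume_unique=True)
    O = int(shared.sum())

    def _of(query: np.ndarray, target: np.ndarray, kmin: np.ndarray | None) -> int:
        if len(query) == 0 or len(target) == 0:
            return 0
        k = net.links_into(query, target)
        if kmin is None:
            kmin = significance_k_threshold(
                N, len(target), int(deg[query].max(initial=0)), alpha
            )
        return int((k >= kmin[deg[query]]).sum())

    of12 = _of(idx1[~shared], idx2, kmin1)
    shared2 = np.isin(idx2, idx1, assume_unique=True)
    of21 = _of(idx2[~shared2], idx1, kmin2)
    s12 = (O + of12) / len(idx1)
    s21 = (O + of21) / len(idx2)
    return s12, s21, O, of12, of21


# ---------------------------------------------------------------------------
# Monte-Carlo null machinery

def _sample_pair_indices(
    rng: np.random.Generator, B: int, l1: int, l2: int, R: int
) -> tuple[np.ndarray, np.ndarray]:
    """R independent pairs of without-replacement draws from range(B).

    Returns integer arrays of shape (R, l1) and (R, l2).  Uses the
    random-keys trick (argpartition of uniforms) in chunks to bound
    memory.
    """
    out1 = np.empty((R, l1), dtype=np.intp)
    out2 = np.empty((R, l2), dtype=np.intp)
    chunk = max(1, min(R, 4_000_000 // max(B, 1)))
    for start in range(0, R, chunk):
        stop = min(start + chunk, R)
        for out, l in ((out1, l1), (out2, l2)):
            u = rng.random((stop - start, B))
            out[start:stop] = np.argpartition(u, l - 1, axis=1)[:, :l]
    return out1, out2


def _null_pog_scores(
    rng: np.random.Generator, B: int, l1: int, l2: int, R: int
) -> tuple[np.ndarray, np.ndarray]:
    """Null POG scores for R random list pairs from a background of size B."""
    idx1, idx2 = _sample_pair_indices(rng, B, l1, l2, R)
    member2 = np.zeros((R, B), dtype=bool)
    np.put_along_axis(member2, idx2, True, axis=1)
    m = np.take_along_axis(member2, idx1, axis=1).sum(axis=1)
    return m / l1, m / l2


def _null_pogf_scores(
    rng: np.random.Generator,
    net: PPINetwork,
    l1: int,
    l2: int,
    R: int,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Null POGF scores for R random list pairs drawn from the network genes."""
    V = net.n_nodes
    N = V - 1
    n_max = int(net.link_degree.max(initial=0))
    kmin1 = significance_k_threshold(N, l2, n_max, alpha)
    kmin2 = significance_k_threshold(N, l1, n_max, alpha)
    idx1s, idx2s = _sample_pair_indices(rng, V, l1, l2, R)
    s12 = np.empty(R)
    s21 = np.empty(R)
    for r in range(R):
        s12[r], s21[r], *_ = _pogf_from_indices(
            net, idx1s[r], idx2s[r], alpha, kmin1=kmin1, kmin2=kmin2
        )
    return s12, s21


def _null_scores(
    metric: str,
    l1: int,
    l2: int,
    rng: np.random.Generator,
    R: int,
    background: GeneList | None = None,
    net: PPINetwork | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    if metric == "pog":
        if background is None:
            raise ParameterError("POG null requires a background gene universe")
        B = len(background)
        if l1 > B or l2 > B:
            raise ParameterError(
                f"list lengths ({l1}, {l2}) exceed background size {B}"
            )
        return _null_pog_scores(rng, B, l1, l2, R)
    if metric == "pogf":
        if net is None:
            raise ParameterError("POGF null requires the PPI network")
        V = net.n_nodes
        if l1 > V or l2 > V:
            raise ParameterError(
                f"list lengths ({l1}, {l2}) exceed network size {V}"
            )
        return _null_pogf_scores(rng, net, l1, l2, R, alpha)
    raise ParameterError(f"unknown metric: {metric!r}")


def expected_score(
    metric: str,
    l1: int,
    l2: int,
    background: GeneList | None = None,
    net: PPINetwork | None = None,
    R: int = 10_000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Chance expectation of a consistency score, both directions.

    Means over ``R`` independent random list pairs of lengths ``l1`` and
    ``l2`` — drawn from *background* for POG, from the network genes for
    POGF.  Seeded and reproducible.
    """
    rng = np.random.default_rng(seed)
    s12, s21 = _null_scores(metric, l1, l2, rng, R, background, net, alpha)
    return float(s12.mean()), float(s21.mean())


def normalize(score: float, expected: float) -> float:
    """Map the chance expectation to 0 and a perfect score to 1.

    ``(score - expected) / (1 - expected)``; undefined (NaN, with a
    warning) when the expectation is already 1.
    """
    if expected >= 1.0:
        warnings.warn(
            "normalized score undefined when the expected score is 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return (score - expected) / (1.0 - expected)


def permutation_pvalue(
    observed: float,
    metric: str,
    l1: int,
    l2: int,
    background: GeneList | None = None,
    net: PPINetwork | None = None,
    R: int = 10_000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    smoothed: bool = False,
) -> float:
    """Fraction of null scores strictly larger than the observed score.

    The null draws random list pairs of the same lengths (direction
    1 -> 2; swap ``l1``/``l2`` for the other direction).  Ties count as
    not larger.  ``smoothed`` switches to the add-one estimator
    ``(b + 1) / (R + 1)``, which never returns an exact zero.
    """
    rng = np.random.default_rng(seed)
    s12, _ = _null_scores(metric, l1, l2, rng, R, background, net, alpha)
    b = int((s12 > observed).sum())
    return (b + 1) / (R + 1) if smoothed else b / R


def format_pvalue(p: float, R: int) -> str:
    """Render a permutation p-value, reporting an exact zero as ``< 1/R``."""
    return f"< {1.0 / R:g}" if p == 0.0 else f"{p:g}"


# ---------------------------------------------------------------------------
# full pairwise comparison

def compare_lists(
    net: PPINetwork,
    list1: GeneList,
    list2: GeneList,
    universe: GeneList | None = None,
    alpha: float = 0.05,
    R: int = 10_000,
    seed: int | None = None,
) -> ConsistencyResult:
    """All consistency scores, expectations and p-values for one list pair.

    *universe* is the background for the POG null (e.g. all genes of the
    genome assayed); when omitted, the network gene set is used for both
    nulls and a note is logged.
    """
    if universe is None:
        logger.info(
            "no POG background universe supplied; using the %d network genes",
            net.n_nodes,
        )
        universe = GeneList("network", tuple(net.node_list))
    pog12, pog21, m = pog(list1, list2)
    pogf12, pogf21, O, of12, of21 = pogf(net, list1, list2, alpha)
    l1_net = len(list1.restrict_to(net.nodes))
    l2_net = len(list2.restrict_to(net.nodes))

    ss = np.random.SeedSequence(seed)
    rng_pog, rng_pogf = (np.random.default_rng(s) for s in ss.spawn(2))
    null_pog12, null_pog21 = _null_scores(
        "pog", len(list1), len(list2), rng_pog, R, background=universe
    )
    null_pogf12, null_pogf21 = _null_scores(
        "pogf", l1_net, l2_net, rng_pogf, R, net=net, alpha=alpha
    )
    e_pog12 = float(null_pog12.mean())
    e_pog21 = float(null_pog21.mean())
    e_pogf12 = float(null_pogf12.mean())
    e_pogf21 = float(null_pogf21.mean())
    return ConsistencyResult(
        list1=list1.name, list2=list2.name,
        l1=len(list1), l2=len(list2), l1_net=l1_net, l2_net=l2_net,
        m=m, pog12=pog12, pog21=pog21,
        O=O, of12=of12, of21=of21, pogf12=pogf12, pogf21=pogf21,
        e_pog12=e_pog12, e_pog21=e_pog21,
        e_pogf12=e_pogf12, e_pogf21=e_pogf21,
        npog12=normalize(pog12, e_pog12),
        npog21=normalize(pog21, e_pog21),
        npogf12=normalize(pogf12, e_pogf12),
        npogf21=normalize(pogf21, e_pogf21),
        p_pog12=float((null_pog12 > pog12).mean()),
        p_pog21=float((null_pog21 > pog21).mean()),
        p_pogf12=float((null_pogf12 > pogf12).mean()),
        p_pogf21=float((null_pogf21 > pogf21).mean()),
        R=R, alpha=alpha, seed=seed,
    )


def compare_many(
    net: PPINetwork,
    lists: Sequence[GeneList],
    universe: GeneList | None = None,
    alpha: float = 0.05,
    R: int = 10_000,
    seed: int | None = None,
    include_self: bool = False,
) -> list[ConsistencyResult]:
    """Consistency scores for every unordered pair of lists.

    Each pair gets its own seeded Monte-Carlo stream derived from *seed*,
    recorded in the result for replay.
    """
    if len(lists) < 2 and not include_self:
        raise ParameterError("compare_many requires at least two gene lists")
    pairs = list(itertools.combinations(range(len(lists)), 2))
    if include_self:
        pairs = [(i, i) for i in range(len(lists))] + pairs
    ss = np.random.SeedSequence(seed)
    pair_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(pairs))]
    results = []
    for (i, j), pair_seed in zip(pairs, pair_seeds):
        results.append(
            compare_lists(
                net, lists[i], lists[j], universe=universe,
                alpha=alpha, R=R, seed=pair_seed,
            )
        )
    return results
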