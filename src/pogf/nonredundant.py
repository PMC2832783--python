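"""Representative (non-redundant) subset selection.

Given a gene list L on the PPI network, choose a subset S of L such that
every gene of L is either in S or functionally similar to S — i.e. the
functional consistency score from L to S equals 1.  A greedy maximum-
coverage loop adds, each round, the list gene that covers the most
still-uncovered list genes, with ties broken by higher PPI-link degree
and then by symbol.  Because the per-gene similarity test depends on the
current size of S, coverage is re-evaluated against S every round; a gene
that nothing can cover is eventually added to S itself (membership covers
it), so termination is guaranteed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .io import GeneList
from .network import PPINetwork
from .similarity import _check_alpha, significance_k_threshold

logger = logging.getLogger(__name__)

__all__ = ["CoverageRecord", "representative_subset"]


@dataclass(frozen=True)
class CoverageRecord:
    """How one list gene is covered by the representative subset."""

    gene: str
    covered_by: str  # "member" | "similar"
    k: int           # links into the final subset
    p_attained: bool  # similarity significant at alpha vs the final subset


def _covered_mask(
    net: PPINetwork,
    list_idx: np.ndarray,
    subset_idx: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Which list genes are members of, or functionally similar to, the subset."""
    member = np.isin(list_idx, subset_idx, assume_unique=True)
    covered = member.copy()
    rest = list_idx[~member]
    if len(rest) and len(subset_idx):
        deg = net.link_degree
        kmin = significance_k_threshold(
            net.n_nodes - 1, len(subset_idx), int(deg[rest].max()), alpha
        )
        k = net.links_into(rest, subset_idx)
        covered[~member] = k >= kmin[deg[rest]]
    return covered


def representative_subset(
    net: PPINetwork,
    gene_list: GeneList,
    alpha: float = 0.05,
) -> tuple[GeneList, list[CoverageRecord]]:
    """Greedy representative subset with full functional coverage.

    Returns ``(subset, coverage)`` where every network gene of the input
    list is in the subset or functionally similar to it at *alpha* — so
    the functional consistency score from the list to the subset is 1.
    """
    _check_alpha(alpha)
    restricted = gene_list.restrict_to(net.nodes)
    if len(restricted) == 0:
        raise ParameterError(
            f"gene list {gene_list.name!r} has no members on the network"
        )
    symbols = list(restricted.genes)
    list_idx = net.indices_of(symbols)
    pos = {int(i): s for i, s in zip(list_idx, symbols)}
    deg = net.link_degree
    N = net.n_nodes - 1

    subset: list[int] = []
    while True:
        sub_idx = np.array(sorted(subset), dtype=np.intp)
        covered = _covered_mask(net, list_idx, sub_idx, alpha)
        if covered.all():
            break
        uncov_idx = list_idx[~covered]
        cand_idx = list_idx[~np.isin(list_idx, sub_idx, assume_unique=True)]
        # coverage of the uncovered genes if one candidate joins the subset
        M_new = len(subset) + 1
        n_max = int(deg[uncov_idx].max())
        kmin = significance_k_threshold(N, M_new, n_max, alpha)
        k_base = (
            net.links_into(uncov_idx, sub_idx)
            if len(subset)
            else np.zeros(len(uncov_idx), dtype=np.int64)
        )
        link_block = np.asarray(
            net.link_matrix[uncov_idx][:, cand_idx].todense(), dtype=np.int64
        )
        best: tuple[int, int, str] | None = None
        best_cand: int | None = None
        for j, c in enumerate(cand_idx):
            k_new = k_base + link_block[:, j]
            gain = int((k_new >= kmin[deg[uncov_idx]]).sum())
            if c in uncov_idx:  # candidate covers itself by membership
                self_row = int(np.flatnonzero(uncov_idx == c)[0])
                if k_new[self_row] < kmin[deg[c]]:
                    gain += 1
            key = (gain, int(deg[c]), _neg_lex(pos[int(c)]))
            if best is None or key > best:
                best = key
                best_cand = int(c)
        assert best_cand is not None
        subset.append(best_cand)

    chosen = sorted(subset, key=lambda i: symbols.index(pos[i]))
    sub_list = GeneList(
        f"{gene_list.name}:representative", tuple(pos[i] for i in chosen)
    )
    final_idx = np.array(sorted(subset), dtype=np.intp)
    member = np.isin(list_idx, final_idx, assume_unique=True)
    kmin = significance_k_threshold(
        N, len(final_idx), int(deg[list_idx].max()), alpha
    )
    k_all = net.links_into(list_idx, final_idx)
    coverage = [
        CoverageRecord(
            gene=s,
            covered_by="member" if member[i] else "similar",
            k=int(k_all[i]),
            p_attained=bool(member[i] or k_all[i] >= kmin[deg[list_idx[i]]]),
        )
        for i, s in enumerate(symbols)
    ]
    logger.info(
        "representative subset: %d of %d genes (alpha=%g)",
        len(sub_list), len(restricted), alpha,
    )
    return sub_list, coverage


class _neg_lex(str):
    """Reverses lexicographic comparison so max() prefers the smaller symbol."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)
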