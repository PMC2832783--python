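"""PPI network model and the PPI-link relation.

The network is an undirected simple graph of gene symbols (no self-loops,
each unordered pair stored once).  Two genes have a *PPI link* when they
interact directly or share at least one interaction neighbour; this
relation — not the raw edge relation — is the substrate of all functional
similarity scores.  For batch scoring the link relation is materialized
once as a sparse boolean matrix.
"""

from __future__ import annotations

import logging
import os
from collections.abc import Iterable
from dataclasses import dataclass
from typing import TextIO

import networkx as nx
import numpy as np
from scipy import sparse

from .exceptions import EmptyListError, ParseError, UnknownGeneError
from .io import GeneList, normalize_symbol, _open_maybe

logger = logging.getLogger(__name__)

__all__ = ["PPINetwork", "LinkProfile", "load_edge_list"]


@dataclass(frozen=True)
class LinkProfile:
    """PPI-link partners of one gene.

    ``n`` is the number of genes with a PPI link to ``gene`` anywhere in
    the network; ``N`` is the number of possible partners (all other
    network genes).
    """

    gene: str
    partners: frozenset[str]
    n: int
    N: int


class PPINetwork:
    """Undirected simple graph of gene symbols.

    Parameters
    ----------
    edges
        Iterable of (a, b) symbol pairs. Self-pairs are dropped and
        duplicate pairs (either orientation) collapse to one edge.
    nodes
        Optional extra symbols to include as isolated nodes.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_self = 0
        for a, b in edges:
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
        if n_self:
            logger.info("dropped %d self-interactions", n_self)
        self._graph = g
        self._node_list: list[str] = sorted(g.nodes)
        self._index: dict[str, int] = {s: i for i, s in enumerate(self._node_list)}
        self._link_csr: sparse.csr_array | None = None
        self._link_degree: np.ndarray | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._index)

    @property
    def node_list(self) -> list[str]:
        """Nodes in the canonical (sorted) order used by index arrays."""
        return list(self._node_list)

    @property
    def n_nodes(self) -> int:
        return len(self._node_list)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, symbol: object) -> bool:
        return symbol in self._index

    def __len__(self) -> int:
        return len(self._node_list)

    def index_of(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise UnknownGeneError(symbol) from None

    def indices_of(self, symbols: Iterable[str]) -> np.ndarray:
        return np.array([self.index_of(s) for s in symbols], dtype=np.intp)

    def neighbors(self, symbol: str) -> set[str]:
        self.index_of(symbol)
        return set(self._graph[symbol])

    # -- the PPI-link relation ---------------------------------------------

    def ppi_link(self, a: str, b: str) -> bool:
        """True iff *a* and *b* interact directly or share a neighbour."""
        self.index_of(a)
        self.index_of(b)
        if a == b:
            raise ValueError("ppi_link is defined for distinct genes")
        g = self._graph
        if g.has_edge(a, b):
            return True
        na, nb = g[a], g[b]
        if len(na) > len(nb):
            na, nb = nb, na
        return any(x in nb for x in na)

    def link_profile(self, gene: str) -> LinkProfile:
        """All PPI-link partners of *gene* (direct plus shared-neighbour)."""
        self.index_of(gene)
        g = self._graph
        partners: set[str] = set(g[gene])
        for nb in list(partners):
            partners.update(g[nb])
        partners.discard(gene)
        return LinkProfile(
            gene=gene,
            partners=frozenset(partners),
            n=len(partners),
            N=self.n_nodes - 1,
        )

    def count_links_to_list(
        self, gene: str, gene_list: GeneList | Iterable[str]
    ) -> tuple[int, int]:
        """Count the gene's PPI links into a list: returns ``(k, M)``.

        ``M`` is the number of list genes on the network, excluding the
        query gene itself; ``k`` of those have a PPI link to the query.
        """
        members = set(gene_list) & self.nodes
        members.discard(gene)
        partners = self.link_profile(gene).partners
        return len(partners & members), len(members)

    # -- materialized link matrix (batch scoring) --------------------------

    @property
    def link_matrix(self) -> sparse.csr_array:
        """Boolean CSR matrix of the PPI-link relation, canonical node order."""
        if self._link_csr is None:
            a = nx.to_scipy_sparse_array(
                self._graph, nodelist=self._node_list, dtype=np.int32, format="csr"
            )
            link = ((a + a @ a) > 0).astype(np.int8)
            link.setdiag(0)
            link.eliminate_zeros()
            self._link_csr = sparse.csr_array(link.astype(bool))
        return self._link_csr

    @property
    def link_degree(self) -> np.ndarray:
        """Per-node count of PPI-link partners (``n``), canonical order."""
        if self._link_degree is None:
            self._link_degree = np.asarray(
                self.link_matrix.sum(axis=1), dtype=np.int64
            ).ravel()
        return self._link_degree

    def links_into(self, query_idx: np.ndarray, target_idx: np.ndarray) -> np.ndarray:
        """For each query node index, the count of PPI links into the target set."""
        if len(query_idx) == 0:
            return np.zeros(0, dtype=np.int64)
        sub = self.link_matrix[query_idx][:, target_idx]
        return np.asarray(sub.sum(axis=1), dtype=np.int64).ravel()

    def __repr__(self) -> str:  # pragma: no cover
        return f"PPINetwork({self.n_nodes} nodes, {self.n_edges} edges)"


def _parse_tsv2col(
    stream: TextIO, uppercase: bool
) -> Iterable[tuple[str, str]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2 or not all(f.strip() for f in fields):
            raise ParseError(
                f"expected two symbol columns, got {len(fields)}", lineno
            )
        yield (
            normalize_symbol(fields[0], uppercase),
            normalize_symbol(fields[1], uppercase),
        )


def _parse_sif(stream: TextIO, uppercase: bool) -> Iterable[tuple[str, str]]:
    # SIF: "node relation node [node ...]"; a lone node declares an
    # isolated node, encoded here as a self-pair that the constructor drops
    # after the node is registered separately by load_edge_list.
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) == 1:
            yield (normalize_symbol(fields[0], uppercase), None)  # type: ignore[misc]
            continue
        if len(fields) == 2:
            raise ParseError(
                "SIF row with a relation must name at least one target node",
                lineno,
            )
        src = normalize_symbol(fields[0], uppercase)
        for tgt in fields[2:]:
            yield src, normalize_symbol(tgt, uppercase)


def load_edge_list(
    source: str | os.PathLike | TextIO,
    dialect: str = "tsv2col",
    uppercase: bool = True,
) -> PPINetwork:
    """Load an undirected PPI network from a two-column TSV or SIF file.

    Self-interactions are removed and duplicate edges (either orientation)
    collapsed; counts of dropped rows are logged.

    Raises
    ------
    ParseError
        On a malformed row (with its line number).
    EmptyListError
        If the file yields no nodes at all.
    """
    if dialect not in ("tsv2col", "sif"):
        raise ValueError(f"unknown edge-list dialect: {dialect!r}")
    stream, close = _open_maybe(source)
    try:
        parser = _parse_tsv2col if dialect == "tsv2col" else _parse_sif
        lone_nodes: list[str] = []
        edges: list[tuple[str, str]] = []
        for a, b in parser(stream, uppercase):
            if b is None:
                lone_nodes.append(a)
            else:
                edges.append((a, b))
    finally:
        if close:
            stream.close()
    net = PPINetwork(edges, nodes=lone_nodes)
    if net.n_nodes == 0:
        raise EmptyListError("edge list yields an empty network")
    n_dupes = len(edges) - sum(1 for a, b in edges if a == b) - net.n_edges
    if n_dupes:
        logger.info("collapsed %d duplicate edges", n_dupes)
    logger.info(
        "loaded PPI network: %d nodes, %d edges", net.n_nodes, net.n_edges
    )
    return net
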