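"""Hypergeometric pathway enrichment and selected-vs-remaining comparison.

Enrichment of a gene set in a pathway is the upper-tail hypergeometric
probability of drawing at least the observed number of pathway genes when
sampling the set from the universe.  The comparison table contrasts a
selected/remaining partition of candidates: both p-values per pathway plus
the ratio of pathway fractions, rendered ``Inf`` when the remaining genes
avoid the pathway entirely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections.abc import Sequence

from scipy import stats

from .exceptions import ParameterError
from .io import GeneList, PathwaySet

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentRow", "hypergeom_enrichment", "selected_vs_rest"]


@dataclass(frozen=True)
class EnrichmentRow:
    pathway: str
    pathway_size: int
    p_selected: float
    p_remaining: float
    ratio: float


def _clip_to_universe(genes: frozenset[str], universe: frozenset[str], label: str) -> frozenset[str]:
    outside = genes - universe
    if outside:
        logger.warning(
            "%s: %d genes outside the universe were clipped", label, len(outside)
        )
    return genes & universe


def hypergeom_enrichment(
    gene_set: GeneList, pathway: PathwaySet, universe: GeneList
) -> float:
    """Upper-tail probability that the set contains >= its observed pathway genes.

    Set and pathway are clipped to the universe (violations logged).
    """
    if len(universe) == 0:
        raise ParameterError("enrichment requires a non-empty universe")
    uni = universe.gene_set
    setg = _clip_to_universe(gene_set.gene_set, uni, gene_set.name)
    pw = _clip_to_universe(pathway.genes, uni, pathway.name)
    k = len(setg & pw)
    p = stats.hypergeom.sf(k - 1, len(uni), len(pw), len(setg))
    return float(min(max(p, 0.0), 1.0))


def selected_vs_rest(
    selected: GeneList,
    remaining: GeneList,
    pathways: Sequence[PathwaySet],
    universe: GeneList,
) -> list[EnrichmentRow]:
    """Per-pathway enrichment of a selected/remaining candidate partition.

    The ratio is (selected pathway fraction) / (remaining pathway
    fraction): ``Inf`` when only the selected genes hit the pathway, 0
    when the selected genes miss it.
    """
    if selected.gene_set & remaining.gene_set:
        raise ParameterError("selected and remaining gene sets overlap")
    uni = universe.gene_set
    sel = _clip_to_universe(selected.gene_set, uni, selected.name)
    rem = _clip_to_universe(remaining.gene_set, uni, remaining.name)
    rows = []
    for pw in pathways:
        pwg = _clip_to_universe(pw.genes, uni, pw.name)
        p_sel = hypergeom_enrichment(selected, pw, universe)
        p_rem = hypergeom_enrichment(remaining, pw, universe)
        f_sel = len(sel & pwg) / len(sel) if sel else 0.0
        f_rem = len(rem & pwg) / len(rem) if rem else 0.0
        if f_sel == 0.0:
            ratio = 0.0
        elif f_rem == 0.0:
            ratio = math.inf
        else:
            ratio = f_sel / f_rem
        rows.append(
            EnrichmentRow(
                pathway=pw.name,
                pathway_size=len(pw),
                p_selected=p_sel,
                p_remaining=p_rem,
                ratio=ratio,
            )
        )
    return rows
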