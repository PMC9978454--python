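"""Hypergeometric gene-set enrichment.

Target genes of DNM-containing enhancers are tested for over-representation
in disorder gene lists and in loss-of-function-intolerant genes
(pLI >= 0.9).  The universe is a required explicit parameter: all sets are
intersected with it before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

from .burden_enrichment import fdr_adjust

logger = logging.getLogger(__name__)

__all__ = ["GeneSetTest", "hypergeom_enrichment", "pli_enrichment", "enrich_many"]


@dataclass
class GeneSetTest:
    set_name: str
    universe_n: int
    set_k: int
    draws_n: int
    hits_k: int
    p: float
    fdr: float | None = None


def hypergeom_enrichment(
    target_genes: Iterable[str],
    gene_list: Iterable[str],
    universe: Iterable[str],
    set_name: str = "",
) -> GeneSetTest:
    """Upper-tail hypergeometric test: Pr[X >= k] for X ~ HG(N, K, n)."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    targets = set(target_genes) & universe
    listed = set(gene_list) & universe
    n_universe = len(universe)
    n_list = len(listed)
    n_draws = len(targets)
    hits = len(targets & listed)
    if n_draws == 0:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(hits - 1, n_universe, n_list, n_draws))
    return GeneSetTest(
        set_name=set_name,
        universe_n=n_universe,
        set_k=n_list,
        draws_n=n_draws,
        hits_k=hits,
        p=min(p, 1.0),
    )


def pli_enrichment(
    target_genes: Iterable[str],
    pli_table: Mapping[str, float],
    universe: Iterable[str],
    cutoff: float = 0.9,
) -> GeneSetTest:
    """Enrichment of LoF-intolerant genes (pLI >= cutoff, inclusive).

    Genes missing a pLI value are excluded from both the list and the
    universe, with a log message.
    """
    universe = set(universe)
    missing = universe - set(pli_table)
    if missing:
        logger.info("%d universe genes lack pLI and are excluded", len(missing))
    scored = universe & set(pli_table)
    for g, v in pli_table.items():
        if not 0 <= v <= 1:
            raise ValueError(f"pLI for {g} outside [0, 1]")
    intolerant = {g for g in scored if pli_table[g] >= cutoff}
    return hypergeom_enrichment(
        set(target_genes) & scored, intolerant, scored, set_name=f"pli>={cutoff}"
    )


def enrich_many(
    target_genes: Iterable[str],
    list_collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[GeneSetTest]:
    """One hypergeometric test per list, with BH FDR across the lists."""
    if not list_collection:
        raise ValueError("need at least one gene list")
    universe = set(universe)
    targets = set(target_genes)
    results = [
        hypergeom_enrichment(targets, genes, universe, set_name=name)
        for name, genes in list_collection.items()
    ]
    for res, q in zip(results, fdr_adjust([r.p for r in results])):
        res.fdr = float(q)
    return results
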