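"""Nested (sub-level) over-representation analysis.

For each term found over-represented at the upper level, the genes
annotated to that term become the background population of a second round
of Fisher exact tests, and the analysis list shrinks to the list genes
inside the parent term. Every other term overlapping the parent — from any
category, not only ontology descendants — is a candidate "driver" of the
parent's enrichment. Consequently, for every nested row, the list size
equals the parent's upper-level list hits and the population size equals
the parent's upper-level population hits.

Two derived columns are candidate interpretations flagged as such in all
outputs: ``pvalue_log_diff`` (absolute log10 difference between the nested
term's within-parent p and the same term's p against the full category
background) and ``nease_gene_enrich`` (the nested gene enrichment scaled by
the parent's enrichment relative to its expectation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .annotation_io import AnnotationUniverse, GeneList
from .enrichment_core import (
    ContingencyCounts,
    EnrichmentResult,
    bh_adjust,
    build_contingency,
    fisher_upper_tail,
    gene_enrich,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NestedResult",
    "restrict_background",
    "pct_gene_enrich",
    "pvalue_log_diff",
    "run_nease",
]


@dataclass(frozen=True)
class NestedResult:
    """One (parent term, nested term) pair's counts and statistics."""

    parent_term: str
    parent_name: str
    parent_category: str
    nested_term: str
    nested_name: str
    nested_category: str
    counts: ContingencyCounts
    fisher_p: float
    corrected_p: float
    gene_enrich: float
    pct_gene_enrich: float
    pvalue_log_diff: float
    nease_gene_enrich: float


def restrict_background(universe: AnnotationUniverse, parent: str) -> AnnotationUniverse:
    """Condition a universe on a parent term's gene set.

    The returned universe's background is exactly the parent's gene set;
    every other term is intersected with it, terms with empty intersection
    are dropped, and the parent itself is excluded.
    """
    if parent not in universe:
        raise KeyError(f"parent term {parent!r} not in category {universe.category!r}")
    parent_genes = universe.term_to_genes[parent]
    if not parent_genes:
        raise ValueError(f"parent term {parent!r} has an empty gene set")
    return _restrict_terms(universe, parent_genes, exclude=parent)


def _restrict_terms(
    universe: AnnotationUniverse,
    background: frozenset[str],
    exclude: str | None = None,
) -> AnnotationUniverse:
    restricted = {
        term: inter
        for term, genes in universe.term_to_genes.items()
        if term != exclude and (inter := genes & background)
    }
    if not restricted:
        raise ValueError(
            f"no term of category {universe.category!r} overlaps the restricted background"
        )
    return AnnotationUniverse(
        universe.category, restricted, dict(universe.term_names), background=background
    )


def pct_gene_enrich(counts: ContingencyCounts) -> float:
    """Gene enrichment as a percentage of the term's population hits."""
    return 100.0 * gene_enrich(counts) / counts.pop_hits


def pvalue_log_diff(nested_p: float, parent_level_p: float) -> float:
    """Absolute log10 difference between within-parent and full-background p.

    Candidate interpretation of the tabulated "p-value log difference";
    flagged as such wherever it is written out.
    """
    if not (0.0 < nested_p <= 1.0 and 0.0 < parent_level_p <= 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return abs(math.log10(parent_level_p) - math.log10(nested_p))


def _descendant_filter(ontology, parent: str) -> frozenset[str] | None:
    """Terms below ``parent`` in the ontology graph (edges point child→parent)."""
    import networkx as nx

    if parent not in ontology:
        logger.warning("parent %r absent from ontology; no descendants", parent)
        return frozenset()
    return frozenset(nx.ancestors(ontology, parent))


def run_nease(
    ease_results: Iterable[EnrichmentResult],
    genes: GeneList,
    universes: Iterable[AnnotationUniverse],
    min_hits: int = 2,
    alpha: float = 0.05,
    family: str = "global",
    descendants_only: bool = False,
    ontology=None,
) -> list[NestedResult]:
    """Second-level analysis under every over-represented upper-level term.

    Parents are the upper-level results with ``corrected_p <= alpha``. For
    each parent the candidate nested terms are all terms (any category)
    whose gene sets overlap the parent's; candidates with fewer than
    ``min_hits`` within-parent list hits are skipped. BH correction spans
    all (parent, nested) pairs of the run (``family="global"``) or each
    parent's own family (``"per-parent"``). Rows with corrected p <= alpha
    are returned, sorted by parent then by nested Fisher p.

    ``descendants_only`` restricts candidates to ontology descendants of
    the parent; it requires ``ontology`` (an obonet-style graph whose edges
    point from a term to its parents).
    """
    ease_results = list(ease_results)
    if not ease_results:
        raise ValueError("nested analysis needs at least one upper-level result")
    universes = list(universes)
    if family not in ("global", "per-parent"):
        raise ValueError(f"unknown BH family mode {family!r}")
    if descendants_only and ontology is None:
        raise ValueError("descendants_only requires an ontology graph")

    by_category = {u.category: u for u in universes}
    parents = [r for r in ease_results if r.corrected_p <= alpha]
    if not parents:
        logger.warning("no upper-level term passes corrected_p <= %g", alpha)
        return []

    gene_set = genes.as_set()
    full_p_cache: dict[tuple[str, str], float] = {}

    def full_background_p(category: str, term: str) -> float:
        key = (category, term)
        if key not in full_p_cache:
            counts = build_contingency(genes, term, by_category[category])
            full_p_cache[key] = fisher_upper_tail(counts)
        return full_p_cache[key]

    partial: list[tuple[int, EnrichmentResult, str, str, ContingencyCounts, float, float]] = []
    families: list[list[int]] = []
    for parent_idx, parent in enumerate(parents):
        home = by_category.get(parent.category)
        if home is None or parent.term not in home:
            logger.warning("parent %r has no home universe; skipped", parent.term)
            continue
        parent_genes = home.term_to_genes[parent.term]
        within_list = gene_set & parent_genes
        if len(within_list) < min_hits:
            logger.info("parent %r: within-parent list too small; skipped", parent.term)
            continue
        allowed = _descendant_filter(ontology, parent.term) if descendants_only else None
        indices: list[int] = []
        for universe in universes:
            exclude = parent.term if universe.category == parent.category else None
            try:
                restricted = _restrict_terms(universe, parent_genes, exclude=exclude)
            except ValueError:
                continue
            for term in restricted.term_to_genes:
                if allowed is not None and term not in allowed:
                    continue
                counts = build_contingency(genes, term, restricted)
                if counts.list_hits < min_hits:
                    continue
                p = fisher_upper_tail(counts)
                indices.append(len(partial))
                partial.append((parent_idx, parent, term, universe.category, counts, p,
                                full_background_p(universe.category, term)))
        if indices:
            families.append(indices)
        else:
            logger.info("parent %r has no testable nested terms; skipped", parent.term)

    if not partial:
        return []

    corrected = np.empty(len(partial))
    raw = [row[5] for row in partial]
    if family == "global":
        corrected[:] = bh_adjust(raw)
    else:
        for indices in families:
            corrected[indices] = bh_adjust([raw[i] for i in indices])

    keyed: list[tuple[int, NestedResult]] = []
    for (parent_idx, parent, term, category, counts, p, full_p), corr in zip(partial, corrected):
        if corr > alpha:
            continue
        ge = gene_enrich(counts)
        parent_expected = parent.counts.expected_hits
        keyed.append(
            (parent_idx,
             NestedResult(
                parent_term=parent.term,
                parent_name=parent.term_name,
                parent_category=parent.category,
                nested_term=term,
                nested_name=by_category[category].name_of(term),
                nested_category=category,
                counts=counts,
                fisher_p=p,
                corrected_p=float(corr),
                gene_enrich=ge,
                pct_gene_enrich=pct_gene_enrich(counts),
                pvalue_log_diff=pvalue_log_diff(p, full_p),
                nease_gene_enrich=ge * (parent.gene_enrich / parent_expected),
             ))
        )
    keyed.sort(key=lambda kr: (kr[0], kr[1].fisher_p, kr[1].nested_term))
    return [r for _, r in keyed]
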