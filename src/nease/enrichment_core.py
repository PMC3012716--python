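"""Upper-level over-representation statistics.

The statistical core is the one-sided Fisher exact test for
over-representation: with a background ("population") of N annotated genes
of which K carry a term, and an analysis list of n annotated genes of which
k carry the term, the p-value is the hypergeometric upper tail

    P(X >= k),  X ~ Hypergeometric(N, K, n),

computed exactly (no normal approximation). The conservative "EASE score"
jackknife variant removes one list hit before taking the tail. Families of
term tests are corrected by the Benjamini–Hochberg step-up FDR procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation_io import AnnotationUniverse, GeneList

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyCounts",
    "EnrichmentResult",
    "build_contingency",
    "fisher_upper_tail",
    "ease_score",
    "gene_enrich",
    "bh_adjust",
    "run_ease",
]

#: Smallest positive p-value ever reported; underflow clamps here.
MIN_P = 5e-324


@dataclass(frozen=True)
class ContingencyCounts:
    """The (list hits, list size, pop hits, pop size) quadruple (k, n, K, N)."""

    list_hits: int
    list_size: int
    pop_hits: int
    pop_size: int

    def __post_init__(self) -> None:
        k, n, K, N = self.list_hits, self.list_size, self.pop_hits, self.pop_size
        if min(n, K, N) < 1:
            raise ValueError("list_size, pop_hits and pop_size must be positive")
        if n > N or K > N:
            raise ValueError("list_size and pop_hits cannot exceed pop_size")
        if not max(0, n + K - N) <= k <= min(n, K):
            raise ValueError(
                f"list_hits={k} outside hypergeometric support "
                f"[{max(0, n + K - N)}, {min(n, K)}]"
            )

    @property
    def expected_hits(self) -> float:
        """Hits expected under random sampling from the background."""
        return self.list_size * self.pop_hits / self.pop_size


@dataclass(frozen=True)
class EnrichmentResult:
    """One upper-level term's counts and statistics."""

    term: str
    term_name: str
    category: str
    counts: ContingencyCounts
    fisher_p: float
    ease_p: float
    corrected_p: float
    gene_enrich: float
    over_represented: bool = False


def build_contingency(
    genes: GeneList | frozenset[str] | set[str],
    term: str,
    universe: AnnotationUniverse,
) -> ContingencyCounts:
    """Intersect a gene list with a term and its category background.

    Identifiers outside the category background are excluded from both the
    list size and the hit count; the background itself is the population.
    """
    if term not in universe:
        raise KeyError(f"term {term!r} not in category {universe.category!r}")
    gene_set = genes.as_set() if isinstance(genes, GeneList) else frozenset(genes)
    annotated = gene_set & universe.background
    if not annotated:
        raise ValueError(
            f"gene list shares no identifiers with the {universe.category!r} background"
        )
    term_genes = universe.term_to_genes[term]
    return ContingencyCounts(
        list_hits=len(annotated & term_genes),
        list_size=len(annotated),
        pop_hits=len(term_genes),
        pop_size=universe.pop_size,
    )


def _upper_tail(k: int, n: int, K: int, N: int) -> float:
    # sf(k-1) = P(X >= k); scipy's hypergeom is an exact tail computation
    p = float(hypergeom.sf(k - 1, N, K, n))
    if p <= 0.0:
        logger.info("p-value underflow clamped to %.3g", MIN_P)
        return MIN_P
    return min(p, 1.0)


def fisher_upper_tail(counts: ContingencyCounts) -> float:
    """One-sided Fisher exact p-value for over-representation, P(X >= k)."""
    return _upper_tail(counts.list_hits, counts.list_size, counts.pop_hits, counts.pop_size)


def ease_score(counts: ContingencyCounts) -> float:
    """Jackknifed variant: the tail with one list hit removed, P(X >= k-1).

    Always at least as large as the plain Fisher value; equal to 1 whenever
    k <= 1.
    """
    k = max(counts.list_hits - 1, 0)
    return _upper_tail(k, counts.list_size, counts.pop_hits, counts.pop_size)


def gene_enrich(counts: ContingencyCounts) -> float:
    """Observed list hits minus the hits expected from background proportions."""
    return counts.list_hits - counts.expected_hits


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ease(
    genes: GeneList,
    universes: Iterable[AnnotationUniverse],
    min_hits: int = 2,
    alpha: float = 0.05,
    use_ease_score: bool = False,
    family: str = "per-category",
) -> list[EnrichmentResult]:
    """Test every term with at least ``min_hits`` list hits in every category.

    The canonical p-value is the plain Fisher upper tail unless
    ``use_ease_score`` selects the jackknifed variant. BH correction is
    applied within each category's family of tested terms (``family =
    "per-category"``) or across all categories pooled (``"global"``).
    Results come back sorted by corrected p ascending; each carries an
    ``over_represented`` flag for ``corrected_p <= alpha``.
    """
    universes = list(universes)
    if not universes:
        raise ValueError("at least one annotation universe is required")
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    if family not in ("per-category", "global"):
        raise ValueError(f"unknown BH family mode {family!r}")

    partial: list[tuple[AnnotationUniverse, str, ContingencyCounts, float, float]] = []
    families: list[list[int]] = []
    for universe in universes:
        annotated = genes.as_set() & universe.background
        if not annotated:
            logger.warning(
                "gene list shares no identifiers with category %r; skipped",
                universe.category,
            )
            continue
        indices: list[int] = []
        for term in universe.term_to_genes:
            counts = build_contingency(genes, term, universe)
            if counts.list_hits < min_hits:
                continue
            fisher_p = fisher_upper_tail(counts)
            ease_p = ease_score(counts)
            indices.append(len(partial))
            partial.append((universe, term, counts, fisher_p, ease_p))
        if indices:
            families.append(indices)
    if not partial:
        logger.warning("no term reached min_hits=%d; empty result", min_hits)
        return []

    canonical = [row[4] if use_ease_score else row[3] for row in partial]
    corrected = np.empty(len(partial))
    if family == "global":
        corrected[:] = bh_adjust(canonical)
    else:
        for indices in families:
            corrected[indices] = bh_adjust([canonical[i] for i in indices])

    results = [
        EnrichmentResult(
            term=term,
            term_name=universe.name_of(term),
            category=universe.category,
            counts=counts,
            fisher_p=fisher_p,
            ease_p=ease_p,
            corrected_p=float(corr),
            gene_enrich=gene_enrich(counts),
            over_represented=bool(corr <= alpha),
        )
        for (universe, term, counts, fisher_p, ease_p), corr in zip(partial, corrected)
    ]
    results.sort(key=lambda r: (r.corrected_p, r.fisher_p, r.category, r.term))
    return results


def significant(results: Iterable[EnrichmentResult]) -> list[EnrichmentResult]:
    """The over-represented subset of a result collection."""
    return [r for r in results if r.over_represented]
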