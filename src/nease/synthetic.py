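"""Seeded generators of annotation universes, gene lists and DE tables.

These emulate, at the summary level the pipeline consumes, the study
conditions of a knock-down microarray experiment: an annotation universe
of overlapping term gene sets, a differential gene list with planted
term-level enrichment, optional nested "driver" structure (a child term
enriched specifically within a parent term's genes), and a SAM-style
differential table with q-values and signed fold changes. A single integer
seed governs all sampling; every writer embeds the seed and a spec hash in
a ``#`` metadata line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import AnnotationUniverse, DifferentialTable, GeneList, write_gmt

__all__ = [
    "PlantedTerm",
    "NestedPlant",
    "SyntheticSpec",
    "make_universe",
    "make_gene_list",
    "make_differential_table",
    "write_gene_list",
    "write_differential_table",
]


@dataclass(frozen=True)
class PlantedTerm:
    """A term whose members are over-sampled into the gene list."""

    term: str
    odds_ratio: float


@dataclass(frozen=True)
class NestedPlant:
    """A child term enriched specifically within its parent's genes."""

    parent: str
    child: str
    within_parent_odds_ratio: float


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 1000
    n_terms: int = 50
    term_size_range: tuple[int, int] = (20, 60)
    planted_terms: tuple[PlantedTerm, ...] = ()
    nested_plants: tuple[NestedPlant, ...] = ()
    list_size: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if self.n_genes < 1 or self.n_terms < 1:
            raise ValueError("n_genes and n_terms must be positive")
        if not 1 <= lo <= hi:
            raise ValueError("term_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("term sizes cannot exceed n_genes")
        if self.n_terms * hi < self.n_genes:
            raise ValueError(
                "infeasible: n_terms * max term size cannot cover all genes"
            )
        if self.list_size > self.n_genes:
            raise ValueError("list_size cannot exceed n_genes")
        for plant in self.planted_terms:
            if plant.odds_ratio < 1:
                raise ValueError("odds ratios must be >= 1")
        for nest in self.nested_plants:
            if nest.within_parent_odds_ratio < 1:
                raise ValueError("odds ratios must be >= 1")
            if nest.parent == nest.child:
                raise ValueError("a nested plant needs distinct parent and child")

    def digest(self) -> str:
        """Short stable hash of the spec, embedded in output metadata."""
        return hashlib.md5(repr(self).encode()).hexdigest()[:10]

    def metadata(self) -> str:
        return f"seed={self.seed} spec={self.digest()}"

    def term_labels(self) -> list[str]:
        """Accessions: planted/nested names first, then numbered fillers."""
        named = list(dict.fromkeys(
            [p.term for p in self.planted_terms]
            + [n.parent for n in self.nested_plants]
            + [n.child for n in self.nested_plants]
        ))
        if len(named) > self.n_terms:
            raise ValueError("more planted/nested terms than n_terms")
        fillers = [f"T{i:04d}" for i in range(self.n_terms - len(named))]
        return named + fillers


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([spec.seed % 2**31, stream])


def make_universe(spec: SyntheticSpec) -> AnnotationUniverse:
    """Draw a universe of overlapping term gene sets covering every gene.

    Term members are sampled uniformly without replacement within the size
    range; terms are drawn independently, so overlap arises naturally as in
    real ontologies. For every nested plant (parent, child) the child's
    overlap with the parent is forced to at least min(|child|, |parent|/2).
    Genes left unannotated after sampling are distributed to terms with
    spare capacity so the background covers all genes.
    """
    rng = _rng(spec, 0)
    genes = np.array([f"g{i:05d}" for i in range(spec.n_genes)])
    lo, hi = spec.term_size_range
    labels = spec.term_labels()
    sizes = {t: int(rng.integers(lo, hi + 1)) for t in labels}

    term_to_genes: dict[str, set[str]] = {}
    for nest in spec.nested_plants:
        if nest.parent not in term_to_genes:
            term_to_genes[nest.parent] = {
                str(g) for g in rng.choice(genes, size=sizes[nest.parent], replace=False)
            }
    for nest in spec.nested_plants:
        parent_genes = np.array(sorted(term_to_genes[nest.parent]))
        child_size = sizes[nest.child]
        overlap = min(child_size, len(parent_genes) // 2)
        inside = rng.choice(parent_genes, size=overlap, replace=False)
        outside_pool = np.setdiff1d(genes, parent_genes, assume_unique=True)
        outside = rng.choice(outside_pool, size=child_size - overlap, replace=False)
        term_to_genes[nest.child] = {str(g) for g in inside} | {str(g) for g in outside}
    for term in labels:
        if term not in term_to_genes:
            term_to_genes[term] = {str(g) for g in rng.choice(genes, size=sizes[term], replace=False)}

    covered = set().union(*term_to_genes.values())
    orphans = [str(g) for g in genes if g not in covered]
    if orphans:
        # plant-involved terms keep their drawn membership so that planted
        # overlap and odds-ratio structure stay exactly as constructed
        frozen = {p.term for p in spec.planted_terms} | {
            t for n in spec.nested_plants for t in (n.parent, n.child)
        }
        open_terms = [t for t in labels if t not in frozen and len(term_to_genes[t]) < hi]
        slots = sum(hi - len(term_to_genes[t]) for t in open_terms)
        if slots < len(orphans):
            raise ValueError("infeasible: not enough term capacity to cover all genes")
        i = 0
        for orphan in orphans:
            while len(term_to_genes[open_terms[i % len(open_terms)]]) >= hi:
                i += 1
            term_to_genes[open_terms[i % len(open_terms)]].add(orphan)
            i += 1

    return AnnotationUniverse(
        "synthetic", {t: frozenset(g) for t, g in term_to_genes.items()}
    )


def make_gene_list(
    universe: AnnotationUniverse, spec: SyntheticSpec
) -> tuple[GeneList, dict[str, int]]:
    """Sample the differential list with planted enrichment.

    Per-gene sampling weights are the product of the odds ratios of planted
    terms containing the gene (and of within-parent odds ratios for genes in
    a nested plant's child ∩ parent), so odds ratio 1 everywhere reduces to
    uniform sampling without replacement. Returns the list plus the
    ground-truth hit count of every planted and nested-child term.
    """
    rng = _rng(spec, 1)
    genes = sorted(universe.background)
    if spec.list_size > len(genes):
        raise ValueError("list_size exceeds number of genes in the universe")
    weights = np.ones(len(genes))
    index = {g: i for i, g in enumerate(genes)}
    for plant in spec.planted_terms:
        for g in universe.term_to_genes[plant.term]:
            weights[index[g]] *= plant.odds_ratio
    for nest in spec.nested_plants:
        core = universe.term_to_genes[nest.child] & universe.term_to_genes[nest.parent]
        for g in core:
            weights[index[g]] *= nest.within_parent_odds_ratio
    p = weights / weights.sum()
    chosen = rng.choice(len(genes), size=spec.list_size, replace=False, p=p)
    picked = [genes[i] for i in chosen]
    gene_list = GeneList.from_iterable(picked, source_label=spec.metadata())
    truth_terms = {pl.term for pl in spec.planted_terms} | {
        n.child for n in spec.nested_plants
    }
    truth = {
        t: len(gene_list.as_set() & universe.term_to_genes[t]) for t in truth_terms
    }
    return gene_list, truth


def make_differential_table(
    universe: AnnotationUniverse,
    spec: SyntheticSpec,
    boundary: float = 2.0,
    n_planted: int | None = None,
) -> tuple[DifferentialTable, int]:
    """Emulate a SAM-style summary table with a known signature pass count.

    ``n_planted`` rows (default: the spec's list size) drawn as in
    :func:`make_gene_list` get q-value 0 and |fold change| at or above
    ``boundary``; all other genes get |fold change| below 2 and a q-value in
    (0, 1]. With the default signature filter (q <= 0, |FC| >= 2) exactly the
    planted rows survive; the pass count is returned as ground truth.
    """
    if boundary < 2.0:
        raise ValueError("boundary must be >= 2 so planted rows pass the default filter")
    rng = _rng(spec, 2)
    genes = sorted(universe.background)
    n_planted = spec.list_size if n_planted is None else n_planted
    if n_planted > len(genes):
        raise ValueError("n_planted exceeds number of genes")
    planted: set[str] = set()
    if n_planted:
        planted_list, _ = make_gene_list(
            universe,
            SyntheticSpec(
                n_genes=spec.n_genes,
                n_terms=spec.n_terms,
                term_size_range=spec.term_size_range,
                planted_terms=spec.planted_terms,
                nested_plants=spec.nested_plants,
                list_size=n_planted,
                seed=spec.seed,
            ),
        )
        planted = set(planted_list.genes)
    rows = []
    for g in genes:
        if g in planted:
            fc = rng.uniform(boundary, boundary + 3)
            q = 0.0
        else:
            fc = rng.uniform(1.0, min(2.0, boundary) - 1e-9)
            q = float(rng.uniform(np.nextafter(0.0, 1.0), 1.0))
        sign = -1.0 if rng.random() < 0.5 else 1.0
        rows.append((g, abs(np.log2(fc)) * sign * 5, q, sign * fc))
    frame = pd.DataFrame(rows, columns=["feature_id", "score", "q_value", "fold_change"])
    return DifferentialTable(frame), len(planted)


# ---------------------------------------------------------------------------
# Writers (the formats the readers consume)
# ---------------------------------------------------------------------------

def write_gene_list(gene_list: GeneList, path: str | Path, metadata: str = "") -> None:
    with open(path, "w") as handle:
        if metadata:
            handle.write(f"# {metadata}\n")
        for gene in gene_list:
            handle.write(gene + "\n")


def write_differential_table(
    table: DifferentialTable, path: str | Path, metadata: str = ""
) -> None:
    with open(path, "w") as handle:
        if metadata:
            handle.write(f"# {metadata}\n")
        table.frame.to_csv(handle, sep="\t", index=False)


def write_ground_truth(
    spec: SyntheticSpec, truth: dict[str, int], path: str | Path
) -> None:
    payload = {
        "seed": spec.seed,
        "spec_digest": spec.digest(),
        "planted_terms": [
            {"term": p.term, "odds_ratio": p.odds_ratio} for p in spec.planted_terms
        ],
        "nested_plants": [
            {
                "parent": n.parent,
                "child": n.child,
                "within_parent_odds_ratio": n.within_parent_odds_ratio,
            }
            for n in spec.nested_plants
        ],
        "list_hits": truth,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
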