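"""Readers, writers and derivation of analysis-ready gene lists.

Supported external formats:

* GAF 2.x gene-association files (tab-separated, ``!`` comment lines;
  columns 2, 4, 5 and 9 — DB Object ID, Qualifier, GO ID, Aspect — are
  consumed, ``NOT``-qualified lines are skipped).
* GMT gene-set matrices (term, description, member genes).
* Plain two-column TSV ``gene<TAB>term``.
* One-identifier-per-line gene lists, optionally translated through a
  probeset→gene mapping TSV.
* Differential-expression summary tables (feature id, score, q-value,
  signed fold change) from which a gene signature is filtered.
* OBO 1.2/1.4 ontologies (via :mod:`obonet`) for term names, namespaces
  and the term graph used by descendant-restricted nesting.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "AnnotationUniverse",
    "GeneList",
    "DifferentialTable",
    "SignatureFilterConfig",
    "read_annotations",
    "read_gaf_universes",
    "write_gmt",
    "read_gene_list",
    "read_probeset_map",
    "read_ontology",
    "derive_signature",
]

#: GAF aspect code → category label used throughout outputs.
GAF_ASPECTS = {
    "P": "GO Biological Process",
    "F": "GO Molecular Function",
    "C": "GO Cellular Component",
}


class AnnotationError(ValueError):
    """Raised for malformed or empty annotation inputs."""


@dataclass
class AnnotationUniverse:
    """Gene↔term incidence for one annotation category.

    For a parsed universe the background is the union of all term gene
    sets: genes carrying no annotation in the category are invisible to it
    and take no part in either the population or the analysis list. A
    universe conditioned on a parent term instead carries the parent's full
    gene set as an explicit background, which may strictly contain the
    union of the intersected term sets.
    """

    category: str
    term_to_genes: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    background: frozenset[str] | None = None
    gene_to_terms: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.term_to_genes = {
            term: frozenset(genes) for term, genes in self.term_to_genes.items()
        }
        inverse: dict[str, set[str]] = defaultdict(set)
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise AnnotationError(f"term {term!r} has an empty gene set")
            for gene in genes:
                inverse[gene].add(term)
        self.gene_to_terms = {g: frozenset(ts) for g, ts in inverse.items()}
        union = frozenset(self.gene_to_terms)
        if self.background is None:
            self.background = union
        else:
            self.background = frozenset(self.background)
            if not union <= self.background:
                raise AnnotationError("background must contain every annotated gene")
        if not self.term_to_genes:
            raise AnnotationError(f"annotation category {self.category!r} is empty")

    # -- convenience accessors -------------------------------------------------
    @property
    def pop_size(self) -> int:
        """Number of genes with at least one annotation in this category."""
        return len(self.background)

    def pop_hits(self, term: str) -> int:
        """Number of background genes annotated to ``term``."""
        return len(self.term_to_genes[term])

    def name_of(self, term: str) -> str:
        return self.term_names.get(term, term)

    def __contains__(self, term: str) -> bool:
        return term in self.term_to_genes

    def __len__(self) -> int:
        return len(self.term_to_genes)


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of gene identifiers."""

    genes: tuple[str, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise AnnotationError("gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise AnnotationError("gene list contains duplicates")

    @classmethod
    def from_iterable(cls, genes: Iterable[str], source_label: str = "") -> "GeneList":
        """Build a list keeping first-appearance order and dropping duplicates."""
        return cls(tuple(dict.fromkeys(genes)), source_label)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class DifferentialTable:
    """Summary-level differential-expression results.

    One row per feature (probeset or gene) with a test score, a q-value in
    [0, 1] and a signed fold change whose sign encodes direction and whose
    magnitude is the expression ratio. This is an input contract: the table
    is consumed by :func:`derive_signature`, never recomputed here.
    """

    frame: pd.DataFrame

    COLUMNS = ("feature_id", "score", "q_value", "fold_change")
    _ALIASES = {
        "id": "feature_id",
        "feature": "feature_id",
        "probeset": "feature_id",
        "gene": "feature_id",
        "qvalue": "q_value",
        "q": "q_value",
        "fc": "fold_change",
        "foldchange": "fold_change",
    }

    def __post_init__(self) -> None:
        frame = self.frame.rename(
            columns=lambda c: self._ALIASES.get(str(c).strip().lower(), str(c).strip().lower())
        )
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise AnnotationError(f"differential table lacks columns: {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if frame.empty:
            raise AnnotationError("differential table has no rows")
        q = frame["q_value"].astype(float)
        fc = frame["fold_change"].astype(float)
        import numpy as np

        if ((q < 0) | (q > 1)).any():
            raise AnnotationError("q_value outside [0, 1]")
        if (~np.isfinite(fc)).any() or (fc == 0).any():
            raise AnnotationError("fold_change must be finite and non-zero")
        self.frame = frame

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DifferentialTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class SignatureFilterConfig:
    """Thresholds reducing a differential table to a gene signature.

    Defaults keep features called at a 0% false-discovery rate whose
    absolute fold change is at least 2 (inclusive); ``strict_inequality``
    switches the fold-change comparison to strictly-greater-than.
    """

    max_q: float = 0.0
    min_abs_fold_change: float = 2.0
    strict_inequality: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_q <= 1.0:
            raise ValueError("max_q must lie in [0, 1]")
        if self.min_abs_fold_change < 1.0:
            raise ValueError("min_abs_fold_change must be >= 1")


# ---------------------------------------------------------------------------
# Annotation readers
# ---------------------------------------------------------------------------

def _fold(identifier: str, fold_case: bool) -> str:
    return identifier.upper() if fold_case else identifier


def read_annotations(
    path: str | Path,
    format: str = "gmt",
    category_filter: str | None = None,
    fold_case: bool = False,
) -> AnnotationUniverse:
    """Read a gene→term annotation source into one :class:`AnnotationUniverse`.

    ``format`` is one of ``gaf``, ``gmt`` or ``tsv2col``. For GAF input the
    aspect column selects the category: pass ``category_filter`` as an
    aspect code (``P``/``F``/``C``) or its long label; without a filter all
    aspects are pooled into a single universe labelled ``GO``.
    """
    path = Path(path)
    if format == "gaf":
        universes = read_gaf_universes(path, fold_case=fold_case)
        if category_filter is None:
            pooled: dict[str, frozenset[str]] = {}
            names: dict[str, str] = {}
            for u in universes.values():
                pooled.update(u.term_to_genes)
                names.update(u.term_names)
            return AnnotationUniverse("GO", pooled, names)
        label = GAF_ASPECTS.get(category_filter, category_filter)
        for u in universes.values():
            if u.category == label:
                return u
        raise AnnotationError(
            f"no annotations for category {category_filter!r} in {path}"
        )
    if format == "gmt":
        return _read_gmt(path, category_filter or "gene sets", fold_case)
    if format in ("tsv2col", "tsv"):
        return _read_tsv2col(path, category_filter or "annotations", fold_case)
    raise AnnotationError(f"unknown annotation format {format!r}")


def _read_gmt(path: Path, category: str, fold_case: bool) -> AnnotationUniverse:
    term_to_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
                )
            term, description, *genes = fields
            genes = [_fold(g, fold_case) for g in genes if g]
            if not genes:
                raise AnnotationError(f"{path}:{lineno}: GMT line has no genes")
            term_to_genes.setdefault(term, set()).update(genes)
            if description and description not in ("na", "NA", "-"):
                term_names[term] = description
    if not term_to_genes:
        raise AnnotationError(f"{path}: no gene sets parsed")
    return AnnotationUniverse(category, {t: frozenset(g) for t, g in term_to_genes.items()}, term_names)


def _read_tsv2col(path: Path, category: str, fold_case: bool) -> AnnotationUniverse:
    term_to_genes: dict[str, set[str]] = defaultdict(set)
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise AnnotationError(
                    f"{path}:{lineno}: expected exactly 'gene<TAB>term'"
                )
            gene, term = fields
            term_to_genes[term].add(_fold(gene, fold_case))
    if not term_to_genes:
        raise AnnotationError(f"{path}: no annotations parsed")
    return AnnotationUniverse(category, {t: frozenset(g) for t, g in term_to_genes.items()})


def read_gaf_universes(
    path: str | Path, fold_case: bool = False
) -> dict[str, AnnotationUniverse]:
    """Read a GAF 2.x file into one universe per aspect present.

    Returns a mapping from aspect code (``P``/``F``/``C``) to universe.
    ``NOT``-qualified association lines are skipped.
    """
    path = Path(path)
    per_aspect: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    names: dict[str, dict[str, str]] = defaultdict(dict)
    n_lines = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise AnnotationError(
                    f"{path}:{lineno}: GAF line has {len(fields)} columns, expected >=15"
                )
            qualifier, go_id, aspect = fields[3], fields[4], fields[8]
            gene = _fold(fields[1], fold_case)
            if "NOT" in qualifier.split("|"):
                continue
            if aspect not in GAF_ASPECTS:
                raise AnnotationError(f"{path}:{lineno}: unknown GAF aspect {aspect!r}")
            if not gene or not go_id:
                raise AnnotationError(f"{path}:{lineno}: missing gene or term id")
            per_aspect[aspect][go_id].add(gene)
            if fields[9]:
                names[aspect][go_id] = fields[9]
            n_lines += 1
    if n_lines == 0:
        raise AnnotationError(f"{path}: no associations parsed")
    return {
        aspect: AnnotationUniverse(
            GAF_ASPECTS[aspect],
            {t: frozenset(g) for t, g in terms.items()},
            names[aspect],
        )
        for aspect, terms in per_aspect.items()
    }


def write_gmt(universe: AnnotationUniverse, path: str | Path, metadata: str | None = None) -> None:
    """Write a universe as GMT; genes within a term are sorted for stability."""
    with open(path, "w") as handle:
        if metadata:
            handle.write(f"# {metadata}\n")
        for term in sorted(universe.term_to_genes):
            genes = sorted(universe.term_to_genes[term])
            desc = universe.term_names.get(term, term)
            handle.write("\t".join([term, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Gene lists & signatures
# ---------------------------------------------------------------------------

def read_probeset_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``probeset<TAB>gene`` mapping."""
    mapping: dict[str, str] = {}
    path = Path(path)
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise AnnotationError(f"{path}:{lineno}: expected 'probeset<TAB>gene'")
            mapping[fields[0]] = fields[1]
    return mapping


def read_gene_list(
    path: str | Path,
    probeset_map: Mapping[str, str] | None = None,
    fold_case: bool = False,
) -> GeneList:
    """Read one identifier per line, optionally collapsing probesets to genes.

    Many-probesets-to-one-gene collisions collapse to a single entry at the
    position of first appearance. Probesets absent from the map are dropped
    (counted and logged), never fatal.
    """
    path = Path(path)
    identifiers: list[str] = []
    unmapped = 0
    with open(path) as handle:
        for raw in handle:
            token = raw.strip()
            if not token or token.startswith("#"):
                continue
            if probeset_map is not None:
                if token not in probeset_map:
                    unmapped += 1
                    continue
                token = probeset_map[token]
            identifiers.append(_fold(token, fold_case))
    if unmapped:
        logger.info("%d unmapped probesets dropped from %s", unmapped, path)
    if not identifiers:
        raise AnnotationError(f"{path}: no identifiers read")
    return GeneList.from_iterable(identifiers, source_label=str(path))


def derive_signature(
    table: DifferentialTable, config: SignatureFilterConfig | None = None
) -> GeneList:
    """Filter a differential table to the gene signature passing thresholds.

    A row survives when ``q_value <= max_q`` and its absolute fold change
    clears ``min_abs_fold_change`` (inclusive by default, exclusive when
    ``strict_inequality`` is set).
    """
    config = config or SignatureFilterConfig()
    frame = table.frame
    abs_fc = frame["fold_change"].abs()
    if config.strict_inequality:
        fc_pass = abs_fc > config.min_abs_fold_change
    else:
        fc_pass = abs_fc >= config.min_abs_fold_change
    keep = frame.loc[(frame["q_value"] <= config.max_q) & fc_pass, "feature_id"]
    if keep.empty:
        raise AnnotationError(
            "no features pass the signature filter; relax max_q or "
            "min_abs_fold_change"
        )
    return GeneList.from_iterable(keep.astype(str), source_label="signature")


def read_ontology(path: str | Path):
    """Read an OBO file; returns ``(graph, term_names, term_namespaces)``.

    The graph is the :mod:`obonet` convention: a directed edge points from a
    term to its ``is_a`` parent, so the descendants of a term ``t`` are
    ``networkx.ancestors(graph, t)``.
    """
    import obonet

    graph = obonet.read_obo(path)
    names = {n: d["name"] for n, d in graph.nodes(data=True) if "name" in d}
    namespaces = {n: d["namespace"] for n, d in graph.nodes(data=True) if "namespace" in d}
    return graph, names, namespaces
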