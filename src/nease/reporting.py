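"""Table rendering and run manifests.

P-values render at two significant figures in scientific notation, either
ASCII (``2.1e-09``, default) or the glyph dialect used in print tables
(``2.1×10^−9``, with a true minus sign). Derived enrichment statistics
render at two decimals. Output tables reproduce the published headers
column for column.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable

from .enrichment_core import EnrichmentResult
from .nease_engine import NestedResult

__all__ = [
    "format_p",
    "parse_p",
    "format_fixed",
    "write_ease_tsv",
    "write_nease_tsv",
    "write_manifest",
    "EASE_HEADER",
    "NEASE_HEADER",
]

EASE_HEADER = (
    "Accession Type", "Accession Number", "Accession Term",
    "List Hits", "List Size", "Pop. Hits", "Pop. Size",
    "Fisher's Exact", "Corrected P Value",
)
NEASE_HEADER = (
    "nEASE Term", "List Hits", "List Size", "Pop. Hits", "Pop. Size",
    "Fisher's Exact", "Gene Enrich", "nEASE pvalue Diff", "nEASE Gene Enrich",
    "% Gene Enrich", "EASE Term",
)
#: Columns whose definitions are candidate interpretations, flagged in output.
CANDIDATE_COLUMNS = ("nEASE pvalue Diff", "nEASE Gene Enrich")

_MINUS = "−"
_GLYPH_RE = re.compile(r"^([0-9.]+)×10\^([−\-+]?)(\d+)\^?$")


def format_p(p: float, glyphs: bool = False) -> str:
    """Render a probability at two significant figures.

    ``glyphs=False`` gives ASCII e-notation (``2.1e-09``); ``glyphs=True``
    gives the print-table dialect ``2.1×10^−9``.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    ascii_form = f"{p:.1e}"
    if not glyphs:
        return ascii_form
    mantissa, exponent = ascii_form.split("e")
    exp = int(exponent)
    sign = _MINUS if exp < 0 else ""
    return f"{mantissa}×10^{sign}{abs(exp)}"


def parse_p(text: str) -> float:
    """Parse either rendering dialect back to a float."""
    text = text.strip()
    match = _GLYPH_RE.match(text)
    if match:
        mantissa, sign, exp = match.groups()
        factor = -1 if sign in (_MINUS, "-") else 1
        return float(mantissa) * 10.0 ** (factor * int(exp))
    return float(text)


def format_fixed(value: float) -> str:
    return f"{value:.2f}"


def write_ease_tsv(
    results: Iterable[EnrichmentResult], path: str | Path, glyphs: bool = False
) -> None:
    """Write upper-level results in the published nine-column layout."""
    with open(path, "w") as handle:
        handle.write("\t".join(EASE_HEADER) + "\n")
        for r in results:
            c = r.counts
            handle.write(
                "\t".join(
                    [
                        r.category,
                        r.term,
                        r.term_name,
                        str(c.list_hits),
                        str(c.list_size),
                        str(c.pop_hits),
                        str(c.pop_size),
                        format_p(r.fisher_p, glyphs),
                        format_p(r.corrected_p, glyphs),
                    ]
                )
                + "\n"
            )


def write_nease_tsv(
    results: Iterable[NestedResult], path: str | Path, glyphs: bool = False
) -> None:
    """Write nested results in the published eleven-column layout.

    A leading comment line flags the candidate-interpretation columns.
    """
    with open(path, "w") as handle:
        handle.write(
            "# candidate-interpretation columns (definitions not fixed by the "
            "published legend): " + ", ".join(CANDIDATE_COLUMNS) + "\n"
        )
        handle.write("\t".join(NEASE_HEADER) + "\n")
        for r in results:
            c = r.counts
            handle.write(
                "\t".join(
                    [
                        r.nested_name,
                        str(c.list_hits),
                        str(c.list_size),
                        str(c.pop_hits),
                        str(c.pop_size),
                        format_p(r.fisher_p, glyphs),
                        format_fixed(r.gene_enrich),
                        format_fixed(r.pvalue_log_diff),
                        format_fixed(r.nease_gene_enrich),
                        format_fixed(r.pct_gene_enrich),
                        r.parent_name,
                    ]
                )
                + "\n"
            )


def write_manifest(path: str | Path, payload: dict) -> None:
    """Write a machine-readable record sufficient to reproduce a run."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        payload = {"nease_version": version("nease"), **payload}
    except PackageNotFoundError:
        pass
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
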