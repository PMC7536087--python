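"""Pairwise co-annotation matrices over a term list.

For a list of GO terms, the co-annotation matrix holds, in cell (i, j), the
number of gene products annotated (directly or by transitivity) to both
term i and term j.  The diagonal is each term's total annotated gene count.
Small off-diagonal cells are the curation signal: gene products co-annotated
to biologically unrelated processes usually indicate an annotation,
mapping or ontology error.  Gene sets behind each cell are kept for
drill-down by default; a low-memory mode keeps the counts only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from .annotations import AnnotationIndex
from .errors import CoannoQCError

__all__ = [
    "CoannotationMatrix",
    "intersection_genes",
    "build_matrix",
    "export_matrix",
    "matrix_from_json",
]


@dataclass
class CoannotationMatrix:
    """Symmetric grid of pairwise co-annotation counts.

    ``counts`` is row-major in the input term order.  ``gene_sets`` keys
    cells by the ordered term pair ``(terms[i], terms[j])`` with i <= j;
    it is empty when the matrix was built with ``keep_gene_sets=False``.
    """

    terms: list[str]
    counts: list[list[int]]
    gene_sets: dict[tuple[str, str], frozenset[str]] = field(
        default_factory=dict
    )

    def cell(self, t1: str, t2: str) -> int:
        i, j = self.terms.index(t1), self.terms.index(t2)
        return self.counts[i][j]

    def genes(self, t1: str, t2: str) -> frozenset[str]:
        i, j = self.terms.index(t1), self.terms.index(t2)
        if i > j:
            i, j = j, i
        return self.gene_sets[(self.terms[i], self.terms[j])]


def intersection_genes(
    index: AnnotationIndex, t1: str, t2: str
) -> frozenset[str]:
    """Gene products annotated to both ``t1`` and ``t2`` (closure semantics).

    A gene lands here either by carrying two separate annotations or by a
    single annotation to a common descendant of both terms — the latter is
    one of the legitimate ways otherwise-exclusive terms share genes.
    """
    return index.genes_at(t1) & index.genes_at(t2)


def build_matrix(
    index: AnnotationIndex,
    terms: list[str],
    keep_gene_sets: bool = True,
) -> CoannotationMatrix:
    """Compute all pairwise intersection counts for ``terms``.

    Terms must be unique (a duplicated id raises) and known to the index's
    closure.  Cells are symmetric by construction; only the upper triangle
    is intersected.
    """
    if not terms:
        raise CoannoQCError("term list must be non-empty")
    dupes = {t for t in terms if terms.count(t) > 1}
    if dupes:
        raise CoannoQCError(
            "duplicate term(s) in matrix term list: " + ", ".join(sorted(dupes))
        )
    n = len(terms)
    gene_lists = [index.genes_at(t) for t in terms]  # validates term ids
    counts = [[0] * n for _ in range(n)]
    gene_sets: dict[tuple[str, str], frozenset[str]] = {}
    for i in range(n):
        for j in range(i, n):
            shared = gene_lists[i] & gene_lists[j]
            counts[i][j] = counts[j][i] = len(shared)
            if keep_gene_sets:
                gene_sets[(terms[i], terms[j])] = shared
    return CoannotationMatrix(list(terms), counts, gene_sets)


def export_matrix(
    m: CoannotationMatrix, format: str = "tsv", include_gene_sets: bool = False
) -> str:
    """Serialise a matrix to ``tsv`` or ``json`` text.

    TSV: a header row of term ids, then one row per term (row label first).
    JSON: ``{"terms": [...], "counts": [[...]]}`` plus, on request, gene
    sets serialised lexicographically for reproducible diffs.  JSON exports
    round-trip losslessly for counts via :func:`matrix_from_json`.
    """
    if format == "tsv":
        lines = ["\t".join(["term"] + m.terms)]
        for term, row in zip(m.terms, m.counts):
            lines.append("\t".join([term] + [str(c) for c in row]))
        return "\n".join(lines) + "\n"
    if format == "json":
        doc: dict = {"terms": m.terms, "counts": m.counts}
        if include_gene_sets:
            doc["gene_sets"] = {
                f"{a}|{b}": sorted(genes)
                for (a, b), genes in sorted(m.gene_sets.items())
            }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    raise CoannoQCError(f"unknown matrix export format: {format!r}")


def matrix_from_json(text: str) -> CoannotationMatrix:
    """Inverse of :func:`export_matrix` for the JSON format."""
    doc: Mapping = json.loads(text)
    gene_sets = {}
    for key, genes in doc.get("gene_sets", {}).items():
        a, b = key.split("|", 1)
        gene_sets[(a, b)] = frozenset(genes)
    return CoannotationMatrix(
        terms=list(doc["terms"]),
        counts=[list(row) for row in doc["counts"]],
        gene_sets=gene_sets,
    )
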