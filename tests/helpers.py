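"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's closure table, annotation index and
rule engine: reachability is a plain DFS over the raw edge list, the index
oracle is a quadratic gene x term scan, and the violation oracle re-derives
each gene's reachable-term set from its direct annotations.
"""

from __future__ import annotations

from collections import defaultdict

from coannoqc.annotations import Annotation
from coannoqc.ontology import OntologyGraph


def brute_ancestors(
    graph: OntologyGraph, term: str, relations: frozenset[str]
) -> set[str]:
    """Reflexive reachability by explicit DFS over the raw edge list."""
    adj: dict[str, set[str]] = defaultdict(set)
    for e in graph.edges:
        if e.relation in relations:
            adj[e.child].add(e.parent)
    seen = {term}
    stack = [term]
    while stack:
        node = stack.pop()
        for parent in adj[node]:
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen


def brute_index(
    anns: list[Annotation],
    graph: OntologyGraph,
    relations: frozenset[str],
) -> dict[str, set[str]]:
    """Quadratic scan: for every term, test closure membership of every
    annotation's direct term."""
    anc_cache: dict[str, set[str]] = {}
    live = [t.id for t in graph.terms.values() if not t.is_obsolete]
    out: dict[str, set[str]] = {t: set() for t in live}
    for a in anns:
        if a.negated:
            continue
        if a.term not in anc_cache:
            anc_cache[a.term] = brute_ancestors(graph, a.term, relations)
        for t in anc_cache[a.term]:
            out[t].add(a.gene.id)
    return out


def brute_violations(
    rules,
    anns: list[Annotation],
    graph: OntologyGraph,
    relations: frozenset[str],
    family_map: dict[str, str] | None = None,
) -> set[tuple[str, str, str]]:
    """Exhaustive gene x rule scan, independent of the rule engine.

    Returns (term1, term2, gene) triples.  Taxon exceptions are matched on
    the numeric suffix, mirroring the documented CURIE handling.
    """
    reach: dict[str, set[str]] = defaultdict(set)
    taxa: dict[str, str] = {}
    anc_cache: dict[str, set[str]] = {}
    for a in anns:
        if a.negated:
            continue
        if a.term not in anc_cache:
            anc_cache[a.term] = brute_ancestors(graph, a.term, relations)
        reach[a.gene.id] |= anc_cache[a.term]
        taxa[a.gene.id] = a.gene.taxon
    out: set[tuple[str, str, str]] = set()
    for rule in rules:
        for gene, terms in reach.items():
            if rule.term1 not in terms or rule.term2 not in terms:
                continue
            if any(e in terms for e in rule.excepted_terms):
                continue
            if gene in rule.excepted_entities:
                continue
            if family_map and family_map.get(gene) in rule.excepted_entities:
                continue
            taxon = taxa.get(gene, "")
            if taxon and any(
                ":" in e
                and e.split(":", 1)[0] in ("NCBITaxon", "taxon")
                and e.split(":", 1)[1] == taxon.split(":", 1)[-1]
                for e in rule.excepted_entities
            ):
                continue
            out.add((rule.term1, rule.term2, gene))
    return out
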