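"""Gene Ontology graph loading and relation-filtered transitive closures.

The ontology is read from OBO 1.2 flat-file text in the *go-basic* dialect:
``[Term]`` stanzas carrying ``id``, ``name``, ``namespace``, ``alt_id``,
``is_a``, ``relationship``, ``is_obsolete`` and ``replaced_by`` tags.  The
loaded graph is a directed multigraph whose edges point from child to parent
and carry a relation label (``is_a``, ``part_of``, ``regulates``, ...).

Annotation propagation in GO is *relation-filtered reachability*: a term's
ancestors under a relation set R are all terms reachable along directed
paths whose every edge label belongs to R.  Two presets mirror standard GO
practice: :data:`DEFAULT_RELATIONS` (``is_a`` + ``part_of``) and
:data:`WITH_REGULATES`, which additionally traverses the three regulation
relations.  This is a deliberate approximation of the OWL semantics of GO:
property chains such as ``regulates o part_of`` are not composed; every edge
on a path must itself carry an allowed label.
"""

from __future__ import annotations

import io
import logging
import re
from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx

from .errors import (
    OboParseError,
    ObsoleteTermError,
    OntologyCycleError,
    UnknownTermError,
)

logger = logging.getLogger(__name__)

GO_CURIE_RE = re.compile(r"^GO:\d{7}$")

#: Relation labels the loader recognises.  Anything else is preserved as
#: ``other`` and never traversed.
KNOWN_RELATIONS = frozenset(
    {
        "is_a",
        "part_of",
        "regulates",
        "positively_regulates",
        "negatively_regulates",
        "occurs_in",
    }
)

#: Default traversal preset: the two transitive relations annotations are
#: always propagated over.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

REGULATES_RELATIONS = frozenset(
    {"regulates", "positively_regulates", "negatively_regulates"}
)

#: Traversal preset that also follows the regulation relations.
WITH_REGULATES = DEFAULT_RELATIONS | REGULATES_RELATIONS

RELATION_PRESETS: Mapping[str, frozenset[str]] = {
    "default": DEFAULT_RELATIONS,
    "with-regulates": WITH_REGULATES,
}


@dataclass(frozen=True)
class Term:
    """A single ontology class.

    ``alt_ids`` are merged/secondary identifiers that resolve to this term.
    Obsolete terms are retained for diagnostics but carry no edges and do
    not participate in closures.
    """

    id: str
    name: str = ""
    namespace: str = ""
    alt_ids: frozenset[str] = frozenset()
    is_obsolete: bool = False
    replaced_by: str | None = None


@dataclass(frozen=True)
class OntologyEdge:
    """A directed, labelled child -> parent relationship."""

    child: str
    parent: str
    relation: str


class OntologyGraph:
    """Typed directed multigraph of GO terms.

    Attributes
    ----------
    terms:
        Primary id -> :class:`Term`, including obsolete terms.
    edges:
        All loaded edges (endpoints are non-obsolete primary ids).
    alt_index:
        alt_id -> primary id.
    """

    def __init__(
        self,
        terms: Mapping[str, Term],
        edges: Iterable[OntologyEdge],
        alt_index: Mapping[str, str] | None = None,
    ):
        self.terms: dict[str, Term] = dict(terms)
        self.edges: list[OntologyEdge] = list(edges)
        if alt_index is None:
            alt_index = {
                alt: t.id for t in self.terms.values() for alt in t.alt_ids
            }
        self.alt_index: dict[str, str] = dict(alt_index)
        g = nx.MultiDiGraph()
        g.add_nodes_from(t.id for t in self.terms.values() if not t.is_obsolete)
        for e in self.edges:
            g.add_edge(e.child, e.parent, relation=e.relation)
        self._nx = g

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_index

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str, follow_replaced_by: bool = False) -> str:
        """Map a primary or alt id to its primary id.

        With ``follow_replaced_by``, an obsolete term that names a
        replacement resolves (transitively) to that replacement; without it,
        obsolete ids resolve to themselves and callers that need a live term
        must raise.
        """
        seen: set[str] = set()
        current = term_id
        while True:
            if current in self.alt_index:
                current = self.alt_index[current]
            if current not in self.terms:
                raise UnknownTermError(f"unknown term id: {term_id!r}")
            term = self.terms[current]
            if follow_replaced_by and term.is_obsolete and term.replaced_by:
                if current in seen:  # replaced_by loop: give up
                    raise ObsoleteTermError(
                        f"cyclic replaced_by chain at {current}"
                    )
                seen.add(current)
                current = term.replaced_by
                continue
            return current

    def parents(self, term_id: str, relations: frozenset[str]) -> set[str]:
        """Direct parents of a (primary, non-obsolete) id reachable over
        one edge with an allowed label."""
        traversable = frozenset(relations) - {"other"}
        out: set[str] = set()
        for _, parent, data in self._nx.out_edges(term_id, data=True):
            if data["relation"] in traversable:
                out.add(parent)
        return out

    def subgraph_edges(
        self, relations: frozenset[str]
    ) -> Iterator[tuple[str, str]]:
        """(child, parent) pairs whose label is in ``relations``."""
        traversable = frozenset(relations) - {"other"}
        for e in self.edges:
            if e.relation in traversable:
                yield (e.child, e.parent)

    def _require_live(self, term_id: str, follow_replaced_by: bool) -> str:
        primary = self.resolve(term_id, follow_replaced_by=follow_replaced_by)
        term = self.terms[primary]
        if term.is_obsolete:
            raise ObsoleteTermError(
                f"term {primary} is obsolete and has no replaced_by target"
                if not term.replaced_by
                else f"term {primary} is obsolete; pass follow_replaced_by=True "
                f"to redirect to {term.replaced_by}"
            )
        return primary


@dataclass(frozen=True)
class ClosureTable:
    """Reflexive term -> ancestor-set map under a fixed relation set.

    Precomputing the closure turns every pairwise intersection query into
    set operations over already-propagated gene sets; it is the backbone of
    fast co-annotation counting.
    """

    relation_set: frozenset[str]
    ancestors: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def lookup(self, term_id: str) -> frozenset[str]:
        try:
            return self.ancestors[term_id]
        except KeyError:
            raise UnknownTermError(
                f"term {term_id!r} not present in closure table"
            ) from None

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ancestors

    def to_tsv(self) -> str:
        """Debug dump: one ``term<TAB>ancestor`` row per closure pair."""
        lines = ["term\tancestor"]
        for term in sorted(self.ancestors):
            for anc in sorted(self.ancestors[term]):
                lines.append(f"{term}\t{anc}")
        return "\n".join(lines) + "\n"


def _iter_lines(stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from io.StringIO(stream)
    else:
        yield from stream


_TAG_RE = re.compile(r"^([A-Za-z_]+):\s*(.*)$")


def _strip_obo_comment(value: str) -> str:
    # OBO trailing comments start with " ! "; a bare "!" inside quoted text
    # is not expected for the tags we read.
    idx = value.find("!")
    if idx >= 0:
        value = value[:idx]
    return value.strip()


def _check_curie(curie: str, line_no: int) -> str:
    if not GO_CURIE_RE.match(curie):
        raise OboParseError(f"malformed GO CURIE: {curie!r}", line_no)
    return curie


def parse_obo(stream: str | IO[str] | Iterable[str]) -> OntologyGraph:
    """Parse OBO 1.2 text (go-basic dialect) into an :class:`OntologyGraph`.

    Only the tags listed in the module docstring are interpreted; all other
    tags, header lines and non-``[Term]`` stanzas are ignored.  Unknown
    relationship labels are mapped to ``other`` (logged once per label) and
    never traversed.  Edges incident to obsolete terms are dropped so that
    obsolete terms never appear in closures.

    Raises
    ------
    OboParseError
        On a malformed CURIE (with the offending line number) or an edge
        whose target term is never declared.
    """
    stanzas: list[dict] = []
    current: dict | None = None
    in_term = False
    for line_no, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            current = {"_line": line_no} if in_term else None
            if in_term:
                stanzas.append(current)
            continue
        if not in_term or current is None:
            continue
        m = _TAG_RE.match(line)
        if not m:
            continue
        tag, value = m.group(1), m.group(2)
        if tag == "id":
            current["id"] = _check_curie(_strip_obo_comment(value), line_no)
        elif tag == "name":
            current["name"] = value.strip()
        elif tag == "namespace":
            current["namespace"] = value.strip()
        elif tag == "alt_id":
            current.setdefault("alt_ids", []).append(
                _check_curie(_strip_obo_comment(value), line_no)
            )
        elif tag == "is_obsolete":
            current["is_obsolete"] = _strip_obo_comment(value) == "true"
        elif tag == "replaced_by":
            current["replaced_by"] = _check_curie(
                _strip_obo_comment(value), line_no
            )
        elif tag == "is_a":
            parent = _check_curie(_strip_obo_comment(value), line_no)
            current.setdefault("edges", []).append(("is_a", parent, line_no))
        elif tag == "relationship":
            parts = _strip_obo_comment(value).split()
            if len(parts) != 2:
                raise OboParseError(
                    f"malformed relationship line: {value!r}", line_no
                )
            rel, parent = parts
            _check_curie(parent, line_no)
            current.setdefault("edges", []).append((rel, parent, line_no))
        # every other tag (def, synonym, xref, subset, ...) is ignored

    terms: dict[str, Term] = {}
    alt_index: dict[str, str] = {}
    unknown_rels_seen: set[str] = set()
    edge_specs: list[tuple[str, str, str, int]] = []  # child, rel, parent, line

    for stanza in stanzas:
        if "id" not in stanza:
            raise OboParseError("[Term] stanza without id", stanza["_line"])
        tid = stanza["id"]
        if tid in terms:
            raise OboParseError(f"duplicate term id {tid}", stanza["_line"])
        term = Term(
            id=tid,
            name=stanza.get("name", ""),
            namespace=stanza.get("namespace", ""),
            alt_ids=frozenset(stanza.get("alt_ids", [])),
            is_obsolete=stanza.get("is_obsolete", False),
            replaced_by=stanza.get("replaced_by"),
        )
        terms[tid] = term
        for alt in term.alt_ids:
            alt_index[alt] = tid
        for rel, parent, line_no in stanza.get("edges", []):
            edge_specs.append((tid, rel, parent, line_no))

    edges: list[OntologyEdge] = []
    dangling: list[str] = []
    for child, rel, parent, line_no in edge_specs:
        if parent not in terms and parent not in alt_index:
            dangling.append(parent)
            continue
        parent_primary = alt_index.get(parent, parent)
        if terms[child].is_obsolete or terms[parent_primary].is_obsolete:
            logger.debug(
                "dropping edge %s -%s-> %s incident to an obsolete term",
                child,
                rel,
                parent_primary,
            )
            continue
        if rel not in KNOWN_RELATIONS:
            if rel not in unknown_rels_seen:
                unknown_rels_seen.add(rel)
                logger.warning(
                    "unknown relationship label %r mapped to 'other' "
                    "(never traversed)",
                    rel,
                )
            rel = "other"
        edges.append(OntologyEdge(child, parent_primary, rel))
    if dangling:
        raise OboParseError(
            "edges reference undeclared term id(s): "
            + ", ".join(sorted(set(dangling)))
        )

    graph = OntologyGraph(terms, edges, alt_index)
    _check_acyclic(graph, DEFAULT_RELATIONS)
    return graph


def _check_acyclic(graph: OntologyGraph, relations: frozenset[str]) -> None:
    sub = nx.DiGraph(graph.subgraph_edges(relations))
    try:
        cycle = nx.find_cycle(sub)
    except nx.NetworkXNoCycle:
        return
    path = " -> ".join(a for a, _ in cycle) + f" -> {cycle[-1][1]}"
    raise OntologyCycleError(
        f"cycle among {{{', '.join(sorted(relations))}}} edges: {path}"
    )


def ancestors(
    graph: OntologyGraph,
    term: str,
    relations: frozenset[str] = DEFAULT_RELATIONS,
    follow_replaced_by: bool = False,
) -> frozenset[str]:
    """Reflexive ancestor set of ``term`` under label-filtered reachability.

    ``term`` may be a primary or alt id; the result is keyed on primary ids
    and always contains the (resolved) term itself.  An obsolete id raises
    :class:`ObsoleteTermError` unless ``follow_replaced_by`` redirects it to
    a live replacement.
    """
    start = graph._require_live(term, follow_replaced_by)
    out: set[str] = {start}
    queue: deque[str] = deque([start])
    while queue:
        node = queue.popleft()
        for parent in graph.parents(node, relations):
            if parent not in out:
                out.add(parent)
                queue.append(parent)
    return frozenset(out)


def build_closure(
    graph: OntologyGraph, relations: frozenset[str] = DEFAULT_RELATIONS
) -> ClosureTable:
    """Precompute reflexive ancestor sets for every non-obsolete term.

    Runs a single reverse-topological dynamic program over the subgraph of
    traversable edges, so the table is equivalent to calling
    :func:`ancestors` per term but much cheaper.  Raises
    :class:`OntologyCycleError` if the traversable subgraph is cyclic.
    """
    relations = frozenset(relations)
    live = [t.id for t in graph.terms.values() if not t.is_obsolete]
    sub = nx.DiGraph()
    sub.add_nodes_from(live)
    sub.add_edges_from(graph.subgraph_edges(relations))
    _check_acyclic(graph, relations)

    table: dict[str, frozenset[str]] = {}
    # Process parents before children: reverse topological order of the
    # child->parent DAG is a plain topological order on reversed edges.
    for node in reversed(list(nx.topological_sort(sub))):
        acc: set[str] = {node}
        for _, parent in sub.out_edges(node):
            acc |= table[parent]
        table[node] = frozenset(acc)
    return ClosureTable(relation_set=relations, ancestors=table)
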