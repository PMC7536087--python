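from __future__ import annotations

from dataclasses import dataclass

import pytest

from coannoqc import (
    DEFAULT_RELATIONS,
    AnnotationIndex,
    ClosureTable,
    OntologyGraph,
    Rule,
    build_closure,
    build_index,
    parse_gaf,
    parse_obo,
    parse_rules,
)
from coannoqc.fixtures import FixtureSpec, demo_fixture, generate_fixture


@dataclass
class Corpus:
    """A parsed fixture triple plus the derived closure and index."""

    obo: str
    gaf: str
    rules_text: str
    graph: OntologyGraph
    closure: ClosureTable
    index: AnnotationIndex
    rules: list[Rule]
    annotations: list

    @classmethod
    def load(cls, obo: str, gaf: str, rules_text: str,
             relations=DEFAULT_RELATIONS) -> "Corpus":
        graph = parse_obo(obo)
        closure = build_closure(graph, relations)
        anns = parse_gaf(gaf, ontology=graph)
        return cls(
            obo=obo,
            gaf=gaf,
            rules_text=rules_text,
            graph=graph,
            closure=closure,
            index=build_index(anns, closure),
            rules=parse_rules(rules_text),
            annotations=anns,
        )


@pytest.fixture(scope="session")
def demo() -> Corpus:
    """The hand-written demo corpus under the default relation set."""
    return Corpus.load(*demo_fixture())


def random_corpus(seed: int, n_terms: int = 60, n_genes: int = 40,
                  relations=DEFAULT_RELATIONS, **kw) -> Corpus:
    """A generated corpus with two planted overlaps, varied by seed."""
    spec = FixtureSpec(
        n_terms=n_terms,
        n_genes=n_genes,
        planted_overlaps=kw.pop(
            "planted_overlaps",
            [
                ("GO:9100001", "GO:9100002", 3, 4, 2),
                ("GO:9100003", "GO:9100004", 0, 3, 3),
            ],
        ),
        seed=seed,
        **kw,
    )
    return Corpus.load(*generate_fixture(spec), relations=relations)
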