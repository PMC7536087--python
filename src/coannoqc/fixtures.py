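"""Synthetic ontology / annotation / rule fixtures.

Real GO releases and annotation corpora are large, versioned and external.
This module generates small, fully self-contained OBO + GAF + rule-file
triples with *known* co-annotation structure, so that every other module
can be exercised end-to-end without downloads and with exact expected
counts.

Two generators are provided:

* :func:`generate_fixture` builds a random ranked DAG (acyclic by
  construction: edges only point from later to earlier ranks) and plants
  exact co-annotation overlaps on dedicated leaf term pairs.  Gene
  assignment to planted cells is deterministic; randomness shapes only the
  DAG topology and background annotations.  Identical specs (including the
  seed) yield byte-identical files.

* :func:`demo_fixture` is a hand-written corpus embedding the three
  canonical mutual-exclusivity rules (tRNA metabolism vs protein folding;
  tRNA metabolism vs DNA recombination excepting isotype switching;
  cytoplasmic translation vs protein targeting excepting *C. elegans*
  prx-10), genes exercising each pass/fail branch, and a term with paths to
  two otherwise-exclusive parents (the pentose-phosphate-shunt motif).

Generated fixture ids live in a reserved high range (``GO:9......``) so
they can never collide with the real GO ids used in the demo.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import FixtureError
from .ontology import GO_CURIE_RE

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "expected_violations",
    "demo_fixture",
    "DEMO_PLANTED_VIOLATIONS",
    "DEMO_MATRIX_TERMS",
]

_BACKBONE_BASE = 9000000  # GO:9000001 .. backbone DAG
_PAIR_BASE = 9100000  # GO:91xxxxx default planted pair terms
_EXC_BASE = 9200000  # GO:92xxxxx planted exception terms

_DEFAULT_RELATION_MIX: Mapping[str, float] = {
    "is_a": 0.7,
    "part_of": 0.2,
    "regulates": 0.1,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic corpus.

    ``planted_overlaps`` rows are
    ``(term_a, term_b, n_shared, n_exclusive_a, n_exclusive_b)``: term_a
    and term_b are created as fresh leaf terms hanging off the backbone
    DAG, with exactly ``n_shared`` genes annotated to both and the stated
    numbers annotated to one side only.  Because the pair terms are leaves,
    propagation from elsewhere can never inflate the planted cell, so the
    co-annotation count under the default relations equals ``n_shared``
    exactly.

    ``planted_exceptions`` rows are ``(overlap_index, kind)`` with kind
    ``"term"`` or ``"gene"``; each adds an exception to that overlap's rule
    which exempts the overlap's first shared gene.
    """

    n_terms: int = 60
    branching: float = 1.5
    relation_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RELATION_MIX)
    )
    n_genes: int = 50
    planted_overlaps: Sequence[tuple[str, str, int, int, int]] = ()
    planted_exceptions: Sequence[tuple[int, str]] = ()
    seed: int = 0


def _validate(spec: FixtureSpec) -> None:
    if spec.n_terms < 1:
        raise FixtureError("n_terms must be >= 1")
    if spec.n_genes < 0:
        raise FixtureError("n_genes must be >= 0")
    seen_terms: set[str] = set()
    used_genes = 0
    for k, (a, b, shared, ex_a, ex_b) in enumerate(spec.planted_overlaps):
        for t in (a, b):
            if not GO_CURIE_RE.match(t):
                raise FixtureError(f"planted term id is not a GO CURIE: {t!r}")
            n = int(t.split(":")[1])
            if _BACKBONE_BASE < n <= _BACKBONE_BASE + spec.n_terms:
                raise FixtureError(
                    f"planted term {t} collides with the backbone id range"
                )
        if a == b:
            raise FixtureError(f"overlap {k}: pair terms must differ")
        if a in seen_terms or b in seen_terms:
            raise FixtureError(
                f"overlap {k}: pair terms may not be shared between overlaps"
            )
        seen_terms.update((a, b))
        if min(shared, ex_a, ex_b) < 0:
            raise FixtureError(f"overlap {k}: counts must be non-negative")
        need = shared + ex_a + ex_b
        if need > spec.n_genes:
            raise FixtureError(
                f"overlap {k}: needs {need} genes but n_genes={spec.n_genes}"
            )
        used_genes += need
    if used_genes > spec.n_genes:
        raise FixtureError(
            f"planted overlaps need {used_genes} distinct genes in total but "
            f"n_genes={spec.n_genes}"
        )
    for k, kind in spec.planted_exceptions:
        if not 0 <= k < len(spec.planted_overlaps):
            raise FixtureError(f"planted exception refers to overlap {k}")
        if kind not in ("term", "gene"):
            raise FixtureError(f"unknown exception kind {kind!r}")
        if spec.planted_overlaps[k][2] < 1:
            raise FixtureError(
                f"overlap {k} has no shared gene to hang an exception on"
            )


def _poisson_like(rng: random.Random, mean: float, hi: int) -> int:
    """Small-count sample in [1, hi] with the given mean-ish parameter."""
    k = 1
    p = mean - 1.0
    while p > 0 and k < hi:
        if rng.random() < min(p, 1.0):
            k += 1
        p -= 1.0
    return min(k, hi)


def _term_stanza(
    tid: str,
    name: str,
    parents: Sequence[tuple[str, str]] = (),
    namespace: str = "biological_process",
    alt_ids: Sequence[str] = (),
    obsolete: bool = False,
    replaced_by: str | None = None,
) -> str:
    lines = [f"[Term]", f"id: {tid}", f"name: {name}", f"namespace: {namespace}"]
    for alt in alt_ids:
        lines.append(f"alt_id: {alt}")
    for rel, parent in parents:
        if rel == "is_a":
            lines.append(f"is_a: {parent}")
        else:
            lines.append(f"relationship: {rel} {parent}")
    if obsolete:
        lines.append("is_obsolete: true")
    if replaced_by:
        lines.append(f"replaced_by: {replaced_by}")
    return "\n".join(lines) + "\n"


def _gaf_line(
    gene: str,
    term: str,
    qualifier: str = "involved_in",
    evidence: str = "IDA",
    taxon: str = "taxon:4896",
    entity_type: str = "protein",
    symbol: str | None = None,
    assigned_by: str = "FixtureDB",
) -> str:
    db, local = gene.split(":", 1)
    cols = [
        db,
        local,
        symbol or local,
        qualifier,
        term,
        "GO_REF:0000001",
        evidence,
        "",
        "P",
        "",
        "",
        entity_type,
        taxon,
        "20200101",
        assigned_by,
        "",
        "",
    ]
    return "\t".join(cols)


def generate_fixture(spec: FixtureSpec) -> tuple[str, str, str]:
    """Generate an (OBO text, GAF text, rule text) triple from ``spec``.

    Raises :class:`FixtureError` before generating anything if the spec is
    infeasible (an overlap needing more genes than exist, colliding ids,
    an exception pointing at an overlap with no shared genes).
    """
    _validate(spec)
    rng = random.Random(spec.seed)

    backbone = [f"GO:{_BACKBONE_BASE + i + 1:07d}" for i in range(spec.n_terms)]
    rel_labels = sorted(spec.relation_mix)
    rel_weights = [spec.relation_mix[r] for r in rel_labels]

    stanzas: list[str] = []
    for i, tid in enumerate(backbone):
        parents: list[tuple[str, str]] = []
        if i > 0:
            k = _poisson_like(rng, spec.branching, hi=min(i, 4))
            for j in sorted(rng.sample(range(i), k)):
                rel = rng.choices(rel_labels, weights=rel_weights, k=1)[0]
                parents.append((rel, backbone[j]))
        stanzas.append(_term_stanza(tid, f"fixture backbone term {i + 1}", parents))

    genes = [f"FX:G{i + 1:04d}" for i in range(spec.n_genes)]
    gaf_lines: list[str] = []
    rule_lines: list[str] = []
    exceptions_by_overlap: dict[int, list[str]] = {}
    for k, kind in spec.planted_exceptions:
        exceptions_by_overlap.setdefault(k, []).append(kind)

    cursor = 0
    used_gene_ids: set[str] = set()
    n_exc_terms = 0
    for k, (a, b, shared, ex_a, ex_b) in enumerate(spec.planted_overlaps):
        # dedicated leaf pair: one outgoing is_a each, no children, so the
        # planted cell is exactly the shared slice
        anchor_a = backbone[rng.randrange(spec.n_terms)]
        anchor_b = backbone[rng.randrange(spec.n_terms)]
        stanzas.append(_term_stanza(a, f"planted pair {k} side a", [("is_a", anchor_a)]))
        stanzas.append(_term_stanza(b, f"planted pair {k} side b", [("is_a", anchor_b)]))
        shared_genes = genes[cursor : cursor + shared]
        cursor += shared
        only_a = genes[cursor : cursor + ex_a]
        cursor += ex_a
        only_b = genes[cursor : cursor + ex_b]
        cursor += ex_b
        used_gene_ids.update(shared_genes + only_a + only_b)
        for g in shared_genes:
            gaf_lines.append(_gaf_line(g, a))
            gaf_lines.append(_gaf_line(g, b))
        for g in only_a:
            gaf_lines.append(_gaf_line(g, a))
        for g in only_b:
            gaf_lines.append(_gaf_line(g, b))

        exc_terms: list[str] = []
        exc_entities: list[str] = []
        for kind in exceptions_by_overlap.get(k, ()):
            target = shared_genes[0]
            if kind == "gene":
                exc_entities.append(target)
            else:
                n_exc_terms += 1
                etid = f"GO:{_EXC_BASE + n_exc_terms:07d}"
                anchor = backbone[rng.randrange(spec.n_terms)]
                stanzas.append(
                    _term_stanza(etid, f"planted exception term {n_exc_terms}", [("is_a", anchor)])
                )
                gaf_lines.append(_gaf_line(target, etid))
                exc_terms.append(etid)
        cols = [a, b]
        if exc_terms or exc_entities:
            cols.append("|".join(exc_terms))
        if exc_entities:
            cols.append("|".join(exc_entities))
        rule_lines.append("\t".join(cols))

    # background annotations keep the corpus from being all-planted;
    # leftover genes land on random backbone terms only, which planted leaf
    # pairs can never inherit from
    for g in genes:
        if g not in used_gene_ids:
            gaf_lines.append(_gaf_line(g, backbone[rng.randrange(spec.n_terms)]))

    obo = "format-version: 1.2\nontology: coannoqc-fixture\n\n" + "\n".join(stanzas)
    gaf = "!gaf-version: 2.2\n" + "\n".join(gaf_lines) + ("\n" if gaf_lines else "")
    rules = (
        "# synthetic co-annotation QC rules\n"
        + "\n".join(rule_lines)
        + ("\n" if rule_lines else "")
    )
    return obo, gaf, rules


def expected_violations(spec: FixtureSpec) -> dict[tuple[str, str], int]:
    """Violation count each planted rule must yield: the shared-gene count
    minus one when any planted exception exempts the first shared gene."""
    excepted = {k for k, _ in spec.planted_exceptions}
    return {
        (a, b): shared - (1 if k in excepted and shared > 0 else 0)
        for k, (a, b, shared, _, _) in enumerate(spec.planted_overlaps)
    }


# --------------------------------------------------------------------------
# Hand-written demo corpus
# --------------------------------------------------------------------------

_DEMO_OBO = """\
format-version: 1.2
ontology: coannoqc-demo

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0006399
name: tRNA metabolic process
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0006457
name: protein folding
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0006310
name: DNA recombination
namespace: biological_process
alt_id: GO:0099999
is_a: GO:0008150

[Term]
id: GO:0045190
name: isotype switching
namespace: biological_process
is_a: GO:0006310

[Term]
id: GO:0002181
name: cytoplasmic translation
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0006605
name: protein targeting
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0009117
name: nucleotide metabolic process
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:1901135
name: carbohydrate derivative metabolic process
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0006098
name: pentose-phosphate shunt
namespace: biological_process
is_a: GO:0009117
is_a: GO:1901135

[Term]
id: GO:9000001
name: demo tRNA processing subtype
namespace: biological_process
is_a: GO:0006399

[Term]
id: GO:9000010
name: demo regulation of protein folding
namespace: biological_process
is_a: GO:0008150
relationship: regulates GO:0006457

[Term]
id: GO:9000020
name: demo retired folding term
namespace: biological_process
is_obsolete: true
replaced_by: GO:0006457
"""

_DEMO_GAF_ROWS: list[tuple[str, str, str, str]] = [
    # (gene id, qualifier, term, taxon)
    ("PomBase:SPDEMO01", "involved_in", "GO:0006399", "taxon:4896"),
    ("PomBase:SPDEMO01", "involved_in", "GO:0006457", "taxon:4896"),
    ("PomBase:SPDEMO02", "involved_in", "GO:0006399", "taxon:4896"),
    ("PomBase:SPDEMO02", "involved_in", "GO:0006310", "taxon:4896"),
    ("PomBase:SPDEMO02", "involved_in", "GO:0045190", "taxon:4896"),
    ("PomBase:SPDEMO03", "involved_in", "GO:0006399", "taxon:4896"),
    # annotation through the merged secondary id of DNA recombination
    ("PomBase:SPDEMO03", "involved_in", "GO:0099999", "taxon:4896"),
    ("WB:WBGene00006946", "involved_in", "GO:0002181", "taxon:6239"),
    ("WB:WBGene00006946", "involved_in", "GO:0006605", "taxon:6239"),
    ("PomBase:SPDEMO05", "involved_in", "GO:0002181", "taxon:4896"),
    ("PomBase:SPDEMO05", "involved_in", "GO:0006605", "taxon:4896"),
    # common-descendant motif: one annotation, two exclusive-looking parents
    ("PomBase:SPDEMO06", "involved_in", "GO:0006098", "taxon:4896"),
    # violation discovered only through closure: descendant of term1
    ("PomBase:SPDEMO07", "involved_in", "GO:9000001", "taxon:4896"),
    ("PomBase:SPDEMO07", "involved_in", "GO:0006457", "taxon:4896"),
    # a NOT annotation must never create an intersection
    ("PomBase:SPDEMO08", "involved_in", "GO:0006399", "taxon:4896"),
    ("PomBase:SPDEMO08", "NOT|involved_in", "GO:0006457", "taxon:4896"),
    # reaches protein folding only over a regulates edge
    ("PomBase:SPDEMO09", "involved_in", "GO:0006399", "taxon:4896"),
    ("PomBase:SPDEMO09", "involved_in", "GO:9000010", "taxon:4896"),
]

_DEMO_RULES = """\
# demo co-annotation QC rules
# Term1	Term2	excepted GO term	excepted gene
GO:0006399\tGO:0006457
GO:0006399\tGO:0006310\tGO:0045190
GO:0002181\tGO:0006605\t\tWB:WBGene00006946
GO:0009117\tGO:1901135\tGO:0006098
"""

#: (term1, term2, gene) triples the demo corpus is constructed to flag when
#: checked with the default relation set (no regulates traversal).
DEMO_PLANTED_VIOLATIONS: frozenset[tuple[str, str, str]] = frozenset(
    {
        ("GO:0006399", "GO:0006457", "PomBase:SPDEMO01"),
        ("GO:0006399", "GO:0006457", "PomBase:SPDEMO07"),
        ("GO:0006399", "GO:0006310", "PomBase:SPDEMO03"),
        ("GO:0002181", "GO:0006605", "PomBase:SPDEMO05"),
    }
)

#: A small slim-style term list used by examples and CLI demos.
DEMO_MATRIX_TERMS: tuple[str, ...] = (
    "GO:0006399",
    "GO:0006457",
    "GO:0006310",
    "GO:0002181",
)


def demo_fixture() -> tuple[str, str, str]:
    """The hand-written demo corpus as (OBO text, GAF text, rule text).

    Construction (all under the default is_a/part_of traversal):

    * ``SPDEMO01`` violates the tRNA-metabolism/protein-folding rule.
    * ``SPDEMO02`` carries the pair tRNA-metabolism/DNA-recombination but
      also isotype switching, the rule's excepted term — no violation;
      ``SPDEMO03`` carries the pair without it — one violation.
    * ``WB:WBGene00006946`` (*C. elegans* prx-10) carries cytoplasmic
      translation + protein targeting and is the rule's excepted gene;
      ``SPDEMO05`` carries the same pair — one violation.
    * ``SPDEMO06`` is annotated once, to pentose-phosphate shunt, which has
      paths to both nucleotide metabolism and carbohydrate-derivative
      metabolism; the fourth rule excepts that common descendant.
    * ``SPDEMO07`` reaches tRNA metabolism only through a descendant term,
      so its violation exists purely by closure.
    * ``SPDEMO08``'s protein-folding annotation is NOT-qualified and must
      not create an intersection; ``SPDEMO09`` reaches protein folding only
      over a regulates edge, so it violates only when regulates traversal
      is switched on.
    """
    gaf_lines = ["!gaf-version: 2.2"]
    for gene, qualifier, term, taxon in _DEMO_GAF_ROWS:
        assigned = gene.split(":", 1)[0]
        gaf_lines.append(
            _gaf_line(
                gene,
                term,
                qualifier=qualifier,
                taxon=taxon,
                assigned_by=assigned,
            )
        )
    return _DEMO_OBO, "\n".join(gaf_lines) + "\n", _DEMO_RULES
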