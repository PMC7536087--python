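"""Co-annotation QC rules: parsing, evaluation and violation reports.

A rule asserts that two biological-process terms are mutually exclusive —
no gene product should be annotated to both — optionally relaxed by
exceptions.  The file format is tab-delimited with four positional columns:

    Term1 <TAB> Term2 <TAB> excepted GO term(s) <TAB> excepted entity id(s)

Column 3 may hold one or more pipe-separated GO ids; a gene annotated to
ANY of them (closure semantics: annotation to a descendant also counts) is
exempt.  Column 4 holds pipe-separated entity ids: PANTHER family ids
(``PTHR`` prefix, matched through an optional gene -> family map), NCBI
taxon CURIEs (``NCBITaxon:``/``taxon:`` prefix, matched against the gene's
taxon) or individual gene-product ids.  An empty column 3 with a populated
column 4 is written as two consecutive tabs.  Lines starting with ``#`` or
``!`` are comments.

Evaluation runs against a propagated :class:`~coannoqc.annotations.AnnotationIndex`:
the candidate violators for a rule are exactly the genes in the closure
intersection of its two terms, minus any gene an exception clears.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

from .annotations import AnnotationIndex
from .errors import CoannoQCError, RuleParseError
from .matrix import intersection_genes
from .ontology import GO_CURIE_RE

logger = logging.getLogger(__name__)

PANTHER_RE = re.compile(r"^PTHR\d+")
TAXON_RE = re.compile(r"^(NCBITaxon|taxon):\d+$")


@dataclass(frozen=True)
class Rule:
    """A (Term1, Term2) mutual-exclusivity assertion with exceptions."""

    term1: str
    term2: str
    excepted_terms: frozenset[str] = frozenset()
    excepted_entities: frozenset[str] = frozenset()
    line_no: int = 0

    def __post_init__(self):
        if self.term1 == self.term2:
            raise RuleParseError(
                f"rule pair must be two distinct terms, got {self.term1} "
                "twice",
                self.line_no or None,
            )
        clash = self.excepted_terms & {self.term1, self.term2}
        if clash:
            raise RuleParseError(
                "excepted term(s) duplicate the rule pair: "
                + ", ".join(sorted(clash)),
                self.line_no or None,
            )

    @property
    def pair(self) -> frozenset[str]:
        """The unordered term pair; (A, B) and (B, A) are the same rule."""
        return frozenset((self.term1, self.term2))


@dataclass(frozen=True)
class Violation:
    """A gene co-annotated to a rule's pair with no applicable exception.

    ``direct_terms_1``/``direct_terms_2`` are the directly annotated terms
    (from index provenance) that placed the gene under each side — the
    annotations a curator must inspect.
    """

    rule: Rule
    gene: str
    direct_terms_1: frozenset[str]
    direct_terms_2: frozenset[str]


@dataclass
class QCReport:
    """Ordered violations plus per-rule summary counts and run metadata."""

    violations: list[Violation] = field(default_factory=list)
    summary: dict[tuple[str, str], int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.violations)


def _iter_lines(stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from io.StringIO(stream)
    else:
        yield from stream


def _classify_tokens(fields: list[str], line_no: int) -> tuple[str, str]:
    """Lenient-mode recovery: sniff GO-prefixed vs entity tokens in
    columns 3+ when the writer omitted the empty-column tab."""
    go_tokens, entity_tokens = [], []
    for f in fields:
        for tok in f.split("|"):
            tok = tok.strip()
            if not tok:
                continue
            if GO_CURIE_RE.match(tok):
                go_tokens.append(tok)
            else:
                entity_tokens.append(tok)
    return "|".join(go_tokens), "|".join(entity_tokens)


def parse_rules(
    stream: str | IO[str] | Iterable[str],
    lenient: bool = False,
) -> list[Rule]:
    """Parse tab-delimited rule text into a list of :class:`Rule`.

    Strict positional semantics by default: column 3 is excepted GO terms,
    column 4 excepted entities, an empty column 3 expressed as two
    consecutive tabs.  ``lenient`` instead sniffs GO-prefixed tokens in
    columns 3+ so files missing the empty tab still load.

    A duplicated unordered pair is merged (union of exceptions) with a
    warning.  Fewer than two columns, or a non-GO id in columns 1-3,
    raise :class:`RuleParseError` with the line number.
    """
    rules: list[Rule] = []
    by_pair: dict[frozenset[str], int] = {}
    for line_no, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith(("#", "!")):
            continue
        cols = line.split("\t")
        if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
            raise RuleParseError(
                "a rule needs at least two tab-separated GO term columns",
                line_no,
            )
        if len(cols) > 4 and not lenient:
            raise RuleParseError(
                f"too many columns ({len(cols)}); expected at most 4", line_no
            )
        term1, term2 = cols[0].strip(), cols[1].strip()
        for t in (term1, term2):
            if not GO_CURIE_RE.match(t):
                raise RuleParseError(f"not a GO term id: {t!r}", line_no)
        if lenient:
            exc_terms_field, exc_entities_field = _classify_tokens(
                cols[2:], line_no
            )
        else:
            exc_terms_field = cols[2].strip() if len(cols) > 2 else ""
            exc_entities_field = cols[3].strip() if len(cols) > 3 else ""
        excepted_terms = frozenset(
            t.strip() for t in exc_terms_field.split("|") if t.strip()
        )
        for t in excepted_terms:
            if not GO_CURIE_RE.match(t):
                raise RuleParseError(
                    f"excepted-term column holds a non-GO id: {t!r}", line_no
                )
        excepted_entities = frozenset(
            e.strip() for e in exc_entities_field.split("|") if e.strip()
        )
        rule = Rule(term1, term2, excepted_terms, excepted_entities, line_no)
        if rule.pair in by_pair:
            idx = by_pair[rule.pair]
            prev = rules[idx]
            logger.warning(
                "line %d duplicates rule pair (%s, %s) from line %d; "
                "merging exceptions",
                line_no,
                prev.term1,
                prev.term2,
                prev.line_no,
            )
            rules[idx] = Rule(
                prev.term1,
                prev.term2,
                prev.excepted_terms | rule.excepted_terms,
                prev.excepted_entities | rule.excepted_entities,
                prev.line_no,
            )
            continue
        by_pair[rule.pair] = len(rules)
        rules.append(rule)
    return rules


def load_family_map(stream: str | IO[str] | Iterable[str]) -> dict[str, str]:
    """Read a 2-column TSV of gene-product id -> PANTHER family id."""
    mapping: dict[str, str] = {}
    for line_no, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "!")):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise RuleParseError(
                "family map rows need two tab-separated columns", line_no
            )
        mapping[cols[0].strip()] = cols[1].strip()
    return mapping


def _is_exempt(
    gene: str,
    rule: Rule,
    index: AnnotationIndex,
    family_map: Mapping[str, str] | None,
) -> bool:
    for exc_term in rule.excepted_terms:
        # closure semantics: annotation anywhere under the excepted term
        # clears the gene, consistent with how pair membership is computed
        if exc_term in index.closure and gene in index.genes_at(exc_term):
            return True
    if gene in rule.excepted_entities:
        return True
    if family_map is not None and family_map.get(gene) in rule.excepted_entities:
        return True
    gp = index.genes.get(gene)
    if gp is not None and gp.taxon:
        for ent in rule.excepted_entities:
            if TAXON_RE.match(ent) and _same_taxon(ent, gp.taxon):
                return True
    return False


def _same_taxon(a: str, b: str) -> bool:
    return a.split(":", 1)[1] == b.split(":", 1)[1] if ":" in a and ":" in b else a == b


def check_rule(
    rule: Rule,
    index: AnnotationIndex,
    family_map: Mapping[str, str] | None = None,
) -> list[Violation]:
    """Evaluate one rule; violations are ordered lexicographically by gene.

    A gene in the closure intersection of the rule's pair violates unless
    (a) it is annotated (by closure) to an excepted term, (b) its id is an
    excepted entity, (c) its PANTHER family is excepted, or (d) its taxon
    matches an excepted taxon CURIE.
    """
    if family_map is None and any(
        PANTHER_RE.match(e) for e in rule.excepted_entities
    ):
        logger.warning(
            "rule (%s, %s) has PANTHER family exception(s) but no family "
            "map was supplied; they will match nothing",
            rule.term1,
            rule.term2,
        )
    violations = []
    for gene in sorted(intersection_genes(index, rule.term1, rule.term2)):
        if _is_exempt(gene, rule, index, family_map):
            continue
        violations.append(
            Violation(
                rule=rule,
                gene=gene,
                direct_terms_1=frozenset(
                    index.provenance.get((rule.term1, gene), ())
                ),
                direct_terms_2=frozenset(
                    index.provenance.get((rule.term2, gene), ())
                ),
            )
        )
    return violations


def check_all(
    rules: Iterable[Rule],
    index: AnnotationIndex,
    family_map: Mapping[str, str] | None = None,
    metadata: Mapping | None = None,
) -> QCReport:
    """Evaluate every rule in file order and assemble a :class:`QCReport`.

    Output is deterministic for identical inputs: rules in file order,
    violations within a rule sorted by gene id.
    """
    report = QCReport(metadata=dict(metadata or {}))
    for rule in rules:
        found = check_rule(rule, index, family_map)
        report.violations.extend(found)
        report.summary[(rule.term1, rule.term2)] = len(found)
    return report


REPORT_HEADER = (
    "rule_line\tterm1\tterm2\tgene\tdirect_terms_1\tdirect_terms_2"
)


def write_report(report: QCReport, format: str = "tsv") -> str:
    """Serialise a report to ``tsv`` or ``json`` with stable ordering."""
    if format == "tsv":
        lines = [REPORT_HEADER]
        for v in report.violations:
            lines.append(
                "\t".join(
                    [
                        str(v.rule.line_no),
                        v.rule.term1,
                        v.rule.term2,
                        v.gene,
                        "|".join(sorted(v.direct_terms_1)),
                        "|".join(sorted(v.direct_terms_2)),
                    ]
                )
            )
        return "\n".join(lines) + "\n"
    if format == "json":
        doc = {
            "metadata": report.metadata,
            "summary": [
                {"term1": t1, "term2": t2, "violations": n}
                for (t1, t2), n in report.summary.items()
            ],
            "violations": [
                {
                    "rule_line": v.rule.line_no,
                    "term1": v.rule.term1,
                    "term2": v.rule.term2,
                    "gene": v.gene,
                    "direct_terms_1": sorted(v.direct_terms_1),
                    "direct_terms_2": sorted(v.direct_terms_2),
                }
                for v in report.violations
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    raise CoannoQCError(f"unknown report format: {format!r}")
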