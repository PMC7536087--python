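"""GAF reading, annotation filtering and closure propagation.

A GAF (Gene Association File) record associates a gene product with a GO
term, together with an evidence code, a citation and provenance metadata.
This module parses GAF 2.1/2.2 text, applies organism / entity-type /
evidence filters, and propagates the surviving annotations over a
precomputed :class:`~coannoqc.ontology.ClosureTable` into a term -> gene-set
index.  The index is the object every downstream query (matrix cells, rule
checks) operates on: a gene is "annotated to T" iff some direct annotation
of the gene names a term whose closure contains T.

NOT-qualified annotations assert *non*-involvement; they are parsed (the
``negated`` flag) but are never propagated into an index, since a negative
assertion must not create co-annotation intersections.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

from .errors import ConfigError, GafParseError, UnknownTermError
from .ontology import ClosureTable, OntologyGraph

logger = logging.getLogger(__name__)

GAF_COLUMNS = 17


@dataclass(frozen=True)
class GeneProduct:
    """An annotated entity, identified by its database-qualified id
    (e.g. ``WB:WBGene00006946``, ``PomBase:SPAC144.02``)."""

    id: str
    symbol: str = ""
    taxon: str = ""
    entity_type: str = ""


@dataclass(frozen=True)
class Annotation:
    """One gene-product -> GO-term association with its evidence trail."""

    gene: GeneProduct
    term: str
    negated: bool = False
    qualifiers: tuple[str, ...] = ()
    evidence: str = ""
    reference: str = ""
    assigned_by: str = ""
    date: str = ""
    aspect: str = ""
    extension: str = ""  # column 16, carried opaquely


def _iter_lines(stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from io.StringIO(stream)
    else:
        yield from stream


def parse_gaf(
    stream: str | IO[str] | Iterable[str],
    ontology: OntologyGraph | None = None,
    strict: bool = True,
) -> list[Annotation]:
    """Parse GAF 2.1/2.2 text into a list of :class:`Annotation`.

    Header lines start with ``!``; a ``!gaf-version:`` header selects the
    qualifier dialect (2.1 allows a bare ``NOT``, 2.2 requires
    ``NOT|<relation>``) — both spellings are accepted either way, and an
    absent header defaults to 2.2 with a warning.  Records must have 17
    tab-separated columns: in strict mode a short record raises
    :class:`GafParseError` with its line number, in lenient mode it is
    rejected and logged.  If ``ontology`` is given, term ids are resolved
    through alt_ids to primary ids; records whose term does not resolve are
    rejected and logged.
    """
    annotations: list[Annotation] = []
    version_seen = False
    rejected = 0
    for line_no, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("!"):
            header = line[1:].strip()
            if header.lower().startswith("gaf-version:"):
                version_seen = True
                version = header.split(":", 1)[1].strip()
                if version not in ("2.1", "2.2"):
                    logger.warning(
                        "unrecognised gaf-version %r; parsing as 2.2", version
                    )
            continue
        if not version_seen:
            logger.warning(
                "no !gaf-version header before first record; assuming 2.2"
            )
            version_seen = True
        cols = line.split("\t")
        if len(cols) != GAF_COLUMNS:
            msg = f"expected {GAF_COLUMNS} columns, got {len(cols)}"
            if strict:
                raise GafParseError(msg, line_no)
            logger.warning("line %d rejected: %s", line_no, msg)
            rejected += 1
            continue
        (
            db,
            local_id,
            symbol,
            qualifier,
            term,
            reference,
            evidence,
            _with_from,
            aspect,
            _name,
            _synonyms,
            entity_type,
            taxon,
            date,
            assigned_by,
            extension,
            _form_id,
        ) = cols
        if not db or not local_id:
            msg = "empty DB or DB Object ID column"
            if strict:
                raise GafParseError(msg, line_no)
            logger.warning("line %d rejected: %s", line_no, msg)
            rejected += 1
            continue
        if ontology is not None:
            try:
                term = ontology.resolve(term, follow_replaced_by=True)
            except UnknownTermError:
                logger.warning(
                    "line %d rejected: term %s not in ontology", line_no, term
                )
                rejected += 1
                continue
            if ontology.terms[term].is_obsolete:
                logger.warning(
                    "line %d rejected: term %s is obsolete with no "
                    "replacement",
                    line_no,
                    term,
                )
                rejected += 1
                continue
        qualifiers = tuple(q for q in qualifier.split("|") if q)
        negated = "NOT" in qualifiers
        # column 13 may list interaction taxa pipe-separated; only the
        # first identifies the annotated entity
        primary_taxon = taxon.split("|", 1)[0]
        gene = GeneProduct(
            id=f"{db}:{local_id}",
            symbol=symbol,
            taxon=primary_taxon,
            entity_type=entity_type,
        )
        annotations.append(
            Annotation(
                gene=gene,
                term=term,
                negated=negated,
                qualifiers=qualifiers,
                evidence=evidence,
                reference=reference,
                assigned_by=assigned_by,
                date=date,
                aspect=aspect,
                extension=extension,
            )
        )
    if rejected:
        logger.info("parse_gaf: rejected %d malformed record(s)", rejected)
    return annotations


def filter_annotations(
    anns: Iterable[Annotation],
    taxon: str | None = None,
    entity_type: str | None = None,
    evidence_include: Iterable[str] | None = None,
    evidence_exclude: Iterable[str] | None = None,
    drop_negated: bool = False,
) -> list[Annotation]:
    """Order-preserving subset of ``anns`` satisfying every given predicate.

    Raises :class:`ConfigError` if an evidence code appears in both the
    include and the exclude set.
    """
    include = frozenset(evidence_include) if evidence_include else None
    exclude = frozenset(evidence_exclude) if evidence_exclude else None
    if include and exclude:
        clash = include & exclude
        if clash:
            raise ConfigError(
                "evidence code(s) both included and excluded: "
                + ", ".join(sorted(clash))
            )
    out = []
    for a in anns:
        if taxon is not None and a.gene.taxon != taxon:
            continue
        if entity_type is not None and a.gene.entity_type != entity_type:
            continue
        if include is not None and a.evidence not in include:
            continue
        if exclude is not None and a.evidence in exclude:
            continue
        if drop_negated and a.negated:
            continue
        out.append(a)
    return out


@dataclass
class AnnotationIndex:
    """Term -> gene-set map after closure propagation.

    ``provenance[(term, gene)]`` records which *directly* annotated terms
    placed the gene under ``term``, so a violation report can point a
    curator at the actual annotations to inspect.
    """

    relation_set: frozenset[str]
    closure: ClosureTable
    by_term: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    genes: dict[str, GeneProduct] = field(default_factory=dict)

    def genes_at(self, term: str) -> frozenset[str]:
        """Gene ids annotated (directly or by transitivity) to ``term``.

        Unknown terms raise; terms known to the closure but with no
        annotated genes return the empty set.
        """
        if term not in self.closure:
            raise UnknownTermError(f"term {term!r} not in the closure table")
        return frozenset(self.by_term.get(term, ()))


def build_index(
    anns: Iterable[Annotation], closure: ClosureTable
) -> AnnotationIndex:
    """Propagate annotations over ``closure`` into an :class:`AnnotationIndex`.

    Every non-negated annotation (gene, D) adds the gene to ``by_term[T]``
    for each T in the (reflexive) closure of D, recording D as provenance.
    Negated annotations are skipped entirely.
    """
    index = AnnotationIndex(relation_set=closure.relation_set, closure=closure)
    for a in anns:
        if a.negated:
            continue
        direct = a.term
        gid = a.gene.id
        index.genes.setdefault(gid, a.gene)
        for t in closure.lookup(direct):
            index.by_term.setdefault(t, set()).add(gid)
            index.provenance.setdefault((t, gid), set()).add(direct)
    return index
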