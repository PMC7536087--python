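# Methods

## Model

`coannoqc` operates on three inputs: an ontology graph, an annotation
corpus, and a set of mutual-exclusivity rules.

**Ontology.** The OBO loader builds a typed directed multigraph whose
edges point child → parent and carry one relation label. Only the tags
`id`, `name`, `namespace`, `alt_id`, `is_a`, `relationship`,
`is_obsolete` and `replaced_by` are interpreted; everything else (text
definitions, synonyms, xrefs, logical definitions) is ignored. Relation
labels outside the recognised set (`is_a`, `part_of`, the three
regulates relations, `occurs_in`) are preserved as `other`, logged once
per label, and never traversed. Obsolete terms stay in the term map for
diagnostics but carry no edges and appear in no closure; traversing from
an obsolete id is an error unless the caller opts into `replaced_by`
redirection (the GAF reader does, so annotations to merged or retired
ids land on their live replacements).

**Traversal semantics.** Ancestors are computed as *label-filtered
reachability*: every edge on a path must carry an allowed label. This is
a documented approximation of the OWL semantics of GO — property chains
such as `regulates ∘ part_of` are not composed, and a `regulates` edge
is either traversed as a plain edge or not traversed at all. For the QC
use case the approximation errs on the conservative side: it can only
*miss* some inferred memberships, never invent them. Closures are
reflexive (a direct annotation to *T* counts as annotation to *T*),
because intersection queries must include directly annotated genes.

The full closure table is computed by one dynamic program over a
reverse topological order of the traversable subgraph: `anc(T) = {T} ∪
⋃_{T→P} anc(P)`. A cycle among traversable edges is a hard error that
names one offending cycle; go-basic guarantees acyclicity and the
fixture generator enforces it by construction.

**Annotations.** GAF 2.1 and 2.2 are both accepted (the `!gaf-version`
header is honoured; an absent header is treated as 2.2 with a warning —
both NOT spellings are recognised regardless). Gene identity is the full
database-qualified id; no cross-database identifier merging is
attempted, since contributing databases are triaged separately. When
column 13 lists multiple pipe-separated taxa (interaction annotations),
only the first identifies the annotated entity. Annotation extensions
(column 16) are carried as opaque text. NOT-qualified records are
parsed but never enter an index: a negative assertion must not create a
co-annotation intersection. The propagated index stores, per (term,
gene) membership, the set of *directly* annotated terms that caused it,
so every reported violation points at concrete records.

**Matrix.** Cell (i, j) is `|genes(T_i) ∩ genes(T_j)|` over the
propagated index. Symmetry, `cell(i,i) = |genes(T_i)|` and
`cell(i,j) ≤ min(diagonals)` hold by construction and are asserted as
properties. Rows and columns follow the input term order; gene sets
serialise lexicographically so exports diff cleanly. Gene sets are kept
per cell by default for drill-down; `keep_gene_sets=False` keeps counts
only for genome-scale term lists.

**Rules.** A rule file line holds 2–4 tab-separated positional columns:
the exclusive pair, optional pipe-separated excepted GO terms, optional
pipe-separated excepted entities. An empty excepted-term column with a
populated entity column is written as two consecutive tabs; a lenient
mode (off by default) instead sniffs GO-prefixed tokens, for files
written without the empty tab. The pair is unordered — (A, B) appearing
again as (B, A) is merged with a warning, taking the union of
exceptions. Excepted entities are disambiguated by prefix: `PTHR…` is a
PANTHER family (matched through an optional gene → family TSV),
`NCBITaxon:`/`taxon:` CURIEs match the gene's taxon (numeric suffix
comparison), and anything else is a gene-product id. Multiple excepted
terms use ANY-of semantics: one match exempts.

Excepted-term membership is tested against the *propagated* index, i.e.
annotation to a descendant of the excepted term also exempts. This was a
genuinely open choice; closure semantics was chosen for consistency with
how pair membership itself is computed, and because exceptions name a
biological context ("only if involved in isotype switching") that any
more specific descendant also satisfies.

## Workflow defaults

The `matrix` command traverses regulates relations by default (broad
retrieval for inspection); the `check` command excludes them by default,
so genes in upstream regulatory pathways — an accepted category of
legitimate co-annotation, alongside common descendants and
multifunctional/fusion proteins — do not trip rules. Both accept
`--relations` to override. `check` exits 0 only on a clean report and 1
when violations exist, so it gates CI-style annotation pipelines; I/O
and configuration failures exit 2. Options can come from a YAML config
file; explicit flags win. Per-stage record counts (parsed, filtered,
NOT-qualified, indexed) are logged for triage auditability.

## Synthetic fixtures

The generator emulates the structural features the QC machinery depends
on — a multi-relation DAG, propagated annotations, planted intersection
counts — not the statistics of a real GO release. Backbone terms
(default 60; ids `GO:9000001+`) form a ranked DAG: each term draws ~1.5
parents (clipped Poisson-like) among earlier ranks, with relation labels
sampled at weights is_a 0.7 / part_of 0.2 / regulates 0.1, roughly the
flavour mix of go-basic biological-process edges. Edges only point to
earlier ranks, so acyclicity holds over *all* relations by construction.
Planted overlaps get dedicated leaf term pairs: with no descendants,
nothing can propagate into them, so each planted cell equals its
specified shared-gene count exactly under the default relations. Gene
slices for planted cells are assigned deterministically and disjointly
(randomness shapes only topology and background annotations), and an
infeasible specification fails before any generation. Identical specs,
including the seed, produce byte-identical files.

Consequently, passing tests demonstrate correctness of closure,
propagation, counting and rule semantics — they say nothing about
real-corpus properties such as annotation depth skew, evidence-code
composition, or inter-database redundancy.

The hand-written demo corpus embeds three canonical rules (tRNA
metabolism ⊗ protein folding; tRNA metabolism ⊗ DNA recombination except
isotype switching; cytoplasmic translation ⊗ protein targeting except
the *C. elegans* fusion gene prx-10), one gene per pass/fail branch, a
closure-only violation via a planted descendant term, a NOT-qualified
record, a regulates-only path, an alt_id and an obsolete term with a
replacement — so a single small corpus exercises every mechanism.

## Numerical and procedural choices

- Problem sizes in the test and acceptance runs (random DAGs of ~200
  terms, dozens of seeds; corpora of 40–80 terms and 30–50 genes) were
  chosen so that independent brute-force oracles — per-node DFS
  reachability, a quadratic gene × term scan, an exhaustive gene × rule
  scan — remain cheap enough to check every value exactly.
- Violations are ordered by rule-file order, then lexicographic gene id;
  reports are byte-identical across runs on identical inputs.
- Strict parsing is the default everywhere; lenient modes skip-and-log
  (malformed GAF records, rules naming unknown terms) for exploratory
  runs on imperfect inputs.

## Known limitations

- No OWL reasoning: property chains, equivalence axioms and logical
  definitions are out of scope; closures may under-infer relative to a
  full reasoner when regulates composes with part_of.
- No cross-ontology references and no identifier merging across
  contributing databases.
- Exception clauses conditioned on a gene's molecular function or
  cellular component are not supported; exceptions are terms, genes,
  families or taxa only.
- Rule authoring/maintenance is the user's task; rules are input, not a
  bundled ruleset.
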