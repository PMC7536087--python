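# coannoqc

Co-annotation quality control for Gene Ontology (GO) annotation corpora.

## The problem

Gene products often act in several biological processes, so a gene may
legitimately carry multiple GO annotations. But processes that are
functionally, spatially or temporally distant — say *tRNA metabolic
process* and *protein folding* — almost never share gene products, and a
gene annotated to both usually marks an error somewhere in the curation
chain: a misread phenotype, a bad InterPro-to-GO mapping, or a wrong
parent relationship in the ontology itself.

`coannoqc` turns that observation into a QC pipeline for biocurators:

1. **Closure.** Parse an OBO ontology (go-basic dialect) and precompute,
   for every term *T*, its reflexive ancestor set
   `anc_R(T) = {T} ∪ {A : T →* A over edges labelled in R}` under a chosen
   relation set *R*. Two presets mirror GO practice: `default`
   (`is_a` + `part_of`) and `with-regulates` (adding `regulates`,
   `positively_regulates`, `negatively_regulates`).
2. **Index.** Parse GAF 2.1/2.2 annotations, filter by taxon, entity type
   and evidence code, and propagate: a gene *g* directly annotated to *D*
   is counted at every `T ∈ anc_R(D)`. NOT-qualified annotations never
   propagate.
3. **Matrix.** For a term list, compute every pairwise intersection
   `|genes(T_i) ∩ genes(T_j)|` — the co-annotation matrix whose small
   off-diagonal cells are the curation signal — with per-cell gene sets
   for drill-down.
4. **Rules.** Evaluate tab-delimited mutual-exclusivity rules
   (`Term1 <TAB> Term2 [<TAB> excepted GO terms] [<TAB> excepted entities]`):
   every gene in the pair's intersection is a violation unless an
   exception clears it — annotation under an excepted term, an excepted
   gene id, an excepted PANTHER family (via a gene→family map), or an
   excepted taxon. Violations come with the direct annotations that caused
   them, so a curator knows exactly what to inspect.

A synthetic-fixture generator produces OBO/GAF/rule triples with exactly
planted co-annotation counts, so the whole stack is testable without
downloading a GO release.

## Worked example

Write the bundled demo corpus and check it:

```sh
coannoqc fixtures --demo --out-dir demo
coannoqc check --obo demo/ontology.obo --gaf demo/annotations.gaf \
    --rules demo/rules.tsv
echo "exit: $?"
```

Output:

```
rule_line	term1	term2	gene	direct_terms_1	direct_terms_2
3	GO:0006399	GO:0006457	PomBase:SPDEMO01	GO:0006399	GO:0006457
3	GO:0006399	GO:0006457	PomBase:SPDEMO07	GO:9000001	GO:0006457
4	GO:0006399	GO:0006310	PomBase:SPDEMO03	GO:0006399	GO:0006310
5	GO:0002181	GO:0006605	PomBase:SPDEMO05	GO:0002181	GO:0006605
exit: 1
```

Four violations (and exit status 1, so the command can gate a pipeline):
`SPDEMO01` carries the flatly exclusive pair tRNA metabolism + protein
folding; `SPDEMO07` is flagged for the same rule purely by closure — its
direct annotation is a *descendant* of tRNA metabolism; `SPDEMO03`
carries tRNA metabolism + DNA recombination without the rule's excepted
term (isotype switching), which its sibling `SPDEMO02` does carry and so
passes; and `SPDEMO05` carries cytoplasmic translation + protein
targeting, a pair allowed only for the excepted *C. elegans* gene
`WB:WBGene00006946` (a tandem gene fusion).

The matrix view of the same corpus:

```sh
coannoqc matrix --obo demo/ontology.obo --gaf demo/annotations.gaf \
    --terms GO:0006399,GO:0006457,GO:0006310,GO:0002181 --relations default
```

```
term	GO:0006399	GO:0006457	GO:0006310	GO:0002181
GO:0006399	6	2	2	0
GO:0006457	2	2	0	0
GO:0006310	2	0	2	0
GO:0002181	0	0	0	2
```

Diagonals are per-term totals; the off-diagonal 2s are the intersections a
curator would click into. Re-running with `--relations with-regulates`
raises the tRNA-metabolism/protein-folding cell from 2 to 3, because one
demo gene reaches protein folding only over a `regulates` edge — which is
exactly why `check` excludes regulates by default: upstream regulators are
an accepted source of legitimate co-annotation.

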