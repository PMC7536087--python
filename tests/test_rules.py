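"""Rule parsing, exception semantics and violation reporting."""

from __future__ import annotations

import logging

import pytest

from coannoqc import (
    DEFAULT_RELATIONS,
    Rule,
    build_closure,
    build_index,
    check_all,
    check_rule,
    intersection_genes,
    load_family_map,
    parse_gaf,
    parse_obo,
    parse_rules,
    write_report,
)
from coannoqc.errors import RuleParseError
from conftest import Corpus
from helpers import brute_violations
from test_annotations import HEADER, gaf_line

# --- parsing ---------------------------------------------------------------


def test_two_column_rule_has_no_exceptions():
    (rule,) = parse_rules("GO:0006399\tGO:0006457\n")
    assert (rule.term1, rule.term2) == ("GO:0006399", "GO:0006457")
    assert rule.excepted_terms == frozenset()
    assert rule.excepted_entities == frozenset()
    assert rule.line_no == 1


def test_third_column_holds_excepted_terms_pipe_separated():
    (rule,) = parse_rules("GO:0006399\tGO:0006310\tGO:0045190|GO:0006098\n")
    assert rule.excepted_terms == {"GO:0045190", "GO:0006098"}


def test_two_consecutive_tabs_put_entities_in_column_four():
    (rule,) = parse_rules("GO:0002181\tGO:0006605\t\tWB:WBGene00006946\n")
    assert rule.excepted_terms == frozenset()
    assert rule.excepted_entities == {"WB:WBGene00006946"}


def test_comments_and_blank_lines_skipped():
    text = "# header\n! bang comment\n\nGO:0006399\tGO:0006457\n"
    assert len(parse_rules(text)) == 1


def test_fewer_than_two_columns_is_an_error_with_line_number():
    with pytest.raises(RuleParseError, match="line 2"):
        parse_rules("# ok\nGO:0006399\n")


def test_non_go_id_in_term_columns_is_an_error():
    with pytest.raises(RuleParseError, match="WB:X"):
        parse_rules("GO:0006399\tWB:X\n")
    with pytest.raises(RuleParseError, match="excepted-term"):
        parse_rules("GO:0006399\tGO:0006457\tWB:X\n")


def test_identical_pair_terms_rejected():
    with pytest.raises(RuleParseError):
        parse_rules("GO:0006399\tGO:0006399\n")


def test_excepted_term_may_not_duplicate_the_pair():
    with pytest.raises(RuleParseError):
        parse_rules("GO:0006399\tGO:0006457\tGO:0006457\n")


def test_duplicate_pair_merges_exceptions_with_warning(caplog):
    text = (
        "GO:0006399\tGO:0006457\tGO:0045190\n"
        "GO:0006457\tGO:0006399\t\tWB:WBGene00006946\n"  # reversed order
    )
    with caplog.at_level(logging.WARNING, logger="coannoqc.rules"):
        rules = parse_rules(text)
    assert len(rules) == 1
    assert rules[0].excepted_terms == {"GO:0045190"}
    assert rules[0].excepted_entities == {"WB:WBGene00006946"}
    assert any("merging" in r.message for r in caplog.records)


def test_lenient_mode_sniffs_misplaced_columns():
    # entity id in column 3 without the empty tab
    (rule,) = parse_rules("GO:0002181\tGO:0006605\tWB:WBGene00006946\n",
                          lenient=True)
    assert rule.excepted_entities == {"WB:WBGene00006946"}
    assert rule.excepted_terms == frozenset()


def test_load_family_map():
    fam = load_family_map("# comment\nWB:WBGene1\tPTHR10000\n")
    assert fam == {"WB:WBGene1": "PTHR10000"}


# --- evaluation on the demo corpus ----------------------------------------


def rule_for(demo, t1, t2):
    return next(r for r in demo.rules if r.pair == frozenset((t1, t2)))


def test_plain_pair_coannotation_is_a_violation(demo):
    found = check_rule(rule_for(demo, "GO:0006399", "GO:0006457"), demo.index)
    assert {v.gene for v in found} == {"PomBase:SPDEMO01", "PomBase:SPDEMO07"}


def test_excepted_term_annotation_exempts_only_carriers(demo):
    found = check_rule(rule_for(demo, "GO:0006399", "GO:0006310"), demo.index)
    # SPDEMO02 carries isotype switching and is exempt; SPDEMO03 is not
    assert [v.gene for v in found] == ["PomBase:SPDEMO03"]


def test_excepted_gene_exempts_only_that_gene(demo):
    found = check_rule(rule_for(demo, "GO:0002181", "GO:0006605"), demo.index)
    assert [v.gene for v in found] == ["PomBase:SPDEMO05"]


def test_descendant_annotation_violates_through_closure(demo):
    # SPDEMO07 carries only a descendant of tRNA metabolism
    found = check_rule(rule_for(demo, "GO:0006399", "GO:0006457"), demo.index)
    v = next(v for v in found if v.gene == "PomBase:SPDEMO07")
    assert v.direct_terms_1 == {"GO:9000001"}
    assert v.direct_terms_2 == {"GO:0006457"}


def test_violation_provenance_is_nonempty_and_direct(demo):
    report = check_all(demo.rules, demo.index)
    for v in report.violations:
        assert v.direct_terms_1 and v.direct_terms_2
        for d in v.direct_terms_1:
            assert v.rule.term1 in demo.closure.lookup(d)


# --- exception mechanisms needing bespoke corpora --------------------------

EXC_OBO = """\
[Term]
id: GO:0000001
name: process a

[Term]
id: GO:0000002
name: process b

[Term]
id: GO:0000003
name: allowed context

[Term]
id: GO:0000004
name: allowed context subtype
is_a: GO:0000003
"""


def exc_corpus(extra_gaf: str = "") -> Corpus:
    gaf = (
        HEADER
        + gaf_line(gene="DB:G1", term="GO:0000001") + "\n"
        + gaf_line(gene="DB:G1", term="GO:0000002") + "\n"
        + extra_gaf
    )
    return Corpus.load(EXC_OBO, gaf, "GO:0000001\tGO:0000002\tGO:0000003\n")


def test_excepted_term_matches_through_closure():
    # annotation to a *descendant* of the excepted term also exempts
    corpus = exc_corpus(gaf_line(gene="DB:G1", term="GO:0000004") + "\n")
    assert check_rule(corpus.rules[0], corpus.index) == []
    # without that annotation the gene violates
    corpus = exc_corpus()
    assert [v.gene for v in check_rule(corpus.rules[0], corpus.index)] == ["DB:G1"]


def family_rule():
    return Rule("GO:0000001", "GO:0000002",
                excepted_entities=frozenset({"PTHR10000"}))


def test_family_exception_requires_and_uses_the_map(caplog):
    corpus = exc_corpus()
    rule = family_rule()
    assert check_rule(rule, corpus.index,
                      family_map={"DB:G1": "PTHR10000"}) == []
    assert [v.gene for v in check_rule(rule, corpus.index,
                                       family_map={"DB:G1": "PTHR99999"})] == ["DB:G1"]
    with caplog.at_level(logging.WARNING, logger="coannoqc.rules"):
        found = check_rule(rule, corpus.index, family_map=None)
    assert [v.gene for v in found] == ["DB:G1"]
    assert any("family" in r.message for r in caplog.records)


def test_taxon_curie_exception_matches_the_genes_taxon():
    corpus = exc_corpus()  # gene taxon is taxon:4896
    rule = Rule("GO:0000001", "GO:0000002",
                excepted_entities=frozenset({"NCBITaxon:4896"}))
    assert check_rule(rule, corpus.index) == []
    rule = Rule("GO:0000001", "GO:0000002",
                excepted_entities=frozenset({"NCBITaxon:9606"}))
    assert [v.gene for v in check_rule(rule, corpus.index)] == ["DB:G1"]


# --- check_all and reports --------------------------------------------------


def test_empty_rule_list_gives_empty_report(demo):
    report = check_all([], demo.index)
    assert report.violations == [] and report.summary == {}


def test_all_disjoint_pairs_yield_zero_violations(demo):
    # the NO OVERLAP state: rules over pairs with empty intersections
    rules = parse_rules(
        "GO:0002181\tGO:0006310\nGO:0006605\tGO:0006457\n"
    )
    report = check_all(rules, demo.index)
    assert report.total == 0
    assert set(report.summary.values()) == {0}


def test_check_all_matches_exhaustive_gene_rule_scan(demo):
    report = check_all(demo.rules, demo.index)
    got = {(v.rule.term1, v.rule.term2, v.gene) for v in report.violations}
    expected = brute_violations(demo.rules, demo.annotations, demo.graph,
                                DEFAULT_RELATIONS)
    assert got == expected
    assert sum(report.summary.values()) == report.total


def test_empty_exceptions_violations_equal_raw_intersection(demo):
    bare = Rule("GO:0006399", "GO:0006457")
    found = check_rule(bare, demo.index)
    assert {v.gene for v in found} == intersection_genes(
        demo.index, "GO:0006399", "GO:0006457"
    )


def test_adding_exceptions_never_increases_violations(demo):
    base = Rule("GO:0006399", "GO:0006457")
    n_base = len(check_rule(base, demo.index))
    for exc in [
        Rule("GO:0006399", "GO:0006457",
             excepted_terms=frozenset({"GO:9000001"})),
        Rule("GO:0006399", "GO:0006457",
             excepted_entities=frozenset({"PomBase:SPDEMO01"})),
        Rule("GO:0006399", "GO:0006457",
             excepted_entities=frozenset({"NCBITaxon:4896"})),
    ]:
        assert len(check_rule(exc, demo.index)) <= n_base


def test_correction_loop_reaches_zero_violations(demo):
    # drop every violating gene's annotations, rebuild, re-check
    report = check_all(demo.rules, demo.index)
    bad_genes = {v.gene for v in report.violations}
    assert bad_genes
    corrected = [a for a in demo.annotations if a.gene.id not in bad_genes]
    index2 = build_index(corrected, demo.closure)
    assert check_all(demo.rules, index2).total == 0


def test_report_is_byte_identical_across_runs(demo):
    def run():
        corpus = Corpus.load(demo.obo, demo.gaf, demo.rules_text)
        return write_report(check_all(corpus.rules, corpus.index), "json")

    assert run() == run()


def test_empty_report_is_header_only_tsv(demo):
    text = write_report(check_all([], demo.index), "tsv")
    assert text.splitlines() == [
        "rule_line\tterm1\tterm2\tgene\tdirect_terms_1\tdirect_terms_2"
    ]


def test_one_violation_report_is_two_tsv_lines(demo):
    rule = rule_for(demo, "GO:0002181", "GO:0006605")
    report = check_all([rule], demo.index)
    assert len(write_report(report, "tsv").strip().splitlines()) == 2


def test_tsv_report_round_trips_rule_gene_pairs(demo):
    report = check_all(demo.rules, demo.index)
    lines = write_report(report, "tsv").strip().splitlines()[1:]
    reparsed = {(c[1], c[2], c[3]) for c in (l.split("\t") for l in lines)}
    assert reparsed == {
        (v.rule.term1, v.rule.term2, v.gene) for v in report.violations
    }
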