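"""Cutoff filtering and the majority/score merge rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxconsensus import (
    Config,
    RankedLineage,
    ScoredAssignment,
    TaxonomyError,
    TaxonomyTable,
    apply_cutoff,
    build_consensus,
    consensus_rank,
    harmonize,
)
from taxconsensus.consensus import DEFAULT_TIE_ORDER
from taxconsensus.core import (
    RULE_ALL_AGREE,
    RULE_MAJORITY,
    RULE_NONE,
    RULE_SCORE_BREAK,
    RULE_SINGLE,
    SOURCES,
)

from ._oracle import oracle_consensus
from .conftest import all_rank_configs


def _sa(otu, names, scores):
    return ScoredAssignment(otu, RankedLineage.from_names(names),
                            tuple(scores) + (None,) * (7 - len(scores)))


def _table(source, assignments):
    t = TaxonomyTable(source)
    for sa in assignments:
        t.assignments[sa.otu_id] = sa
    return t


class TestConsensusRank:
    @pytest.mark.parametrize("calls,expect_name,expect_rule", [
        # the seven published rule-table rows
        ((("A", .9), ("A", .9), ("A", .9)), "A", RULE_ALL_AGREE),
        ((("A", .9), ("A", .9), ("B", .9)), "A", RULE_MAJORITY),
        ((("A", .90), ("B", .95), ("C", .85)), "B", RULE_SCORE_BREAK),
        ((("A", .9), ("A", .8), None), "A", RULE_MAJORITY),
        ((("A", .85), ("B", .95), None), "B", RULE_SCORE_BREAK),
        ((("A", .9), None, None), "A", RULE_SINGLE),
        ((None, None, None), None, RULE_NONE),
    ])
    def test_rule_table_rows(self, calls, expect_name, expect_rule):
        decision = consensus_rank(calls)
        assert decision.name == expect_name
        assert decision.rule == expect_rule

    def test_exact_score_tie_follows_tie_order(self):
        calls = (("A", 0.9), ("B", 0.9), None)  # RDP vs UTAX, tied
        assert consensus_rank(calls, ("RDP", "UTAX", "SINTAX")).name == "A"
        assert consensus_rank(calls, ("UTAX", "RDP", "SINTAX")).name == "B"
        # default priority is RDP, SINTAX, UTAX
        calls = (None, ("B", 0.9), ("C", 0.9))
        assert consensus_rank(calls, DEFAULT_TIE_ORDER).name == "C"

    def test_provenance_sources_and_score(self):
        d = consensus_rank((("A", .9), ("B", .7), ("A", .95)))
        assert d.rule == RULE_MAJORITY
        assert d.sources == ("RDP", "SINTAX")
        assert d.score == .95

    def test_matches_independent_oracle_on_all_configs(self):
        n = 0
        for calls in all_rank_configs():
            got = consensus_rank(calls, DEFAULT_TIE_ORDER, SOURCES)
            want = oracle_consensus(calls, DEFAULT_TIE_ORDER, SOURCES)
            assert got.name == want, f"disagreement on {calls}"
            n += 1
        assert n == 4 ** 3 * 3 ** 3


class TestApplyCutoff:
    def test_truncates_at_first_subthreshold_rank(self):
        t = _table("RDP", [_sa("O1", ["K", "P", "C", "O"],
                               [1.0, 0.85, 0.60, 0.90])])
        out = apply_cutoff(t, 0.8)
        sa = out.assignments["O1"]
        assert sa.lineage.names == ("K", "P", None, None, None, None, None)
        assert sa.scores[:2] == (1.0, 0.85)

    def test_noop_when_all_pass_or_cutoff_zero(self):
        t = _table("RDP", [_sa("O1", ["K", "P"], [0.9, 0.81]),
                           _sa("O2", ["K"], [0.3])])
        assert apply_cutoff(t, 0.8).assignments["O1"] == \
            t.assignments["O1"]
        assert apply_cutoff(t, 0.0).assignments == t.assignments

    def test_invalid_cutoff_errors(self):
        with pytest.raises(TaxonomyError):
            apply_cutoff(_table("RDP", []), 1.5)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=7),
           st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_assigned_count_monotone_in_cutoff(self, scores, c1, c2):
        lo, hi = min(c1, c2), max(c1, c2)
        names = [f"T{i}" for i in range(len(scores))]
        t = _table("RDP", [_sa("O1", names, scores)])
        low = apply_cutoff(t, lo).assignments["O1"].lineage.n_assigned
        high = apply_cutoff(t, hi).assignments["O1"].lineage.n_assigned
        assert high <= low


def _three_tables(per_source):
    tables = [_table(src, [ _sa(otu, names, scores)
                            for otu, names, scores in rows])
              for src, rows in zip(SOURCES, per_source)]
    return harmonize(tables)


class TestBuildConsensus:
    def test_unanimity_reproduces_any_input(self):
        rows = [("O1", ["Fungi", "Ascomycota"], [1.0, 0.9])]
        tables = _three_tables([rows, rows, rows])
        consensus, records = build_consensus(tables, Config())
        assert consensus.assignments["O1"].lineage == \
            tables[0].assignments["O1"].lineage
        assert records[0].decisions[0].rule == RULE_ALL_AGREE
        assert not records[0].chimeric

    def test_majority_overrides_lone_disagreement(self):
        # two classifiers in one phylum outvote the third
        tables = _three_tables([
            [("O1", ["Fungi", "Basidiomycota"], [1.0, 0.9])],
            [("O1", ["Fungi", "Ascomycota"], [1.0, 0.99])],
            [("O1", ["Fungi", "Basidiomycota"], [1.0, 0.85])],
        ])
        consensus, records = build_consensus(tables, Config())
        assert consensus.assignments["O1"].lineage.names[1] == \
            "Basidiomycota"
        assert records[0].decisions[1].sources == ("RDP", "SINTAX")

    def test_single_assignment_is_adopted(self):
        tables = _three_tables([
            [("O1", ["Fungi", "Basidiomycota", "Agaricomycetes"],
              [1.0, 0.9, 0.88])],
            [("O1", ["Fungi"], [1.0])],
            [("O1", ["Fungi", "Basidiomycota"], [1.0, 0.95])],
        ])
        consensus, records = build_consensus(tables, Config())
        assert consensus.assignments["O1"].lineage.names[2] == \
            "Agaricomycetes"
        assert records[0].decisions[2].rule == RULE_SINGLE

    def test_mismatched_universes_error(self):
        t1 = _table("RDP", [_sa("O1", ["K"], [1.0])])
        t2 = _table("UTAX", [_sa("O2", ["K"], [1.0])])
        t3 = _table("SINTAX", [_sa("O1", ["K"], [1.0])])
        with pytest.raises(TaxonomyError, match="harmonize"):
            build_consensus([t1, t2, t3], Config())

    def test_idempotent_on_its_own_output(self, study_tables):
        tables = harmonize(list(study_tables.values()))
        filtered = [apply_cutoff(t, 0.8) for t in tables]
        consensus, _ = build_consensus(filtered, Config())
        again, _ = build_consensus([consensus] * 3, Config())
        assert again.assignments == consensus.assignments

    def test_permutation_invariant_off_ties(self, study_tables):
        config = Config()
        tables = [apply_cutoff(t, config.cutoff)
                  for t in harmonize(list(study_tables.values()))]
        base, _ = build_consensus(tables, config)
        # scores are continuous draws, so exact ties have measure zero
        shuffled, _ = build_consensus(
            [tables[2], tables[0], tables[1]], config)
        assert {o: sa.lineage for o, sa in base.assignments.items()} == \
            {o: sa.lineage for o, sa in shuffled.assignments.items()}

    def test_chimeric_lineage_flagged(self):
        # consensus adopts Phylum from one source and Class from another,
        # a parent/child pair no single classifier reported
        tables = _three_tables([
            [("O1", ["Fungi", "Basidiomycota"], [1.0, 0.99])],
            [("O1", ["Fungi", "Ascomycota", "Sordariomycetes"],
              [1.0, 0.9, 0.9])],
            [("O1", ["Fungi", "Basidiomycota"], [1.0, 0.95])],
        ])
        consensus, records = build_consensus(tables, Config())
        assert consensus.assignments["O1"].lineage.names[1:3] == \
            ("Basidiomycota", "Sordariomycetes")
        assert records[0].chimeric

    def test_divergent_rank_decisions_are_independent(self):
        # agreement can be lost at one rank and regained via other rules
        tables = _three_tables([
            [("O1", ["Fungi", "Basidiomycota", "Pucciniomycetes"],
              [1.0, 0.9, 0.9])],
            [("O1", ["Fungi", "Ascomycota"], [1.0, 0.85])],
            [("O1", ["Fungi", "Basidiomycota", "Agaricomycetes"],
              [1.0, 0.9, 0.95])],
        ])
        consensus, records = build_consensus(tables, Config())
        assert records[0].decisions[1].rule == RULE_MAJORITY
        assert records[0].decisions[2].rule == RULE_SCORE_BREAK
        assert consensus.assignments["O1"].lineage.names[2] == \
            "Agaricomycetes"
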