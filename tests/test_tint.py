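import numpy as np
import pytest

from retroscape import synthetic_data as sd
from retroscape.repeat_io import RepeatAnnotation
from retroscape.tint_activity import (
    PrecedenceMatrix,
    build_precedence_matrix,
    detect_nested,
    estimate_activity_order,
    link_fragments,
)


def ann(q, qs, qe, fam, cs, ce, strand="+", link=None):
    return RepeatAnnotation(q, qs, qe, strand, fam, cs, ce, 0, link_id=link)


class TestLinkFragments:
    def test_shared_link_id_chains(self):
        chains = link_fragments([ann("q", 1, 100, "A", 1, 100, link=4),
                                 ann("q", 500, 600, "A", 101, 201, link=4)])
        assert len(chains) == 1 and len(chains[0].fragments) == 2

    def test_different_strands_never_chain(self):
        chains = link_fragments([ann("q", 1, 100, "A", 1, 100),
                                 ann("q", 150, 250, "A", 101, 201, strand="C")])
        assert len(chains) == 2

    def test_large_consensus_gap_breaks_chain(self):
        chains = link_fragments([ann("q", 1, 100, "A", 1, 100),
                                 ann("q", 150, 250, "A", 201, 301)])
        assert len(chains) == 2

    def test_heuristic_chains_across_nested_insert(self):
        rows = [
            ann("q", 1, 100, "A", 1, 100),
            ann("q", 101, 400, "B", 1, 300),
            ann("q", 401, 500, "A", 101, 200),
        ]
        chains = link_fragments(rows)
        sizes = sorted(len(c.fragments) for c in chains)
        assert sizes == [1, 2]

    def test_c_strand_consensus_runs_backwards(self):
        rows = [
            ann("q", 1, 100, "A", 101, 200, strand="C"),
            ann("q", 300, 400, "A", 1, 100, strand="C"),
        ]
        assert len(link_fragments(rows)) == 1


class TestDetectNested:
    def test_simple_sandwich(self):
        rows = [
            ann("q", 1, 100, "A", 1, 100, link=1),
            ann("q", 150, 350, "B", 1, 201, link=2),
            ann("q", 400, 500, "A", 101, 201, link=1),
        ]
        (event,) = detect_nested(link_fragments(rows))
        assert (event.inner_family, event.outer_family) == ("B", "A")

    def test_no_multifragment_chains_no_events(self):
        rows = [ann("q", 1, 100, "A", 1, 100), ann("q", 200, 300, "B", 1, 101)]
        assert detect_nested(link_fragments(rows)) == []

    def test_partial_overlap_discarded(self):
        rows = [
            ann("q", 1, 100, "A", 1, 100, link=1),
            ann("q", 80, 350, "B", 1, 271, link=2),
            ann("q", 400, 500, "A", 101, 201, link=1),
        ]
        assert detect_nested(link_fragments(rows)) == []

    def test_double_nesting_yields_two_events(self):
        # A( B( C ) B )A: C into B and B into A, not C into A
        rows = [
            ann("q", 1, 100, "A", 1, 100, link=1),
            ann("q", 150, 250, "B", 1, 101, link=2),
            ann("q", 300, 400, "C", 1, 101, link=3),
            ann("q", 450, 550, "B", 102, 202, link=2),
            ann("q", 600, 700, "A", 101, 201, link=1),
        ]
        events = detect_nested(link_fragments(rows))
        directions = sorted((e.inner_family, e.outer_family) for e in events)
        assert directions == [("B", "A"), ("C", "B")]


class TestMatrix:
    def test_single_event_counts(self):
        rows = [
            ann("q", 1, 100, "A", 1, 100, link=1),
            ann("q", 150, 350, "B", 1, 201, link=2),
            ann("q", 400, 500, "A", 101, 201, link=1),
        ]
        m = build_precedence_matrix(detect_nested(link_fragments(rows)))
        assert m.counts.loc["B", "A"] == 1 and m.total_events == 1

    def test_empty_and_permutation(self):
        assert build_precedence_matrix([], ["A", "B"]).total_events == 0
        pairs = [("B", "A")] * 3 + [("A", "B")] * 2
        m1 = PrecedenceMatrix.from_pairs(pairs)
        m2 = PrecedenceMatrix.from_pairs(pairs[::-1])
        assert m1.counts.equals(m2.counts)

    def test_inner_outer_totals_conserved(self, bundle):
        from retroscape.tint_activity import link_fragments as lf

        events = detect_nested(lf(bundle.annotations))
        m = build_precedence_matrix(events)
        assert m.total_events == len(events)
        assert m.counts.sum(axis=1).sum() == m.counts.sum(axis=0).sum() == len(events)


class TestOrder:
    def test_one_directional_counts(self):
        m = PrecedenceMatrix.from_pairs([("A", "B")] * 12)
        order = estimate_activity_order(m, min_events=10)
        assert order.families == ["A", "B"]
        assert dict(order.ranking) == {"A": 1.0, "B": 0.0}

    def test_symmetric_pair_flagged_unresolved(self):
        m = PrecedenceMatrix.from_pairs([("A", "B")] * 5 + [("B", "A")] * 5)
        order = estimate_activity_order(m, min_events=10)
        assert not order.pair_tests.iloc[0]["resolved"]

    def test_self_nesting_excluded_from_scores(self):
        m = PrecedenceMatrix.from_pairs([("A", "A")] * 50 + [("A", "B")] * 12)
        order = estimate_activity_order(m, min_events=10)
        assert dict(order.ranking)["A"] == 1.0

    def test_insufficient_family_reported(self):
        m = PrecedenceMatrix.from_pairs([("A", "B")] * 12 + [("C", "B")] * 2)
        order = estimate_activity_order(m, min_events=10)
        assert order.insufficient == ["C"]

    def test_fewer_than_two_eligible_errors(self):
        m = PrecedenceMatrix.from_pairs([("A", "B")] * 3)
        with pytest.raises(ValueError, match="2 families"):
            estimate_activity_order(m, min_events=10)

    def test_relabeling_invariance(self):
        pairs = [("A", "B")] * 20 + [("B", "C")] * 15 + [("A", "C")] * 5
        m1 = PrecedenceMatrix.from_pairs(pairs)
        ren = {"A": "X", "B": "Y", "C": "Z"}
        m2 = PrecedenceMatrix.from_pairs([(ren[i], ren[o]) for i, o in pairs])
        o1 = estimate_activity_order(m1, 10)
        o2 = estimate_activity_order(m2, 10)
        assert [ren[f] for f in o1.families] == o2.families
        assert [s for _, s in o1.ranking] == [s for _, s in o2.ranking]


class TestSimulatedHistoryRecovery:
    def test_sequential_history_recovered_through_full_path(self):
        windows = {"A": (80.0, 61.0), "B": (60.0, 41.0),
                   "C": (40.0, 21.0), "D": (20.0, 1.0)}
        annotations, _, true_order = sd.simulate_activity_history(windows, 400, seed=99)
        chains = link_fragments(annotations)
        events = detect_nested(chains)
        m = build_precedence_matrix(events)
        order = estimate_activity_order(m, min_events=10)
        assert order.families == true_order

    def test_youngest_family_tops_ranking_across_replicates(self):
        windows = {"A": (80.0, 61.0), "B": (60.0, 41.0), "C": (40.0, 1.0)}
        wins = 0
        for seed in range(40):
            _, truth, true_order = sd.simulate_activity_history(windows, 500, seed=seed)
            m = PrecedenceMatrix.from_pairs(
                list(zip(truth["inner_family"], truth["outer_family"])), list(windows)
            )
            order = estimate_activity_order(m, min_events=10)
            wins += order.families[0] == true_order[0]
        assert wins / 40 >= 0.95
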