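"""Levenshtein distance, clone sharing, and CDR3 similarity networks."""

import itertools
import random

import pytest

from tcrep import (
    Clonotype,
    Group,
    Repertoire,
    RepertoireSet,
    ValidationError,
    build_network,
    levenshtein,
    network_summary,
    shared_clones,
)

from helpers import brute_force_shared, dp_levenshtein, random_cdr3_string


def rep_from(counts, animal, group=Group.RESPONDER):
    return Repertoire(animal, [Clonotype(c, n) for c, n in counts.items()], group=group)


def cohort(reps, tracked=("CASGETGTNERLFF",)):
    return RepertoireSet({r.animal_id: r for r in reps}, tracked_clones=list(tracked))


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("CASSL", "CASSL", 0),
            ("CASSL", "CASSF", 1),   # substitution
            ("CASSL", "CASSLG", 1),  # insertion
            ("CASSLG", "CASSL", 1),  # deletion, symmetric
            ("CAT", "GCT", 2),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected

    def test_empty_string_rejected(self):
        with pytest.raises(ValidationError):
            levenshtein("", "CASSL")

    def test_agrees_with_dp_reference_on_random_pairs(self):
        rng = random.Random(2024)
        for _ in range(500):
            a = random_cdr3_string(rng)
            b = random_cdr3_string(rng)
            d = levenshtein(a, b)
            assert d == dp_levenshtein(a, b)
            assert d == levenshtein(b, a)

    def test_triangle_inequality(self):
        rng = random.Random(8)
        for _ in range(100):
            a, b, c = (random_cdr3_string(rng) for _ in range(3))
            assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestSharedClones:
    def test_disjoint_repertoires_share_nothing(self):
        reps = [
            rep_from({f"CASS{aa}GELFF": 2}, f"m{aa}")
            for aa in "ACD"
        ]
        result = shared_clones(cohort(reps))
        assert len(result.table) == 0

    def test_responder_only_sharing_classified(self):
        reps = [
            rep_from({"CASSWSHAREDF": 2, "CASSAGELFF": 1}, "r1", Group.RESPONDER),
            rep_from({"CASSWSHAREDF": 4}, "r2", Group.RESPONDER),
            rep_from({"CASSDGELFF": 3}, "n1", Group.NON_RESPONDER),
        ]
        table = shared_clones(cohort(reps)).table
        assert len(table) == 1
        row = table.iloc[0]
        assert row.cdr3_aa == "CASSWSHAREDF"
        assert row.n_animals_total == 2
        assert row.sharing_class == "responders_only"

    def test_five_animal_toy_matches_brute_force(self, two_group_cohort):
        result = shared_clones(two_group_cohort)
        oracle = brute_force_shared(
            {r.animal_id: r.counts() for r in two_group_cohort}
        )
        assert set(result.table.cdr3_aa) == set(oracle)
        for row in result.table.itertuples(index=False):
            assert row.n_animals_total == len(oracle[row.cdr3_aa])
            assert row.n_responders + row.n_non_responders == row.n_animals_total
        classes = dict(zip(result.table.cdr3_aa, result.table.sharing_class))
        assert classes["CASSRRSHAREDF"] == "responders_only"
        assert classes["CASSNNSHAREDF"] == "non_responders_only"
        assert classes["CASSMWSHAREDF"] == "mixed"

    def test_degree_histogram(self, two_group_cohort):
        hist = shared_clones(two_group_cohort).degree_histogram
        assert hist.set_index("n_animals").n_clones.to_dict() == {2: 3}

    def test_tracked_clone_excluded_by_default(self):
        tracked = "CASGETGTNERLFF"
        reps = [
            rep_from({tracked: 5}, "r1", Group.RESPONDER),
            rep_from({tracked: 7}, "n1", Group.NON_RESPONDER),
        ]
        assert len(shared_clones(cohort(reps)).table) == 0
        kept = shared_clones(cohort(reps), exclude=[])
        assert list(kept.table.cdr3_aa) == [tracked]

    def test_invariant_under_animal_ordering(self, two_group_cohort):
        reps = list(two_group_cohort)
        reordered = RepertoireSet(
            {r.animal_id: r for r in reversed(reps)},
            tracked_clones=list(two_group_cohort.tracked_clones),
        )
        a = shared_clones(two_group_cohort).table
        b = shared_clones(reordered).table
        assert a.equals(b)

    def test_fewer_than_two_animals_rejected(self):
        with pytest.raises(ValidationError):
            shared_clones(cohort([rep_from({"CASSAGELFF": 1}, "m1")]))


TOY_SEQS = {
    "AAAAAAAA": 10,
    "AAAAAAAD": 5,  # 1 sub from the first
    "AAAAAADD": 3,  # 1 sub from the second, 2 from the first
    "CCCCCCCC": 2,
}


class TestBuildNetwork:
    def test_toy_edges_and_components(self):
        # single animal carrying four sequences; all pairwise distances
        # verified by hand with the DP recurrence
        rset = cohort([rep_from(TOY_SEQS, "r1")], tracked=())
        net = build_network(rset, top_n=10)
        assert set(map(frozenset, net.graph.edges())) == {
            frozenset({"AAAAAAAA", "AAAAAAAD"}),
            frozenset({"AAAAAAAD", "AAAAAADD"}),
        }
        assert sorted(len(c) for c in net.components) == [1, 3]

    def test_every_edge_reverifies_distance_one(self, small_cohort):
        net = build_network(small_cohort.repertoire_set, top_n=25)
        for a, b in net.graph.edges():
            assert dp_levenshtein(a, b) == 1
        # and no missed pair: recheck exhaustively with the DP oracle
        nodes = sorted(net.graph.nodes)
        expected = {
            frozenset({a, b})
            for a, b in itertools.combinations(nodes, 2)
            if dp_levenshtein(a, b) == 1
        }
        assert set(map(frozenset, net.graph.edges())) == expected

    def test_node_count_bounded_by_topn_times_animals(self, small_cohort):
        net = build_network(small_cohort.repertoire_set, top_n=50)
        assert net.graph.number_of_nodes() <= 50 * len(small_cohort.repertoire_set)

    def test_single_animal_cohort(self):
        rset = cohort([rep_from(TOY_SEQS, "n1", Group.NON_RESPONDER)], tracked=())
        net = build_network(rset, top_n=10)
        presences = {d["group_presence"] for _, d in net.graph.nodes(data=True)}
        assert presences == {"non_responders_only"}

    def test_clone_in_both_groups_is_flagged_both(self):
        reps = [
            rep_from({"CASSAGELFF": 5}, "r1", Group.RESPONDER),
            rep_from({"CASSAGELFF": 2, "CASSDGELFF": 9}, "n1", Group.NON_RESPONDER),
        ]
        net = build_network(cohort(reps, tracked=()), top_n=10)
        assert net.graph.nodes["CASSAGELFF"]["group_presence"] == "both"
        assert net.graph.nodes["CASSAGELFF"]["n_animals"] == 2

    def test_attributes_counted_over_full_repertoire_not_top_list(self):
        # clone ranks below top_n in r2 but still counts towards n_animals
        reps = [
            rep_from({"CASSAGELFF": 50}, "r1", Group.RESPONDER),
            rep_from({"CASSWGELFF": 50, "CASSAGELFF": 1}, "r2", Group.RESPONDER),
        ]
        net = build_network(cohort(reps, tracked=()), top_n=1)
        assert net.graph.nodes["CASSAGELFF"]["n_animals"] == 2

    def test_empty_node_set_rejected(self):
        reps = [rep_from({"CASSAGELFF": 1}, "r1")]
        with pytest.raises(ValidationError):
            build_network(cohort(reps, tracked=()), top_n=1, exclude=["CASSAGELFF"])


class TestNetworkSummary:
    def test_toy_summary_counts(self):
        rset = cohort([rep_from(TOY_SEQS, "r1")], tracked=())
        summary = network_summary(build_network(rset, top_n=10))
        assert summary.n_nodes == 4
        assert summary.n_nodes_in_networks == 3
        assert summary.n_components_ge2 == 1

    def test_edgeless_network(self):
        reps = [rep_from({"CASSAGELFF": 1, "CCCCCCCC": 1}, "r1")]
        summary = network_summary(build_network(cohort(reps, tracked=()), top_n=10))
        assert summary.n_nodes_in_networks == 0
        assert summary.n_components_ge2 == 0

    def test_responder_exclusive_component_listed(self):
        reps = [
            rep_from({"AAAAAAAA": 4, "AAAAAAAD": 3}, "r1", Group.RESPONDER),
            rep_from({"CCCCCCCC": 5, "CCCCCCCA": 1}, "n1", Group.NON_RESPONDER),
        ]
        summary = network_summary(build_network(cohort(reps, tracked=()), top_n=10))
        classes = {cls for cls, _ in summary.group_exclusive_components}
        assert classes == {"responders_only", "non_responders_only"}

    def test_mixed_component_not_exclusive(self):
        reps = [
            rep_from({"AAAAAAAA": 4}, "r1", Group.RESPONDER),
            rep_from({"AAAAAAAD": 3}, "n1", Group.NON_RESPONDER),
        ]
        summary = network_summary(build_network(cohort(reps, tracked=()), top_n=10))
        assert summary.n_components_ge2 == 1
        assert summary.group_exclusive_components == ()
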