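"""Cluster systems: hierarchies, P1-P3, arboreal reconstruction, bad arcs."""

import itertools

import pytest

from fbnet.clustersys import (
    ClusterSystem,
    ClusterSystemError,
    bad_arcs,
    build_arboreal_network,
    check_P123,
    collapse_bad_arcs,
    is_hierarchy,
    is_uniquely_determined,
    maximal_clusters,
    same_clusters_iff_collapse_equivalent,
)
from fbnet.netcore import are_equivalent, cluster_system, validate_network
from fbnet.genfix import fixture

from conftest import random_batch


def system(*clusters):
    return ClusterSystem.of(*clusters)


class TestHierarchy:
    def test_cherry_hierarchy(self):
        assert is_hierarchy(system({"1"}, {"2"}, {"1", "2"}))

    def test_crossing_pair_is_not_a_hierarchy(self):
        assert not is_hierarchy(
            system({"1"}, {"2"}, {"3"}, {"1", "2"}, {"2", "3"}, {"1", "2", "3"})
        )

    def test_cluster_systems_of_generated_trees_are_hierarchies(self):
        # oracle: the pairwise definition check is the implementation;
        # trees come from an independent route (the generator)
        for net in random_batch(25, n_leaves=6, n_hybrids=0, n_roots=1):
            assert is_hierarchy(ClusterSystem.from_network(net))

    def test_missing_trivial_cluster_fails(self):
        assert not is_hierarchy(system({"1"}, {"1", "2"}))


class TestP123:
    def test_arboreal_cluster_systems_satisfy_all_three(self):
        for net in random_batch(50, kind="arboreal", n_leaves=6, n_hybrids=2):
            assert check_P123(ClusterSystem.from_network(net)).all_ok()

    def test_disjoint_maximal_clusters_fail_p2(self):
        rep = check_P123(
            system({"1"}, {"2"}, {"3"}, {"4"}, {"1", "2"}, {"3", "4"})
        )
        assert rep.p1 and not rep.p2
        assert "p2" in rep.witnesses

    def test_fig6_cluster_system_passes(self, nets):
        assert check_P123(ClusterSystem.from_network(nets["fig6N"])).all_ok()

    def test_non_hierarchical_interior_fails_p1(self):
        rep = check_P123(
            system({"1"}, {"2"}, {"3"}, {"1", "2"}, {"2", "3"}, {"1", "2", "3"})
        )
        assert not rep.p1

    def test_missing_intersection_cluster_fails_p3(self):
        rep = check_P123(
            system({"1"}, {"2"}, {"3"}, {"4"}, {"1", "2", "3"}, {"2", "3", "4"})
        )
        assert rep.p1 and rep.p2 and not rep.p3


class TestBuild:
    def test_hierarchy_builds_its_unique_tree(self):
        cs = system({"1"}, {"2"}, {"3"}, {"1", "2"}, {"1", "2", "3"})
        net = build_arboreal_network(cs)
        assert len(net.roots) == 1 and not net.hybrids
        assert ClusterSystem.from_network(net) == cs

    def test_fig6_system_rebuilds_to_a_collapse_equivalent_network(self, nets):
        cs = ClusterSystem.from_network(nets["fig6N"])
        rebuilt = build_arboreal_network(cs)
        assert ClusterSystem.from_network(rebuilt) == cs
        assert are_equivalent(
            collapse_bad_arcs(rebuilt), collapse_bad_arcs(nets["fig6N"])
        )

    def test_round_trip_on_generated_arboreal_networks(self):
        for h in (1, 2, 3):
            for net in random_batch(25, kind="arboreal", n_leaves=4 + h, n_hybrids=h):
                cs = ClusterSystem.from_network(net)
                rebuilt = build_arboreal_network(cs)
                assert rebuilt.is_arboreal()
                assert len(rebuilt.roots) == len(maximal_clusters(cs))
                assert ClusterSystem.from_network(rebuilt) == cs
                assert are_equivalent(
                    collapse_bad_arcs(rebuilt), collapse_bad_arcs(net)
                )

    def test_failing_systems_are_refused_with_their_report(self):
        bad = system({"1"}, {"2"}, {"3"}, {"4"}, {"1", "2"}, {"3", "4"})
        with pytest.raises(ClusterSystemError) as e:
            build_arboreal_network(bad)
        assert not e.value.report.p2

    def test_three_pairwise_distinct_intersections_are_unrealizable(self):
        # P1-P3 hold but three maximal clusters with three distinct
        # pairwise intersections would need three hybrids, impossible in
        # an arboreal 3-network; the construction detects and refuses it
        cs = system({"1"}, {"2"}, {"3"}, {"1", "2"}, {"1", "3"}, {"2", "3"})
        assert check_P123(cs).all_ok()
        with pytest.raises(ClusterSystemError, match="no single attachment"):
            build_arboreal_network(cs)


class TestBadArcs:
    def test_fig6_bad_arcs_match_their_stated_hybrid_pairs(self, nets):
        assert bad_arcs(nets["fig6N"]) == {("h1", "h2")}
        assert bad_arcs(nets["fig6Nprime"]) == {("h2p", "h1p")}

    def test_trees_have_no_bad_arcs_and_collapse_is_identity(self):
        net = validate_network((), [("r", "1"), ("r", "2")])
        assert bad_arcs(net) == frozenset()
        assert collapse_bad_arcs(net) is net

    def test_bad_arc_presence_matches_triple_intersection_condition(self):
        # both sides computed independently on generated networks
        seen_with = seen_without = 0
        for h in (2, 3):
            for net in random_batch(40, kind="arboreal", n_leaves=4 + h, n_hybrids=h):
                cs = ClusterSystem.from_network(net)
                cm = sorted(maximal_clusters(cs), key=sorted)
                triple = any(
                    c1 & c2 == c1 & c3 == c2 & c3 != frozenset()
                    for c1, c2, c3 in itertools.combinations(cm, 3)
                )
                has_bad = bool(bad_arcs(net))
                assert triple == has_bad
                seen_with += has_bad
                seen_without += not has_bad
        assert seen_with and seen_without  # both branches exercised


class TestUniqueness:
    def test_fig6N_is_not_uniquely_determined(self, nets):
        assert not is_uniquely_determined(nets["fig6N"])

    def test_trees_are_uniquely_determined(self):
        net = validate_network((), [("r", "a"), ("r", "3"), ("a", "1"), ("a", "2")])
        assert is_uniquely_determined(net)

    def test_non_arboreal_input_is_rejected(self, nets):
        with pytest.raises(ValueError, match="arboreal"):
            is_uniquely_determined(nets["fig2"])

    def test_pair_predicate_on_fig6(self, nets):
        assert same_clusters_iff_collapse_equivalent(
            nets["fig6N"], nets["fig6Nprime"]
        ) == (True, True)
        assert same_clusters_iff_collapse_equivalent(
            nets["fig6N"], nets["fig6N"]
        ) == (True, True)
        assert same_clusters_iff_collapse_equivalent(
            nets["fig6N"], nets["fig5"]
        ) == (False, False)


def _all_arboreal_networks(max_n):
    """Every strict arboreal network with at most max_n vertices, leaves
    labelled x1..xL in all possible ways (independent brute-force route)."""
    import networkx as nx

    nets = []
    for n in range(2, max_n + 1):
        for shape in nx.nonisomorphic_trees(n):
            edges = list(shape.edges())
            for mask in range(2 ** len(edges)):
                arcs = [
                    (a, b) if mask >> i & 1 else (b, a)
                    for i, (a, b) in enumerate(edges)
                ]
                outdeg = {v: 0 for v in shape.nodes}
                indeg = {v: 0 for v in shape.nodes}
                for u, v in arcs:
                    outdeg[u] += 1
                    indeg[v] += 1
                ok = all(
                    not (indeg[v] == 0 and outdeg[v] < 2)
                    and not (indeg[v] >= 2 and (indeg[v] != 2 or outdeg[v] != 1))
                    and not (indeg[v] == 1 and outdeg[v] == 1)
                    for v in shape.nodes
                )
                if not ok:
                    continue
                leaves = sorted(v for v in shape.nodes if outdeg[v] == 0)
                for perm in itertools.permutations(range(1, len(leaves) + 1)):
                    ren = {v: f"x{perm[i]}" for i, v in enumerate(leaves)}
                    ren.update(
                        {v: f"i{v}" for v in shape.nodes if v not in leaves}
                    )
                    nets.append(
                        validate_network(
                            (), [(ren[u], ren[v]) for u, v in arcs], "strict"
                        )
                    )
    return nets


class TestExhaustiveUniqueness:
    def test_uniqueness_iff_no_bad_arc_over_all_small_arboreal_networks(self):
        """Brute force over every arboreal network with <= 8 vertices:
        a network has no bad arc exactly when no non-equivalent arboreal
        network shares its cluster system."""
        nets = _all_arboreal_networks(8)
        assert len(nets) > 10000
        groups: dict = {}
        for net in nets:
            key = frozenset(ClusterSystem.from_network(net).clusters)
            groups.setdefault(key, []).append(net)
        for members in groups.values():
            classes: list = []
            for net in members:
                for rep in classes:
                    if are_equivalent(net, rep):
                        break
                else:
                    classes.append(net)
            ambiguous = len(classes) > 1
            for net in members:
                assert is_uniquely_determined(net) == (not ambiguous)
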