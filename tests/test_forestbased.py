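"""Forest-based recognition: oracle, path partitions, arboreal route,
proper forest-basedness, base forests and universality."""

import itertools

import pytest

from fbnet.forestbased import (
    ArcBudgetExceeded,
    arboreal_forest_based,
    base_forests,
    has_forbidden_configuration,
    is_base_forest,
    is_forest_based,
    is_proper_forest_based,
    is_universal_forest_based,
    oracle_is_forest_based,
    path_partition_certificate,
    verify_certificate,
)
from fbnet.netcore import PhylogeneticForest, validate_network
from fbnet.genfix import fig11_configuration, fixture

from conftest import random_batch


def cherry12():
    return validate_network((), [("r", "1"), ("r", "2")])


class TestOracle:
    def test_fig5_admits_no_subdivision_forest(self, nets):
        assert oracle_is_forest_based(nets["fig5"]) is None

    def test_fig2_certificate_includes_the_stated_base_forest(self, nets):
        target = PhylogeneticForest([[{"1"}], [{"2"}], [{"3"}, {"4"}, {"3", "4"}]])
        assert target in base_forests(nets["fig2"])

    def test_cherry_is_forest_based_on_the_trivial_forest(self):
        cert = oracle_is_forest_based(cherry12())
        assert cert is not None
        assert len(cert.contact_arcs) == 1
        assert cert.base_forest == PhylogeneticForest([[{"1"}], [{"2"}]])

    def test_single_leaf_input_is_an_error_not_false(self):
        single = validate_network(["x"], [])
        with pytest.raises(ValueError):
            oracle_is_forest_based(single)
        with pytest.raises(ValueError):
            is_forest_based(single)

    def test_arc_budget_is_enforced(self):
        net = random_batch(1, n_leaves=8, n_hybrids=4)[0]
        assert len(net.arcs) > 18
        with pytest.raises(ArcBudgetExceeded):
            oracle_is_forest_based(net)


class TestPathPartition:
    def test_fig7_is_forest_based(self, nets):
        ok, pp = is_forest_based(nets["fig7"])
        assert ok
        cert = path_partition_certificate(nets["fig7"], pp)
        assert verify_certificate(nets["fig7"], cert)

    def test_fig5_is_not_forest_based(self, nets):
        assert is_forest_based(nets["fig5"]) == (False, None)

    def test_path_partition_paths_end_at_distinct_leaves(self, nets):
        ok, pp = is_forest_based(nets["fig2"])
        assert ok
        paths = pp.paths(nets["fig2"])
        ends = [p[-1] for p in paths]
        assert sorted(ends) == sorted(nets["fig2"].leaves)

    def test_agreement_with_exhaustive_oracle_on_random_networks(self):
        checked = 0
        for kind, m in (("general", 1), ("general", 2), ("tree_child", 1)):
            for seed_net in random_batch(35, kind=kind, n_leaves=4, n_hybrids=2, n_roots=m):
                if len(seed_net.arcs) > 18:
                    continue
                a = oracle_is_forest_based(seed_net) is not None
                b, pp = is_forest_based(seed_net)
                assert a == b
                if b:
                    cert = path_partition_certificate(seed_net, pp)
                    assert verify_certificate(seed_net, cert)
                checked += 1
        assert checked >= 90


class TestArborealRoute:
    def test_fig5_refuted_with_a_witness_hybrid(self, nets):
        ok, witness = arboreal_forest_based(nets["fig5"])
        assert not ok
        assert witness in ("h1", "h2")

    def test_single_rooted_arboreal_network_is_a_tree_and_forest_based(self):
        net = validate_network((), [("r", "a"), ("r", "3"), ("a", "1"), ("a", "2")])
        ok, cert = arboreal_forest_based(net)
        assert ok and verify_certificate(net, cert)

    def test_certificate_of_multirooted_arboreal_network_is_proper(self, nets):
        ok, cert = arboreal_forest_based(nets["fig6N"])
        assert ok
        assert len(cert.base_forest) == len(nets["fig6N"].roots)

    def test_agreement_with_path_partition_on_random_arboreal_networks(self):
        for h in (1, 2, 3):
            for net in random_batch(25, kind="arboreal", n_leaves=4 + h, n_hybrids=h):
                ok3, out = arboreal_forest_based(net)
                ok1, _ = is_forest_based(net)
                assert ok3 == ok1
                if ok3:
                    assert verify_certificate(net, out)

    def test_non_arboreal_input_is_rejected(self, nets):
        with pytest.raises(ValueError, match="arboreal"):
            arboreal_forest_based(nets["fig2"])


class TestProper:
    def test_fig7_is_not_proper_forest_based(self, nets):
        ok, _ = is_proper_forest_based(nets["fig7"])
        assert not ok

    def test_fig8_is_proper_forest_based(self, nets):
        ok, cert = is_proper_forest_based(nets["fig8"])
        assert ok and verify_certificate(nets["fig8"], cert)

    def test_fig2_proper_base_forest_is_the_two_cherries(self, nets):
        ok, cert = is_proper_forest_based(nets["fig2"])
        assert ok
        assert cert.base_forest == PhylogeneticForest(
            [[{"1"}, {"2"}, {"1", "2"}], [{"3"}, {"4"}, {"3", "4"}]]
        )

    def test_single_rooted_input_is_an_error(self, nets):
        with pytest.raises(ValueError, match="two roots"):
            is_proper_forest_based(nets["fig4B"])

    def test_proper_certificates_have_one_tree_per_root(self):
        for net in random_batch(40, n_leaves=5, n_hybrids=2, n_roots=2):
            ok, cert = is_proper_forest_based(net)
            if ok:
                assert len(cert.base_forest) == len(net.roots)


class TestLeafRootBounds:
    def test_forest_based_networks_have_at_least_m_leaves(self):
        for m in (1, 2, 3):
            for net in random_batch(20, n_leaves=2 * m + 1, n_hybrids=max(1, m - 1), n_roots=m):
                if len(net.arcs) <= 18 and is_forest_based(net)[0]:
                    assert len(net.leaves) >= len(net.roots)

    def test_when_leaf_count_equals_root_count_forest_based_is_proper(self):
        # |X| = m forces every base forest to have exactly m trees
        net = validate_network(
            (), [("p1", "h1"), ("p1", "h2"), ("p2", "h1"), ("p2", "h2"),
                 ("h1", "1"), ("h2", "2")],
        )
        assert len(net.leaves) == len(net.roots) == 2
        assert is_forest_based(net)[0]
        assert is_proper_forest_based(net)[0]


class TestBaseForest:
    def test_fig2_is_based_on_the_trivial_forest(self, nets):
        assert is_base_forest(
            nets["fig2"], PhylogeneticForest.trivial(nets["fig2"].leaves)
        )

    def test_fig2_is_based_on_the_stated_mixed_forest(self, nets):
        assert is_base_forest(
            nets["fig2"],
            PhylogeneticForest([[{"1"}], [{"2"}], [{"3"}, {"4"}, {"3", "4"}]]),
        )

    def test_certificate_base_forests_round_trip(self):
        for net in random_batch(15, n_leaves=4, n_hybrids=2, n_roots=1):
            ok, pp = is_forest_based(net)
            if ok:
                cert = path_partition_certificate(net, pp)
                assert is_base_forest(net, cert.base_forest)

    def test_wrong_label_set_is_rejected(self, nets):
        with pytest.raises(ValueError, match="label set"):
            is_base_forest(nets["fig2"], PhylogeneticForest.trivial({"a", "b"}))


class TestUniversality:
    def test_fig10_is_universal_on_three_labels(self, nets):
        assert is_universal_forest_based(nets["fig10"])

    def test_cherry_is_universal_on_two_labels(self):
        # the only phylogenetic forest on a 2-set is the trivial forest
        assert is_universal_forest_based(cherry12())

    def test_no_tested_four_leaf_network_is_universal(self, nets):
        assert not is_universal_forest_based(nets["fig2"])
        for net in random_batch(25, n_leaves=4, n_hybrids=2, n_roots=1):
            assert not is_universal_forest_based(net)
        for net in random_batch(15, n_leaves=4, n_hybrids=2, n_roots=2):
            assert not is_universal_forest_based(net)


class TestForbiddenConfiguration:
    @pytest.mark.parametrize("p,q", [(0, 0), (1, 1), (1, 2), (2, 2)])
    def test_detector_fires_on_built_configurations(self, p, q):
        host = fig11_configuration(p, q)
        assert has_forbidden_configuration(host, "x", "y")

    def test_breaking_a_chain_with_a_tree_vertex_hides_the_configuration(self):
        # same shape as (1,1) but the x-chain passes a tree vertex
        arcs = [
            ("rho", "w"), ("rho", "s1"), ("w", "t"), ("w", "u1"),
            ("t", "v1"), ("t", "x2"), ("v1", "x"), ("u1", "y"),
            ("s1", "v1"), ("s2", "u1"), ("s1", "s2"), ("s2", "z"),
        ]
        net = validate_network((), arcs)
        assert not has_forbidden_configuration(net, "x", "y")

    def test_no_configuration_without_shared_branching_parent(self):
        # hybrids all have tree-vertex children and no vertex has two
        # leaf-reaching hybrid-free-or-hybrid-only path pairs
        net = validate_network(
            (), [("r", "a"), ("r", "b"), ("a", "1"), ("a", "h"), ("b", "h"),
                 ("b", "c"), ("c", "4"), ("c", "3"), ("h", "d"),
                 ("d", "2"), ("d", "5")],
        )
        assert not has_forbidden_configuration(net, "1", "2")

    def test_fig10_exhibits_the_configuration_without_contradiction(self, nets):
        # every forest-based network shows the configuration at a lowest
        # branching vertex; for three leaves this coexists with
        # universality, while for four or more it forbids it
        pairs = [
            (x, y)
            for x, y in itertools.combinations(sorted(nets["fig10"].leaves), 2)
            if has_forbidden_configuration(nets["fig10"], x, y)
        ]
        assert pairs  # present, and the network is still universal
        assert is_universal_forest_based(nets["fig10"])
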