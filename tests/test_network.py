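"""Network structure: validation, displayed trees, attachment, geometry, RF."""
import pytest

from retnet import (NetworkError, PhyloNetwork, PhyloTree, add_reticulation,
                    as_network, contained_trees, make_species_tree,
                    random_network, reticulation_geometry, rf_distance,
                    tree_probability, validate)
from retnet.network import _display, _induction_choices

from conftest import brute_force_bipartitions


def _net(children, lengths, root, gamma=None):
    return PhyloNetwork(root, children, lengths, gamma)


class TestValidate:
    def test_plain_tree_is_valid_network(self, tree4):
        assert validate(as_network(tree4)) == []

    def test_gamma_sum_violation_reported(self, tree4):
        net = add_reticulation(as_network(tree4), ("u", "A"), ("v", "C"), 0.3)
        head = net.reticulation_nodes()[0]
        partner = [p for p in net.parents[head] if (p, head) in net.gamma][0]
        # corrupt: 0.3 + 0.6 != 1
        for p in net.parents[head]:
            net.gamma[(p, head)] = 0.3 if p != partner else 0.6
        net.gamma[[e for e in net.gamma if e[1] == head][0]]  # touch
        problems = validate(net)
        assert any("sum to 1" in p for p in problems)

    def test_cycle_detected(self):
        # back-edge h1 -> u creates a directed cycle u -> x -> h1 -> u;
        # the oracle is an independent DFS over the child map
        children = {"r": ("u", "D"), "u": ("x", "C"), "x": ("A", "h1"),
                    "h1": ("u",)}
        lengths = {e: 1.0 for e in
                   [("r", "u"), ("r", "D"), ("u", "x"), ("u", "C"),
                    ("x", "A"), ("x", "h1"), ("h1", "u")]}
        net = _net(children, lengths, "r")

        def has_cycle_dfs(children):
            WHITE, GRAY, BLACK = 0, 1, 2
            color = {}

            def visit(v):
                color[v] = GRAY
                for c in children.get(v, ()):
                    if color.get(c, WHITE) == GRAY:
                        return True
                    if color.get(c, WHITE) == WHITE and visit(c):
                        return True
                color[v] = BLACK
                return False

            return any(visit(v) for v in list(children) if color.get(v, WHITE) == WHITE)

        assert has_cycle_dfs(children)
        assert any("cycle" in p for p in validate(net))

    def test_degree_violations_named(self):
        net = _net({"r": ("A", "B", "C")},
                   {("r", "A"): 1.0, ("r", "B"): 1.0, ("r", "C"): 1.0}, "r")
        assert any("out-degree 3" in p for p in validate(net))

    def test_negative_length_reported(self, tree4):
        net = as_network(tree4)
        net.lengths[("u", "A")] = -0.1
        assert any("negative" in p for p in validate(net))


class TestContainedTrees:
    def test_tree_displays_itself(self, tree4):
        [(t, p)] = contained_trees(as_network(tree4))
        assert p == 1.0
        assert t.canonical_newick() == tree4.canonical_newick()

    def test_single_reticulation_probabilities(self, tree4):
        net = add_reticulation(as_network(tree4), ("u", "A"), ("v", "C"), 0.3)
        trees = contained_trees(net)
        assert sorted(p for _, p in trees) == pytest.approx([0.3, 0.7])

    def test_two_reticulations_product_weights(self):
        # 6-taxon caterpillar, two well-separated reticulations with gammas
        # 0.2 and 0.4: the four displayed topologies are distinct and carry
        # the four products {0.08, 0.12, 0.32, 0.48}
        tree = make_species_tree(6)
        net = add_reticulation(as_network(tree), ("i3", "3"), ("i4", "4"), 0.2)
        net = add_reticulation(net, ("i6", "6"), ("i2", "2"), 0.4)
        trees = contained_trees(net)
        assert len(trees) == 4
        assert sorted(p for _, p in trees) == pytest.approx(
            sorted([0.2 * 0.4, 0.2 * 0.6, 0.8 * 0.4, 0.8 * 0.6]))

    def test_probabilities_sum_to_one_on_random_networks(self, rng):
        for i in range(40):
            net = random_network(rng, n_taxa=int(rng.integers(4, 8)),
                                 n_reticulations=int(rng.integers(1, 4)))
            total = sum(p for _, p in contained_trees(net))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_at_most_2_to_h_trees(self, rng):
        for i in range(20):
            h = int(rng.integers(1, 4))
            net = random_network(rng, n_taxa=6, n_reticulations=h)
            assert len(contained_trees(net)) <= 2 ** h

    def test_displayed_trees_keep_taxon_set(self, rng):
        for i in range(20):
            net = random_network(rng, n_taxa=6, n_reticulations=3)
            for kept, _ in _induction_choices(net):
                t = _display(net, kept)
                assert set(t.leaves()) == set(net.leaves())
                # suppression: strictly binary result
                assert all(len(cs) == 2 for cs in t.children.values())


class TestTreeProbability:
    def test_not_displayed_gives_zero(self, tree4):
        net = add_reticulation(as_network(tree4), ("u", "A"), ("v", "C"), 0.3)
        other = PhyloTree(
            "r", {"r": ("u", "v"), "u": ("A", "D"), "v": ("B", "C")},
            {("r", "u"): 1.0, ("r", "v"): 1.0, ("u", "A"): 1.0,
             ("u", "D"): 1.0, ("v", "B"): 1.0, ("v", "C"): 1.0})
        assert tree_probability(net, other) == 0.0

    def test_taxon_mismatch_raises(self, tree4, caterpillar10):
        with pytest.raises(NetworkError):
            tree_probability(as_network(tree4), caterpillar10)

    def test_two_induction_sets_same_topology_sum(self, tree4):
        # plant two reticulations moving the same leaf A to the same place:
        # choosing either transfer edge (or both) can collapse to the same
        # unrooted topology, so probabilities of identical topologies add
        net = add_reticulation(as_network(tree4), ("v", "C"), ("u", "A"), 0.25)
        head1 = net.reticulation_nodes()[0]
        lower = [e for e in net.lengths if e[1] == "A"][0]
        net2 = add_reticulation(net, ("v", "D"), lower, 0.5)
        trees = contained_trees(net2)
        total = sum(p for _, p in trees)
        assert total == pytest.approx(1.0, abs=1e-12)
        probs = {}
        for kept, w in _induction_choices(net2):
            key = frozenset(_display(net2, kept).bipartitions())
            probs[key] = probs.get(key, 0.0) + w
        assert sorted(probs.values()) == pytest.approx(
            sorted(p for _, p in trees))
        for t, p in trees:
            assert tree_probability(net2, t) == pytest.approx(p)


class TestAddReticulation:
    def test_subdivision_halves_lengths(self, tree4):
        net = add_reticulation(as_network(tree4), ("u", "A"), ("v", "C"), 0.3)
        head = net.reticulation_nodes()[0]
        x1 = [p for p in net.parents[head] if p not in tree4.nodes()][0]
        assert net.lengths[("u", x1)] == pytest.approx(0.15)
        assert net.lengths[(x1, "A")] == pytest.approx(0.15)
        assert net.lengths[("v", head)] == pytest.approx(0.125)
        assert net.lengths[(head, "C")] == pytest.approx(0.125)
        assert net.lengths[(x1, head)] == 0.0

    def test_sibling_edges_rejected(self, tree4):
        with pytest.raises(NetworkError, match="sibling"):
            add_reticulation(as_network(tree4), ("u", "A"), ("u", "B"), 0.3)

    def test_identical_edges_rejected(self, tree4):
        with pytest.raises(NetworkError, match="identical"):
            add_reticulation(as_network(tree4), ("u", "A"), ("u", "A"), 0.3)

    def test_cycle_rejected(self, tree4):
        # transfer from a pendant edge up into its own ancestral edge
        with pytest.raises(NetworkError, match="cycle"):
            add_reticulation(as_network(tree4), ("u", "A"), ("r", "u"), 0.3)

    def test_gamma_out_of_range_rejected(self, tree4):
        with pytest.raises(NetworkError):
            add_reticulation(as_network(tree4), ("u", "A"), ("v", "C"), 1.0)

    def test_removing_new_edge_recovers_input(self, tree4):
        net = add_reticulation(as_network(tree4), ("u", "A"), ("v", "C"), 0.3)
        head = net.reticulation_nodes()[0]
        # keep the original (partner) parent: suppression must restore the
        # input tree exactly, lengths included
        partner = [p for p in net.parents[head] if p in tree4.nodes()][0]
        restored = _display(net, {head: partner})
        assert restored.canonical_newick() == tree4.canonical_newick()

    def test_total_tree_length_preserved(self, tree4, rng):
        base_total = tree4.total_length()
        for _ in range(10):
            edges = sorted(tree4.lengths)
            e1 = edges[rng.integers(len(edges))]
            e2 = edges[rng.integers(len(edges))]
            try:
                net = add_reticulation(as_network(tree4), e1, e2, 0.3)
            except NetworkError:
                continue
            # new reticulation edge has length 0, so subdivision conserves sum
            assert sum(net.lengths.values()) == pytest.approx(base_total)


class TestReticulationGeometry:
    def test_fixed_donor_diameter_series(self):
        # 16-taxon caterpillar, pendant 0.05 / internal 0.1: transfers from
        # taxon 1 to taxa 3..8 have diameters 0.15, 0.25, ..., 0.65
        tree = make_species_tree(16, pendant_length=0.05, internal_length=0.1)
        diameters = []
        for r in range(3, 9):
            net = add_reticulation(as_network(tree), tree.edge_above("1"),
                                   tree.edge_above(str(r)), 0.3)
            head = net.reticulation_nodes()[0]
            x1 = [p for p in net.parents[head] if p not in tree.nodes()][0]
            diameters.append(reticulation_geometry(net, (x1, head)).diameter)
        assert diameters == pytest.approx([0.15, 0.25, 0.35, 0.45, 0.55, 0.65])

    def test_diameter_matches_path_length_oracle(self, rng):
        # independent oracle: all-pairs path lengths on the subdivided tree
        tree = make_species_tree(8)
        for _ in range(10):
            edges = sorted(tree.lengths)
            e1 = edges[rng.integers(len(edges))]
            e2 = edges[rng.integers(len(edges))]
            try:
                net = add_reticulation(as_network(tree), e1, e2, 0.3)
            except NetworkError:
                continue
            head = net.reticulation_nodes()[0]
            x1 = [p for p in net.parents[head] if p not in tree.nodes()][0]
            geom = reticulation_geometry(net, (x1, head))
            # oracle: drop the reticulation edge, treat as tree, use the
            # depth/LCA path-length routine of PhyloTree
            children = {v: tuple(c for c in cs if (v, c) != (x1, head))
                        for v, cs in net.children.items()}
            lengths = {e: l for e, l in net.lengths.items() if e != (x1, head)}
            t = PhyloTree(net.root, children, lengths)
            assert geom.diameter == pytest.approx(t.path_length(x1, head))

    def test_leaf_end_attachments_have_zero_height(self):
        # pendant edges of length 0: the attachment midpoints sit at the
        # leaves, so no descendant hangs below either attachment point
        tree = make_species_tree(5, pendant_length=0.0, internal_length=0.2)
        net = add_reticulation(as_network(tree), tree.edge_above("3"),
                               tree.edge_above("5"), 0.3)
        head = net.reticulation_nodes()[0]
        x1 = [p for p in net.parents[head] if p not in tree.nodes()][0]
        assert reticulation_geometry(net, (x1, head)).height == 0.0

    def test_non_reticulation_edge_raises(self, tree4):
        net = add_reticulation(as_network(tree4), ("u", "A"), ("v", "C"), 0.3)
        with pytest.raises(NetworkError):
            reticulation_geometry(net, ("r", "u"))


class TestRfDistance:
    def test_identical_trees(self, tree4):
        assert rf_distance(tree4, tree4.copy()) == 0

    def test_one_nni_gives_two(self):
        t1 = make_species_tree(5)
        from retnet import apply_hgt
        t2 = apply_hgt(t1, t1.edge_above("3"), t1.edge_above("4"))
        # oracle: brute-force bipartition sets
        b1 = brute_force_bipartitions(t1)
        b2 = brute_force_bipartitions(t2)
        assert len(b1 ^ b2) == 2
        assert rf_distance(t1, t2) == 2

    def test_symmetry_and_dendropy_agreement(self, rng):
        import dendropy
        from retnet.newick import write_newick
        for _ in range(15):
            a = random_network(rng, n_taxa=7, n_reticulations=1)
            b = random_network(rng, n_taxa=7, n_reticulations=1)
            t1 = contained_trees(a)[0][0]
            t2 = contained_trees(b)[0][0]
            d = rf_distance(t1, t2)
            assert d == rf_distance(t2, t1)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert d == dendropy.calculate.treecompare.symmetric_difference(d1, d2)

    def test_taxon_mismatch_raises(self, tree4, caterpillar10):
        with pytest.raises(NetworkError):
            rf_distance(tree4, caterpillar10)
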