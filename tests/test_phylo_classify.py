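import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acrofp import phylo_classify as pc
from acrofp import pipeline as pl
from acrofp import synthetic_data as sd
from acrofp.trees import Node, parse_newick, to_newick

import oracles
from conftest import sim_inputs


class TestAlign:
    def test_identical_pair_gap_free(self):
        msa = pc.align([("a", "ACDEFG"), ("b", "ACDEFG")])
        assert msa.row("a") == msa.row("b") == "ACDEFG"

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            pc.align([("a", "ACD"), ("a", "ACD")])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            pc.align([("a", "ACD")])

    @given(st.lists(st.text(alphabet="ACDG", min_size=1, max_size=12),
                    min_size=2, max_size=5, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_ungapping_recovers_inputs(self, seqs):
        named = [(f"s{i}", s) for i, s in enumerate(seqs)]
        msa = pc.align(named)
        for sid, original in named:
            assert msa.ungapped(sid) == original
        assert len({len(row) for _, row in msa.rows}) == 1

    def test_center_star_within_twice_optimal_cost(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            seqs = ["".join(rng.choice(list("ACDG"),
                                       size=rng.integers(4, 10)))
                    for _ in range(3)]
            named = [(f"s{i}", s) for i, s in enumerate(seqs)]
            # unit-cost scoring: match 0, mismatch/gap -1
            msa = pc.align(named, match=0.0, mismatch=-1.0, gap=-1.0)
            cost = oracles.sp_cost([row for _, row in msa.rows])
            optimal = oracles.optimal_sp_cost_3(seqs)
            assert cost <= 2 * optimal

    def test_reference_panel_chromophores_in_common_columns(
            self, reference_alignment):
        rows, chromo_cols = reference_alignment
        msa = pc.align([(rid, row.replace("-", "")) for rid, row in rows])
        columns = {msa.columns_of(rid, chromo_cols) for rid, _ in rows}
        assert len(columns) == 1
        col_triplet = columns.pop()
        for rid, _ in rows:
            gapped = msa.row(rid)
            tri = "".join(gapped[c - 1] for c in col_triplet)
            assert tri[1:] == "YG" or tri[1:] == "FG"


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = pc.MSA([("a", "ACDEF"), ("b", "ACDEF")])
        d, ids = pc.distance_matrix(msa)
        assert d[0, 1] == 0.0

    def test_three_of_thirty(self):
        base = "A" * 30
        other = "C" * 3 + "A" * 27
        d, _ = pc.distance_matrix(pc.MSA([("a", base), ("b", other)]))
        assert d[0, 1] == pytest.approx(0.1)

    def test_hand_computed_three_rows(self):
        rows = [("a", "AAAA-"), ("b", "AACA-"), ("c", "CCCAA")]
        d, ids = pc.distance_matrix(pc.MSA(rows))
        assert d[ids.index("a"), ids.index("b")] == pytest.approx(1 / 4)
        assert d[ids.index("a"), ids.index("c")] == pytest.approx(3 / 4)
        assert d[ids.index("b"), ids.index("c")] == pytest.approx(2 / 4)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_zero_comparable_columns_error_names_pair(self):
        msa = pc.MSA([("left", "A--"), ("right", "-AA")])
        with pytest.raises(ValueError, match="left.*right"):
            pc.distance_matrix(msa)


def tree_distances(root: Node) -> tuple[np.ndarray, list[str]]:
    leaves = root.leaves()
    labels = [l.label for l in leaves]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = {id(x): (x.length or 0.0) for x in leaves[i].ancestors(True)}
            dist, node = 0.0, leaves[j]
            path = leaves[j].length or 0.0
            anc = leaves[j]
            total = 0.0
            node = leaves[j]
            while id(node) not in a:
                total += node.length or 0.0
                node = node.parent
            # climb from leaf i to the meeting node
            meet = node
            node = leaves[i]
            while node is not meet:
                total += node.length or 0.0
                node = node.parent
            d[i, j] = d[j, i] = total
    return d, labels


def random_tree(labels, rng) -> Node:
    nodes = [Node(label=l, length=float(rng.uniform(0.1, 1.0)))
             for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Node(length=float(rng.uniform(0.1, 1.0)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return nodes[0]


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = pc.nj_tree(d, ["a", "b", "c"])
        lengths = {n.label: n.length for n in tree.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_additive_four_taxon_split_and_path_lengths(self):
        # ((A,B),(C,D)) with internal branch 0.4
        tree = parse_newick("((A:0.2,B:0.3):0.4,(C:0.5,D:0.6):0.0);")
        d, labels = tree_distances(tree)
        nj = pc.nj_tree(d, labels)
        assert oracles.unrooted_splits(nj) == frozenset(
            {frozenset({"C", "D"})})
        # oracle: least-squares over all three quartets picks the same split
        assert oracles.quartet_least_squares(d, labels) == frozenset(
            {frozenset({"A", "B"}), frozenset({"C", "D"})})
        dn, ln = tree_distances(nj)
        order = [ln.index(l) for l in labels]
        assert np.allclose(dn[np.ix_(order, order)], d, atol=1e-9)

    def test_ultrametric_five_taxon_exact(self):
        tree = parse_newick(
            "(((A:1,B:1):1,C:2):1,(D:2.5,E:2.5):0.5);")
        d, labels = tree_distances(tree)
        nj = pc.nj_tree(d, labels)
        dn, ln = tree_distances(nj)
        order = [ln.index(l) for l in labels]
        assert np.allclose(dn[np.ix_(order, order)], d, atol=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_consistency(self, n):
        rng = np.random.default_rng(n * 17)
        labels = [f"t{i}" for i in range(n)]
        for _ in range(8):
            tree = random_tree(labels, rng)
            d, lab = tree_distances(tree)
            nj = pc.nj_tree(d, lab)
            assert oracles.unrooted_splits(nj) == oracles.unrooted_splits(tree)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError):
            pc.nj_tree(d, list("abc"))

    def test_tie_break_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = to_newick(pc.nj_tree(d, list("abcd")), lengths=False)
        t2 = to_newick(pc.nj_tree(d, list("abcd")), lengths=False)
        assert t1 == t2


class TestBootstrap:
    def test_default_replicates_is_1000(self):
        import inspect
        sig = inspect.signature(pc.bootstrap_support)
        assert sig.parameters["n_replicates"].default == 1000

    def test_perfect_signal_full_support(self):
        rows = [("a", "AAAA"), ("b", "AAAA"), ("c", "CCCC"), ("d", "CCCC")]
        supports = pc.bootstrap_support(pc.MSA(rows), n_replicates=100, seed=1)
        key = frozenset({"c", "d"})
        assert supports[key] == 100.0

    def test_bit_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(0)
        rows = [(f"s{i}", "".join(rng.choice(list("ACDG"), size=40)))
                for i in range(5)]
        s1 = pc.bootstrap_support(pc.MSA(rows), n_replicates=50, seed=7)
        s2 = pc.bootstrap_support(pc.MSA(rows), n_replicates=50, seed=7)
        assert s1 == s2


class TestRooting:
    def test_single_outgroup_leaf_child_of_root(self):
        un = pc.nj_tree(*reversed((list("abcd"),
                                   np.array([[0, .2, .6, .7],
                                             [.2, 0, .6, .7],
                                             [.6, .6, 0, .5],
                                             [.7, .7, .5, 0.0]]))))
        rooted = pc.root_tree(un, ["d"])
        assert any(c.label == "d" for c in rooted.children)

    def test_outgroup_rooting_idempotent(self):
        d = np.array([[0, .2, .6, .7],
                      [.2, 0, .6, .7],
                      [.6, .6, 0, .5],
                      [.7, .7, .5, 0.0]])
        un = pc.nj_tree(d, list("abcd"))
        r1 = pc.root_tree(un, ["c", "d"])
        r2 = pc.root_tree(r1, ["c", "d"])
        assert to_newick(r1) == to_newick(r2)

    def test_empty_outgroup_midpoint(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:5):1);")
        rooted = pc.root_tree(tree, [])
        # longest path is D..A/B (8); midpoint sits inside D's branch
        assert any(c.label == "D" for c in rooted.children)

    def test_midpoint_matches_brute_force(self):
        rng = np.random.default_rng(5)
        labels = [f"x{i}" for i in range(6)]
        tree = random_tree(labels, rng)
        d, lab = tree_distances(tree)
        rooted = pc.midpoint_root(tree)
        # distance from the new root to the two farthest leaves is equal
        dr, lr = tree_distances(rooted)
        # brute force: max pairwise distance
        far = d.max() / 2
        depths = {}
        def depth_of(node, acc):
            if node.is_leaf:
                depths[node.label] = acc
            for c in node.children:
                depth_of(c, acc + (c.length or 0.0))
        depth_of(rooted, 0.0)
        assert max(depths.values()) == pytest.approx(far)


def build_colored_tree():
    # candR nested among the RFP refs, candC among the ChrP refs
    newick = ("(((RFP1:0.1,(RFP2:0.1,candR:0.1):0.05):0.2,"
              "((CHRP1:0.1,(CHRP2:0.1,candC:0.1):0.05):0.2,candG:0.4):0.1)"
              ":0.1,OUT:0.5);")
    root = parse_newick(newick)
    return root


class TestAssignColors:
    refs = {"RFP1": "RFP", "RFP2": "RFP", "CHRP1": "ChrP", "CHRP2": "ChrP",
            "OUT": "GFP/CFP"}

    def test_supported_clades_assign_classes(self):
        tree = pc.GeneTree(build_colored_tree(), {})
        out = pc.assign_colors(tree, self.refs, support_min=90)
        assert out["candR"] == ("RFP", "clade")
        assert out["candC"] == ("ChrP", "clade")
        assert out["candG"] == ("GFP/CFP", "default")

    def test_default_support_min_is_90(self):
        import inspect
        sig = inspect.signature(pc.assign_colors)
        assert sig.parameters["support_min"].default == 90.0

    def test_unsupported_clade_falls_back_to_default(self):
        root = build_colored_tree()
        gt = pc.GeneTree(root, {})
        # attach explicit low support to the RFP clade bipartition
        rfp_node = gt.mrca(["RFP1", "RFP2"])
        leaves = frozenset(root.leaf_labels())
        side = frozenset(rfp_node.leaf_labels())
        key = side if min(leaves) not in side else leaves - side
        gt.supports = {key: 50.0}
        out = pc.assign_colors(gt, self.refs, support_min=90)
        assert out["candR"] == ("GFP/CFP", "default")

    def test_assignment_total_and_monotone(self):
        tree = pc.GeneTree(build_colored_tree(), {})
        sizes = []
        for smin in (0, 50, 90, 101):
            out = pc.assign_colors(tree, self.refs, support_min=smin)
            assert set(out) == {"candR", "candC", "candG"}
            sizes.append(sum(1 for cls, _ in out.values()
                             if cls in ("RFP", "ChrP")))
        assert sizes == sorted(sizes, reverse=True)

    def test_missing_references_rejected(self):
        tree = pc.GeneTree(parse_newick("((a:1,b:1):1,c:1);"), {})
        with pytest.raises(ValueError):
            pc.assign_colors(tree, {"a": "RFP"})


class TestColorRecoveryOnSimulation:
    def test_agreement_with_simulator_classes(self):
        """Clade classification matches the simulator's true classes."""
        agree = total = 0
        for seed in (1, 2, 3):
            # low divergence per the envelope: subst_rate * depth <= 0.3
            cfg = sd.SimConfig(seed=seed, species_tree=sd._RECOVERY_TREE,
                               root_copies=5, dup_rate=0.08, loss_rate=0.03,
                               subst_rate=0.08, tandem_prob=0.7,
                               decoy_genes_per_species=6, root_divergence=0.5)
            fastas, gffs, log = sd.simulate_family(cfg)
            proteomes, features = sim_inputs(fastas, gffs)
            result = pl.scan_stage(proteomes, features)
            cl = pl.classify_stage(result.complete,
                                   pl.RunConfig(n_replicates=25))
            for leaf, (cls, _prov) in cl.colors.items():
                gene_id = leaf.split("|", 1)[1]
                lid = log.gene_lineage[gene_id]
                true_cls = log.lineage_class[lid][0]
                total += 1
                agree += cls == true_cls
        assert total > 0
        assert agree / total >= 0.95
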