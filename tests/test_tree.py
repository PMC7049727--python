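"""Expansion metric, split/strip classification, tree construction,
enclave labeling, and nestedness."""

import numpy as np
import pytest

from hicenclave import (
    Bisection,
    build_partition_tree,
    classify_bisection,
    expansion_metric,
    label_enclaves,
    nestedness,
    PartitionTree,
    boxcox_scale,
    kr_balance,
    generate_matrix,
    nested_binary,
)
from hicenclave.errors import InsulationUndefinedError, PreconditionError
from conftest import (
    brute_expansion,
    contact_matrix_from_weights,
    make_tree,
    random_symmetric_matrix,
    random_topology_tree,
)


class TestExpansionMetric:
    def test_zero_crossing_edges_gives_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 5.0
        w[2, 3] = w[3, 2] = 2.0
        assert expansion_metric(w, {0, 1}, {2, 3}) == 0.0

    def test_ordered_pair_convention_on_toy_graph(self):
        # inside C1={a,b}: w(a,b)=3 counted twice in the ordered-pair
        # denominator (=6); one cross edge w(b,c)=2 counted once
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 3.0
        w[1, 2] = w[2, 1] = 2.0
        assert expansion_metric(w, {0, 1}, {2}) == pytest.approx(2.0 / 6.0)

    def test_matches_brute_force_on_random_bipartitions(self):
        for seed in range(50):
            g = np.random.default_rng(seed)
            w = random_symmetric_matrix(g, 8)
            cut = int(g.integers(1, 7))
            perm = g.permutation(8)
            c1, c2 = set(perm[:cut].tolist()), set(perm[cut:].tolist())
            expected = brute_expansion(w, sorted(c1), sorted(c2))
            got = expansion_metric(w, c1, c2)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_internal_weight_is_undefined(self):
        w = np.zeros((3, 3))
        w[0, 2] = w[2, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        with pytest.raises(InsulationUndefinedError):
            expansion_metric(w, {0, 1}, {2})

    def test_overlapping_parts_rejected(self):
        w = np.ones((4, 4))
        with pytest.raises(PreconditionError):
            expansion_metric(w, {0, 1}, {1, 2})


class TestClassifyBisection:
    @staticmethod
    def _bisect(a, b):
        return Bisection(frozenset(a), frozenset(b), 0.1, np.zeros(1))

    def test_two_disconnected_cliques_split(self):
        w = np.zeros((6, 6))
        for grp in (range(3), range(3, 6)):
            for i in grp:
                for j in grp:
                    if i != j:
                        w[i, j] = 1.0
        kind, ea, eb = classify_bisection(w, self._bisect({0, 1, 2}, {3, 4, 5}))
        assert kind == "split"
        assert ea == 0.0 and eb == 0.0

    def test_dense_clique_with_loose_appendage_strips(self):
        # appendage members interact with the clique but barely with
        # each other: only the clique side is insulated
        n_clique, n_app = 5, 3
        n = n_clique + n_app
        w = np.zeros((n, n))
        w[:n_clique, :n_clique] = 4.0
        np.fill_diagonal(w, 0.0)
        w[n_clique:, :n_clique] = w.T[:n_clique, n_clique:] = 1.0
        w[:n_clique, n_clique:] = 1.0
        w[n_clique:, n_clique:] = 0.05
        np.fill_diagonal(w[n_clique:, n_clique:], 0.0)
        w = 0.5 * (w + w.T)
        clique, app = set(range(n_clique)), set(range(n_clique, n))
        kind, ea, eb = classify_bisection(w, self._bisect(clique, app))
        assert kind == "strip"
        assert ea == pytest.approx(brute_expansion(w, sorted(clique), sorted(app)))
        assert ea < 1 < eb

    def test_complete_bipartite_graph_stops(self):
        # nearly all weight crosses the bisection: neither side insulated
        w = np.zeros((6, 6))
        w[:3, 3:] = 5.0
        w[3:, :3] = 5.0
        w[:3, :3] = 0.01
        w[3:, 3:] = 0.01
        np.fill_diagonal(w, 0.0)
        kind, ea, eb = classify_bisection(w, self._bisect({0, 1, 2}, {3, 4, 5}))
        assert kind == "stop"
        assert ea > 1 and eb > 1

    def test_undefined_insulation_counts_as_not_insulated(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 3.0  # C1 internally connected
        w[1, 2] = w[2, 1] = 1.0
        w[1, 3] = w[3, 1] = 1.0  # C2 = {2,3} has no internal weight
        kind, ea, eb = classify_bisection(w, self._bisect({0, 1}, {2, 3}))
        assert kind == "strip"
        assert eb == np.inf


class TestBuildPartitionTree:
    def test_recovers_planted_two_level_hierarchy(self):
        spec = nested_binary(n_bins=48)
        m, _ = generate_matrix(spec, 48, 50_000, seed=1)
        scaled, _ = boxcox_scale(kr_balance(m))
        t = build_partition_tree(scaled)
        # first two levels are splits recovering the planted halves and quarters
        assert t.nodes["R"].branch_kind == "split"
        halves = {frozenset(range(24)), frozenset(range(24, 48))}
        assert {t.nodes["R.0"].loci, t.nodes["R.1"].loci} == halves
        for nid in ("R.0", "R.1"):
            assert t.nodes[nid].branch_kind == "split"
            kids = {t.nodes[c].loci for c in t.nodes[nid].children}
            base = min(t.nodes[nid].loci)
            assert kids == {frozenset(range(base, base + 12)),
                            frozenset(range(base + 12, base + 24))}

    def test_three_loci_matrix_terminates_immediately(self):
        w = np.array([[2.0, 3.0, 0.5], [3.0, 2.0, 0.5], [0.5, 0.5, 2.0]])
        m = contact_matrix_from_weights(w, stage="boxcox_scaled")
        t = build_partition_tree(m)
        for node in t.nodes.values():
            if node.id != t.root:
                assert len(node.loci) <= 2
                assert node.is_leaf

    def test_uniform_weights_yield_no_split_structure(self):
        # a uniform matrix has no two-cluster structure: no split
        # branching may appear, and every recorded expansion must match
        # the brute-force oracle (for uniform weights the larger part of
        # any bisection scores n_small/n_large under the ordered-pair
        # convention, so strips may still occur)
        w = np.ones((12, 12))
        m = contact_matrix_from_weights(w, stage="boxcox_scaled")
        t = build_partition_tree(m)
        assert all(n.branch_kind != "split" for n in t.nodes.values())
        for node in t.nodes.values():
            if node.parent is None or node.expansion is None:
                continue
            parent = t.nodes[node.parent]
            partner = (parent.loci - node.loci) or parent.aux_loci
            assert node.expansion == pytest.approx(
                brute_expansion(w, sorted(node.loci), sorted(partner))
            )

    def test_every_retained_non_root_node_is_insulated(self):
        m, _ = generate_matrix(nested_binary(n_bins=48), 48, 50_000, seed=5)
        scaled, _ = boxcox_scale(kr_balance(m))
        t = build_partition_tree(scaled)
        for node in t.nodes.values():
            if node.parent is not None:
                assert node.expansion is not None and node.expansion < 1

    def test_split_children_partition_parent(self):
        m, _ = generate_matrix(nested_binary(n_bins=48), 48, 50_000, seed=6)
        scaled, _ = boxcox_scale(kr_balance(m))
        t = build_partition_tree(scaled)
        t.validate()  # includes the split-partition check
        saw_split = any(n.branch_kind == "split" for n in t.nodes.values())
        assert saw_split

    def test_deterministic_and_json_round_trip(self, tmp_path):
        m, _ = generate_matrix(nested_binary(n_bins=48), 48, 50_000, seed=2)
        scaled, _ = boxcox_scale(kr_balance(m))
        t1 = build_partition_tree(scaled, master_seed=99)
        t2 = build_partition_tree(scaled, master_seed=99)
        assert t1.to_dict() == t2.to_dict()
        p = tmp_path / "tree.json"
        t1.to_json(p)
        t3 = PartitionTree.from_json(p)
        assert t3.to_dict() == t1.to_dict()

    def test_requires_scaled_stage_unless_overridden(self):
        w = random_symmetric_matrix(np.random.default_rng(0), 6)
        m = contact_matrix_from_weights(w, stage="raw")
        with pytest.raises(PreconditionError):
            build_partition_tree(m)
        build_partition_tree(m, require_scaled=False)  # explicit override works

    def test_non_contiguous_planted_block_kept_in_one_node(self):
        # the defining enclave property: a cluster split across distant
        # genomic segments is still recovered as a single tree node
        spec = nested_binary(n_bins=48, non_contiguous=True)
        m, truth = generate_matrix(spec, 48, 50_000, seed=4)
        scaled, _ = boxcox_scale(kr_balance(m))
        t = build_partition_tree(scaled)
        planted = {
            frozenset(i for i, lab in truth.assignment.items() if lab == name)
            for name in set(truth.assignment.values())
        }
        node_loci = {n.loci for n in t.nodes.values()}
        recovered = planted & node_loci
        assert recovered
        starts = np.array([b.start for b in t.bins])
        gaps = [np.diff(sorted(starts[sorted(loci)])).max() for loci in recovered]
        assert max(gaps) > t.resolution  # genuinely non-contiguous members


class TestLabelEnclaves:
    def test_split_split_then_strips_marks_second_level_children(self):
        shape = {
            "R": (None, "split", range(16)),
            "R.0": ("R", "split", range(8)),
            "R.1": ("R", "split", range(8, 16)),
            "R.0.0": ("R.0", "strip", range(4)),
            "R.0.0.0": ("R.0.0", "none", range(2)),
            "R.0.1": ("R.0", "strip", range(4, 8)),
            "R.0.1.0": ("R.0.1", "none", range(4, 6)),
            "R.1.0": ("R.1", "strip", range(8, 12)),
            "R.1.0.0": ("R.1.0", "none", range(8, 10)),
            "R.1.1": ("R.1", "strip", range(12, 16)),
            "R.1.1.0": ("R.1.1", "none", range(12, 14)),
        }
        t = make_tree(shape)
        labels = label_enclaves(t)
        assert labels.bottom_enclaves == {"R.0.0", "R.0.1", "R.1.0", "R.1.1"}
        assert labels.top_enclaves == frozenset()
        assert labels.leaves == {"R.0.0.0", "R.0.1.0", "R.1.0.0", "R.1.1.0"}

    def test_root_strip_is_top_enclave(self):
        shape = {
            "R": (None, "strip", range(10)),
            "R.0": ("R", "split", range(8)),
            "R.0.0": ("R.0", "strip", range(4)),
            "R.0.0.0": ("R.0.0", "none", range(2)),
            "R.0.1": ("R.0", "strip", range(4, 8)),
            "R.0.1.0": ("R.0.1", "none", range(4, 6)),
        }
        labels = label_enclaves(make_tree(shape))
        assert labels.top_enclaves == {"R"}
        assert labels.bottom_enclaves == {"R.0.0", "R.0.1"}

    def test_first_strip_with_only_strips_below_is_bottom_not_top(self):
        # a node that is simultaneously "first strip" and a last-split
        # child goes to the bottom-enclave set (the sets stay disjoint)
        shape = {
            "R": (None, "split", range(8)),
            "R.0": ("R", "strip", range(4)),
            "R.0.0": ("R.0", "none", range(2)),
            "R.1": ("R", "strip", range(4, 8)),
            "R.1.0": ("R.1", "none", range(4, 6)),
        }
        labels = label_enclaves(make_tree(shape))
        assert labels.bottom_enclaves == {"R.0", "R.1"}
        assert labels.top_enclaves == frozenset()

    def test_sets_pairwise_disjoint_and_match_naive_scan(self):
        for seed in range(50):
            t = random_topology_tree(np.random.default_rng(seed))
            labels = label_enclaves(t)
            assert not labels.top_enclaves & labels.bottom_enclaves
            assert not labels.top_enclaves & labels.leaves
            assert not labels.bottom_enclaves & labels.leaves

            # naive two-pass oracle over explicit ancestor/descendant lists
            def ancestors(nid):
                out = []
                while t.nodes[nid].parent is not None:
                    nid = t.nodes[nid].parent
                    out.append(nid)
                return out

            def descendants(nid):
                out = []
                stack = list(t.nodes[nid].children)
                while stack:
                    c = stack.pop()
                    out.append(c)
                    stack.extend(t.nodes[c].children)
                return out

            leaves = {n for n in t.nodes if not t.nodes[n].children}
            bottom = {
                n for n in t.nodes
                if n not in leaves
                and t.nodes[n].parent is not None
                and t.nodes[t.nodes[n].parent].branch_kind == "split"
                and t.nodes[n].branch_kind != "split"
                and all(t.nodes[d].branch_kind != "split" for d in descendants(n))
            }
            top = {
                n for n in t.nodes
                if t.nodes[n].branch_kind == "strip"
                and n not in bottom
                and all(t.nodes[a].branch_kind == "split" for a in ancestors(n))
            }
            assert labels.leaves == leaves
            assert labels.bottom_enclaves == bottom
            assert labels.top_enclaves == top


class TestNestedness:
    def _tree_with_depths(self):
        # path: R -(splits)- top enclave at D=2 - ... - bottom at D=5 -
        # strips - leaf at D=7; plus a sibling bottom branch at D=3
        shape = {
            "R": (None, "split", range(40)),
            "R.1": ("R", "none", range(32, 40)),
            "R.0": ("R", "split", range(32)),
            "R.0.1": ("R.0", "none", range(28, 32)),
            "R.0.0": ("R.0", "strip", range(28)),          # top enclave, D=2
            "R.0.0.0": ("R.0.0", "split", range(24)),      # D=3
            "R.0.0.0.1": ("R.0.0.0", "strip", range(20, 24)),  # bottom, D=4
            "R.0.0.0.1.0": ("R.0.0.0.1", "none", range(20, 22)),
            "R.0.0.0.0": ("R.0.0.0", "split", range(20)),  # D=4
            "R.0.0.0.0.1": ("R.0.0.0.0", "none", range(16, 20)),
            "R.0.0.0.0.0": ("R.0.0.0.0", "strip", range(16)),  # bottom, D=5
            "R.0.0.0.0.0.0": ("R.0.0.0.0.0", "strip", range(12)),  # D=6
            "R.0.0.0.0.0.0.0": ("R.0.0.0.0.0.0", "none", range(8)),  # leaf, D=7
        }
        return make_tree(shape)

    def test_anchor_values(self):
        t = self._tree_with_depths()
        labels = label_enclaves(t)
        ns = nestedness(t, labels)
        assert ns.node_ns["R.0.0"] == 0.0
        assert ns.node_ns["R.0.0.0.0.0"] == 0.5
        assert ns.node_ns["R.0.0.0.1"] == 0.5
        assert ns.node_ns["R.0.0.0.0.0.0.0"] == 1.0

    def test_upper_segment_interpolation(self):
        # top at D=2, node at D=3, furthest descendant bottom at D=5:
        # NS = 0.5 * (3-2) / ((5-2)+1) = 0.125
        t = self._tree_with_depths()
        ns = nestedness(t, label_enclaves(t))
        assert ns.node_ns["R.0.0.0"] == pytest.approx(0.125)
        # node at D=4 above the D=5 bottom only: 0.5*(4-2)/((5-2)+1) = 0.25
        assert ns.node_ns["R.0.0.0.0"] == pytest.approx(0.25)

    def test_lower_segment_interpolation(self):
        # bottom at D=5, node at D=6, its leaf at D=7:
        # NS = 0.5 * (6-5) / (7-5) + 0.5 = 0.75
        t = self._tree_with_depths()
        ns = nestedness(t, label_enclaves(t))
        assert ns.node_ns["R.0.0.0.0.0.0"] == pytest.approx(0.75)

    def test_contract_on_generated_and_random_trees(self):
        trees = []
        for seed in range(6):
            m, _ = generate_matrix(nested_binary(n_bins=48), 48, 50_000, seed=seed)
            scaled, _ = boxcox_scale(kr_balance(m))
            trees.append(build_partition_tree(scaled))
        for seed in range(20):
            trees.append(random_topology_tree(np.random.default_rng(1000 + seed)))
        for t in trees:
            labels = label_enclaves(t)
            ns = nestedness(t, labels)
            for nid in labels.top_enclaves:
                assert ns.node_ns[nid] == 0.0
            for nid in labels.bottom_enclaves:
                assert ns.node_ns[nid] == 0.5
            for nid in labels.leaves:
                assert ns.node_ns[nid] == 1.0
            defined = [v for v in ns.node_ns.values() if v is not None]
            assert all(0.0 <= v <= 1.0 for v in defined)
            # upper-segment values strictly below 0.5
            for nid, v in ns.node_ns.items():
                if v is None or nid in labels.bottom_enclaves or \
                        nid in labels.leaves:
                    continue
                in_lower = any(a.id in labels.bottom_enclaves
                               for a in t.ancestors(nid))
                if not in_lower:
                    assert v < 0.5
            # monotone non-decreasing along root-to-leaf paths
            for leaf in labels.leaves:
                path = [t.nodes[leaf]]
                while path[-1].parent is not None:
                    path.append(t.nodes[path[-1].parent])
                scores = [ns.node_ns[n.id] for n in reversed(path)
                          if ns.node_ns[n.id] is not None]
                assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))
            # per-locus values defined for the whole universe, in [0,1]
            assert set(ns.locus_ns) == set(t.universe)
            assert all(0.0 <= v <= 1.0 for v in ns.locus_ns.values())
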