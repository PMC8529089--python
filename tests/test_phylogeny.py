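import math

import dendropy
import numpy as np
import pytest

from fechsurvey.phylogeny import (
    DistanceMatrix,
    bootstrap_trees,
    distance_matrix_from_msa,
    jc_correct,
    majority_consensus,
    neighbor_joining,
    p_distance,
    read_newick,
    write_newick,
)

# ---------------------------------------------------------------- helpers


def random_additive_tree(n_leaves, rng):
    """Random unrooted binary tree with positive branch lengths.

    Returns (edges, leaf labels): edges as {frozenset({u, v}): length} over
    integer node ids; leaves are ids 0..n_leaves-1 labeled "L0".."L<n-1>".
    Built by sequential random edge subdivision, independently of any NJ
    machinery.
    """
    edges = {}
    nxt = n_leaves  # internal ids from here
    center = nxt
    nxt += 1
    for leaf in range(3):
        edges[frozenset((center, leaf))] = rng.uniform(0.1, 1.0)
    for leaf in range(3, n_leaves):
        target = list(edges)[rng.integers(0, len(edges))]
        length = edges.pop(target)
        u, v = tuple(target)
        w = nxt
        nxt += 1
        split = rng.uniform(0.2, 0.8)
        edges[frozenset((u, w))] = length * split
        edges[frozenset((w, v))] = length * (1 - split)
        edges[frozenset((w, leaf))] = rng.uniform(0.1, 1.0)
    return edges, [f"L{i}" for i in range(n_leaves)]


def tree_distances(edges, n_leaves):
    adj = {}
    for e, length in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, length))
        adj.setdefault(v, []).append((u, length))
    d = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, length in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + length
                    stack.append(nbr)
        for dst in range(n_leaves):
            d[src, dst] = dist[dst]
    return d


def true_bipartition_lengths(edges, n_leaves, labels):
    """Map frozenset(leaf labels on the side away from L0) -> branch length."""
    adj = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    def side_leaves(start, banned):
        seen = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr in adj[node]:
                if nbr != banned and nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return {x for x in seen if x < n_leaves}

    out = {}
    all_leaves = set(range(n_leaves))
    for e, length in edges.items():
        u, v = tuple(e)
        side = side_leaves(u, v)
        if 0 in side:
            side = all_leaves - side
        out[frozenset(labels[i] for i in side)] = length
    return out


def dendropy_bipartition_lengths(tree, labels):
    all_labels = set(labels)
    ref = labels[0]
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if ref in side:
            side = all_labels - side
        key = frozenset(side)
        if key in out:  # seed-node trifurcation can repeat one bipartition
            out[key] += node.edge.length
        else:
            out[key] = node.edge.length
    return out


def quartet_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------- p / JC


class TestDistances:
    def test_identical_rows(self):
        assert p_distance("ACDEF", "ACDEF") == 0.0

    def test_pairwise_gap_deletion(self):
        assert p_distance("AC-G", "AT-G") == pytest.approx(1 / 3)

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance("A-", "-A")

    def test_census_oracle(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACDE-"), size=300))
        b = "".join(rng.choice(list("ACDE-"), size=300))
        comparable = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        expected = sum(x != y for x, y in comparable) / len(comparable)
        assert p_distance(a, b) == pytest.approx(expected)

    def test_jc_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_jc_known_value(self):
        # -(19/20) ln(1 - (20/19) 0.1), evaluated independently
        expected = -(19 / 20) * math.log(17 / 19)
        assert jc_correct(0.1, states=20) == pytest.approx(expected, abs=1e-12)
        assert jc_correct(0.1, states=20) == pytest.approx(0.1056644, abs=1e-6)

    def test_jc_saturation_error(self):
        with pytest.raises(ValueError, match="saturated"):
            jc_correct(0.95, states=20)

    def test_jc_monotone_and_dominates_p(self):
        ps = np.linspace(0.0, 0.9, 50)
        ds = [jc_correct(p, states=20) for p in ps]
        assert all(b >= a for a, b in zip(ds, ds[1:]))
        assert all(d >= p for d, p in zip(ds, ps))


# ---------------------------------------------------------------- NJ


class TestNeighborJoining:
    def test_quartet_worked_example(self):
        """Additive quartet AB|CD with known branch lengths."""
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lengths = dendropy_bipartition_lengths(tree, labels)
        assert lengths[frozenset({"B"})] == pytest.approx(2.0)
        assert lengths[frozenset({"C"})] == pytest.approx(3.0)
        assert lengths[frozenset({"D"})] == pytest.approx(4.0)
        assert lengths[frozenset({"C", "D"})] == pytest.approx(1.0)  # internal
        assert lengths[frozenset({"B", "C", "D"})] == pytest.approx(1.0)  # A

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        dab, dac, dbc = 0.4, 0.6, 0.8
        d = np.array([[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]])
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((dab + dac - dbc) / 2)
        assert lengths["B"] == pytest.approx((dab + dbc - dac) / 2)
        assert lengths["C"] == pytest.approx((dac + dbc - dab) / 2)

    def test_all_zero_distances(self):
        d = np.zeros((4, 4))
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d))
        assert all(
            (e.length or 0) == pytest.approx(0.0)
            for e in tree.preorder_edge_iter()
            if e.length is not None
        )

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_recovers_random_additive_trees(self):
        """Topology and branch lengths exact on additive 6-taxon matrices."""
        rng = np.random.default_rng(95549)
        for _ in range(30):
            edges, labels = random_additive_tree(6, rng)
            d = tree_distances(edges, 6)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            got = dendropy_bipartition_lengths(tree, labels)
            expected = true_bipartition_lengths(edges, 6, labels)
            assert set(got) == set(expected)
            for key, length in expected.items():
                assert got[key] == pytest.approx(length, abs=1e-9), key

    def test_agrees_with_dendropy_nj_topology(self):
        rng = np.random.default_rng(7)
        edges, labels = random_additive_tree(8, rng)
        d = tree_distances(edges, 8)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        pdm_csv = [" ," + ",".join(labels)]
        for i, lab in enumerate(labels):
            pdm_csv.append(lab + "," + ",".join(str(x) for x in d[i]))
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO("\n".join(pdm_csv)), delimiter=","
        )
        ref_tree = pdm.nj_tree()
        ref_tree.is_rooted = False
        got = set(dendropy_bipartition_lengths(tree, labels))
        ref_labels = [t.label for t in ref_tree.taxon_namespace]
        ref = set(dendropy_bipartition_lengths(ref_tree, labels))
        assert got == ref


# ---------------------------------------------------------------- bootstrap


@pytest.fixture(scope="module")
def rows():
    rng = np.random.default_rng(13)
    base = rng.choice(list("ACDEFGHIKL"), size=120)
    out = []
    for _ in range(6):
        row = base.copy()
        idx = rng.choice(120, size=12, replace=False)
        row[idx] = rng.choice(list("ACDEFGHIKL"), size=12)
        out.append("".join(row))
    return out


class TestBootstrap:
    labels = [f"s{i}" for i in range(6)]

    def test_same_seed_reproduces_replicates(self, rows):
        a = bootstrap_trees(self.labels, rows, n_replicates=5, seed=99)
        b = bootstrap_trees(self.labels, rows, n_replicates=5, seed=99)
        assert [write_newick(t) for t in a] == [write_newick(t) for t in b]

    def test_zero_replicates(self, rows):
        assert bootstrap_trees(self.labels, rows, n_replicates=0, seed=1) == []

    def test_replicate_count(self, rows):
        assert len(bootstrap_trees(self.labels, rows, 7, seed=5)) == 7


# ---------------------------------------------------------------- consensus


class TestMajorityConsensus:
    def test_identical_trees_full_support(self):
        trees = [
            quartet_tree("((A:1,B:1):1,(C:1,D:1):1,E:1);") for _ in range(3)
        ]
        result = majority_consensus(trees)
        assert all(v == pytest.approx(1.0) for v in result.supports.values())
        assert frozenset({"C", "D"}) in result.supports or frozenset(
            {"A", "B"}
        ) in result.supports

    def test_two_versus_one_quartets(self):
        trees = [
            quartet_tree("((A:1,B:1):1,(C:1,D:1):1);"),
            quartet_tree("((A:1,B:1):1,(C:1,D:1):1);"),
            quartet_tree("((A:1,C:1):1,(B:1,D:1):1);"),
        ]
        result = majority_consensus(trees, threshold=0.5)
        assert result.supports == {frozenset({"C", "D"}): pytest.approx(2 / 3)}

    def test_full_conflict_at_unit_threshold_gives_star(self):
        trees = [
            quartet_tree("((A:1,B:1):1,(C:1,D:1):1);"),
            quartet_tree("((A:1,C:1):1,(B:1,D:1):1);"),
        ]
        result = majority_consensus(trees, threshold=1.0)
        assert result.supports == {}
        internal = [
            n
            for n in result.tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert internal == []

    def test_supports_invariant_under_tree_permutation(self):
        trees = [
            quartet_tree("((A:1,B:1):1,(C:1,D:1):1,E:1);"),
            quartet_tree("((A:1,C:1):1,(B:1,D:1):1,E:1);"),
            quartet_tree("((A:1,B:1):1,(C:1,D:1):1,E:1);"),
        ]
        fwd = majority_consensus(trees).supports
        rev = majority_consensus(trees[::-1]).supports
        assert fwd == rev

    def test_mismatched_leaf_sets_rejected(self):
        trees = [
            quartet_tree("((A:1,B:1):1,(C:1,D:1):1);"),
            quartet_tree("((A:1,B:1):1,(C:1,E:1):1);"),
        ]
        with pytest.raises(ValueError, match="leaf set"):
            majority_consensus(trees)


# ---------------------------------------------------------------- newick


class TestNewick:
    def test_round_trip(self):
        text = "(A:1.0,B:2.0,(C:3.0,D:4.0):1.0);"
        tree = read_newick(text)
        again = read_newick(write_newick(tree))
        assert {l.taxon.label for l in again.leaf_node_iter()} == {"A", "B", "C", "D"}
        lengths = dendropy_bipartition_lengths(again, ["A", "B", "C", "D"])
        assert lengths[frozenset({"C", "D"})] == pytest.approx(1.0)
        assert lengths[frozenset({"D"})] == pytest.approx(4.0)

    def test_quoted_labels_with_spaces(self):
        tree = read_newick("('Taxon one':1,'Taxon two':2,C:1);")
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        assert "Taxon one" in labels
        out = write_newick(tree)
        assert read_newick(out)  # still parseable

    def test_malformed_input_raises(self):
        with pytest.raises(ValueError, match="parse"):
            read_newick("((A:1,B:2;")


# ---------------------------------------------------------------- matrices


class TestDistanceMatrixFromMsa:
    def test_saturation_modes(self):
        labels = ["a", "b"]
        rows = ["AAAA", "CCCC"]  # p = 1.0: saturated
        with pytest.raises(ValueError, match="saturated"):
            distance_matrix_from_msa(labels, rows, on_saturation="error")
        dm = distance_matrix_from_msa(labels, rows, on_saturation="cap")
        assert np.isfinite(dm.d).all()

    def test_phylip_serialization_parses_back(self):
        labels = ["a", "b", "c"]
        rows = ["AAAA", "AACA", "ACCA"]
        dm = distance_matrix_from_msa(labels, rows)
        text = dm.to_phylip()
        lines = text.strip().split("\n")
        assert lines[0].strip() == "3"
        assert len(lines) == 4
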