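"""Distance-based phylogeny: Jukes-Cantor distances, neighbor joining,
bootstrap resampling and majority-rule consensus.

The tree protocol mirrors the survey's settings: generalized (20-state)
Jukes-Cantor correction of protein p-distances, neighbor joining with no
outgroup, bootstrap resampling of alignment columns (default 100
replicates) and a strict majority-rule (>50%) consensus with support
values. Trees are :class:`dendropy.Tree` objects; Newick serialization
carries supports as internal node labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal, label-indexed."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def to_phylip(self) -> str:
        """PHYLIP square-format serialization."""
        lines = [f" {len(self.labels)}"]
        for label, row in zip(self.labels, self.d):
            cells = " ".join(f"{v:.6f}" for v in row)
            lines.append(f"{label:<10s} {cells}")
        return "\n".join(lines) + "\n"


@dataclass
class SupportedTree:
    """Consensus tree plus per-bipartition support fractions in [0, 1]."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)


def p_distance(row_i: str, row_j: str) -> float:
    """Proportion of mismatches over sites where both rows are non-gap."""
    if len(row_i) != len(row_j):
        raise ValueError("aligned rows differ in length")
    comparable = 0
    mismatch = 0
    for a, b in zip(row_i, row_j):
        if a == "-" or b == "-":
            continue
        comparable += 1
        if a != b:
            mismatch += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) sites between rows")
    return mismatch / comparable


def jc_correct(p: float, states: int = 20) -> float:
    """Generalized Jukes-Cantor correction for a b-state alphabet.

    d = -((b-1)/b) ln(1 - (b/(b-1)) p). Valid for p < (b-1)/b; beyond
    that the distance is saturated (undefined) and an error is raised.
    """
    b = states
    if b < 2:
        raise ValueError("states must be >= 2")
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    limit = (b - 1) / b
    if p >= limit:
        raise ValueError(f"saturated p-distance {p} >= {limit}")
    return -((b - 1) / b) * math.log1p(-(b / (b - 1)) * p)


def distance_matrix_from_msa(
    labels: Sequence[str],
    rows: Sequence[str],
    states: int = 20,
    on_saturation: str = "error",
) -> DistanceMatrix:
    """Pairwise JC-corrected distances from an alignment.

    Gap handling is pairwise deletion (each pair uses its own gap-free
    sites). ``on_saturation='cap'`` replaces saturated pairs with the
    largest representable correction instead of raising.
    """
    if on_saturation not in {"error", "cap"}:
        raise ValueError("on_saturation must be 'error' or 'cap'")
    n = len(labels)
    if len(rows) != n:
        raise ValueError("labels/rows length mismatch")
    arr = np.array([list(r) for r in rows])
    gap = arr == "-"
    limit = (states - 1) / states
    cap_p = limit - 1e-6
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]} and {labels[j]}"
                )
            p = float((arr[i, ok] != arr[j, ok]).sum()) / comparable
            if p >= limit:
                if on_saturation == "error":
                    raise ValueError(
                        f"saturated pair {labels[i]}/{labels[j]} (p={p:.3f})"
                    )
                logger.warning(
                    "saturated pair %s/%s capped", labels[i], labels[j]
                )
                p = cap_p
            d[i, j] = d[j, i] = jc_correct(p, states)
    return DistanceMatrix(labels=list(labels), d=d)


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining (Saitou-Nei with Studier-Keppler Q).

    Q-matrix ties are broken by the lexicographically smallest pair of
    cluster labels (a cluster is labeled by its smallest leaf label), so
    the result is deterministic. Negative branch lengths are clamped to
    zero with a log note. Requires at least three taxa; the returned tree
    is unrooted (trifurcating seed node).
    """
    n0 = len(D.labels)
    if n0 < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    ns = dendropy.TaxonNamespace(list(D.labels))
    tree = dendropy.Tree(taxon_namespace=ns)

    nodes: list[dendropy.Node] = []
    for label in D.labels:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(node)
    cluster_label = list(D.labels)  # smallest leaf label per active cluster
    d = D.d.astype(float).copy()
    active = list(range(n0))

    def clamp(value: float, context: str) -> float:
        if value < 0:
            if value < -1e-9:
                logger.info("negative branch length %.4g clamped (%s)", value, context)
            return 0.0
        return value

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    la = cluster_label[active[a]]
                    lb = cluster_label[active[b]]
                    key = (min(la, lb), max(la, lb))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = clamp(0.5 * dij + (r[a] - r[b]) / (2 * (m - 2)), cluster_label[i])
        lj = clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))), cluster_label[j])
        new = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        # distances from the new cluster to the remaining ones
        newdist = 0.5 * (d[i, :] + d[j, :] - dij)
        u = i  # reuse slot i for the merged cluster
        d[u, :] = newdist
        d[:, u] = newdist
        d[u, u] = 0.0
        nodes[u] = new
        cluster_label[u] = min(cluster_label[i], cluster_label[j])
        active = [k for k in active if k != j]

    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = clamp(0.5 * (dab + dac - dbc), cluster_label[a])
    lb = clamp(0.5 * (dab + dbc - dac), cluster_label[b])
    lc = clamp(0.5 * (dac + dbc - dab), cluster_label[c])
    root = tree.seed_node
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.edge.length = length
        root.add_child(node)
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def bootstrap_trees(
    labels: Sequence[str],
    rows: Sequence[str],
    n_replicates: int = 100,
    seed: int = 95549,
    states: int = 20,
) -> list[dendropy.Tree]:
    """Column-bootstrap replicates of the JC+NJ tree.

    Each replicate resamples alignment columns with replacement (to the
    original length), recomputes JC distances (saturated pairs capped)
    and reruns NJ. Fully determined by ``seed``.
    """
    if not rows or not rows[0]:
        raise ValueError("alignment must have at least one column")
    rng = np.random.default_rng(seed)
    width = len(rows[0])
    arr = np.array([list(r) for r in rows])
    trees = []
    for _ in range(n_replicates):
        cols = rng.integers(0, width, size=width)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        dm = distance_matrix_from_msa(labels, rep_rows, states, on_saturation="cap")
        trees.append(neighbor_joining(dm))
    return trees


def _clades(tree: dendropy.Tree, ref_label: str) -> set[frozenset]:
    """Nontrivial bipartitions as leaf-label sets on the side away from ref."""
    all_labels = frozenset(
        leaf.taxon.label for leaf in tree.leaf_node_iter()
    )
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if ref_label in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            out.add(side)
    return out


def majority_consensus(
    trees: Sequence[dendropy.Tree], threshold: float = 0.5
) -> SupportedTree:
    """Majority-rule consensus: bipartitions in more than ``threshold`` of trees.

    Retained bipartitions are added greedily in decreasing support order,
    skipping any that conflict with those already accepted (with a strict
    >50% threshold every retained bipartition is automatically
    compatible). Supports are occurrence fractions in [0, 1], stored as
    internal node labels.
    """
    if not trees:
        raise ValueError("no trees to summarize")
    leaf_sets = [
        frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees
    ]
    if len(set(leaf_sets)) != 1:
        raise ValueError("trees do not share a common leaf set")
    labels = sorted(leaf_sets[0])
    ref = labels[0]

    counts: dict[frozenset, int] = {}
    for t in trees:
        for clade in _clades(t, ref):
            counts[clade] = counts.get(clade, 0) + 1
    ntrees = len(trees)
    candidates = sorted(
        ((c, k / ntrees) for c, k in counts.items() if k / ntrees > threshold),
        key=lambda cv: (-cv[1], -len(cv[0]), sorted(cv[0])),
    )

    def compatible(a: frozenset, b: frozenset) -> bool:
        return a.isdisjoint(b) or a <= b or b <= a

    accepted: list[tuple[frozenset, float]] = []
    for clade, support in candidates:
        if all(compatible(clade, c) for c, _ in accepted):
            accepted.append((clade, support))

    # build the consensus tree by nesting the laminar clade family
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    support_map = dict(accepted)
    ordered = sorted(support_map, key=len, reverse=True)
    clade_nodes: dict[frozenset, dendropy.Node] = {}

    def parent_of(clade: frozenset) -> dendropy.Node:
        best = None
        for other in ordered:
            if clade < other and (best is None or len(other) < len(best)):
                best = other
        return clade_nodes[best] if best is not None else tree.seed_node

    for clade in ordered:
        node = dendropy.Node()
        node.label = f"{support_map[clade]:.2f}"
        clade_nodes[clade] = node
    for clade in ordered:
        parent_of(clade).add_child(clade_nodes[clade])
    for label in labels:
        leaf = dendropy.Node(taxon=ns.get_taxon(label))
        smallest = None
        for clade in ordered:
            if label in clade and (smallest is None or len(clade) < len(smallest)):
                smallest = clade
        (clade_nodes[smallest] if smallest else tree.seed_node).add_child(leaf)
    tree.is_rooted = False
    return SupportedTree(tree=tree, supports=support_map)


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize to Newick; internal node labels (supports) preserved."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=False,
    ).strip() + "\n"


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; malformed input raises ValueError."""
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"Newick parse error: {exc}") from exc
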