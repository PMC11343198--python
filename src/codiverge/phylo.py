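"""Core phylogenetic containers and operations.

Trees are :class:`dendropy.Tree` objects throughout; this module adds the
operations the co-diversification pipeline needs on top of them: validated
Newick I/O, patristic distance matrices, clade span queries, and the
same-host dereplication ("collapse") used to remove pseudoreplication from
cophylogenetic tests.

Internal nodes are given stable identifiers ``N0, N1, ...`` in preorder by
:func:`index_tree`; all scan results refer to nodes by these ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "HOST_CATEGORIES",
    "Clade",
    "read_newick",
    "write_newick",
    "parse_newick",
    "newick_string",
    "index_tree",
    "tip_labels",
    "patristic_distances",
    "clade_span",
    "collapse_host_monophyletic",
    "read_tip_metadata",
    "validate_tip_metadata",
    "TreeIndex",
    "as_rng",
]

#: Valid host categories for Mus musculus domesticus-derived genomes;
#: every other host takes ``other``.
HOST_CATEGORIES = frozenset(
    {"lab_mouse", "wild_mouse", "wildling", "rewilded", "ex_wild", "other"}
)


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, SeedSequence, or Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Clade:
    """A clade of the symbiont tree: node id, its tip set, and its span.

    ``span`` is the largest tip-to-tip patristic distance within the clade,
    the quantity compared against a fraction of the whole-tree span when
    restricting scans to the distal part of the phylogeny.
    """

    node_id: str
    tips: frozenset = field(default_factory=frozenset)
    span: float = 0.0


# ---------------------------------------------------------------------------
# Newick I/O


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lbl is None for lbl in labels):
        raise ValueError("tree has unlabeled tips")
    dupes = {lbl for lbl in labels if labels.count(lbl) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree; reject duplicate tips."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy error messages carry the offset
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return _validate(tree)


def read_newick(path) -> dendropy.Tree:
    """Read a rooted tree from a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def newick_string(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        ).strip()
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# Node indexing and distances


def index_tree(tree: dendropy.Tree) -> dict:
    """Assign stable preorder ids ``N0..`` to internal nodes; return id → node.

    Existing internal labels are preserved in ``node.label`` only if they
    already follow the ``N<k>`` scheme produced here; otherwise they are
    replaced (bootstrap-style labels are kept on ``node.original_label``).
    """
    mapping = {}
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        node_id = f"N{k}"
        if node.label is not None and not node.label.startswith("N"):
            node.original_label = node.label
        node.label = node_id
        mapping[node_id] = node
        k += 1
    return mapping


def tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _patristic_matrix(tree: dendropy.Tree, order: list) -> np.ndarray:
    """All-pairs path-length matrix over ``order`` (tip labels)."""
    idx = {lbl: i for i, lbl in enumerate(order)}
    n = len(order)
    D = np.zeros((n, n))
    # postorder merge: each node carries (tip index, distance-to-node) pairs
    carry = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            carry[node] = ([idx[lbl]], [0.0]) if lbl in idx else ([], [])
            continue
        groups = []
        for child in node.child_nodes():
            tips_i, dists_i = carry.pop(child)
            bl = child.edge.length or 0.0
            groups.append((tips_i, [d + bl for d in dists_i]))
        merged_t, merged_d = [], []
        for tips_i, dists_i in groups:
            if merged_t and tips_i:
                a = np.asarray(merged_d)[:, None] + np.asarray(dists_i)[None, :]
                ti = np.asarray(merged_t)
                tj = np.asarray(tips_i)
                D[ti[:, None], tj[None, :]] = a
                D[tj[:, None], ti[None, :]] = a.T
            merged_t.extend(tips_i)
            merged_d.extend(dists_i)
        carry[node] = (merged_t, merged_d)
    return D


def patristic_distances(tree: dendropy.Tree, tips=None) -> DistanceMatrix:
    """Patristic (path-length) distance matrix over ``tips``.

    Distances are sums of branch lengths along the unique path between two
    tips; ``None`` branch lengths count as 0.
    """
    all_tips = tip_labels(tree)
    if tips is None:
        order = all_tips
    else:
        order = [t for t in all_tips if t in set(tips)]
        missing = set(tips) - set(order)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
    return DistanceMatrix(_patristic_matrix(tree, order), ids=order)


class TreeIndex:
    """Caches tip order, the full patristic matrix, and per-node tip indices.

    Scans test hundreds of nodes against the same tree; this avoids
    recomputing path sums per node.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.nodes = index_tree(tree)
        self.tips = tip_labels(tree)
        self.tip_index = {t: i for i, t in enumerate(self.tips)}
        self.matrix = _patristic_matrix(tree, self.tips)
        self._node_tips = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._node_tips[node] = [node.taxon.label]
            else:
                tips = []
                for child in node.child_nodes():
                    tips.extend(self._node_tips[child])
                self._node_tips[node] = tips

    def node_tips(self, node_id: str) -> list:
        return list(self._node_tips[self.nodes[node_id]])

    def node_tip_indices(self, node_id: str) -> np.ndarray:
        return np.asarray(
            [self.tip_index[t] for t in self._node_tips[self.nodes[node_id]]]
        )

    def span(self, node_id: str) -> float:
        ix = self.node_tip_indices(node_id)
        if len(ix) < 2:
            return 0.0
        return float(self.matrix[np.ix_(ix, ix)].max())

    def total_span(self) -> float:
        return float(self.matrix.max()) if len(self.tips) > 1 else 0.0

    def clade(self, node_id: str) -> Clade:
        return Clade(
            node_id=node_id,
            tips=frozenset(self._node_tips[self.nodes[node_id]]),
            span=self.span(node_id),
        )

    def is_ancestor(self, node_id_a: str, node_id_b: str) -> bool:
        """True if node a is a proper ancestor of node b."""
        node = self.nodes[node_id_b].parent_node
        target = self.nodes[node_id_a]
        while node is not None:
            if node is target:
                return True
            node = node.parent_node
        return False


def clade_span(tree: dendropy.Tree, node_id: str = None) -> float:
    """Largest tip-to-tip patristic distance within a clade.

    With ``node_id=None`` (or the root id) this is the span of the whole
    tree, the denominator of the distal-fraction filter.
    """
    ti = TreeIndex(tree)
    if node_id is None:
        return ti.total_span()
    node = ti.nodes.get(node_id)
    if node is None:
        raise KeyError(f"unknown or terminal node id {node_id!r}")
    return ti.span(node_id)


# ---------------------------------------------------------------------------
# Tip metadata


def read_tip_metadata(path) -> pd.DataFrame:
    """Read a tip metadata TSV (tip_id, host_species, host_category[, taxonomy])."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tip_id", "host_species", "host_category"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if "taxonomy" not in meta.columns:
        meta["taxonomy"] = "unclassified"
    meta = meta.set_index("tip_id")
    bad = set(meta["host_category"]) - HOST_CATEGORIES
    if bad:
        raise ValueError(f"unknown host categories: {sorted(bad)}")
    return meta


def validate_tip_metadata(tree: dendropy.Tree, meta: pd.DataFrame) -> None:
    tips = set(tip_labels(tree))
    missing = tips - set(meta.index)
    if missing:
        raise ValueError(f"tips without metadata: {sorted(missing)[:5]} ...")
    if meta.index.has_duplicates:
        raise ValueError("duplicate tip_id rows in metadata")


# ---------------------------------------------------------------------------
# Same-host dereplication


def _subtree_host_groups(node, meta, host_of):
    """Maximal monophyletic same-host tip groups within the subtree at ``node``.

    Returns a list of tip-label lists. Postorder computes the host set under
    every node; preorder emits a node's tips as one group the first time the
    host set is a singleton.
    """
    hosts_below = {}
    tips_below = {}
    for nd in node.postorder_iter():
        if nd.is_leaf():
            lbl = nd.taxon.label
            tips_below[nd] = [lbl]
            hosts_below[nd] = {host_of[lbl]}
        else:
            tips, hosts = [], set()
            for child in nd.child_nodes():
                tips.extend(tips_below[child])
                hosts |= hosts_below[child]
            tips_below[nd] = tips
            hosts_below[nd] = hosts
    groups = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if len(hosts_below[nd]) == 1:
            groups.append(tips_below[nd])
        else:
            stack.extend(reversed(nd.child_nodes()))
    return groups


def collapse_host_monophyletic(tree, meta, clade, rng_seed=0):
    """Dereplicate a clade to one tip per maximal same-host monophyletic group.

    Parameters
    ----------
    tree : dendropy.Tree
        Tree whose internal nodes were labeled by :func:`index_tree` (a
        :class:`TreeIndex` does this).
    meta : pd.DataFrame
        Tip metadata with a ``host_species`` column.
    clade : Clade or str
        The clade (or its node id) to collapse.
    rng_seed : int or Generator
        Drives the uniform choice of representative within each group.

    Returns
    -------
    list of str
        Retained tip labels, in tree order. Tips whose host is unique in
        their neighborhood are kept as-is; within each maximal monophyletic
        group of tips sharing one host species a single representative is
        chosen uniformly at random.
    """
    rng = as_rng(rng_seed)
    node_id = clade.node_id if isinstance(clade, Clade) else clade
    node = None
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf() and nd.label == node_id:
            node = nd
            break
    if node is None:
        raise KeyError(f"unknown internal node {node_id!r}")
    host_of = meta["host_species"].to_dict()
    groups = _subtree_host_groups(node, meta, host_of)
    keep = set()
    for tips in groups:
        keep.add(tips[int(rng.integers(len(tips)))] if len(tips) > 1 else tips[0])
    order = {t: i for i, t in enumerate(tip_labels(tree))}
    return sorted(keep, key=order.get)
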