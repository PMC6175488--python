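"""Rooted phylogenetic trees with branch lengths.

A :class:`PhyloTree` is a light array-backed container used throughout the
package: node ids are ``0..n_nodes-1``, every non-root node carries the
length of the edge to its parent, and edges are identified by their child
node id.  Conversion to and from dendropy handles Newick parsing/writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["PhyloTree"]


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths in consistent (My-like) time units.

    Parameters
    ----------
    parent
        ``parent[i]`` is the parent node id of node ``i`` (-1 for the root).
    lengths
        ``lengths[i]`` is the length of the edge above node ``i``
        (0 for the root unless a root stem is supplied).
    labels
        Per-node label; tips must carry unique non-empty labels.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list

    # derived, filled in __post_init__
    children: list = field(default_factory=list, repr=False)
    root: int = field(default=-1, repr=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        n = self.parent.size
        if self.lengths.size != n or len(self.labels) != n:
            raise ValueError("parent/lengths/labels size mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, got {roots.size}")
        self.root = int(roots[0])
        self.children = [[] for _ in range(n)]
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        if np.any(self.lengths[np.arange(n) != self.root] <= 0):
            bad = [i for i in range(n) if i != self.root and self.lengths[i] <= 0]
            raise ValueError(f"non-positive branch lengths on edges {bad}")
        tips = self.tip_indices()
        tl = [self.labels[i] for i in tips]
        if any(not t for t in tl) or len(set(tl)) != len(tl):
            raise ValueError("tip labels must be unique and non-empty")

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def tip_indices(self) -> np.ndarray:
        return np.array(
            [i for i in range(self.n_nodes) if not self.children[i]], dtype=np.int64
        )

    @property
    def n_tips(self) -> int:
        return self.tip_indices().size

    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices()]

    def tip_index_map(self) -> dict:
        """Label -> node id for tips."""
        return {self.labels[i]: int(i) for i in self.tip_indices()}

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def postorder(self) -> np.ndarray:
        """Node ids, children always before parents (iterative DFS)."""
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return np.array(order[::-1], dtype=np.int64)

    def preorder(self) -> np.ndarray:
        """Node ids, parents before children, sibling order preserved."""
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children[node]))
        return np.array(order, dtype=np.int64)

    # ------------------------------------------------------------- geometry
    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node (root stem excluded)."""
        depth = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            if p >= 0:
                depth[node] = depth[p] + self.lengths[node]
        return depth

    def depth(self) -> float:
        return float(self.node_depths()[self.tip_indices()].max())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.node_depths()[self.tip_indices()]
        return bool(d.max() - d.min() <= tol * max(1.0, d.max()))

    def terminal_branch_lengths(self) -> dict:
        """Tip label -> length of the terminal edge (the species' age)."""
        return {self.labels[i]: float(self.lengths[i]) for i in self.tip_indices()}

    def subtree_nodes(self, node: int) -> np.ndarray:
        """All nodes in the clade rooted at ``node`` (inclusive)."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return np.array(out, dtype=np.int64)

    def clade_tips(self, node: int) -> list:
        sub = self.subtree_nodes(node)
        return [self.labels[i] for i in sub if not self.children[i]]

    def mrca(self, tip_labels) -> int:
        """Most recent common ancestor node id of a set of tip labels."""
        idx = self.tip_index_map()
        want = set(tip_labels)
        missing = want - set(idx)
        if missing:
            raise KeyError(f"unknown tips: {sorted(missing)}")
        # count, per node, how many of the wanted tips sit below it
        count = np.zeros(self.n_nodes, dtype=np.int64)
        for lab in want:
            count[idx[lab]] = 1
        for node in self.postorder():
            for c in self.children[node]:
                count[node] += count[c]
        for node in self.postorder():
            if count[node] == len(want):
                return int(node)
        raise RuntimeError("unreachable")  # pragma: no cover

    def is_monophyletic(self, tip_labels) -> bool:
        node = self.mrca(tip_labels)
        return set(self.clade_tips(node)) == set(tip_labels)

    def vcv(self, order=None) -> np.ndarray:
        """Brownian covariance matrix C: shared root-to-MRCA path lengths.

        ``order`` is the tip-label ordering of the rows (default:
        ``tip_labels()``).
        """
        depth = self.node_depths()
        tips = self.tip_indices()
        labs = [self.labels[i] for i in tips]
        if order is None:
            order = labs
        pos = {lab: k for k, lab in enumerate(order)}
        n = len(order)
        C = np.zeros((n, n))
        # accumulate: each node contributes its edge length to all tip pairs below it
        for node in self.postorder():
            if self.parent[node] < 0:
                continue
            below = [self.labels[i] for i in self.subtree_nodes(node) if not self.children[i]]
            ids = [pos[b] for b in below if b in pos]
            if ids:
                ids = np.array(ids)
                C[np.ix_(ids, ids)] += self.lengths[node]
        return C

    # ---------------------------------------------------------- conversions
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        labels = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError("tree has edges without branch lengths")
                lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("unlabeled tip in tree")
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        return cls(parent=parent, lengths=lengths, labels=labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {}
        for node in self.preorder():
            nd = dtree.seed_node if node == self.root else dendropy.Node()
            dnodes[node] = nd
            if node != self.root:
                dnodes[self.parent[node]].add_child(nd)
                nd.edge.length = float(self.lengths[node])
            if not self.children[node]:
                nd.taxon = taxa.new_taxon(label=self.labels[node])
        return dtree

    def to_newick(self) -> str:
        return (
            self.to_dendropy()
            .as_string(schema="newick", suppress_rooting=True)
            .strip()
        )

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(dtree)

    def retain_tips(self, keep_labels) -> "PhyloTree":
        """Prune to the given tips, collapsing unary internal nodes."""
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels())
        if missing:
            raise KeyError(f"unknown tips: {sorted(missing)}")
        dtree = self.to_dendropy()
        taxa = [t for t in dtree.taxon_namespace if t.label in keep]
        dtree.retain_taxa(taxa)
        # dendropy can leave a unary root after pruning; collapse it
        while dtree.seed_node.num_child_nodes() == 1:
            child = dtree.seed_node.child_nodes()[0]
            child.edge.length = (child.edge.length or 0.0)
            dtree.seed_node = child
            child.parent_node = None
        return PhyloTree.from_dendropy(dtree)
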