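"""Phylogeny input/output, validation, and transformation.

The central object is :class:`PhyloTree`, an array-backed rooted tree with
branch lengths.  All phylogenetic covariance used by the statistical modules
(shared root-to-tip path lengths, the matrix usually written C) is computed
here, and the tree transforms (pruning, polytomy resolution, branch scaling,
Pagel's lambda transform) are defined so that their effect on C is exact and
testable.

Newick parsing and serialization are delegated to dendropy; species names are
normalized by replacing spaces with underscores on read, and all subsequent
matching is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "read_newick",
    "write_newick",
    "name_check",
    "prune_to",
    "resolve_polytomies",
    "scale_branches_to_mean",
    "lambda_transform",
    "phylo_covariance",
]


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips...)."""


@dataclass
class PhyloTree:
    """Rooted phylogeny stored as flat arrays.

    Nodes are numbered 0..n_nodes-1 with tips first (0..n_tips-1, in the
    order of ``tip_labels``).  ``parent[root] == -1`` and ``blen[root]`` is
    the root edge length (0 if absent).
    """

    parent: np.ndarray          # (n_nodes,) int
    blen: np.ndarray            # (n_nodes,) float, edge above each node
    tip_labels: list[str]

    _postorder: np.ndarray | None = field(default=None, repr=False, compare=False)
    _children: list[list[int]] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=float)
        if (self.blen < 0).any():
            raise ValueError("negative branch lengths")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise NewickParseError("duplicate tip labels")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")

    # ---- basic structure -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    def postorder(self) -> np.ndarray:
        """Node ids in postorder (children before parents)."""
        if self._postorder is None:
            ch = self.children()
            order: list[int] = []
            stack = [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(ch[node])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node (including its own edge)."""
        depth = np.zeros(self.n_nodes)
        for node in self.postorder()[::-1]:
            p = self.parent[node]
            depth[node] = self.blen[node] + (depth[p] if p >= 0 else 0.0)
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[: self.n_tips]

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        d = self.tip_depths()
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-10))

    def is_binary(self) -> bool:
        counts = [len(c) for c in self.children() if c]
        return all(c == 2 for c in counts)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.blen.copy(), list(self.tip_labels))

    def tip_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.tip_labels)}

    # ---- conversion ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        tips = [n for n in nodes if n.is_leaf()]
        internals = [n for n in nodes if not n.is_leaf()]
        ids: dict[int, int] = {}
        labels = []
        for i, n in enumerate(tips):
            ids[id(n)] = i
            raw = n.taxon.label if n.taxon is not None else (n.label or f"tip{i}")
            labels.append(raw.replace(" ", "_"))
        for j, n in enumerate(internals):
            ids[id(n)] = len(tips) + j
        parent = np.full(len(nodes), -1, dtype=np.int64)
        blen = np.zeros(len(nodes))
        for n in nodes:
            k = ids[id(n)]
            if n.parent_node is not None:
                parent[k] = ids[id(n.parent_node)]
            if n.edge.length is not None:
                blen[k] = float(n.edge.length)
        return cls(parent, blen, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lab in enumerate(self.tip_labels):
            dnodes[i].taxon = taxa.get_taxon(lab)
        for i, p in enumerate(self.parent):
            dnodes[i].edge.length = float(self.blen[i])
            if p >= 0:
                dnodes[p].add_child(dnodes[i])
        dtree.seed_node = dnodes[self.root]
        return dtree


# ---- I/O -----------------------------------------------------------------


def read_newick(source: str) -> PhyloTree:
    """Parse a Newick string or file path into a :class:`PhyloTree`.

    Spaces in taxon names are replaced with underscores; branch lengths
    default to 0 where absent.
    """
    import os

    if "(" not in source and os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise NewickParseError(str(exc)) from exc
    tree = PhyloTree.from_dendropy(dtree)
    if tree.n_tips < 1:
        raise NewickParseError("tree has no tips")
    return tree


def write_newick(tree: PhyloTree) -> str:
    return tree.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()


# ---- validation ----------------------------------------------------------


def name_check(tree: PhyloTree, table) -> tuple[set[str], set[str]]:
    """Exact-match concordance check between tree tips and a trait table.

    Parameters
    ----------
    table : pandas.DataFrame or iterable of names
        If a DataFrame, its ``species`` column (or index) is used.

    Returns
    -------
    (tree_only, table_only) : sets of names present on one side only.
    """
    import pandas as pd

    if isinstance(table, pd.DataFrame):
        names = set(table["species"]) if "species" in table.columns else set(table.index)
    else:
        names = set(table)
    tips = set(tree.tip_labels)
    return tips - names, names - tips


# ---- transforms ----------------------------------------------------------


def prune_to(tree: PhyloTree, names) -> PhyloTree:
    """Restrict the tree to a subset of tips.

    Retained tips keep their root-to-tip path lengths: unary internal nodes
    created by tip removal are collapsed with branch lengths summed.
    """
    names = set(names)
    idx = tree.tip_index()
    unknown = names - set(idx)
    if unknown:
        raise KeyError(f"names not in tree: {sorted(unknown)[:5]}")
    if len(names) < 2:
        raise ValueError("need at least 2 tips after pruning")

    keep = np.zeros(tree.n_nodes, dtype=bool)
    for name in names:
        keep[idx[name]] = True
    # a node survives iff it has a kept tip below it
    for node in tree.postorder():
        p = tree.parent[node]
        if p >= 0 and keep[node]:
            keep[p] = True

    # number of kept children per kept node
    ch = tree.children()
    new_labels = [lab for lab in tree.tip_labels if lab in names]
    new_id: dict[int, int] = {}
    t = 0
    for i in range(tree.n_tips):
        if keep[i]:
            new_id[i] = t
            t += 1

    # walk from each kept node up to the nearest kept ancestor with >=2 kept
    # children (a "junction"); collapse unary chains by summing lengths
    n_kept_children = np.zeros(tree.n_nodes, dtype=np.int64)
    for node in range(tree.n_nodes):
        for c in ch[node]:
            if keep[c]:
                n_kept_children[node] += 1

    junction = keep.copy()
    for node in range(tree.n_tips, tree.n_nodes):
        if keep[node] and n_kept_children[node] < 2:
            junction[node] = False
    # root of the pruned tree: the deepest junction that is an ancestor of all
    # kept tips. Walking up from any kept tip, the last junction encountered.
    internal_ids = [n for n in range(tree.n_nodes) if junction[n] and n >= tree.n_tips]
    for i in internal_ids:
        new_id[i] = t
        t += 1

    parent = np.full(t, -1, dtype=np.int64)
    blen = np.zeros(t)
    for node in range(tree.n_nodes):
        if node not in new_id:
            continue
        length = tree.blen[node]
        p = tree.parent[node]
        while p >= 0 and not junction[p]:
            if keep[p]:
                length += tree.blen[p]
            p = tree.parent[p]
        k = new_id[node]
        blen[k] = length
        parent[k] = new_id[p] if p >= 0 else -1
    # collapse possible multiple roots: all nodes whose ancestor chain found no
    # junction point to -1; exactly one should remain the root (the top
    # junction). If the original root survives with 1 kept child the chain
    # above handles it because that child absorbs the lengths.
    roots = np.flatnonzero(parent < 0)
    if roots.size != 1:
        raise RuntimeError("pruning produced a forest; input tree malformed")
    return PhyloTree(parent, blen, new_labels)


def resolve_polytomies(tree: PhyloTree, seed: int = 0) -> PhyloTree:
    """Randomly resolve multifurcations into binary splits with 0-length
    branches; the tip covariance matrix is unchanged."""
    rng = np.random.default_rng(seed)
    ch = [list(c) for c in tree.children()]
    parent = list(tree.parent)
    blen = list(tree.blen)
    for node in range(tree.n_nodes):
        while len(ch[node]) > 2:
            i, j = sorted(rng.choice(len(ch[node]), size=2, replace=False))
            a, b = ch[node][i], ch[node][j]
            new = len(parent)
            parent.append(node)
            blen.append(0.0)
            ch.append([a, b])
            parent[a] = new
            parent[b] = new
            ch[node] = [c for c in ch[node] if c not in (a, b)] + [new]
    return PhyloTree(np.array(parent), np.array(blen), list(tree.tip_labels))


def scale_branches_to_mean(tree: PhyloTree, target_mean: float) -> PhyloTree:
    """Multiply all branches by one constant so their mean equals target."""
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    mask = np.ones(tree.n_nodes, dtype=bool)
    mask[tree.root] = tree.blen[tree.root] > 0  # root edge counted only if real
    current = tree.blen[mask].mean()
    if current <= 0:
        raise ValueError("tree has no positive branch lengths")
    out = tree.copy()
    out.blen = tree.blen * (target_mean / current)
    return out


def lambda_transform(tree: PhyloTree, lam: float) -> PhyloTree:
    """Pagel's lambda transform: internal branches multiplied by lambda,
    terminal branches extended to preserve root-to-tip distances.

    Off-diagonal entries of the phylogenetic covariance are scaled by lambda
    exactly; diagonal entries are unchanged.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    depth = tree.node_depths()
    out = tree.copy()
    for node in range(tree.n_nodes):
        if node < tree.n_tips:
            p = tree.parent[node]
            pdepth = depth[p] if p >= 0 else 0.0
            out.blen[node] = depth[node] - lam * pdepth
        else:
            out.blen[node] = lam * tree.blen[node]
    return out


def phylo_covariance(tree: PhyloTree, as_correlation: bool = False) -> np.ndarray:
    """Shared-path-length covariance C over tips: C[i, j] is the root-to-tip
    distance of the most recent common ancestor of tips i and j."""
    n = tree.n_tips
    depth = tree.node_depths()
    ch = tree.children()
    C = np.zeros((n, n))
    tipsets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node < n:
            tipsets[node] = np.array([node])
            C[node, node] = depth[node]
            continue
        kids = ch[node]
        sets = [tipsets.pop(c) for c in kids]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                C[np.ix_(sets[a], sets[b])] = depth[node]
                C[np.ix_(sets[b], sets[a])] = depth[node]
        tipsets[node] = np.concatenate(sets)
    if as_correlation:
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    return C
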