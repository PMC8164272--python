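"""Rooted phylogenies: Newick I/O and the manipulations the simulations need.

Trees are stored as flat arrays (parent pointers, branch lengths, tip
labels) after a canonicalisation pass that suppresses unifurcations and
resolves multifurcations into binary nodes joined by zero-length branches.
A zero-length branch has no-substitution probability 1 and an identity
transition matrix, so the novelty-score recursions are invariant under the
resolution (this is tested).

Branch lengths are expected substitutions per site throughout.
"""

from __future__ import annotations

import io
from typing import Iterable

import dendropy
import numpy as np


class TreeError(ValueError):
    """Malformed Newick, duplicate labels, negative branch lengths, ..."""


class _Node:
    """Mutable helper node used during construction and splicing."""

    __slots__ = ("children", "length", "label")

    def __init__(self, label=None, length=0.0):
        self.children: list[_Node] = []
        self.length = length
        self.label = label


def _suppress_unifurcations(node: _Node) -> _Node:
    """Merge chains of single-child nodes; returns the (possibly new) root."""
    while len(node.children) == 1:
        child = node.children[0]
        child.length = 0.0  # absorbed into the root position
        node = child
    stack = [node]
    while stack:
        v = stack.pop()
        new_children = []
        for c in v.children:
            length = c.length
            while len(c.children) == 1:
                c = c.children[0]
                if length is None or c.length is None:
                    raise TreeError(
                        "branch without length; pass default_length to assume one"
                    )
                length += c.length
            c.length = length
            new_children.append(c)
            stack.append(c)
        v.children = new_children
    return node


def _binarise(node: _Node) -> None:
    """Left-first resolution of polytomies via zero-length internal branches."""
    stack = [node]
    while stack:
        v = stack.pop()
        while len(v.children) > 2:
            merged = _Node(length=0.0)
            merged.children = v.children[:2]
            v.children = [merged] + v.children[2:]
        stack.extend(v.children)


class RootedPhylogeny:
    """A rooted binary phylogeny over ``N`` labelled tips.

    Attributes
    ----------
    parent : int array, -1 at the root
    blen : branch length of the edge above each node (0.0 at the root)
    labels : per-node label (``None`` for internal nodes)
    postorder : node indices, children before parents
    """

    def __init__(self, root: _Node):
        root = _suppress_unifurcations(root)
        _binarise(root)
        order: list[_Node] = []
        # iterative postorder to avoid recursion limits on caterpillars
        stack: list[tuple[_Node, bool]] = [(root, False)]
        node_parent: dict[int, _Node] = {}
        while stack:
            v, expanded = stack.pop()
            if expanded:
                order.append(v)
            else:
                stack.append((v, True))
                for c in reversed(v.children):
                    node_parent[id(c)] = v
                    stack.append((c, False))

        index = {id(v): i for i, v in enumerate(order)}
        n = len(order)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.blen = np.zeros(n, dtype=float)
        self.labels: list[str | None] = [None] * n
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, v in enumerate(order):
            self.labels[i] = v.label if not v.children else None
            p = node_parent.get(id(v))
            if p is not None:
                self.parent[i] = index[id(p)]
                self.children[index[id(p)]].append(i)
                if v.length is None:
                    raise TreeError("missing branch length")
                if v.length < 0:
                    raise TreeError(f"negative branch length {v.length}")
                self.blen[i] = float(v.length)
        self.postorder = np.arange(n)  # construction order is postorder
        self.root = n - 1
        self.tip_ids = np.array([i for i in range(n) if not self.children[i]], dtype=np.int64)
        tip_labels = [self.labels[i] for i in self.tip_ids]
        if any(lab is None or lab == "" for lab in tip_labels):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(tip_labels)) != len(tip_labels):
            raise TreeError("duplicate tip labels")
        self.tip_index = {lab: int(i) for i, lab in zip(self.tip_ids, tip_labels)}

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        source,
        default_length: float | None = None,
        require_rooted: bool = False,
    ) -> "RootedPhylogeny":
        """Parse a Newick tree (string, stream, or path).

        An unrooted (trifurcating-root) input is accepted and rooted
        arbitrarily at the first trifurcation -- valid for reversible,
        stationary models, where the scores do not depend on the root
        position.  With ``require_rooted=True`` (non-reversible models)
        such input is refused.
        """
        text = _read_text(source)
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        seed = dtree.seed_node
        if require_rooted and len(seed.child_nodes()) > 2:
            raise TreeError(
                "input tree is unrooted (root trifurcation) but a rooted "
                "phylogeny is required for a non-reversible model"
            )

        def convert(dnode) -> _Node:
            length = dnode.edge.length
            if length is None:
                # missing lengths are only an error if the branch survives
                # unifurcation suppression; checked at tree construction
                length = 0.0 if dnode.parent_node is None else default_length
            label = dnode.taxon.label if dnode.taxon is not None else None
            node = _Node(label=label, length=length)
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10000))
        try:
            root = convert(seed)
        finally:
            sys.setrecursionlimit(old)
        return cls(root)

    # -- basic properties --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.blen)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def total_length(self) -> float:
        return float(self.blen.sum())

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for v in self.postorder:
            if self.is_tip(v):
                body = self.labels[v]
            else:
                body = "(" + ",".join(parts[c] for c in self.children[v]) + ")"
            if v == self.root:
                parts[v] = body + ";"
            else:
                parts[v] = f"{body}:{self.blen[v]:.12g}"
        return parts[self.root]

    # -- manipulations -----------------------------------------------------

    def _to_mutable(self) -> _Node:
        nodes = [
            _Node(label=self.labels[i], length=float(self.blen[i]))
            for i in range(self.n_nodes)
        ]
        for i in range(self.n_nodes):
            for c in self.children[i]:
                nodes[i].children.append(nodes[c])
        return nodes[self.root]

    def scale(self, factor: float) -> "RootedPhylogeny":
        """Multiply every branch length by ``factor > 0``; topology unchanged."""
        if factor <= 0:
            raise TreeError(f"scale factor must be positive, got {factor}")
        root = self._to_mutable()
        stack = [root]
        while stack:
            v = stack.pop()
            v.length *= factor
            stack.extend(v.children)
        root.length = 0.0
        return RootedPhylogeny(root)

    def tip_distances(self) -> tuple[list[str], np.ndarray]:
        """Pairwise tip-to-tip path lengths (order = ``tip_labels``)."""
        n = self.n_nodes
        depth = np.zeros(n)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.blen[v]
        # ancestor chains per tip
        chains = {}
        for t in self.tip_ids:
            chain = {}
            v = int(t)
            while v >= 0:
                chain[v] = depth[t] - depth[v]
                v = int(self.parent[v])
            chains[int(t)] = chain
        N = self.n_tips
        D = np.zeros((N, N))
        tips = [int(t) for t in self.tip_ids]
        for a in range(N):
            for b in range(a + 1, N):
                ca = chains[tips[a]]
                v = tips[b]
                up = 0.0
                while v not in ca:
                    up += self.blen[v]
                    v = int(self.parent[v])
                D[a, b] = D[b, a] = up + ca[v]
        return self.tip_labels, D


def _read_text(source) -> str:
    if isinstance(source, str):
        if source.lstrip().startswith("("):
            return source
        with open(source) as fh:
            return fh.read()
    if isinstance(source, io.IOBase) or hasattr(source, "read"):
        return source.read()
    raise TreeError(f"cannot read Newick from {type(source)!r}")


def read_newick(source, default_length=None, require_rooted=False) -> RootedPhylogeny:
    """Functional alias for :meth:`RootedPhylogeny.from_newick`."""
    return RootedPhylogeny.from_newick(
        source, default_length=default_length, require_rooted=require_rooted
    )


def scale_tree(tree: RootedPhylogeny, factor: float) -> RootedPhylogeny:
    """Functional alias for :meth:`RootedPhylogeny.scale`."""
    return tree.scale(factor)


# -- random trees ----------------------------------------------------------


def random_tree(
    n_tips: int,
    rng,
    mean_branch: float = 0.3,
    labels: Iterable[str] | None = None,
) -> RootedPhylogeny:
    """Random rooted binary tree by sequential attachment.

    Each new tip is grafted onto a uniformly chosen existing branch at a
    uniform point, with an exponentially distributed pendant length of mean
    ``mean_branch``.  Used for property tests and synthetic benchmarks.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n_tips < 2:
        raise TreeError("need at least 2 tips")
    labels = list(labels) if labels is not None else [f"T{i + 1}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise TreeError("label count must equal n_tips")
    root = _Node()
    a = _Node(label=labels[0], length=float(rng.exponential(mean_branch)))
    b = _Node(label=labels[1], length=float(rng.exponential(mean_branch)))
    root.children = [a, b]
    edges = [(root, a), (root, b)]  # (parent, child)
    for k in range(2, n_tips):
        parent, child = edges[rng.integers(len(edges))]
        u = float(rng.uniform())
        mid = _Node(length=child.length * u)
        child.length *= 1.0 - u
        tip = _Node(label=labels[k], length=float(rng.exponential(mean_branch)))
        parent.children[parent.children.index(child)] = mid
        mid.children = [child, tip]
        edges.remove((parent, child))
        edges.extend([(parent, mid), (mid, child), (mid, tip)])
    return RootedPhylogeny(root)


def _kingman_clade(n_tips: int, mean_pairwise_time: float, rng) -> tuple[_Node, list[_Node]]:
    """Kingman coalescent over ``n_tips`` lineages.

    Scale chosen so the expected coalescence time of a random pair equals
    ``mean_pairwise_time`` (pairwise rate ``1 / mean``); with ``k`` active
    lineages the next event is exponential with rate ``k (k - 1) / (2 mean)``.
    Returns the clade root and its tip nodes (heights measured from the tips).
    """
    lineages = [(_Node(), 0.0) for _ in range(n_tips)]
    tips = [node for node, _ in lineages]
    height = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / (2.0 * mean_pairwise_time)
        height += float(rng.exponential(1.0 / rate))
        i, j = rng.choice(k, size=2, replace=False)
        (na, ha), (nb, hb) = lineages[i], lineages[j]
        na.length = height - ha
        nb.length = height - hb
        merged = _Node()
        merged.children = [na, nb]
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((merged, height))
    return lineages[0][0], tips


def attach_coalescent_clade(
    tree: RootedPhylogeny,
    tip: str,
    n_extra: int,
    mean_coalescent_time: float,
    seed,
) -> RootedPhylogeny:
    """Replace a tip with a coalescent clade of ``n_extra + 1`` tips.

    The clade topology and node times are sampled from a Kingman coalescent
    with expected pairwise coalescence time ``mean_coalescent_time`` (so the
    expected pairwise path length within the clade is twice that).  The
    original label is kept for one clade member; the others are labelled
    ``<tip>_1 ... <tip>_<n_extra>``.  Deterministic given ``seed``.
    """
    if tip not in tree.tip_index:
        raise TreeError(f"unknown tip label {tip!r}")
    if n_extra < 1:
        raise TreeError("n_extra must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = tree._to_mutable()
    clade_root, clade_tips = _kingman_clade(n_extra + 1, mean_coalescent_time, rng)
    clade_tips[0].label = tip
    for k, node in enumerate(clade_tips[1:], start=1):
        node.label = f"{tip}_{k}"
    # find and replace the named tip node
    stack = [root]
    while stack:
        v = stack.pop()
        if v.label == tip and not v.children:
            v.label = None
            v.children = clade_root.children
            break
        stack.extend(v.children)
    return RootedPhylogeny(root)
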