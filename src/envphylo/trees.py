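"""Unrooted leaf-labeled phylogenetic trees with branch lengths.

The tree is stored as a rooted data structure whose root is merely a
display anchor: all comparisons (splits, Robinson–Foulds) and the Newick
writer treat the tree as unrooted.  Newick text is parsed with dendropy
and converted to this light internal form so that the deterministic
writer, bipartition extraction and neighbor-joining construction have
full control over node order and formatting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy
import numpy as np

from .errors import ParseError, ValidationError

__all__ = ["Node", "PhyloTree", "read_newick", "write_newick", "random_binary_tree"]


@dataclass
class Node:
    """A tree node; ``length`` is the branch above it (0 at the root)."""

    label: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self


class PhyloTree:
    """An unrooted tree over a set of uniquely labeled leaves."""

    def __init__(self, root: Node, unroot: bool = True):
        if unroot:
            root = _deroot(root)
        self.root = root
        labels = [n.label for n in root.postorder() if n.is_leaf]
        if any(lab is None or lab == "" for lab in labels):
            raise ValidationError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise ValidationError(f"duplicate leaf labels: {dupes}")
        self._leaves = frozenset(labels)

    @property
    def leaves(self) -> frozenset[str]:
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return read_newick(text)

    # -- serialization ---------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    # -- queries ---------------------------------------------------------

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Pairwise leaf-to-leaf path lengths (sum of branch lengths).

        Returns labels in sorted order and the matching symmetric matrix.
        """
        labels = sorted(self._leaves)
        index = {lab: i for i, lab in enumerate(labels)}
        s = len(labels)
        dist = np.zeros((s, s))

        def walk(node: Node) -> dict[int, float]:
            if node.is_leaf:
                return {index[node.label]: 0.0}
            below: dict[int, float] = {}
            child_maps = []
            for child in node.children:
                cmap = {k: v + child.length for k, v in walk(child).items()}
                child_maps.append(cmap)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for i, di in child_maps[a].items():
                        for j, dj in child_maps[b].items():
                            dist[i, j] = dist[j, i] = di + dj
            for cmap in child_maps:
                below.update(cmap)
            return below

        walk(self.root)
        return labels, dist

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_leaves={self.n_leaves})"


def _deroot(root: Node) -> Node:
    """Collapse a basal bifurcation so internal nodes have degree >= 3.

    A rooted binary tree ``((...),(...))`` becomes the unrooted tree with
    a trifurcating (or higher) anchor.  Two-leaf trees are left as-is.
    """
    while len(root.children) == 2:
        internal = next((c for c in root.children if not c.is_leaf), None)
        if internal is None:  # two-leaf tree: nothing to collapse
            break
        other = next(c for c in root.children if c is not internal)
        other.length += internal.length
        new_children = list(internal.children) + [other]
        root = Node(label=root.label, length=0.0, children=new_children)
    root.length = 0.0
    return root


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into an unrooted :class:`PhyloTree`.

    Missing branch lengths default to 0; internal node labels are
    ignored; rooted inputs are unrooted (all comparisons are on
    topologies).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        length = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
        return Node(
            label=label,
            length=length,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    root = convert(dtree.seed_node)
    if root.is_leaf:
        raise ParseError("Newick input has fewer than 2 leaves")
    return PhyloTree(root)


def _quote(label: str) -> str:
    if any(c in label for c in "()[]{}:;,'\" \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _min_leaf(node: Node) -> str:
    if node.is_leaf:
        return node.label  # type: ignore[return-value]
    return min(_min_leaf(c) for c in node.children)


def _write_node(node: Node, out: io.StringIO, with_length: bool) -> None:
    if node.is_leaf:
        out.write(_quote(node.label))  # type: ignore[arg-type]
    else:
        out.write("(")
        ordered = sorted(node.children, key=_min_leaf)
        for i, child in enumerate(ordered):
            if i:
                out.write(",")
            _write_node(child, out, with_length=True)
        out.write(")")
    if with_length:
        out.write(":%.10g" % node.length)


def _canonical_anchor(tree: PhyloTree) -> Node:
    """Re-anchor the unrooted tree at the internal node adjacent to the
    lexicographically smallest leaf, so equal unrooted topologies always
    serialize identically regardless of how they were built."""
    if tree.n_leaves <= 2:
        return tree.root
    adjacency: dict[int, list[tuple[Node, float]]] = {}
    nodes: dict[int, Node] = {}

    def collect(node: Node) -> None:
        nodes[id(node)] = node
        for child in node.children:
            adjacency.setdefault(id(node), []).append((child, child.length))
            adjacency.setdefault(id(child), []).append((node, child.length))
            collect(child)

    collect(tree.root)
    smallest = min(
        (n for n in nodes.values() if n.is_leaf), key=lambda n: n.label
    )
    anchor = adjacency[id(smallest)][0][0]

    def rebuild(node: Node, parent: Node | None, length: float) -> Node:
        children = [
            rebuild(nb, node, l) for nb, l in adjacency[id(node)] if nb is not parent
        ]
        return Node(label=node.label, length=length, children=children)

    return rebuild(anchor, None, 0.0)


def write_newick(tree: PhyloTree) -> str:
    """Serialize deterministically: the tree is anchored at the internal
    node next to the smallest leaf, children are ordered by the smallest
    leaf label beneath them, branch lengths use 10 significant digits."""
    out = io.StringIO()
    _write_node(_canonical_anchor(tree), out, with_length=False)
    out.write(";")
    return out.getvalue()


def random_binary_tree(
    labels: Sequence[str],
    rng: np.random.Generator | None = None,
    branch_length: tuple[float, float] = (0.05, 1.0),
) -> PhyloTree:
    """Uniform-ish random unrooted binary tree via sequential leaf addition.

    Each new leaf is attached to a uniformly chosen existing edge; branch
    lengths are drawn uniformly from ``branch_length``.  Useful for
    simulation configs and for property tests against additive matrices.
    """
    labels = list(labels)
    if len(set(labels)) != len(labels) or len(labels) < 2:
        raise ValidationError("need >= 2 unique labels")
    rng = np.random.default_rng(rng)
    lo, hi = branch_length

    def bl() -> float:
        return float(rng.uniform(lo, hi))

    if len(labels) == 2:
        a, b = (Node(lab, bl()) for lab in labels)
        return PhyloTree(Node(children=[a, b]))

    root = Node(children=[Node(labels[0], bl()), Node(labels[1], bl()), Node(labels[2], bl())])
    for lab in labels[3:]:
        # collect (parent, child-slot) edges
        edges: list[tuple[Node, int]] = []
        stack = [root]
        while stack:
            node = stack.pop()
            for i, child in enumerate(node.children):
                edges.append((node, i))
                stack.append(child)
        parent, slot = edges[rng.integers(len(edges))]
        old = parent.children[slot]
        # split the chosen edge at an interior point so every branch stays
        # strictly positive (additivity oracles need resolvable topologies)
        frac = float(rng.uniform(0.2, 0.8))
        mid = Node(children=[Node(lab, bl()), old], length=old.length * (1.0 - frac))
        old.length = old.length * frac
        parent.children[slot] = mid
    return PhyloTree(root)
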