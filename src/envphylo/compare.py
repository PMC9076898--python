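"""Robinson–Foulds topology comparison.

Removing an internal edge of an unrooted tree bipartitions the leaves;
the set of all such nontrivial bipartitions (splits) characterizes the
topology.  With T₁ and T₂ the split sets of two trees on the same leaves,

    RF  = |T₁ Δ T₂|          (splits in one tree but not the other)
    nRF = |T₁ Δ T₂| / (|T₁| + |T₂|)     ∈ [0, 1]

0 means identical topologies, 1 maximally dissimilar.  Multifurcating
trees are fine: |T| simply counts the internal edges present.  Rooting
and child order never matter — splits are stored canonically as the side
containing the lexicographically smallest leaf.
"""

from __future__ import annotations

import warnings

from .errors import ValidationError
from .trees import Node, PhyloTree

__all__ = ["splits", "rf_distance", "nrf_distance"]

Split = frozenset  # one canonical side of a bipartition


def splits(tree: PhyloTree, collapse_below: float | None = None) -> set[frozenset[str]]:
    """The set of nontrivial splits induced by a tree's internal edges.

    ``collapse_below``: optionally ignore internal edges with branch
    length below the threshold (topology-only comparisons by default
    keep zero-length edges — a resolved edge is a resolved edge).
    """
    leaves = tree.leaves
    n = len(leaves)
    smallest = min(leaves)
    out: set[frozenset[str]] = set()
    if n < 4:
        return out

    def below(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset((node.label,))
        side = frozenset().union(*(below(c) for c in node.children))
        if node is not tree.root and 2 <= len(side) <= n - 2:
            if collapse_below is None or node.length >= collapse_below:
                out.add(side if smallest in side else leaves - side)
        return side

    below(tree.root)
    return out


def _check_leaves(t1: PhyloTree, t2: PhyloTree) -> None:
    if t1.leaves != t2.leaves:
        only1 = sorted(t1.leaves - t2.leaves)
        only2 = sorted(t2.leaves - t1.leaves)
        raise ValidationError(
            f"leaf sets differ: only in first = {only1}, only in second = {only2}"
        )


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """|T₁ Δ T₂|: the number of splits unique to either tree."""
    _check_leaves(t1, t2)
    return len(splits(t1) ^ splits(t2))


def nrf_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """Normalized Robinson–Foulds distance in [0, 1]."""
    _check_leaves(t1, t2)
    s1, s2 = splits(t1), splits(t2)
    denom = len(s1) + len(s2)
    if denom == 0:
        warnings.warn("both trees are stars: nRF undefined, returning 0")
        return 0.0
    return len(s1 ^ s2) / denom
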