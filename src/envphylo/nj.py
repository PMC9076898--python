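"""Neighbor joining and the end-to-end environment-based pipeline.

Standard Saitou–Nei agglomeration with the Studier–Keppler selection
criterion: at each step join the pair (i, j) minimizing

    Q(i, j) = (N − 2)·d(i, j) − Σ_k d(i, k) − Σ_k d(j, k),

with branch lengths from the canonical formulas and distances to the new
node d(u, k) = (d(i, k) + d(j, k) − d(i, j))/2.  On an additive matrix
this recovers the generating tree exactly, topology and branch lengths.

Ties in Q (identical species produce them) are broken by the smallest
(i, j) in input index order, so the output is deterministic.  Negative
branch lengths, which non-additive matrices can produce, are by default
clamped to zero with the deficit transferred to the sibling edge (the
usual NJ convention); pass ``negative_branches="keep"`` to disable.

The dense O(N³) implementation is entirely adequate at the tens-of-taxa
scale this method targets.
"""

from __future__ import annotations

import numpy as np

from .encoding import otu_space
from .errors import ValidationError
from .metrics import DistanceMatrix, distance_matrix
from .proteome import ProteomeSet
from .trees import Node, PhyloTree

__all__ = ["neighbor_joining", "envnj"]


def neighbor_joining(D: DistanceMatrix, negative_branches: str = "clamp") -> PhyloTree:
    """Build an unrooted tree from a labeled distance matrix."""
    if negative_branches not in ("clamp", "keep"):
        raise ValidationError(f"unknown negative_branches policy: {negative_branches!r}")
    n = D.n
    if n < 2:
        raise ValidationError("neighbor joining needs at least 2 taxa")
    clamp = negative_branches == "clamp"

    if n == 2:
        d = float(D.values[0, 1])
        a = Node(D.labels[0], d / 2)
        b = Node(D.labels[1], d / 2)
        return PhyloTree(Node(children=[a, b]))

    dist = D.values.astype(float).copy()
    nodes: list[Node] = [Node(lab) for lab in D.labels]
    active = list(range(n))

    def fix_pair(li: float, lj: float) -> tuple[float, float]:
        if not clamp:
            return li, lj
        if li < 0.0:
            lj = max(0.0, lj + li)
            li = 0.0
        elif lj < 0.0:
            li = max(0.0, li + lj)
            lj = 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        # Q over the upper triangle; first minimum in row-major order is
        # the smallest (i, j) pair, giving deterministic tie-breaking
        q = (m - 2) * sub - r[:, None] - r[None, :]
        best = None
        best_q = np.inf
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best_q:
                    best_q = q[a, b]
                    best = (a, b)
        a, b = best  # type: ignore[misc]
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = fix_pair(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        new = Node(children=[nodes[i], nodes[j]])
        # distances from the new node to every other active taxon
        new_row = np.zeros(dist.shape[0] + 1)
        for c, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (sub[a, c] + sub[b, c] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final 3-way join: closed-form lengths around the central node
    i, j, k = active
    dij, dik, djk = dist[i, j], dist[i, k], dist[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    if clamp:
        li, lj, lk = (max(0.0, x) for x in (li, lj, lk))
    nodes[i].length = li
    nodes[j].length = lj
    nodes[k].length = lk
    return PhyloTree(Node(children=[nodes[i], nodes[j], nodes[k]]))


def envnj(
    pset: ProteomeSet,
    radius: int = 10,
    metric: str = "cosine",
    negative_branches: str = "clamp",
) -> PhyloTree:
    """Proteomes → species vectors → distance matrix → NJ tree.

    The full environment-based pipeline: encode every species at the
    given radius, compute pairwise dissimilarities under the chosen
    metric and agglomerate by neighbor joining.  Deterministic for fixed
    input.
    """
    if len(pset) < 3:
        raise ValidationError("tree building needs at least 3 species")
    space = otu_space(pset, radius)
    D = distance_matrix(space, metric)
    return neighbor_joining(D, negative_branches=negative_branches)
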