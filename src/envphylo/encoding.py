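"""Sequence-environment counting: species as high-dimensional count vectors.

For a chosen radius r, the environment of a residue occurrence is the
window of the r positions on each side of it (the occurrence itself,
offset 0, is excluded).  Counting, for every one of the 20 target
residues X, how often each residue i appears at each signed offset
j ∈ {−r..−1, +1..+r} across a whole proteome yields a 20 × 20 × 2r
tensor; flattened in a fixed canonical order this is the species vector
u ∈ ℕⁿ with n = 800·r (r = 10 gives the classic 8000-dimensional
representation).  A set of species becomes the column matrix these
vectors form, which is all downstream metrics ever see.

Termini truncate environments: offsets falling outside a sequence
contribute nothing, and sequences are hard boundaries (no counting
across sequence ends).  Placeholder characters occupy positions but are
never counted as target or neighbor.

Canonical flattening order: target X outermost (alphabet order
A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V), neighbor i next, signed
offset j innermost (−r..−1 then +1..+r).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AA_ORDER, N_AA, encode
from .errors import ValidationError
from .proteome import ProteomeSet

__all__ = [
    "EnvCountTensor",
    "SpeciesVectorMatrix",
    "count_environments",
    "environment_tensor",
    "otu_space",
    "vector_sum_check",
]


def _offsets(radius: int) -> list[int]:
    return list(range(-radius, 0)) + list(range(1, radius + 1))


def _check_radius(radius: int) -> None:
    if not isinstance(radius, (int, np.integer)) or radius < 1:
        raise ValidationError(f"radius must be a positive integer, got {radius!r}")


@dataclass(frozen=True)
class EnvCountTensor:
    """Neighborhood counts for one species.

    ``counts[X, i, j]`` is the number of times residue ``i`` occurs at
    signed offset ``offsets[j]`` from an occurrence of target residue
    ``X`` anywhere in the proteome.
    """

    radius: int
    counts: np.ndarray  # (20, 20, 2r) int64

    @property
    def offsets(self) -> list[int]:
        return _offsets(self.radius)

    def flatten(self) -> np.ndarray:
        """Canonical species vector of dimension 800·radius."""
        return self.counts.reshape(-1)


@dataclass(frozen=True)
class SpeciesVectorMatrix:
    """Column matrix of species vectors (n = 800·radius rows)."""

    radius: int
    matrix: np.ndarray  # (n, s) int64
    labels: tuple[str, ...]

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_species(self) -> int:
        return self.matrix.shape[1]

    def row_index(self) -> list[tuple[str, str, int]]:
        """Canonical (target, neighbor, offset) triple for every row."""
        offs = _offsets(self.radius)
        return [(X, i, j) for X in AA_ORDER for i in AA_ORDER for j in offs]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]

    def to_tsv(self, path) -> None:
        """Dump as TSV: rows are canonical "X,i,j" triples, columns species."""
        idx = ["%s,%s,%+d" % t for t in self.row_index()]
        pd.DataFrame(self.matrix, index=idx, columns=list(self.labels)).to_csv(
            path, sep="\t", index_label="target,neighbor,offset"
        )


def environment_tensor(sequences: Sequence[str], radius: int) -> EnvCountTensor:
    """Count all (target, neighbor, offset) occurrences in a proteome.

    Sequences are joined with runs of ``radius`` placeholder positions,
    which is equivalent to counting each sequence separately: no window
    can bridge two sequences, and placeholders are never counted.
    """
    _check_radius(radius)
    counts = np.zeros((N_AA, N_AA, 2 * radius), dtype=np.int64)
    if not sequences:
        return EnvCountTensor(radius, counts)
    sep = "-" * radius
    codes = encode(sep.join(sequences))
    L = codes.size
    for col, off in enumerate(_offsets(radius)):
        if off >= L or -off >= L:
            continue
        if off > 0:
            targets, neighbors = codes[:-off], codes[off:]
        else:
            targets, neighbors = codes[-off:], codes[:off]
        mask = (targets >= 0) & (neighbors >= 0)
        pairs = targets[mask].astype(np.int64) * N_AA + neighbors[mask]
        counts[:, :, col] += np.bincount(pairs, minlength=N_AA * N_AA).reshape(N_AA, N_AA)
    return EnvCountTensor(radius, counts)


def count_environments(sequences: Sequence[str], target: str, radius: int) -> np.ndarray:
    """20 × 2r count matrix for one target residue.

    Row ``i`` is the neighbor residue (canonical order), column ``j`` the
    signed offset (−r..−1, +1..+r).  Offsets outside a sequence and
    placeholder neighbors contribute nothing; offset 0 never exists.
    """
    if target not in AA_INDEX:
        raise ValidationError(f"target must be one of the 20 standard residues, got {target!r}")
    return environment_tensor(sequences, radius).counts[AA_INDEX[target]]


def otu_space(pset: ProteomeSet, radius: int) -> SpeciesVectorMatrix:
    """Encode every species of a :class:`ProteomeSet` as a column vector.

    Columns follow the species insertion order; the row dimension is
    exactly 800·radius.  A species whose vector is all zeros (no
    countable environment at all) is an error, since it cannot be placed
    by any direction-based metric.
    """
    _check_radius(radius)
    cols = []
    for label in pset.species:
        vec = environment_tensor(pset[label], radius).flatten()
        if not vec.any():
            raise ValidationError(
                f"species {label!r} has an all-zero vector at radius {radius}"
            )
        cols.append(vec)
    return SpeciesVectorMatrix(
        radius=radius,
        matrix=np.stack(cols, axis=1),
        labels=tuple(pset.species),
    )


def vector_sum_check(matrix: SpeciesVectorMatrix, pset: ProteomeSet) -> pd.DataFrame:
    """QC report: per species, does the vector total match a direct scan?

    The independent scan walks every sequence once and counts, for each
    standard-residue position, how many in-bounds standard residues lie
    within ``radius`` of it.  Report-only: discrepancies are flagged,
    not raised.
    """
    if set(matrix.labels) != set(pset.species):
        raise ValidationError("matrix labels do not match the proteome set")
    r = matrix.radius
    rows = []
    for label in matrix.labels:
        expected = 0
        for seq in pset[label]:
            std = [c in AA_INDEX for c in seq]
            L = len(seq)
            for p in range(L):
                if not std[p]:
                    continue
                for q in range(max(0, p - r), min(L, p + r + 1)):
                    if q != p and std[q]:
                        expected += 1
        actual = int(matrix.column(label).sum())
        rows.append(
            {"species": label, "expected": expected, "actual": actual, "ok": expected == actual}
        )
    return pd.DataFrame(rows).set_index("species")
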