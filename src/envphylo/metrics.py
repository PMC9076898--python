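"""Dissimilarity metrics between species vectors and distance matrices.

The workhorse is the cosine-based dissimilarity

    d(u, v) = −ln((1 + cos θ) / 2),      cos θ = uᵀv / (‖u‖‖v‖),

which depends only on the *direction* of the count vectors — the
neighborhood preferences — not on their magnitude (proteome size).  It
deliberately violates the coincidence axiom: d(u, 2u) = 0, which is
exactly the behaviour wanted when one lineage merely duplicates its
genome.  All other metrics in the registry are computed on sum-normalized
vectors (relative neighborhood frequencies) for the same reason: the
signal is the preference profile, not the absolute counts.

Jensen–Shannon divergence is the raw (not square-rooted) divergence with
base-2 logarithms, so it is bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd
from scipy.special import rel_entr

from .encoding import SpeciesVectorMatrix
from .errors import ParseError, ValidationError

__all__ = [
    "DistanceMatrix",
    "METRICS",
    "cosine_similarity",
    "cosine_dissimilarity",
    "jensen_shannon",
    "chebyshev",
    "distance_matrix",
]

_COS_EPS = 1e-12  # clamp so antipodal vectors give a large finite distance


# ---------------------------------------------------------------------------
# pairwise metrics
# ---------------------------------------------------------------------------


def _as_vector(u, name: str) -> np.ndarray:
    u = np.asarray(u, dtype=float).reshape(-1)
    if u.size == 0:
        raise ValidationError(f"{name} is empty")
    return u


def cosine_similarity(u, v) -> float:
    """cos θ between two vectors; in [0, 1] for non-negative counts."""
    u = _as_vector(u, "u")
    v = _as_vector(v, "v")
    if u.shape != v.shape:
        raise ValidationError(f"dimension mismatch: {u.size} vs {v.size}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValidationError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def cosine_dissimilarity(u, v) -> float:
    """−ln((1 + cos θ)/2): 0 iff the vectors are collinear (scale-free)."""
    cos = cosine_similarity(u, v)
    cos = min(1.0, max(-1.0 + _COS_EPS, cos))
    return float(-np.log((1.0 + cos) / 2.0))


def _to_probability(u, name: str) -> np.ndarray:
    u = _as_vector(u, name)
    if np.any(u < 0):
        raise ValidationError(f"{name} has negative entries")
    total = u.sum()
    if total == 0:
        raise ValidationError(f"{name} sums to zero")
    return u / total


def jensen_shannon(u, v) -> float:
    """Raw Jensen–Shannon divergence (base 2) on sum-normalized vectors."""
    p = _to_probability(u, "u")
    q = _to_probability(v, "v")
    if p.shape != q.shape:
        raise ValidationError(f"dimension mismatch: {p.size} vs {q.size}")
    m = 0.5 * (p + q)
    jsd = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    return float(jsd / np.log(2.0))


def chebyshev(u, v) -> float:
    """max_i |p_i − q_i| on sum-normalized vectors."""
    p = _to_probability(u, "u")
    q = _to_probability(v, "v")
    if p.shape != q.shape:
        raise ValidationError(f"dimension mismatch: {p.size} vs {q.size}")
    return float(np.abs(p - q).max())


def _normalized(fn):
    def wrapped(u, v) -> float:
        p = _to_probability(u, "u")
        q = _to_probability(v, "v")
        if p.shape != q.shape:
            raise ValidationError(f"dimension mismatch: {p.size} vs {q.size}")
        return float(fn(p, q))

    return wrapped


def _hellinger(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sqrt(0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)))


#: registry of available metrics; all are symmetric and return 0 on
#: identical inputs.  More can be added by inserting a callable.
METRICS: dict[str, object] = {
    "cosine": cosine_dissimilarity,
    "jsd": jensen_shannon,
    "cheb": chebyshev,
    "euclidean": _normalized(ssd.euclidean),
    "manhattan": _normalized(ssd.cityblock),
    "canberra": _normalized(ssd.canberra),
    "braycurtis": _normalized(ssd.braycurtis),
    "hellinger": _normalized(_hellinger),
}


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric non-negative matrix of pairwise dissimilarities."""

    labels: tuple[str, ...]
    values: np.ndarray  # (s, s) float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValidationError("distance matrix shape does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate labels in distance matrix")
        if not np.array_equal(v, v.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(v < 0):
            raise ValidationError("distance matrix has negative entries")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    # -- serialization ---------------------------------------------------

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels)).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ParseError("TSV distance matrix rows and columns disagree")
        vals = df.to_numpy(dtype=float)
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ParseError("TSV distance matrix is not symmetric")
        return cls(tuple(str(x) for x in df.index), (vals + vals.T) / 2)

    def to_phylip(self, path) -> None:
        """PHYLIP square distance format (relaxed labels)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join("%.10g" % x for x in self.values[i])
                fh.write(f"{lab}  {row}\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not lines:
            raise ParseError("empty PHYLIP distance file")
        try:
            n = int(lines[0].split()[0])
        except ValueError as exc:
            raise ParseError("PHYLIP file must start with the taxon count") from exc
        if len(lines) != n + 1:
            raise ParseError(f"expected {n} rows, found {len(lines) - 1}")
        labels, rows = [], []
        for ln in lines[1:]:
            parts = ln.split()
            if len(parts) != n + 1:
                raise ParseError(f"row {parts[0]!r} has {len(parts) - 1} values, expected {n}")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        vals = np.array(rows)
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ParseError("PHYLIP distance matrix is not symmetric")
        vals = (vals + vals.T) / 2  # remove rounding asymmetry exactly
        np.fill_diagonal(vals, 0.0)
        return cls(tuple(labels), vals)


def distance_matrix(M: SpeciesVectorMatrix | np.ndarray, metric: str = "cosine",
                    labels=None) -> DistanceMatrix:
    """Pairwise dissimilarities between the columns of a species matrix.

    The upper triangle is computed once (pair order i < j fixed) and
    mirrored, so the result is symmetric bit-exactly.
    """
    if metric not in METRICS:
        raise ValidationError(
            f"unknown metric {metric!r}; available: {', '.join(sorted(METRICS))}"
        )
    if isinstance(M, SpeciesVectorMatrix):
        cols = M.matrix
        labels = M.labels
    else:
        cols = np.asarray(M)
        if labels is None:
            labels = tuple(f"s{i + 1}" for i in range(cols.shape[1]))
        labels = tuple(labels)
    s = cols.shape[1]
    if s < 2:
        raise ValidationError("need at least 2 species")
    fn = METRICS[metric]
    vals = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            d = fn(cols[:, i], cols[:, j])
            vals[i, j] = vals[j, i] = max(0.0, d)
    return DistanceMatrix(labels, vals)
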