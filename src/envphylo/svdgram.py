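"""SVD k-mer species comparison (a latent-semantic-style word method).

Each protein becomes a column of k-mer counts (default k = 4).  A
singular value decomposition A = UΣVᵀ of the pooled k-mer × protein
matrix re-expresses every protein in the latent basis: protein p's
representation is row p of VΣ, optionally truncated to the leading
singular triplets.  A species is the L2-normalized sum of its proteins'
representations; pairwise cosines between species are converted to
distances with d = −ln((1 + cos θ)/2) and fed to neighbor joining.

At full rank the change of basis is exact, so species distances equal
those computed directly from pooled per-species k-mer count vectors —
the truncated ranks are where the method's noise filtering lives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .alphabet import encode
from .errors import ValidationError
from .metrics import DistanceMatrix, cosine_dissimilarity
from .nj import neighbor_joining
from .proteome import ProteomeSet
from .trees import PhyloTree

__all__ = ["NgramMatrix", "ngram_matrix", "svdgram_tree"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NgramMatrix:
    """k-mer × protein count matrix, all species pooled.

    Rows are the k-mers observed at least once (lexicographic order);
    ``protein_species[c]`` maps column c back to its species label.
    Windows containing a placeholder character are skipped.
    """

    k: int
    kmers: tuple[str, ...]
    counts: np.ndarray  # (n_kmers, n_proteins) int64
    protein_species: tuple[str, ...]

    @property
    def n_proteins(self) -> int:
        return self.counts.shape[1]


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    codes = encode(seq)
    out: dict[str, int] = {}
    for start in range(len(seq) - k + 1):
        if np.any(codes[start : start + k] < 0):
            continue
        word = seq[start : start + k]
        out[word] = out.get(word, 0) + 1
    return out


def ngram_matrix(pset: ProteomeSet, k: int = 4) -> NgramMatrix:
    """Sliding-window k-mer counts for every protein of every species.

    Proteins shorter than k are dropped with a warning; if nothing is
    left the input is unusable and an error is raised.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValidationError(f"k must be a positive integer, got {k!r}")
    per_protein: list[dict[str, int]] = []
    owners: list[str] = []
    for label in pset.species:
        for i, seq in enumerate(pset[label]):
            if len(seq) < k:
                logger.warning("dropping protein %d of %r: shorter than k=%d", i, label, k)
                continue
            per_protein.append(_kmer_counts(seq, k))
            owners.append(label)
    if not per_protein:
        raise ValidationError(f"all proteins are shorter than k={k}")
    kmers = sorted(set().union(*per_protein))
    index = {w: r for r, w in enumerate(kmers)}
    counts = np.zeros((len(kmers), len(per_protein)), dtype=np.int64)
    for c, wc in enumerate(per_protein):
        for w, n in wc.items():
            counts[index[w], c] = n
    return NgramMatrix(k=k, kmers=tuple(kmers), counts=counts, protein_species=tuple(owners))


def _species_vectors(ngrams: NgramMatrix, rank_fraction: float) -> tuple[list[str], np.ndarray]:
    if not (0.0 < rank_fraction <= 1.0):
        raise ValidationError(f"rank_fraction must be in (0, 1], got {rank_fraction!r}")
    A = ngrams.counts.astype(float)
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    # resolve the SVD sign ambiguity: largest-magnitude component of each
    # left singular vector is made positive (bit-reproducible output)
    for c in range(U.shape[1]):
        pivot = np.argmax(np.abs(U[:, c]))
        if U[pivot, c] < 0:
            U[:, c] = -U[:, c]
            Vt[c, :] = -Vt[c, :]
    full_rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if full_rank == 0:
        raise ValidationError("k-mer matrix has rank 0")
    rank = max(1, math.ceil(rank_fraction * full_rank))
    protein_repr = Vt[:rank, :].T * S[:rank]  # rows: proteins in latent space

    labels = list(dict.fromkeys(ngrams.protein_species))
    vectors = np.zeros((len(labels), rank))
    for row, owner in zip(protein_repr, ngrams.protein_species):
        vectors[labels.index(owner)] += row
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        bad = [lab for lab, nz in zip(labels, norms) if nz == 0]
        raise ValidationError(f"zero species vector after SVD for: {bad}")
    return labels, vectors / norms[:, None]


def svdgram_tree(pset: ProteomeSet, k: int = 4, rank_fraction: float = 1.0) -> PhyloTree:
    """Full SVD k-mer pipeline: counts → SVD → cosine distances → NJ."""
    if len(pset) < 3:
        raise ValidationError("tree building needs at least 3 species")
    ngrams = ngram_matrix(pset, k)
    labels, vectors = _species_vectors(ngrams, rank_fraction)
    s = len(labels)
    vals = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            d = cosine_dissimilarity(vectors[i], vectors[j])
            vals[i, j] = vals[j, i] = max(0.0, d)
    return neighbor_joining(DistanceMatrix(tuple(labels), vals))
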