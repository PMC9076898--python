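"""Synthetic proteome evolution with a known generating tree.

Two experimental designs are emulated so every pipeline stage can be
tested without downloading real data:

* **orthologous** — a single root proteome is evolved along the tree,
  so every species carries a descendant copy of every protein (the
  mitogenome-like setting with clean one-to-one orthologs).  Each site
  evolves independently as a rate-1 exchange process: over a branch of
  length b the site experiences Poisson(b) replacement events — so it
  substitutes at least once with probability 1 − e^(−b) and branch
  lengths are expected substitutions per site — and every event draws
  the new residue from the root composition excluding the current one.
  Being a proper continuous-time chain, the pairwise leaf kernel depends
  only on path length, so divergence grows monotonically along the tree
  (a single replacement opportunity per branch would break this).

* **non_orthologous** — every species receives its own, independently
  generated protein set: no sequence shares ancestry with any sequence
  of another species.  Lineage signal lives *only* in first-order
  neighbor preferences: residues are emitted by a Markov chain whose
  conditional probabilities drift along the tree (Gaussian perturbations
  in logit space, standard deviation = bias_strength × branch length,
  accumulated root-to-leaf).  At bias_strength 0 the species are
  exchangeable and no tree should be recoverable; at high bias the
  dipeptide preferences alone carry the topology.

A single master seed streams stable per-branch and per-species
substreams, so adding a species leaves the sequences generated for the
others untouched.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AA_ORDER, N_AA
from .errors import ValidationError
from .proteome import ProteomeSet
from .trees import Node, PhyloTree, read_newick

__all__ = ["SimConfig", "simulate_orthologous", "simulate_non_orthologous", "simulate", "write_dataset"]


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Branch lengths are expected substitutions per site per unit length.
    ``protein_length`` is either a single length or one per protein;
    ``root_composition`` is a point of the 20-simplex (uniform default).
    The seed fully determines the output.
    """

    tree: PhyloTree | str
    n_proteins: int = 20
    protein_length: int | Sequence[int] = 400
    root_composition: Sequence[float] | None = None
    mode: str = "orthologous"
    bias_strength: float = 0.0
    seed: int = 0
    _composition: np.ndarray = field(init=False, repr=False)
    _lengths: list[int] = field(init=False, repr=False)

    def __post_init__(self):
        if isinstance(self.tree, str):
            self.tree = read_newick(self.tree)
        if self.mode not in ("orthologous", "non_orthologous"):
            raise ValidationError(f"unknown mode: {self.mode!r}")
        if self.bias_strength < 0:
            raise ValidationError("bias_strength must be >= 0")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValidationError("seed must be a non-negative integer")
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if isinstance(self.protein_length, (int, np.integer)):
            lengths = [int(self.protein_length)] * self.n_proteins
        else:
            lengths = [int(x) for x in self.protein_length]
            if len(lengths) != self.n_proteins:
                raise ValidationError("protein_length list must have n_proteins entries")
        if any(x < 1 for x in lengths):
            raise ValidationError("protein lengths must be >= 1")
        self._lengths = lengths
        if self.root_composition is None:
            comp = np.full(N_AA, 1.0 / N_AA)
        else:
            comp = np.asarray(self.root_composition, dtype=float)
            if comp.shape != (N_AA,) or np.any(comp < 0) or comp.sum() <= 0:
                raise ValidationError("root_composition must be 20 non-negative values")
            comp = comp / comp.sum()
        self._composition = comp
        for node in self.tree.root.postorder():
            if node.length < 0:
                raise ValidationError("branch lengths must be >= 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "tree": self.tree.to_newick(),
                "n_proteins": self.n_proteins,
                "protein_length": self._lengths,
                "root_composition": self._composition.tolist(),
                "mode": self.mode,
                "bias_strength": self.bias_strength,
                "seed": self.seed,
            },
            indent=2,
        )


def _stream(seed: int, tag: str) -> np.random.Generator:
    """A stable substream keyed by a string tag."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(tag.encode())]))


def _leafset_key(node: Node) -> str:
    return ",".join(sorted(n.label for n in node.postorder() if n.is_leaf))


def _sample_codes(rng: np.random.Generator, probs: np.ndarray, size: int) -> np.ndarray:
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(size), side="right").astype(np.int8)


def _codes_to_proteins(codes: np.ndarray, lengths: list[int]) -> list[str]:
    seqs = []
    pos = 0
    letters = np.frombuffer(AA_ORDER.encode(), dtype=np.uint8)
    for L in lengths:
        seqs.append(letters[codes[pos : pos + L]].tobytes().decode())
        pos += L
    return seqs


def simulate_orthologous(cfg: SimConfig) -> tuple[ProteomeSet, PhyloTree]:
    """Evolve one root proteome along the tree; return leaves + topology."""
    if cfg.mode != "orthologous":
        raise ValidationError("config mode is not 'orthologous'")
    comp = cfg._composition
    total = sum(cfg._lengths)
    root_codes = _sample_codes(_stream(cfg.seed, "root"), comp, total)

    # replacement distributions excluding the current residue
    repl = np.tile(comp, (N_AA, 1))
    np.fill_diagonal(repl, 0.0)
    repl /= repl.sum(axis=1, keepdims=True)

    leaves: dict[str, np.ndarray] = {}

    def walk(node: Node, codes: np.ndarray) -> None:
        for child in node.children:
            rng = _stream(cfg.seed, "branch:" + _leafset_key(child))
            child_codes = codes.copy()
            remaining = rng.poisson(child.length, total)
            while np.any(remaining > 0):
                idx = np.nonzero(remaining > 0)[0]
                # snapshot before the sweep: every pending site gets exactly
                # one replacement event this round
                current = child_codes[idx].copy()
                for residue in range(N_AA):
                    here = idx[current == residue]
                    if here.size:
                        child_codes[here] = _sample_codes(rng, repl[residue], here.size)
                remaining[idx] -= 1
            if child.is_leaf:
                leaves[child.label] = child_codes
            else:
                walk(child, child_codes)

    walk(cfg.tree.root, root_codes)
    pset = ProteomeSet(
        (lab, _codes_to_proteins(leaves[lab], cfg._lengths)) for lab in sorted(leaves)
    )
    return pset, cfg.tree


def simulate_non_orthologous(cfg: SimConfig) -> tuple[ProteomeSet, PhyloTree]:
    """Disjoint protein sets per species; signal only in dipeptide bias."""
    if cfg.mode != "non_orthologous":
        raise ValidationError("config mode is not 'non_orthologous'")
    comp = cfg._composition
    base_logits = np.tile(np.log(np.maximum(comp, 1e-300)), (N_AA, 1))

    leaf_logits: dict[str, np.ndarray] = {}

    def walk(node: Node, logits: np.ndarray) -> None:
        for child in node.children:
            rng = _stream(cfg.seed, "drift:" + _leafset_key(child))
            child_logits = logits + rng.normal(
                0.0, cfg.bias_strength * child.length, size=(N_AA, N_AA)
            )
            if child.is_leaf:
                leaf_logits[child.label] = child_logits
            else:
                walk(child, child_logits)

    walk(cfg.tree.root, base_logits)

    max_len = max(cfg._lengths)
    data: dict[str, list[str]] = {}
    for label in sorted(leaf_logits):
        logits = leaf_logits[label]
        P = np.exp(logits - logits.max(axis=1, keepdims=True))
        P /= P.sum(axis=1, keepdims=True)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0
        rng = _stream(cfg.seed, "species:" + label)
        n = cfg.n_proteins
        codes = np.empty((n, max_len), dtype=np.int8)
        codes[:, 0] = _sample_codes(rng, comp, n)
        for pos in range(1, max_len):
            u = rng.random(n)
            codes[:, pos] = (cum[codes[:, pos - 1]] < u[:, None]).sum(axis=1)
        letters = np.frombuffer(AA_ORDER.encode(), dtype=np.uint8)
        data[label] = [
            letters[codes[p, : cfg._lengths[p]]].tobytes().decode() for p in range(n)
        ]

    # independent generation makes cross-species duplicates astronomically
    # unlikely; verify the construction guarantee anyway
    seen: dict[str, str] = {}
    for label, seqs in data.items():
        for s in seqs:
            owner = seen.setdefault(s, label)
            if owner != label:
                raise ValidationError(
                    f"sequence shared between species {owner!r} and {label!r}; "
                    "use a different seed or longer proteins"
                )
    return ProteomeSet(data.items()), cfg.tree


def simulate(cfg: SimConfig) -> tuple[ProteomeSet, PhyloTree]:
    """Dispatch on ``cfg.mode``."""
    if cfg.mode == "orthologous":
        return simulate_orthologous(cfg)
    return simulate_non_orthologous(cfg)


def write_dataset(cfg: SimConfig, outdir: str | Path) -> tuple[ProteomeSet, PhyloTree]:
    """Simulate and write the standard layout: per-species FASTA files,
    ``true_tree.nwk`` and a ``config.json`` sidecar."""
    pset, tree = simulate(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pset.to_fasta_dir(outdir)
    (outdir / "true_tree.nwk").write_text(tree.to_newick() + "\n")
    (outdir / "config.json").write_text(cfg.to_json() + "\n")
    return pset, tree
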