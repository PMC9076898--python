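"""Reading per-species protein FASTA files into a :class:`ProteomeSet`.

One FASTA file per species; the filename stem is the default species
label (sequence headers in public proteomes vary too wildly to be a
reliable label source).  Sequences are normalized on entry: uppercased,
whitespace removed, trailing ``*`` stop markers stripped.  Characters
outside the 20-letter alphabet are *retained* as opaque placeholders —
they occupy a position so the offsets of flanking standard residues are
unaffected, but downstream counting never treats them as targets or
neighbors.  Records left with zero standard residues are dropped with a
warning; a species left with no sequences at all is an error.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

from Bio import SeqIO

from .alphabet import AA_INDEX
from .errors import ValidationError

__all__ = ["ProteomeSet", "normalize_sequence", "read_proteome_dir"]

logger = logging.getLogger(__name__)

_FASTA_SUFFIXES = {".fasta", ".fa", ".faa", ".fas", ".pep"}


def normalize_sequence(seq: str) -> str:
    """Uppercase, remove whitespace, strip trailing stop markers.

    Idempotent: normalizing an already-normalized sequence is a no-op.
    """
    s = "".join(seq.split()).upper()
    return s.rstrip("*")


def _n_standard(seq: str) -> int:
    return sum(1 for c in seq if c in AA_INDEX)


class ProteomeSet(Mapping[str, list[str]]):
    """Ordered mapping from species label to its list of protein sequences.

    Iteration order is insertion order, which fixes the column order of
    every downstream matrix.
    """

    def __init__(self, data: Mapping[str, Iterable[str]] | Iterable[tuple[str, Iterable[str]]] = ()):
        self._data: dict[str, list[str]] = {}
        items = data.items() if isinstance(data, Mapping) else data
        for label, seqs in items:
            self.add(label, seqs)

    def add(self, label: str, sequences: Iterable[str]) -> None:
        if not isinstance(label, str) or not label:
            raise ValidationError("species label must be a non-empty string")
        if label in self._data:
            raise ValidationError(f"duplicate species label: {label!r}")
        kept: list[str] = []
        for i, raw in enumerate(sequences):
            seq = normalize_sequence(raw)
            if _n_standard(seq) == 0:
                logger.warning(
                    "dropping record %d of species %r: no standard residues", i, label
                )
                continue
            kept.append(seq)
        if not kept:
            raise ValidationError(f"species {label!r} has no usable sequences")
        self._data[label] = kept

    # Mapping interface -------------------------------------------------

    def __getitem__(self, label: str) -> list[str]:
        return self._data[label]

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    # ------------------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return list(self._data)

    @property
    def n_sequences(self) -> int:
        return sum(len(v) for v in self._data.values())

    @property
    def n_residues(self) -> int:
        return sum(len(s) for v in self._data.values() for s in v)

    def to_fasta_dir(self, path: str | Path) -> None:
        """Write one FASTA file per species (deterministic bytes)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for label, seqs in self._data.items():
            with open(path / f"{label}.fasta", "w") as fh:
                for i, seq in enumerate(seqs):
                    fh.write(f">{label}_p{i + 1:05d}\n")
                    for j in range(0, len(seq), 60):
                        fh.write(seq[j : j + 60] + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"ProteomeSet({len(self)} species, {self.n_sequences} sequences)"


def read_proteome_dir(path: str | Path, label_rule: str = "filename") -> ProteomeSet:
    """Load a directory of per-species FASTA files.

    Parameters
    ----------
    path
        Directory containing one FASTA file per species.
    label_rule
        ``"filename"`` (default): the filename stem is the species label.
        ``"header"``: the first whitespace-delimited token of the first
        record's header is used instead.
    """
    if label_rule not in ("filename", "header"):
        raise ValidationError(f"unknown label_rule: {label_rule!r}")
    path = Path(path)
    if not path.is_dir():
        raise OSError(f"not a directory: {path}")
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _FASTA_SUFFIXES and p.is_file()
    )
    if not files:
        raise ValidationError(f"no FASTA files found in {path}")
    pset = ProteomeSet()
    for fp in files:
        try:
            records = list(SeqIO.parse(str(fp), "fasta"))
        except OSError:
            raise
        except Exception as exc:
            raise OSError(f"cannot parse FASTA file {fp}: {exc}") from exc
        if not records:
            raise ValidationError(f"FASTA file {fp} contains no records")
        if label_rule == "filename":
            label = fp.stem
        else:
            label = records[0].description.split()[0]
        pset.add(label, (str(rec.seq) for rec in records))
    return pset
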