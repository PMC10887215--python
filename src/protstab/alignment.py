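"""Aligned homolog sets and the seed coordinate convention.

An :class:`AlignmentSet` wraps a gapped multiple sequence alignment together
with a designated seed sequence (the engineering parent).  All substitution
positions in the package are expressed in the seed's 1-based ungapped
coordinates; the alignment provides the map from those positions to alignment
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

GAP = "-"


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments or missing seed sequences."""


@dataclass
class AlignmentSet:
    """A gapped protein alignment with a designated seed sequence."""

    seed_id: str
    sequences: list[tuple[str, str]]  # (id, gapped sequence)
    column_count: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentFormatError("alignment is empty")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment: lengths {sorted(lengths)}")
        self.column_count = lengths.pop()
        ids = [i for i, _ in self.sequences]
        if self.seed_id not in ids:
            raise AlignmentFormatError(f"seed id {self.seed_id!r} not in alignment")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def seed_gapped(self) -> str:
        return dict(self.sequences)[self.seed_id]

    @property
    def seed_ungapped(self) -> str:
        return self.seed_gapped.replace(GAP, "")

    def position_to_column(self) -> dict[int, int]:
        """Map seed position (1-based, ungapped) -> alignment column (0-based)."""
        out: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(self.seed_gapped):
            if ch != GAP:
                pos += 1
                out[pos] = col
        return out

    def column(self, col: int) -> list[str]:
        """Residues (including gaps) of one alignment column, in sequence order."""
        return [seq[col] for _, seq in self.sequences]

    def identity_to_seed(self, seq_id: str) -> float:
        """Fraction of identical residues over columns where both have a residue."""
        seed = self.seed_gapped
        other = dict(self.sequences)[seq_id]
        both = [(a, b) for a, b in zip(seed, other) if a != GAP and b != GAP]
        if not both:
            return 0.0
        return sum(a == b for a, b in both) / len(both)


def load_alignment(path: str | Path, seed_id: str) -> AlignmentSet:
    """Load an aligned, gapped FASTA file.

    Raises :class:`AlignmentFormatError` when sequences have unequal gapped
    lengths or the seed id is absent.
    """
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if len(records) < 2:
        raise AlignmentFormatError(f"{path}: an alignment needs at least 2 sequences")
    return AlignmentSet(seed_id=seed_id, sequences=records)


def write_alignment(aln: AlignmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.sequences:
            fh.write(f">{sid}\n{seq}\n")
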