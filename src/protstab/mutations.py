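"""Amino-acid substitution specs and the hyphenated mutation-string grammar.

A mutation string such as ``"Q85R-C102S-S106T-Y109H-V200L"`` names an ordered
set of single-residue substitutions on the seed (parent) sequence.  Positions
are 1-based and count the initiator methionine as residue 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

#: Canonical 20-letter amino-acid alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TOKEN_RE = re.compile(r"([A-Za-z])(\d+)([A-Za-z])\Z")


class MutationError(ValueError):
    """Base class for mutation parsing/validation failures."""


class MutationParseError(MutationError):
    """A token does not match the ``<wt><position><new>`` grammar."""


class MutationValidationError(MutationError):
    """A token parses but violates a domain invariant."""


@dataclass(frozen=True, order=True)
class MutationSpec:
    """A single amino-acid substitution: wildtype residue, 1-based position, new residue."""

    wt_residue: str
    position: int
    new_residue: str

    def __post_init__(self) -> None:
        if self.wt_residue not in AMINO_ACIDS:
            raise MutationValidationError(
                f"wildtype residue {self.wt_residue!r} is not a canonical amino acid"
            )
        if self.new_residue not in AMINO_ACIDS:
            raise MutationValidationError(
                f"new residue {self.new_residue!r} is not a canonical amino acid"
            )
        if self.position < 1:
            raise MutationValidationError(f"position must be >= 1, got {self.position}")
        if self.wt_residue == self.new_residue:
            raise MutationValidationError(
                f"substitution {self} replaces a residue with itself"
            )

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.new_residue}"


def parse_mutation(token: str) -> MutationSpec:
    """Parse a single token like ``"Q85R"``."""
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise MutationParseError(f"malformed mutation token {token!r}")
    wt, pos, new = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return MutationSpec(wt, pos, new)


def parse_mutation_string(text: str) -> tuple[MutationSpec, ...]:
    """Parse a hyphen-joined mutation string into an ordered tuple of specs.

    Order is preserved exactly as written; ``format_mutation_string`` round-trips
    the result byte-identically.  Two tokens at the same position are rejected
    (a variant cannot carry two substitutions of one residue).
    """
    tokens = text.strip().split("-")
    specs = [parse_mutation(t) for t in tokens]
    seen: dict[int, MutationSpec] = {}
    for s in specs:
        if s.position in seen:
            raise MutationValidationError(
                f"duplicate position {s.position}: {seen[s.position]} vs {s}"
            )
        seen[s.position] = s
    return tuple(specs)


def format_mutation_string(mutations: Iterable[MutationSpec]) -> str:
    """Inverse of :func:`parse_mutation_string`."""
    return "-".join(str(m) for m in mutations)


def check_against_reference(
    mutations: Sequence[MutationSpec], reference: str
) -> None:
    """Validate wildtype residues against a reference (seed) protein sequence.

    ``reference`` is the ungapped seed sequence with Met1 at index 0.  Raises
    :class:`MutationValidationError` on the first mismatch or out-of-range
    position.  Validation is optional throughout the package because the seed
    sequence is not always available.
    """
    for m in mutations:
        if m.position > len(reference):
            raise MutationValidationError(
                f"{m}: position beyond reference length {len(reference)}"
            )
        actual = reference[m.position - 1]
        if actual != m.wt_residue:
            raise MutationValidationError(
                f"{m}: reference has {actual!r} at position {m.position}"
            )
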