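"""Variant tables: mutation sets with measured responses.

A variant table is a CSV with columns ``variant_id``, ``mutations`` (hyphen
grammar, empty for the reference enzyme and natural homologs), an optional
``group`` label, and one or more response columns (e.g. ``half_life_min``,
``cdnb_activity``, ``telcyta_fold``).  Two non-numeric response tokens are
typed, never coerced to 0:

* ``ND`` (also printed ``N/D``) — assayed but no detectable signal;
* ``+`` runs (``+``..``++++``) — ordinal by-eye activity scores.

The package ships three fixture tables: the homolog/point-mutant activities,
the rationally designed double-mutant library, and the thermostability
half-life table covering the machine-learning library.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .mutations import MutationSpec, format_mutation_string, parse_mutation_string


class _NotDetected:
    """Sentinel for an assay that ran but gave no detectable signal."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ND"


#: The not-detected marker. Distinct from a missing (unmeasured) response.
ND = _NotDetected()


@dataclass(frozen=True)
class PlusScore:
    """Ordinal activity score: the number of ``+`` signs."""

    plusses: int

    def __post_init__(self) -> None:
        if self.plusses < 1:
            raise ValueError("PlusScore needs at least one +")

    def __str__(self) -> str:
        return "+" * self.plusses


Response = float | _NotDetected | PlusScore


class VariantTableError(ValueError):
    """Raised with row/column coordinates for unparseable table cells."""


@dataclass
class VariantRecord:
    """One enzyme variant: label, ordered substitutions, measured responses."""

    variant_id: str
    mutations: tuple[MutationSpec, ...]
    responses: dict[str, Response] = field(default_factory=dict)
    group: str | None = None

    def __post_init__(self) -> None:
        hl = self.responses.get("half_life_min")
        if isinstance(hl, float) and hl <= 0:
            raise VariantTableError(
                f"{self.variant_id}: half_life_min must be positive, got {hl}"
            )

    @property
    def mutation_string(self) -> str:
        return format_mutation_string(self.mutations)

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    def has(self, mutation: MutationSpec) -> bool:
        return mutation in self.mutations

    def to_dict(self) -> dict:
        resp = {
            k: (repr(v) if isinstance(v, _NotDetected) else str(v) if isinstance(v, PlusScore) else v)
            for k, v in self.responses.items()
        }
        return {
            "variant_id": self.variant_id,
            "mutations": self.mutation_string,
            "group": self.group,
            "responses": resp,
        }


def parse_response_cell(cell: str) -> Response | None:
    """Parse one response cell; ``None`` means missing (empty cell)."""
    text = cell.strip()
    if not text:
        return None
    if text.upper() in ("ND", "N/D"):
        return ND
    if set(text) == {"+"}:
        return PlusScore(len(text))
    try:
        return float(text)
    except ValueError:
        raise VariantTableError(f"unparseable response cell {cell!r}") from None


_RESERVED = ("variant_id", "mutations", "group")


def load_variant_table(path: str | Path) -> list[VariantRecord]:
    """Load a variant-table CSV; every non-reserved column is a response."""
    records: list[VariantRecord] = []
    seen_ids: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "variant_id" not in reader.fieldnames:
            raise VariantTableError(f"{path}: missing header with variant_id column")
        for rownum, row in enumerate(reader, start=2):
            vid = row["variant_id"].strip()
            if vid in seen_ids:
                raise VariantTableError(f"{path} row {rownum}: duplicate variant_id {vid!r}")
            seen_ids.add(vid)
            mut_text = (row.get("mutations") or "").strip()
            mutations = parse_mutation_string(mut_text) if mut_text else ()
            responses: dict[str, Response] = {}
            for col, cell in row.items():
                if col in _RESERVED or cell is None:
                    continue
                try:
                    val = parse_response_cell(cell)
                except VariantTableError as exc:
                    raise VariantTableError(f"{path} row {rownum}, column {col!r}: {exc}") from None
                if val is not None:
                    responses[col] = val
            group = (row.get("group") or "").strip() or None
            records.append(VariantRecord(vid, mutations, responses, group))
    return records


def write_variant_table(
    records: Iterable[VariantRecord], path: str | Path, response_columns: list[str] | None = None
) -> None:
    records = list(records)
    if response_columns is None:
        cols: list[str] = []
        for r in records:
            for k in r.responses:
                if k not in cols:
                    cols.append(k)
        response_columns = cols
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_RESERVED) + response_columns)
        for r in records:
            row = [r.variant_id, r.mutation_string, r.group or ""]
            for c in response_columns:
                v = r.responses.get(c)
                if v is None:
                    row.append("")
                elif isinstance(v, _NotDetected):
                    row.append("ND")
                elif isinstance(v, PlusScore):
                    row.append(str(v))
                else:
                    row.append(repr(v))
            writer.writerow(row)


def records_by_id(records: Iterable[VariantRecord]) -> dict[str, VariantRecord]:
    return {r.variant_id: r for r in records}


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("protstab") / "data" / name))


def load_activity_table() -> list[VariantRecord]:
    """Homolog and point-mutant activities (Telcyta fold, CDNB specific activity)."""
    return load_variant_table(_fixture_path("table1_activity.csv"))


def load_rational_table() -> list[VariantRecord]:
    """The rationally designed double-mutant library with by-eye Telcyta scores."""
    return load_variant_table(_fixture_path("table2_rational.csv"))


def load_half_life_table() -> list[VariantRecord]:
    """Thermal-inactivation half-lives of the machine-learning library."""
    return load_variant_table(_fixture_path("table3_half_life.csv"))
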