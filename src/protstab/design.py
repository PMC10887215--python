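"""Balanced fractional-factorial assignment of substitutions to variants.

Given N candidate substitutions, build V variants carrying c substitutions
each such that every substitution appears in several variants (occupancy as
even as possible), no variant carries two substitutions at the same residue
position, and pairwise co-occurrence is as uniform as possible.  The engine
is a greedy balanced fill followed by seed-reproducible pairwise-swap descent
on the sum of squared pairwise co-occurrence counts; on small instances it is
verifiable against exhaustive search.

The parental background substitution (e.g. Y109H) is carried by every variant
and lives outside the design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mutations import MutationSpec


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class DesignSpec:
    candidates: tuple[MutationSpec, ...]
    n_variants: int
    subs_per_variant: int
    rng_seed: int = 0
    swap_iterations: int = 2000

    def __post_init__(self) -> None:
        n = len(self.candidates)
        v, c = self.n_variants, self.subs_per_variant
        if n == 0 or v < 1 or c < 1:
            raise DesignError("need at least one candidate, variant, and slot")
        if v * c < n:
            raise DesignError(
                f"V*c = {v * c} cannot host all {n} substitutions at least once"
            )
        positions = {m.position for m in self.candidates}
        if c > len(positions):
            raise DesignError(
                f"{c} substitutions per variant infeasible with only "
                f"{len(positions)} distinct positions"
            )
        for p in sorted(positions):
            if sum(m.position == p for m in self.candidates) > v:
                raise DesignError(
                    f"position {p} carries more mutually exclusive substitutions "
                    f"than there are variants"
                )


@dataclass
class IncidenceDesign:
    """Binary variants x substitutions membership matrix with diagnostics."""

    candidates: tuple[MutationSpec, ...]
    matrix: np.ndarray  # shape (V, N), dtype int

    @property
    def occupancy(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def cooccurrence(self) -> np.ndarray:
        return self.matrix.T @ self.matrix

    @property
    def design_rank(self) -> int:
        """Rank of the membership matrix augmented with an intercept column."""
        aug = np.hstack([np.ones((self.matrix.shape[0], 1)), self.matrix])
        return int(np.linalg.matrix_rank(aug))

    def objective(self) -> float:
        """Sum of squared pairwise (off-diagonal) co-occurrence counts."""
        co = self.cooccurrence
        return float((co**2).sum() - (np.diag(co) ** 2).sum()) / 2.0

    def variant_mutations(self, row: int) -> tuple[MutationSpec, ...]:
        return tuple(
            m for m, on in zip(self.candidates, self.matrix[row]) if on
        )


def _row_feasible(matrix: np.ndarray, positions: list[int], row: int, col: int, c: int) -> bool:
    if matrix[row].sum() >= c:
        return False
    if matrix[row, col]:
        return False
    occupied = {positions[j] for j in np.flatnonzero(matrix[row])}
    return positions[col] not in occupied


def design_library(spec: DesignSpec) -> IncidenceDesign:
    """Greedy balanced fill + pairwise swap descent; deterministic per seed."""
    rng = np.random.default_rng(spec.rng_seed)
    n, v, c = len(spec.candidates), spec.n_variants, spec.subs_per_variant
    positions = [m.position for m in spec.candidates]
    matrix = np.zeros((v, n), dtype=int)

    # Greedy: repeatedly place the currently least-used substitution into the
    # feasible row where it least inflates the co-occurrence objective.
    total_slots = v * c
    for _ in range(total_slots):
        occ = matrix.sum(axis=0)
        order = sorted(range(n), key=lambda j: (occ[j], rng.random()))
        placed = False
        for col in order:
            rows = [r for r in range(v) if _row_feasible(matrix, positions, r, col, c)]
            if not rows:
                continue
            co = matrix.T @ matrix

            def cost(r: int) -> tuple:
                inc = sum((co[col, j] + 1) ** 2 - co[col, j] ** 2 for j in np.flatnonzero(matrix[r]))
                return (inc, matrix[r].sum(), r)

            best = min(rows, key=cost)
            matrix[best, col] = 1
            placed = True
            break
        if not placed:
            blocked = sorted({positions[j] for j in range(n) if occ[j] == occ.min()})
            raise DesignError(
                f"greedy fill blocked; position exclusivity unsatisfiable near "
                f"positions {blocked}"
            )

    _rebalance(matrix, positions, rng)

    # Swap descent: exchange memberships between two rows when the move is
    # feasible and strictly lowers the squared co-occurrence objective.
    design = IncidenceDesign(spec.candidates, matrix)
    current = design.objective()
    for _ in range(spec.swap_iterations):
        r1, r2 = rng.integers(0, v, size=2)
        if r1 == r2:
            continue
        only1 = np.flatnonzero(matrix[r1] & ~matrix[r2].astype(bool))
        only2 = np.flatnonzero(matrix[r2] & ~matrix[r1].astype(bool))
        if len(only1) == 0 or len(only2) == 0:
            continue
        a = int(rng.choice(only1))
        b = int(rng.choice(only2))
        matrix[r1, a] = 0
        matrix[r2, b] = 0
        if _row_feasible(matrix, positions, r1, b, c) and _row_feasible(matrix, positions, r2, a, c):
            matrix[r1, b] = 1
            matrix[r2, a] = 1
            new = design.objective()
            if new < current:
                current = new
                continue
            matrix[r1, b] = 0
            matrix[r2, a] = 0
        matrix[r1, a] = 1
        matrix[r2, b] = 1
    return design


def _rebalance(matrix: np.ndarray, positions: list[int], rng: np.random.Generator) -> None:
    """Move memberships from over- to under-used substitutions until occupancy
    values differ by at most one, or no feasible move remains.

    With all-distinct positions the <=1 spread is always reached; when several
    candidates share a position, exclusivity can force a wider spread (e.g.
    two same-position candidates splitting V slots while singletons keep more)
    and the balance is then best-effort.  A substitution left entirely unused
    is always an error.
    """
    v, n = matrix.shape
    c = int(matrix[0].sum())
    for _ in range(10 * n * v):
        occ = matrix.sum(axis=0)
        if occ.max() - occ.min() <= 1 and occ.min() >= 1:
            return
        donors = np.flatnonzero(occ == occ.max())
        acceptors = np.flatnonzero(occ == occ.min())
        moved = False
        for col_to in acceptors:
            for col_from in donors:
                for r in range(v):
                    if matrix[r, col_from] and not matrix[r, col_to]:
                        matrix[r, col_from] = 0
                        if _row_feasible(matrix, positions, r, col_to, c):
                            matrix[r, col_to] = 1
                            moved = True
                            break
                        matrix[r, col_from] = 1
                if moved:
                    break
            if moved:
                break
        if not moved:
            break
    occ = matrix.sum(axis=0)
    if occ.min() < 1:
        unused = sorted({positions[j] for j in np.flatnonzero(occ == 0)})
        raise DesignError(
            f"position exclusivity leaves substitutions at positions {unused} unused"
        )


@dataclass
class DesignDiagnostics:
    row_sums: list[int]
    occupancy: list[int]
    max_cooccurrence: int
    design_rank: int
    identifiable: bool
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_design(design: IncidenceDesign, spec: DesignSpec) -> DesignDiagnostics:
    """Report balance and identifiability; violations are flagged, not raised."""
    violations: list[str] = []
    rs = design.row_sums
    for r, s in enumerate(rs):
        if s != spec.subs_per_variant:
            violations.append(f"variant {r}: row sum {s} != {spec.subs_per_variant}")
    occ = design.occupancy
    for j, o in enumerate(occ):
        if o < 1:
            violations.append(f"substitution {design.candidates[j]}: never used")
    positions = [m.position for m in design.candidates]
    for r in range(design.matrix.shape[0]):
        used = [positions[j] for j in np.flatnonzero(design.matrix[r])]
        dupes = sorted({p for p in used if used.count(p) > 1})
        for p in dupes:
            violations.append(f"variant {r}: two substitutions at position {p}")
    co = design.cooccurrence.copy()
    np.fill_diagonal(co, 0)
    rank = design.design_rank
    n = len(design.candidates)
    return DesignDiagnostics(
        row_sums=[int(x) for x in rs],
        occupancy=[int(x) for x in occ],
        max_cooccurrence=int(co.max()) if n > 1 else 0,
        design_rank=rank,
        identifiable=rank == n + 1,
        violations=violations,
    )


def incidence_from_variants(
    records,
    background: tuple[MutationSpec, ...] = (),
) -> IncidenceDesign:
    """Reconstruct an incidence design from variant records, excluding the
    fixed background substitutions from the columns."""
    bg = set(background)
    subs: list[MutationSpec] = []
    for r in records:
        for m in r.mutations:
            if m not in bg and m not in subs:
                subs.append(m)
    subs.sort(key=lambda m: (m.position, m.new_residue))
    matrix = np.zeros((len(records), len(subs)), dtype=int)
    col = {m: j for j, m in enumerate(subs)}
    for i, r in enumerate(records):
        for m in r.mutations:
            if m not in bg:
                matrix[i, col[m]] = 1
    return IncidenceDesign(tuple(subs), matrix)
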