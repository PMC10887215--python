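"""Synthetic data with known ground truth for every pipeline stage.

Three generators mirror the three experimental inputs:

* homolog alignments with controlled per-column residue frequencies, optional
  pairwise column coupling (for covariation), and optional per-sequence
  identity targets relative to the seed;
* thermal-inactivation decay curves under either kinetic order with
  multiplicative lognormal noise (activities are positive and errors scale
  with magnitude);
* variant-response tables produced from known additive substitution weights,
  optional pairwise epistasis, and lognormal noise — the forward model that
  the effect estimator inverts.

All generators are deterministic per rng seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentSet
from .design import IncidenceDesign
from .kinetics import DEFAULT_DECAY_TIMES, DecayDataset, first_order, second_order
from .mutations import AMINO_ACIDS, MutationSpec
from .variants import VariantRecord


class GenerationError(ValueError):
    pass


@dataclass
class AlignmentModel:
    """Generative model for a gapped homolog alignment.

    ``profiles`` maps column index -> {residue: probability}; unlisted columns
    are fully conserved at the seed residue.  ``couplings`` are
    (column_i, column_j, strength) triples: with probability ``strength`` the
    residue at column_j is deterministically paired to the residue drawn at
    column_i (rank-matched between the two profiles), otherwise drawn
    independently.  ``target_identities``, when given, instead mutates the
    seed to hit each requested identity exactly (profile residues used where
    available).
    """

    seed: str
    n_sequences: int = 100
    profiles: dict[int, dict[str, float]] = field(default_factory=dict)
    couplings: list[tuple[int, int, float]] = field(default_factory=list)
    identity_band: tuple[float, float] | None = None
    target_identities: list[float] | None = None
    rng_seed: int = 0
    seed_id: str = "seed"
    max_retries: int = 1000

    def __post_init__(self) -> None:
        for col, prof in self.profiles.items():
            if not math.isclose(sum(prof.values()), 1.0, abs_tol=1e-9):
                raise GenerationError(f"column {col} profile does not sum to 1")
            if col >= len(self.seed):
                raise GenerationError(f"profile column {col} outside the seed")
        for i, j, s in self.couplings:
            if i == j:
                raise GenerationError("coupling must reference distinct columns")
            if not 0 <= s <= 1:
                raise GenerationError("coupling strength must lie in [0,1]")


def _profile_for(model: AlignmentModel, col: int) -> dict[str, float]:
    return model.profiles.get(col, {model.seed[col]: 1.0})


def _rank_map(prof_i: dict[str, float], prof_j: dict[str, float]) -> dict[str, str]:
    """Rank-matched residue pairing between two column profiles."""
    ri = sorted(prof_i, key=lambda r: (-prof_i[r], r))
    rj = sorted(prof_j, key=lambda r: (-prof_j[r], r))
    return {a: rj[min(k, len(rj) - 1)] for k, a in enumerate(ri)}


def _sample_sequence(model: AlignmentModel, rng: np.random.Generator) -> str:
    chars = []
    for col in range(len(model.seed)):
        prof = _profile_for(model, col)
        residues = sorted(prof)
        probs = np.array([prof[r] for r in residues])
        chars.append(residues[rng.choice(len(residues), p=probs / probs.sum())])
    for i, j, s in model.couplings:
        if rng.random() < s:
            mapping = _rank_map(_profile_for(model, i), _profile_for(model, j))
            chars[j] = mapping.get(chars[i], chars[j])
    return "".join(chars)


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _mutate_to_identity(
    seed: str, identity: float, model: AlignmentModel, rng: np.random.Generator
) -> str:
    n_mut = round((1.0 - identity) * len(seed))
    sites = rng.choice(len(seed), size=n_mut, replace=False)
    chars = list(seed)
    for col in sites:
        prof = _profile_for(model, int(col))
        options = [r for r in sorted(prof) if r != seed[col]]
        if not options:
            options = [r for r in AMINO_ACIDS if r != seed[col]]
        chars[col] = options[int(rng.integers(len(options)))]
    return "".join(chars)


def gen_alignment(model: AlignmentModel) -> AlignmentSet:
    """Sample an ungapped alignment containing the seed plus n generated homologs."""
    rng = np.random.default_rng(model.rng_seed)
    sequences: list[tuple[str, str]] = [(model.seed_id, model.seed)]
    if model.target_identities is not None:
        for idx, ident in enumerate(model.target_identities):
            seq = _mutate_to_identity(model.seed, ident, model, rng)
            sequences.append((f"hom{idx:04d}", seq))
    else:
        for idx in range(model.n_sequences):
            for _ in range(model.max_retries):
                seq = _sample_sequence(model, rng)
                if model.identity_band is None:
                    break
                lo, hi = model.identity_band
                if lo <= _identity(seq, model.seed) <= hi:
                    break
            else:
                raise GenerationError(
                    f"could not reach identity band {model.identity_band} "
                    f"in {model.max_retries} tries"
                )
            sequences.append((f"hom{idx:04d}", seq))
    return AlignmentSet(seed_id=model.seed_id, sequences=sequences)


def gen_decay(
    model_order: str,
    t_half: float,
    a0: float = 1.0,
    sigma: float = 0.0,
    times=DEFAULT_DECAY_TIMES,
    rng_seed: int = 0,
) -> DecayDataset:
    """Exact decay curve of the given order times a lognormal noise factor.

    ``t_half`` parameterizes the rate constant: k = ln2/t_half (first order)
    or k = 1/(a0*t_half) (second order).  ``sigma=0`` returns the closed form.
    """
    if t_half <= 0 or a0 <= 0 or sigma < 0:
        raise GenerationError("t_half and a0 must be positive, sigma non-negative")
    t = np.asarray(times, dtype=float)
    if model_order == "first":
        curve = first_order(t, a0, math.log(2) / t_half)
    elif model_order == "second":
        curve = second_order(t, a0, 1.0 / (a0 * t_half))
    else:
        raise GenerationError(f"unknown model order {model_order!r}")
    if sigma > 0:
        rng = np.random.default_rng(rng_seed)
        curve = curve * np.exp(sigma * rng.standard_normal(t.size))
    return DecayDataset(times=t, activity=curve)


@dataclass
class ResponseModel:
    """Forward model for variant responses: additive log2 weights, optional
    pairwise epistasis, multiplicative lognormal noise."""

    weights: dict[MutationSpec, float]
    parent_value: float = 2.4
    epistasis: dict[frozenset, float] = field(default_factory=dict)
    sigma: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.parent_value <= 0:
            raise GenerationError("parent value must be positive")
        if self.sigma < 0:
            raise GenerationError("sigma must be non-negative")


def gen_variant_table(
    design: IncidenceDesign,
    rm: ResponseModel,
    background: tuple[MutationSpec, ...] = (),
    response_field: str = "half_life_min",
    id_prefix: str = "V",
) -> list[VariantRecord]:
    """Variant records from a design matrix and a known response model.

    Each variant's response is ``parent * 2**(sum of weights + applicable pair
    terms)`` times a lognormal noise factor ``exp(sigma * z)``.  Background
    substitutions are appended to every variant's mutation list.
    """
    missing = [m for m in design.candidates if m not in rm.weights]
    if missing:
        raise GenerationError(
            "no weight for substitutions: " + ", ".join(str(m) for m in missing)
        )
    rng = np.random.default_rng(rm.rng_seed)
    records = []
    for i in range(design.matrix.shape[0]):
        subs = design.variant_mutations(i)
        log2 = sum(rm.weights[m] for m in subs)
        for pair, w in rm.epistasis.items():
            if pair <= set(subs):
                log2 += w
        value = rm.parent_value * 2.0**log2
        if rm.sigma > 0:
            value *= math.exp(rm.sigma * rng.standard_normal())
        mutations = tuple(sorted(subs + tuple(background), key=lambda m: m.position))
        records.append(
            VariantRecord(
                variant_id=f"{id_prefix}{i + 1}",
                mutations=mutations,
                responses={response_field: float(value)},
                group="synthetic",
            )
        )
    return records
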