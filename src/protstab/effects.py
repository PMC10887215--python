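"""Per-substitution effect estimation from a combinatorial variant library.

Responses (half-lives or activities) are expressed as log2 ratios to the
parental background variant, which makes substitution effects additive and
anchors the parent at zero.  Two estimators are provided:

* marginal means — the average log2 response over the variants containing a
  substitution; simple, assumption-light, used for ranking;
* a ridge-penalized linear model of the incidence matrix with no intercept,
  its penalty chosen by leave-one-out cross-validation over a fixed
  log-spaced grid.  Ridge handles more substitutions than variants (the
  first-generation library has 14 substitutions in 11 variants).  Optional
  pairwise epistasis terms are added for substitution pairs co-occurring in
  at least two variants.

Predictions for new combination variants sum the fitted weights (plus any
applicable pair terms) and map back to the original scale through the parent
value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .mutations import MutationSpec
from .variants import VariantRecord, records_by_id

DEFAULT_PENALTY_GRID: tuple[float, ...] = tuple(2.0**p for p in range(-10, 11))


class EffectModelError(ValueError):
    pass


@dataclass
class EffectDataset:
    """Incidence matrix over non-background substitutions with log2 responses."""

    substitutions: tuple[MutationSpec, ...]
    matrix: np.ndarray  # (n_variants, n_substitutions) binary
    responses: np.ndarray  # log2(value / parent_value)
    variant_ids: tuple[str, ...]
    parent_id: str
    parent_value: float
    excluded: list[tuple[str, str]] = field(default_factory=list)


def build_effect_dataset(
    variants: Sequence[VariantRecord],
    parent_id: str,
    response_field: str = "half_life_min",
) -> EffectDataset:
    """Assemble the incidence/response dataset relative to a parent variant.

    The parent's mutations form the fixed background and are excluded from the
    incidence columns.  Variants lacking a positive numeric response (ND,
    missing, or <= 0) are excluded with a logged reason; so is any variant not
    carrying the full background.
    """
    by_id = records_by_id(variants)
    if parent_id not in by_id:
        raise EffectModelError(f"parent {parent_id!r} not among the variants")
    parent = by_id[parent_id]
    pv = parent.responses.get(response_field)
    if not isinstance(pv, float) or pv <= 0:
        raise EffectModelError(
            f"parent {parent_id!r} needs a positive numeric {response_field!r}"
        )
    background = set(parent.mutations)

    kept: list[VariantRecord] = []
    excluded: list[tuple[str, str]] = []
    values: list[float] = []
    for rec in variants:
        if rec.variant_id == parent_id:
            continue
        val = rec.responses.get(response_field)
        if not isinstance(val, float):
            excluded.append((rec.variant_id, f"no numeric {response_field}"))
            continue
        if val <= 0:
            excluded.append((rec.variant_id, f"non-positive {response_field}"))
            continue
        if not background <= set(rec.mutations):
            excluded.append((rec.variant_id, "missing background substitution"))
            continue
        kept.append(rec)
        values.append(val)
    if len(kept) < 2:
        raise EffectModelError("need at least 2 usable variants besides the parent")
    for vid, reason in excluded:
        warnings.warn(f"excluded {vid}: {reason}", stacklevel=2)

    subs: list[MutationSpec] = []
    for rec in kept:
        for m in rec.mutations:
            if m not in background and m not in subs:
                subs.append(m)
    subs.sort(key=lambda m: (m.position, m.new_residue))
    matrix = np.zeros((len(kept), len(subs)), dtype=float)
    col = {m: j for j, m in enumerate(subs)}
    for i, rec in enumerate(kept):
        for m in rec.mutations:
            if m not in background:
                matrix[i, col[m]] = 1.0
    responses = np.log2(np.asarray(values) / pv)
    return EffectDataset(
        substitutions=tuple(subs),
        matrix=matrix,
        responses=responses,
        variant_ids=tuple(r.variant_id for r in kept),
        parent_id=parent_id,
        parent_value=pv,
        excluded=excluded,
    )


@dataclass
class MarginalStats:
    """Average log2 response over member variants, per substitution."""

    means: dict[MutationSpec, float]
    support: dict[MutationSpec, int]

    def ranking(self) -> list[tuple[MutationSpec, float, int]]:
        """Substitutions sorted by descending marginal mean."""
        return sorted(
            ((m, self.means[m], self.support[m]) for m in self.means),
            key=lambda t: (-t[1], t[0].position, t[0].new_residue),
        )


def marginal_means(ds: EffectDataset) -> MarginalStats:
    means: dict[MutationSpec, float] = {}
    support: dict[MutationSpec, int] = {}
    for j, sub in enumerate(ds.substitutions):
        members = ds.matrix[:, j] > 0
        support[sub] = int(members.sum())
        means[sub] = float(ds.responses[members].mean()) if support[sub] else math.nan
    return MarginalStats(means=means, support=support)


@dataclass
class EffectModel:
    """Ridge-estimated per-substitution weights on the log2 response scale."""

    weights: dict[MutationSpec, float]
    penalty: float
    cv_error: float | None
    parent_value: float
    pair_weights: dict[frozenset[MutationSpec], float] = field(default_factory=dict)
    cv_grid: dict[float, float] = field(default_factory=dict)


def _ridge_solve(x: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    p = x.shape[1]
    if penalty == 0:
        w, *_ = np.linalg.lstsq(x, y, rcond=None)
        return w
    return np.linalg.solve(x.T @ x + penalty * np.eye(p), x.T @ y)


def _loocv_error(x: np.ndarray, y: np.ndarray, penalty: float) -> float:
    n = x.shape[0]
    errs = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        w = _ridge_solve(x[mask], y[mask], penalty)
        errs[i] = (x[i] @ w - y[i]) ** 2
    return float(errs.mean())


def epistasis_pairs(
    ds: EffectDataset, min_support: int = 2
) -> list[tuple[int, int]]:
    """Index pairs of substitutions co-occurring in at least ``min_support`` variants."""
    co = ds.matrix.T @ ds.matrix
    return [
        (i, j)
        for i, j in combinations(range(len(ds.substitutions)), 2)
        if co[i, j] >= min_support
    ]


def fit_effect_model(
    ds: EffectDataset,
    epistasis: bool = False,
    penalty: float | None = None,
    penalty_grid: Iterable[float] = DEFAULT_PENALTY_GRID,
) -> EffectModel:
    """Ridge regression of log2 responses on the incidence matrix, no intercept.

    ``penalty=None`` selects the penalty by leave-one-out cross-validation over
    the grid (ties to the smaller penalty).  A fixed ``penalty`` (including 0,
    which falls back to minimum-norm least squares) bypasses the search.
    """
    if ds.matrix.size == 0:
        raise EffectModelError("empty effect dataset")
    x = ds.matrix.copy()
    pairs: list[tuple[int, int]] = []
    if epistasis:
        pairs = epistasis_pairs(ds)
        if pairs:
            extra = np.column_stack([x[:, i] * x[:, j] for i, j in pairs])
            x = np.hstack([x, extra])
    y = ds.responses

    cv_grid: dict[float, float] = {}
    cv_error: float | None = None
    if penalty is None:
        grid = sorted(penalty_grid)
        for lam in grid:
            cv_grid[lam] = _loocv_error(x, y, lam)
        finite = {lam: e for lam, e in cv_grid.items() if math.isfinite(e)}
        if not finite:
            raise EffectModelError("no finite LOOCV error on the penalty grid")
        penalty = min(finite, key=lambda lam: (finite[lam], lam))
        cv_error = finite[penalty]

    w = _ridge_solve(x, y, penalty)
    n_subs = len(ds.substitutions)
    weights = {m: float(w[j]) for j, m in enumerate(ds.substitutions)}
    pair_weights = {
        frozenset((ds.substitutions[i], ds.substitutions[j])): float(w[n_subs + k])
        for k, (i, j) in enumerate(pairs)
    }
    return EffectModel(
        weights=weights,
        penalty=float(penalty),
        cv_error=cv_error,
        parent_value=ds.parent_value,
        pair_weights=pair_weights,
        cv_grid=cv_grid,
    )


def predict_variant(
    model: EffectModel,
    mutations: Iterable[MutationSpec],
    parent_value: float | None = None,
) -> float:
    """Predicted response on the original scale for a combination variant.

    The log2 prediction is the sum of the weights of the (non-background)
    mutations plus any applicable pair terms; the original-scale value is
    ``parent_value * 2**prediction``.  An empty mutation set predicts the
    parent value itself.
    """
    muts = list(mutations)
    unknown = [m for m in muts if m not in model.weights]
    if unknown:
        raise EffectModelError(
            "unknown substitutions: " + ", ".join(str(m) for m in unknown)
        )
    log2_pred = sum(model.weights[m] for m in muts)
    for pair, w in model.pair_weights.items():
        if pair <= set(muts):
            log2_pred += w
    base = model.parent_value if parent_value is None else parent_value
    return base * 2.0**log2_pred
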