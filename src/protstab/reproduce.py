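"""End-to-end reproduction of the packaged-table analyses.

``run_reproduction`` parses the packaged fixture tables, computes the library
census, half-life ratios, marginal-mean substitution ranking, the ridge effect
model, and the single-substitution prediction check, and returns a
JSON-serializable report.  Identical configuration yields a byte-identical
JSON report: every stage is deterministic and all seeds are embedded.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields

from .design import incidence_from_variants, validate_design, DesignSpec
from .effects import (
    build_effect_dataset,
    fit_effect_model,
    marginal_means,
    predict_variant,
)
from .mutations import MutationSpec, parse_mutation
from .variants import load_half_life_table, load_rational_table, records_by_id


class ReproductionError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Stage parameters for the reproduction run; unknown keys are rejected."""

    parent_id: str = "Y109H"
    response_field: str = "half_life_min"
    epistasis: bool = False
    rng_seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ReproductionError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def library_census(half_life_records, rational_records) -> dict:
    """Structural census of the combinatorial library fixtures."""
    by_group: dict[str, list] = {}
    for r in half_life_records:
        by_group.setdefault(r.group or "", []).append(r)
    gen1 = by_group.get("gen1", [])
    gen2 = by_group.get("gen2", [])
    background = parse_mutation("Y109H")

    def non_bg(rec):
        return [m for m in rec.mutations if m != background]

    positions = sorted({m.position for rec in gen1 + gen2 for m in non_bg(rec)})
    gen1_subs = {m for rec in gen1 for m in non_bg(rec)}
    gen2_only = sorted(
        {str(m) for rec in gen2 for m in non_bg(rec) if m not in gen1_subs}
    )
    warnings = []
    if gen2_only:
        warnings.append(
            "second-generation substitutions never seen in the first generation "
            f"(check against the designed candidate set): {gen2_only}"
        )
    design = incidence_from_variants(gen1, background=(background,))
    spec = DesignSpec(
        candidates=design.candidates,
        n_variants=len(gen1),
        subs_per_variant=int(design.row_sums[0]) if len(gen1) else 1,
    )
    diag = validate_design(design, spec)
    doubles = [r for r in rational_records if len(r.mutations) == 2]
    return {
        "designed_variants": len(gen1) + len(gen2),
        "first_generation_variants": len(gen1),
        "second_generation_variants": len(gen2),
        "mutated_positions": positions,
        "n_mutated_positions": len(positions),
        "first_gen_substitutions_per_variant": sorted(
            {len(non_bg(rec)) for rec in gen1}
        ),
        "second_gen_min_substitutions": min(
            (len(non_bg(rec)) for rec in gen2), default=0
        ),
        "rational_double_mutants": len(doubles),
        "design_occupancy": diag.occupancy,
        "design_row_sums": diag.row_sums,
        "design_violations": diag.violations,
        "warnings": warnings,
    }


def run_reproduction(config: RunConfig | None = None) -> dict:
    """Full fixture-driven analysis; returns a JSON-serializable report."""
    config = config or RunConfig()
    t0 = time.perf_counter()
    hl = load_half_life_table()
    rational = load_rational_table()
    by_id = records_by_id(hl)
    for needed in (config.parent_id, "V6", "V401"):
        if needed not in by_id:
            raise ReproductionError(f"fixture variant {needed!r} missing")

    census = library_census(hl, rational)

    parent_t = by_id[config.parent_id].responses[config.response_field]
    v401_t = by_id["V401"].responses[config.response_field]
    v6_t = by_id["V6"].responses[config.response_field]
    numeric = [
        v
        for r in hl
        if isinstance((v := r.responses.get(config.response_field)), float)
    ]
    ratios = {
        "v401_vs_parent_fold": v401_t / parent_t,
        "v401_vs_v6_fraction": v401_t / v6_t,
        "max_half_life_min": max(numeric),
    }

    gen1 = [r for r in hl if r.group == "gen1"] + [by_id[config.parent_id]]
    ds = build_effect_dataset(gen1, config.parent_id, config.response_field)
    stats = marginal_means(ds)
    ranking = [
        {"substitution": str(m), "marginal_mean_log2": mean, "support": sup}
        for m, mean, sup in stats.ranking()
    ]
    model = fit_effect_model(ds, epistasis=config.epistasis)
    q85r = parse_mutation("Q85R")
    predicted = predict_variant(model, [q85r])

    report = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seeds": {"rng_seed": config.rng_seed},
        "census": census,
        "half_life_ratios": ratios,
        "marginal_ranking": ranking,
        "top_substitution": ranking[0]["substitution"],
        "effect_model": {
            "penalty": model.penalty,
            "cv_error": model.cv_error,
            "weights": {str(m): w for m, w in sorted(
                model.weights.items(), key=lambda kv: (kv[0].position, kv[0].new_residue)
            )},
        },
        "q85r_weight": model.weights[q85r],
        "q85r_predicted_half_life_min": predicted,
        "q85r_prediction_exceeds_parent": predicted > ds.parent_value,
        "v401_measured_half_life_min": v401_t,
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return report


def render_summary(report: dict) -> str:
    """Short human-readable rendering of a reproduction report."""
    c = report["census"]
    r = report["half_life_ratios"]
    lines = [
        f"config {report['config_hash']}",
        f"library: {c['designed_variants']} designed variants "
        f"({c['first_generation_variants']} first-gen + "
        f"{c['second_generation_variants']} second-gen) across "
        f"{c['n_mutated_positions']} positions; "
        f"{c['rational_double_mutants']} rational double mutants",
        f"half-lives: V401/parent = {r['v401_vs_parent_fold']:.2f}-fold, "
        f"V401/V6 = {100 * r['v401_vs_v6_fraction']:.0f}%, "
        f"max = {r['max_half_life_min']:.1f} min",
        f"top substitution by marginal mean: {report['top_substitution']} "
        f"({report['marginal_ranking'][0]['marginal_mean_log2']:.3f} log2)",
        f"Q85R ridge weight {report['q85r_weight']:+.3f}; predicted half-life "
        f"{report['q85r_predicted_half_life_min']:.1f} min vs measured V401 "
        f"{report['v401_measured_half_life_min']:.1f} min",
    ]
    for w in c["warnings"]:
        lines.append(f"warning: {w}")
    return "\n".join(lines)


def report_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, full precision)."""
    stable = {k: v for k, v in report.items() if k != "elapsed_s"}
    return json.dumps(stable, sort_keys=True, indent=2)
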