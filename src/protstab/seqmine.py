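"""Mine candidate substitutions from a homolog alignment.

The pipeline: (1) keep homologs sharing more than a set identity with the
seed (default 0.70, strict); (2) enumerate every residue exchange observed at
a seed position; (3) score each exchange on several criteria — column
frequency, Dayhoff/PAM250 conservativeness, physicochemical proximity in a
principal-component embedding of amino-acid factors, and compensatory
covariation via column mutual information; (4) mean-center each criterion,
scale it to unit maximum absolute deviation, sum, and rank.

Scoring is sequence-only.  The number of retained candidates defaults to the
14 used to seed combinatorial library design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .alignment import GAP, AlignmentSet
from .mutations import AMINO_ACIDS

PAM250 = substitution_matrices.load("PAM250")

# Five-factor physicochemical solution per amino acid (polarity/accessibility,
# secondary-structure propensity, size, codon composition, charge).
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

CRITERIA = ("frequency", "dayhoff", "pc_cluster", "covariation")


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringConfig:
    identity_threshold: float = 0.70
    top_n: int = 14
    criteria: tuple[str, ...] = CRITERIA
    covariation_partners: int = 3
    pc_components: int = 2
    # "normalized to 1" reading: unit maximum absolute deviation (default)
    # or unit variance.
    normalization: str = "max_abs"

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ScoringError("at least one scoring criterion required")
        unknown = set(self.criteria) - set(CRITERIA)
        if unknown:
            raise ScoringError(f"unknown criteria: {sorted(unknown)}")
        if self.top_n < 1:
            raise ScoringError("top_n must be >= 1")
        if self.covariation_partners < 1 or self.pc_components < 1:
            raise ScoringError("covariation_partners and pc_components must be >= 1")
        if self.normalization not in ("max_abs", "variance"):
            raise ScoringError(f"unknown normalization {self.normalization!r}")


@dataclass
class SubstitutionCandidate:
    """A mined residue exchange with per-criterion scores and overall rank."""

    position: int
    from_residue: str
    to_residue: str
    count: int
    criterion_scores: dict[str, float] = field(default_factory=dict)
    aggregate: float = float("nan")
    rank: int | None = None

    def __str__(self) -> str:
        return f"{self.from_residue}{self.position}{self.to_residue}"


def _pc_embedding(k: int) -> dict[str, np.ndarray]:
    """First-k principal-component scores of the amino-acid factor table."""
    residues = sorted(ATCHLEY_FACTORS)
    table = np.array([ATCHLEY_FACTORS[r] for r in residues])
    centered = table - table.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    scores = centered @ vt.T[:, :k]
    return {r: scores[i] for i, r in enumerate(residues)}


def filter_by_identity(aln: AlignmentSet, threshold: float = 0.70) -> AlignmentSet:
    """Keep the seed and every sequence strictly above the identity threshold."""
    if not 0 < threshold < 1:
        raise ScoringError(f"identity threshold must lie in (0,1), got {threshold}")
    kept = [
        (sid, seq)
        for sid, seq in aln.sequences
        if sid == aln.seed_id or aln.identity_to_seed(sid) > threshold
    ]
    return AlignmentSet(seed_id=aln.seed_id, sequences=kept)


def enumerate_substitutions(aln: AlignmentSet) -> list[SubstitutionCandidate]:
    """One unscored candidate per (seed position, observed non-seed residue).

    Gaps never yield candidates; counts are occurrences of the residue in the
    alignment column across all sequences.
    """
    out: list[SubstitutionCandidate] = []
    for pos, col in aln.position_to_column().items():
        seed_res = aln.seed_gapped[col]
        counts: dict[str, int] = {}
        for ch in aln.column(col):
            if ch != GAP and ch in AMINO_ACIDS:
                counts[ch] = counts.get(ch, 0) + 1
        for res in sorted(counts):
            if res != seed_res:
                out.append(SubstitutionCandidate(pos, seed_res, res, counts[res]))
    return out


def _column_residues(aln: AlignmentSet, col: int) -> list[str]:
    return [ch for ch in aln.column(col) if ch != GAP and ch in AMINO_ACIDS]


def _joint_counts(aln: AlignmentSet, ci: int, cj: int) -> np.ndarray:
    """Add-one-smoothed 20x20 joint counts over sequences ungapped at both columns."""
    idx = {r: i for i, r in enumerate(AMINO_ACIDS)}
    joint = np.ones((20, 20))
    for _, seq in aln.sequences:
        a, b = seq[ci], seq[cj]
        if a in idx and b in idx:
            joint[idx[a], idx[b]] += 1
    return joint


def column_mutual_information(aln: AlignmentSet, ci: int, cj: int) -> float:
    """Mutual information between two alignment columns (nats, smoothed)."""
    joint = _joint_counts(aln, ci, cj)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def _consensus(aln: AlignmentSet, col: int) -> str | None:
    """Most frequent non-gap residue in a column; ties to the alphabetically first."""
    counts: dict[str, int] = {}
    for ch in _column_residues(aln, col):
        counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return None
    return max(sorted(counts), key=counts.get)


def _covariation_score(
    aln: AlignmentSet, col: int, to_res: str, n_partners: int
) -> float | None:
    others = [c for c in range(aln.column_count) if c != col and _column_residues(aln, c)]
    if not others:
        return None
    mi = {c: column_mutual_information(aln, col, c) for c in others}
    partners = sorted(others, key=lambda c: (-mi[c], c))[:n_partners]
    idx = {r: i for i, r in enumerate(AMINO_ACIDS)}
    pmis = []
    for c in partners:
        cons = _consensus(aln, c)
        if cons is None:
            continue
        joint = _joint_counts(aln, col, c)
        p = joint / joint.sum()
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        i, j = idx[to_res], idx[cons]
        pmis.append(math.log(p[i, j] / (px[i] * py[j])))
    return sum(pmis) / len(pmis) if pmis else None


def _normalize(raw: np.ndarray, mode: str) -> np.ndarray:
    centered = raw - raw.mean()
    if mode == "max_abs":
        scale = np.abs(centered).max()
    else:
        scale = centered.std()
    if scale == 0:
        return centered
    return centered / scale


def score_candidates(
    cands: list[SubstitutionCandidate],
    aln: AlignmentSet,
    config: ScoringConfig = ScoringConfig(),
) -> list[SubstitutionCandidate]:
    """Score, normalize, aggregate and rank candidates in place; returns them sorted.

    Each enabled criterion yields one raw score per candidate; each criterion
    vector is mean-centered and scaled to unit maximum absolute deviation
    (all-equal vectors stay at zero), and the aggregate is the unweighted sum.
    Rank is by descending aggregate; ties break to higher frequency, then
    lower position, then residue alphabetically.
    """
    if not cands:
        return []
    pos2col = aln.position_to_column()
    pc = _pc_embedding(config.pc_components)
    criteria = list(config.criteria)

    raw: dict[str, list[float]] = {}
    if "frequency" in criteria:
        raw["frequency"] = [c.count / aln.n_sequences for c in cands]
    if "dayhoff" in criteria:
        raw["dayhoff"] = [float(PAM250[c.from_residue, c.to_residue]) for c in cands]
    if "pc_cluster" in criteria:
        raw["pc_cluster"] = [
            -float(np.linalg.norm(pc[c.to_residue] - pc[c.from_residue])) for c in cands
        ]
    if "covariation" in criteria:
        cov = [
            _covariation_score(aln, pos2col[c.position], c.to_residue, config.covariation_partners)
            for c in cands
        ]
        if any(v is None for v in cov):
            warnings.warn(
                "covariation criterion skipped: no partner columns available",
                stacklevel=2,
            )
        else:
            raw["covariation"] = [float(v) for v in cov]

    names = [k for k in criteria if k in raw]
    normalized = {k: _normalize(np.asarray(raw[k], dtype=float), config.normalization) for k in names}
    for i, c in enumerate(cands):
        c.criterion_scores = {k: float(raw[k][i]) for k in names}
        c.aggregate = float(sum(normalized[k][i] for k in names))

    order = sorted(
        cands,
        key=lambda c: (-c.aggregate, -c.count / aln.n_sequences, c.position, c.to_residue),
    )
    for r, c in enumerate(order, start=1):
        c.rank = r
    return order


def select_top(cands: list[SubstitutionCandidate], top_n: int = 14) -> list[SubstitutionCandidate]:
    """First ``top_n`` candidates by rank; all of them (with a warning) if fewer exist."""
    ranked = sorted(cands, key=lambda c: c.rank if c.rank is not None else 1 << 30)
    if len(ranked) < top_n:
        warnings.warn(
            f"only {len(ranked)} candidates available, fewer than requested {top_n}",
            stacklevel=2,
        )
        return ranked
    return ranked[:top_n]


def mine(
    aln: AlignmentSet, config: ScoringConfig = ScoringConfig()
) -> list[SubstitutionCandidate]:
    """Full mining pipeline: identity filter, enumerate, score, select top-n."""
    filtered = filter_by_identity(aln, config.identity_threshold)
    cands = enumerate_substitutions(filtered)
    ranked = score_candidates(cands, filtered, config)
    return select_top(ranked, config.top_n)
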