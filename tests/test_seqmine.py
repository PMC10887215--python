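"""Mining and scoring tests, including an independent brute-force oracle.

The oracle recomputes every criterion with plain Python loops (and an
eigendecomposition-based PC embedding instead of the package's SVD route) and
must agree with the pipeline exactly on small alignments.
"""

import math
import warnings

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from protstab.alignment import AlignmentSet
from protstab.seqmine import (
    ATCHLEY_FACTORS,
    ScoringConfig,
    ScoringError,
    _normalize,
    enumerate_substitutions,
    filter_by_identity,
    score_candidates,
    select_top,
)
from protstab.simulate import AlignmentModel, gen_alignment

AA = "ACDEFGHIKLMNPQRSTVWY"
_PAM250 = substitution_matrices.load("PAM250")


# ---------------------------------------------------------------------------
# brute-force oracle


def _oracle_pc_scores(k):
    residues = sorted(ATCHLEY_FACTORS)
    table = np.array([ATCHLEY_FACTORS[r] for r in residues])
    centered = table - table.mean(axis=0)
    cov = centered.T @ centered / 1.0
    evals, evecs = np.linalg.eigh(cov)
    top = evecs[:, np.argsort(evals)[::-1][:k]]
    proj = centered @ top
    return {r: proj[i] for i, r in enumerate(residues)}


def _oracle_joint(aln, ci, cj):
    joint = {(a, b): 1.0 for a in AA for b in AA}
    for _, seq in aln.sequences:
        a, b = seq[ci], seq[cj]
        if a in AA and b in AA:
            joint[(a, b)] += 1
    total = sum(joint.values())
    return {k: v / total for k, v in joint.items()}


def _oracle_mi(aln, ci, cj):
    p = _oracle_joint(aln, ci, cj)
    px = {a: sum(p[(a, b)] for b in AA) for a in AA}
    py = {b: sum(p[(a, b)] for a in AA) for b in AA}
    return sum(
        p[(a, b)] * math.log(p[(a, b)] / (px[a] * py[b])) for a in AA for b in AA
    )


def _oracle_consensus(aln, col):
    counts = {}
    for _, seq in aln.sequences:
        ch = seq[col]
        if ch in AA:
            counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return None
    best = sorted(counts)
    return max(best, key=lambda r: counts[r])


def brute_force_scores(aln, config):
    """Independent recomputation of raw criterion scores, aggregates, ranks."""
    p2c = aln.position_to_column()
    pc = _oracle_pc_scores(config.pc_components)
    n = aln.n_sequences
    cands = []
    for pos, col in p2c.items():
        seed_res = aln.seed_gapped[col]
        counts = {}
        for _, seq in aln.sequences:
            ch = seq[col]
            if ch in AA:
                counts[ch] = counts.get(ch, 0) + 1
        for res in sorted(counts):
            if res != seed_res:
                cands.append((pos, seed_res, res, counts[res]))

    raw = {}
    raw["frequency"] = [cnt / n for _, _, _, cnt in cands]
    raw["dayhoff"] = [float(_PAM250[f, t]) for _, f, t, _ in cands]
    raw["pc_cluster"] = [
        -math.dist(pc[t], pc[f]) for _, f, t, _ in cands
    ]
    cov_scores = []
    for pos, _, to, _ in cands:
        col = p2c[pos]
        others = [
            c
            for c in range(aln.column_count)
            if c != col and any(seq[c] in AA for _, seq in aln.sequences)
        ]
        mis = sorted(others, key=lambda c: (-_oracle_mi(aln, col, c), c))
        partners = mis[: config.covariation_partners]
        pmis = []
        for c in partners:
            cons = _oracle_consensus(aln, c)
            p = _oracle_joint(aln, col, c)
            px = sum(p[(to, b)] for b in AA)
            py = sum(p[(a, cons)] for a in AA)
            pmis.append(math.log(p[(to, cons)] / (px * py)))
        cov_scores.append(sum(pmis) / len(pmis) if pmis else None)
    if all(v is not None for v in cov_scores):
        raw["covariation"] = cov_scores

    names = [k for k in config.criteria if k in raw]
    normed = {}
    for k in names:
        v = np.array(raw[k], dtype=float)
        v = v - v.mean()
        m = np.abs(v).max()
        normed[k] = v / m if m > 0 else v
    agg = [sum(normed[k][i] for k in names) for i in range(len(cands))]
    order = sorted(
        range(len(cands)),
        key=lambda i: (-agg[i], -raw["frequency"][i], cands[i][0], cands[i][2]),
    )
    ranks = {}
    for r, i in enumerate(order, start=1):
        ranks[cands[i]] = r
    return cands, raw, agg, ranks


# ---------------------------------------------------------------------------
# identity filtering


class TestIdentityFilter:
    def test_identical_copy_always_retained(self):
        aln = AlignmentSet("s", [("s", "MQAKDLFG"), ("h", "MQAKDLFG")])
        assert filter_by_identity(aln, 0.99).n_sequences == 2

    def test_boundary_is_strict(self):
        aln = AlignmentSet(
            "s", [("s", "AAAAAAAAAA"), ("h", "AAAAAAACCC")]  # 7/10 matches
        )
        assert aln.identity_to_seed("h") == pytest.approx(0.70)
        filtered = filter_by_identity(aln, 0.70)
        assert [i for i, _ in filtered.sequences] == ["s"]

    def test_generated_identity_ladder(self):
        model = AlignmentModel(
            seed="MQAKDLFGHTWYNPCVESRI" * 5,
            target_identities=[0.65, 0.75, 0.90],
            rng_seed=3,
        )
        aln = gen_alignment(model)
        filtered = filter_by_identity(aln, 0.70)
        assert filtered.n_sequences == 3  # seed + the 0.75 and 0.90 homologs
        kept = {i for i, _ in filtered.sequences} - {"seed"}
        assert all(aln.identity_to_seed(i) > 0.70 for i in kept)

    def test_threshold_domain(self, toy_alignment):
        with pytest.raises(ScoringError):
            filter_by_identity(toy_alignment, 1.5)


# ---------------------------------------------------------------------------
# candidate enumeration


class TestEnumeration:
    def test_observed_exchanges_with_counts(self):
        # column pattern Q:36, R:60, K:4 over 100 homologs, seed Q
        seqs = [("seed", "MQA")]
        for i in range(35):
            seqs.append((f"q{i}", "MQA"))
        for i in range(60):
            seqs.append((f"r{i}", "MRA"))
        for i in range(4):
            seqs.append((f"k{i}", "MKA"))
        aln = AlignmentSet("seed", seqs)
        cands = {str(c): c.count for c in enumerate_substitutions(aln)}
        assert cands == {"Q2R": 60, "Q2K": 4}

    def test_conserved_column_yields_nothing(self):
        aln = AlignmentSet("s", [("s", "MM"), ("h", "MM")])
        assert enumerate_substitutions(aln) == []

    def test_gaps_never_produce_candidates(self):
        aln = AlignmentSet("s", [("s", "MA"), ("h", "M-"), ("g", "M-")])
        assert enumerate_substitutions(aln) == []

    def test_counts_partition_the_column(self, toy_alignment):
        # per column: candidate counts sum to n - seed-residue count - gaps
        for pos, col in toy_alignment.position_to_column().items():
            column = toy_alignment.column(col)
            seed_res = toy_alignment.seed_gapped[col]
            cands = [
                c for c in enumerate_substitutions(toy_alignment) if c.position == pos
            ]
            expected = (
                len(column) - column.count(seed_res) - column.count("-")
            )
            assert sum(c.count for c in cands) == expected


# ---------------------------------------------------------------------------
# scoring


class TestScoring:
    def test_two_candidates_single_criterion(self):
        seqs = [("seed", "MQ")] + [(f"r{i}", "MR") for i in range(3)] + [("k0", "MK")]
        aln = AlignmentSet("seed", seqs)
        cands = enumerate_substitutions(aln)
        ranked = score_candidates(
            cands, aln, ScoringConfig(criteria=("frequency",))
        )
        assert [str(c) for c in ranked] == ["Q2R", "Q2K"]
        assert ranked[0].aggregate == pytest.approx(1.0)
        assert ranked[1].aggregate == pytest.approx(-1.0)
        assert [c.rank for c in ranked] == [1, 2]

    def test_all_equal_scores_fall_back_to_tiebreak(self):
        # two exchanges with identical frequency: rank by position
        aln = AlignmentSet(
            "seed", [("seed", "QQ"), ("a", "RQ"), ("b", "QR")]
        )
        ranked = score_candidates(
            enumerate_substitutions(aln), aln, ScoringConfig(criteria=("frequency",))
        )
        assert all(c.aggregate == 0.0 for c in ranked)
        assert [str(c) for c in ranked] == ["Q1R", "Q2R"]

    def test_mean_centering_and_unit_max(self, toy_alignment):
        cands = enumerate_substitutions(toy_alignment)
        score_candidates(cands, toy_alignment)
        for crit in cands[0].criterion_scores:
            raw = np.array([c.criterion_scores[crit] for c in cands])
            centered = raw - raw.mean()
            assert abs(centered.mean()) < 1e-9
            scale = np.abs(centered).max()
            if scale > 0:
                assert np.abs(centered / scale).max() <= 1 + 1e-12

    def test_dominant_substitution_wins(self):
        # Y->F dominates every criterion against Y->H: higher frequency,
        # more conservative PAM250 exchange, nearer in factor space
        seqs = [("seed", "MYAKDLFG")]
        for i in range(8):
            seqs.append((f"f{i}", "MFAKELFG"))
        seqs.append(("h0", "MHAKDLFG"))
        aln = AlignmentSet("seed", seqs)
        ranked = score_candidates(enumerate_substitutions(aln), aln)
        by_name = {str(c): c for c in ranked}
        assert by_name["Y2F"].rank < by_name["Y2H"].rank
        assert str(ranked[0]) == "Y2F"

    def test_oracle_equivalence_toy(self, toy_alignment):
        self._check_oracle(toy_alignment)

    def test_oracle_equivalence_generated(self):
        model = AlignmentModel(
            seed="MQAKDLFGHT",
            n_sequences=9,
            profiles={
                1: {"Q": 0.4, "R": 0.4, "K": 0.2},
                4: {"D": 0.5, "E": 0.5},
                7: {"G": 0.6, "A": 0.3, "S": 0.1},
            },
            couplings=[(1, 4, 0.9)],
            rng_seed=17,
        )
        self._check_oracle(gen_alignment(model))

    @staticmethod
    def _check_oracle(aln):
        config = ScoringConfig()
        cands = enumerate_substitutions(aln)
        ranked = score_candidates(list(cands), aln, config)
        o_cands, o_raw, o_agg, o_ranks = brute_force_scores(aln, config)
        lookup = {
            (c[0], c[1], c[2]): i for i, c in enumerate(o_cands)
        }
        assert len(ranked) == len(o_cands)
        for c in ranked:
            i = lookup[(c.position, c.from_residue, c.to_residue)]
            assert c.count == o_cands[i][3]
            for crit, val in c.criterion_scores.items():
                assert val == pytest.approx(o_raw[crit][i], abs=1e-9)
            assert c.aggregate == pytest.approx(o_agg[i], abs=1e-9)
            assert c.rank == o_ranks[o_cands[i]]

    def test_single_column_alignment_skips_covariation(self):
        aln = AlignmentSet("s", [("s", "Q"), ("a", "R"), ("b", "R")])
        cands = enumerate_substitutions(aln)
        with pytest.warns(UserWarning, match="covariation"):
            ranked = score_candidates(cands, aln)
        assert "covariation" not in ranked[0].criterion_scores
        assert ranked[0].rank == 1

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=2, max_size=10
        ),
        st.floats(0.01, 1000),
    )
    def test_normalization_invariant_under_positive_rescaling(self, values, scale):
        """Rescaling a raw criterion by any positive factor leaves the
        normalized vector (hence the aggregate ranking) unchanged."""
        v = np.array(values)
        a = _normalize(v, "max_abs")
        b = _normalize(scale * v, "max_abs")
        assert np.allclose(a, b, atol=1e-9)
        assert abs(a.sum()) < 1e-7  # mean-centered vectors sum to zero


class TestSelectTop:
    def _ranked(self, n):
        seqs = [("seed", "Q" * n)]
        for i in range(4):
            seqs.append((f"h{i}", "".join("RKHE"[i] for _ in range(n))))
        aln = AlignmentSet("seed", seqs)
        return score_candidates(enumerate_substitutions(aln), aln)

    def test_top_14_of_20(self):
        ranked = self._ranked(5)  # 4 exchanges per column x 5 columns
        top = select_top(ranked, 14)
        assert len(top) == 14
        assert [c.rank for c in top] == list(range(1, 15))

    def test_fewer_than_requested_warns(self):
        ranked = self._ranked(1)
        with pytest.warns(UserWarning, match="fewer"):
            top = select_top(ranked, 14)
        assert len(top) == 4

    def test_top_one(self):
        ranked = self._ranked(3)
        top = select_top(ranked, 1)
        assert len(top) == 1 and top[0].rank == 1
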