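# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical choices that matter when reading results.

## Coordinates, mutation strings, and typed responses

Substitution positions are 1-based on the ungapped seed sequence, counting
the initiator methionine as residue 1. Mutation strings follow the
`<wt><position><new>` hyphen grammar (`Q85R-C102S-…`); parsing preserves
order, rejects two substitutions at one position, and round-trips through
the formatter byte-identically. Validation against a reference sequence is
optional, because the seed protein's sequence is not always at hand.

Variant tables keep two non-numeric response types as typed values rather
than coercing them to 0: `ND` (assayed, nothing detected — distinct from a
missing cell) and ordinal `+`-scores from by-eye scoring. Numeric fits must
exclude them explicitly; the effect-model builder logs every exclusion. The
packaged half-life table carries the full published library, including the
one second-generation substitution (Q85P) that never appears in the first
generation; the census surfaces it as a warning instead of silently
correcting it.

## Substitution mining

Identity to the seed is computed over columns where both sequences have a
residue, and the filter is strictly greater than the threshold (default
0.70) so that boundary cases are reproducible. Candidate enumeration emits
one `(position, to_residue)` pair per residue observed at least once in a
column; gaps never produce candidates.

Four criteria score each candidate:

* **frequency** — column count of the new residue divided by the number of
  retained sequences;
* **dayhoff** — the symmetric PAM250 log-odds entry for the exchange
  (higher = more conservative), taken from Biopython's matrix collection;
* **pc_cluster** — negative Euclidean distance between the two residues in
  the first *k* = 2 principal components of the five-factor physicochemical
  solution (polarity/accessibility, secondary-structure propensity, size,
  codon composition, charge), embedded as a constant and decomposed once;
* **covariation** — for the candidate's column, the *m* = 3 partner columns
  with highest mutual information are found (add-one smoothing over the
  20×20 joint, gaps excluded from marginals), and the score is the mean
  pointwise mutual information between the candidate residue and each
  partner's consensus residue. Compensatory pairs score high because the
  proposed residue co-occurs with the family's consensus context.

"Normalized" scoring means: mean-center each criterion vector across
candidates, divide by its maximum absolute deviation (left at zero when all
values are equal), and sum without weights. This makes the aggregate — and
therefore the ranking — invariant under any positive rescaling of a raw
criterion, which is property-tested. Unit variance is available as an
alternative normalization through `ScoringConfig(normalization="variance")`.
Ties rank by higher frequency, then lower position, then residue
alphabetically. Scoring is sequence-only; no structural term is included.
With a single informative column the covariation criterion is skipped with
a warning rather than fabricated.

## Library design

The design engine fills a V×N binary incidence matrix in two phases. The
greedy phase repeatedly places the currently least-used substitution into
the feasible variant where it least increases the squared co-occurrence
objective, which yields near-balanced occupancy by construction; a repair
pass then evens occupancy further. The swap phase proposes random pairwise
exchanges between two variants and accepts only strict improvements of
`Σ_{i<j} c_ij²`, where `c_ij` counts variants carrying both substitutions —
a monotone, seed-reproducible descent that matches exhaustive search on
small instances (verified for 6 substitutions × 3 variants).

Position exclusivity (two alternatives at one residue never share a
variant) is a hard constraint throughout, reflecting how alternative
residues at positions 40, 85 and 200 are distributed in the measured
library. One caveat is inherent: when a position carries several
alternatives and the slot arithmetic is tight, exclusivity can force an
occupancy spread greater than one; the engine then returns the best
achievable balance (never leaving a substitution unused) instead of
failing. With all-distinct positions the ≤1 spread is guaranteed and
property-tested. The parental background substitution is not a design
column; it is appended to every variant downstream.

The reference shape — 14 substitutions into 11 variants of 4 — lands at
44 memberships with twelve substitutions used 3× and two used 4×, the same
occupancy pattern as the measured library.

## Kinetics

Calibration is an ordinary least-squares line over the observed
concentration span; a non-positive slope flags the curve unusable. Initial
rates subtract the matched no-enzyme series pointwise, then take the slope
of the longest initial prefix (≥3 points) whose linear fit reaches
r² ≥ 0.98, shrinking from the full series; if none qualifies the first
three points are used with a low-confidence flag. The prefix rule is a
pragmatic reading of "the initial linear part": on strongly curved progress
data sampled coarsely (e.g. an exponential approach sampled every 3.5 min)
any secant underestimates the true tangent rate, so estimates carry a
downward bias of up to ~30% there — acceptable because downstream use is
ratio-based (fold activity versus a reference measured the same way).
Fold activities at or below the detection floor are reported as `ND`,
never 0.

Thermal inactivation is fitted by `scipy` nonlinear least squares under
first-order decay `A = A0·e^(−kt)` or second-order decay
`A = A0/(1 + A0·k·t)` (the dimer-inactivation form `dA/dt = −kA²`), with
positivity bounds and starting values from the log-linear and
reciprocal-linear transforms respectively. `A0` is fitted, not pinned to
the t = 0 reading, to tolerate noise in the first sample. Order selection
compares AICc (n = 8 sampling points makes the small-sample correction
matter); a fit whose effective decline over the sampled window is below
0.1% is rejected as a boundary solution rather than reported. Half-lives
come either from the closed forms (`ln2/k`, `1/(kA0)`; both satisfy
`A(t½) = A0/2` exactly) or by log-linear interpolation between the
bracketing samples; a series that never reaches 50% of its initial value
returns an explicit out-of-range marker.

## Effect model

Responses are log2 ratios to the parent variant, which makes substitution
effects additive, puts the parent at zero, and turns a weight of +1 into
"doubles the half-life". The model is ridge regression of the response on
the incidence matrix with no intercept; the penalty is chosen by
leave-one-out cross-validation over the fixed grid `2^-10 … 2^10` (ties to
the smaller penalty, fully deterministic). Ridge is needed because the
reference problem has p = 14 substitutions and n = 11 variants: the
least-squares solution is not unique, and with any information-sparing
estimator the individual weights are shrunk toward zero. Interpretation
therefore leans on signs and ranks, not magnitudes; the marginal-mean
estimator (average response over member variants) is reported alongside as
an assumption-light cross-check. Optional pairwise epistasis terms are
added only for pairs co-occurring in at least two variants, below which
they are unidentifiable. Predictions sum weights (plus applicable pair
terms) and map back through the parent value.

On the packaged first-generation table the two estimators agree on the top
substitution (Q85R, marginal mean ≈ 1.25 log2, positive ridge weight), and
the single-substitution prediction exceeds the parent — the directional
claim the measured follow-up variant supports. No published weight values
exist to compare magnitudes against.

## Synthetic data: what it does and does not emulate

* **Alignments** are sampled column-independently from specified residue
  profiles, except for coupled column pairs: with probability equal to the
  coupling strength the partner column's residue is rank-matched to the
  first column's draw. Per-sequence identity targets (exact seed-mutation
  counts) or a rejection-sampled identity band are available. This emulates
  controlled column frequencies and pairwise covariation, not phylogeny:
  there is no tree, no indel process, and no higher-order coupling, so
  passing tests say nothing about phylogenetic correlation structure in
  real homolog sets.
* **Decay curves** are the exact model curve times a lognormal factor
  `exp(σZ)` — multiplicative because activities are positive and errors
  scale with signal. σ = 0 reproduces the closed form to machine precision.
* **Variant tables** apply the forward additive model
  `t = t_parent · 2^(Σw + Σ pairs) · exp(σZ)`. The default σ grid
  {0.05, 0.1, 0.3} brackets the reported assay variability (<10%
  for the spectrophotometric assay, <30% for the chromatographic one).

Everything is deterministic per rng seed.

## Problem sizes and simulation defaults

The simulation studies use 200 replicates each: decay-order selection at 5%
multiplicative noise on the 8-point sampling grid (the selection rate
exceeds 80% comfortably), and weight recovery on freshly designed 11×14
libraries at σ = 0.1 log2 noise with three planted effects of |w| ≥ 1 per
replicate (sign recovery ≥ 90%; across-replicate mean absolute bias below
0.05 log2 — per-replicate estimates are shrunk, so bias is meaningful only
averaged over randomized truth draws). These sizes keep the full test suite
and the acceptance script in the tens of seconds while leaving the pass
margins wide.

## Known limitations

* The mined candidate set cannot be compared to the historical 14-substitution
  set, because the underlying 100-homolog alignment was never deposited;
  mining is validated against a brute-force scorer and generator ground
  truth instead.
* The design engine is a heuristic (greedy + swap descent), not a D-optimal
  solver; it is verified optimal only on exhaustively searchable instances.
* Initial-rate estimates on coarsely sampled curved data are biased low, as
  described above.
* Decay fits assume a single inactivation process; multi-step unfolding
  produces intermediate behaviour that neither model captures, and the AICc
  winner should then be read as "closer", not "true".
* With more substitutions than variants the effect model's weights are
  regularized estimates; second-generation variants can be added to the
  training set via a flag, but the default follows the first-generation-only
  protocol.
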