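# Methods

## Model and assumptions

`quorumpool` implements the simplest collective decision scenario that
exhibits two error types: a single-shot binary choice by a homogeneous
group with aligned interests.

**Cue model.** Each voter observes one scalar cue, drawn from
N(μ₋, σ²) in state "−" and N(μ₊, σ²) in state "+". Equal variances and
a single cue dimension are deliberate: the likelihood ratio is then
monotone in the cue, so the optimal decision rule is a sharp threshold
and everything downstream is closed-form. Unequal variances,
non-Gaussian cues and multi-dimensional cues are out of scope.

**Individual optimum.** With prior *p* for state "+" and outcome costs
(C_TP, C_TN, C_FP, C_FN; lower = better), deciding "+" when the
likelihood ratio exceeds β = (1 − p)(C_FP − C_TN) / [p (C_FN − C_TP)]
minimises expected cost. For the Gaussian cue model the induced
threshold is x* = (μ₊ + μ₋)/2 + σ² ln β/(μ₊ − μ₋); no root-finding is
used anywhere. The state-wise accuracies at any threshold use the
standard normal CDF/survival function (`scipy.stats.norm`, i.e. the
complementary error function); the survival function is used for upper
tails so extreme thresholds stay accurate.

Costs are minimised, not payoffs maximised; callers with payoff
matrices negate them. Validation rejects μ₊ ≤ μ₋ (relabel the states;
the library never silently inverts decisions) and "degenerate" cost
structures where an error is no worse than the correct outcome in the
same state (c_fn ≤ c_tp or c_fp ≤ c_tn), for which the threshold
formula's logarithm would be undefined or the optimum degenerate.

**Group model.** Votes are conditionally independent given the state,
with identical per-state accuracies (a₊, a₋) across voters —
heterogeneous accuracies, weighted votes, correlated voters and
sequential dynamics are out of scope. The group chooses "+" iff the
"+"-vote count strictly exceeds q·N. The strict inequality plus an
explicit tie policy (coin flip by default, counted as half the tie
probability mass in exact computation; `choose_minus` as the
deterministic alternative) makes q = ½ with odd N coincide exactly with
the textbook majority rule. Ties are only possible when q·N is an
integer; an absolute tolerance of 1e-9 decides integrality, so
fractional quorums such as q = 0.035 at N = 5001 (q·N = 175.035) never
spuriously register a tie.

## Computation routes

Three independent routes compute group accuracy, and the tests play
them against each other:

1. **Exact**: binomial tail sums (`scipy.stats.binom.sf/pmf`) per
   state. The brute-force oracle — enumeration of all 2^N vote
   vectors — agrees to 1e-12 for all N ≤ 12.
2. **Monte Carlo**: replicates draw the state, then the vote count
   directly from the state-conditional binomial. A slower cue-level
   path (`group_accuracy_sim_cues`) re-draws N Gaussian cues per
   replicate and thresholds each voter; it is equivalent in law and
   kept as a cross-check. One seeded `numpy` generator per call; the
   seed is recorded in the result.
3. **Asymptotic**: indicator formula
   p·1{a₊ > q} + (1 − p)·1{1 − a₋ < q}. When q equals a₊ or 1 − a₋
   exactly the law-of-large-numbers argument collapses and the code
   raises a boundary error rather than guessing.

The quorum interval (1 − a₋, a₊) exists only above the chance diagonal
(a₊ > 1 − a₋); below it the code raises rather than inverting decisions
for the caller. The recommended quorum is the interval midpoint — a
robust within-interval choice; per-group-size quorum optimisation is a
known refinement and an explicit non-goal. The sub/super-majority label
is derived from the interval itself (wholly below ½ / wholly above ½ /
straddling), which sidesteps any ambiguity in symbol-level conditions.

## Error taxonomy

`classify_scenario` orders its tests from most to least structural:
below-chance points first; then the error-free region (both accuracies
above ½); then, in the mixed-sign region, Error II (expected individual
accuracy a < ½), Error Ib (majority-rule limit below a) and Error Ia
(the remainder). The reported class is the most specific — Ib implies
Ia's defining conditions, and the region maps treat the "Ia" map as
Ia ∪ Ib accordingly. Equalities within 1e-12 of any defining boundary
(a₊ = ½, a₋ = ½, a = ½, limit = a, a₊ = 1 − a₋) are classified
BOUNDARY: a measure-zero set where any assignment would be arbitrary;
plotting layers may render it as NONE. `no_error_iib_search` samples
the (a₊, a₋, p) cube for the impossible fourth case (prediction "to 0"
with the limit above individual accuracy) and must return an empty set.

## Region maps

`region_map` sweeps a grid of priors and cost ratios C_FP/C_FN with
C_TP = C_TN = 0, C_FN = 1, computing the optimal operating point and
class per cell fully vectorised; a sampled test pins the vectorised
classifier to the scalar one. Default grids: 201 linearly spaced priors
on (0.005, 0.995) and 201 log-spaced ratios on [1e-2, 1e2] — the log
scale reflects the multiplicative symmetry of the ratio (above 1, a
false positive is relatively worse; below 1, relatively better). Grids
are recorded in a JSON metadata sidecar next to the long-format CSVs.

## Reference experiments and problem sizes

The six reference panels (module table in `experiments.py`) share
μ₋ = 0, μ₊ = σ = 1, C_TP = C_TN = 0, C_FN = 1 and vary (C_FP, p, q);
simulated curves use 10,000 replicates per group size. Default curve
grids use odd N from 1 to 501 (odd sizes make q = ½ tie-free), with
N = 5001 used for exact-only plateau checks; runs at N = 10,001–20,001
appear in tests purely as convergence checks of the asymptotic
formula. Simulation agreement is asserted within 4 binomial standard
errors of the exact value, with the standard error computed from the
exact accuracy so that near-perfect panels (simulated accuracy exactly
1.0, sample standard error 0) are still compared meaningfully.

## What the simulations do and do not show

The Monte Carlo layer emulates exactly the model's assumptions —
conditional independence, identical accuracies, a known fixed prior —
so simulation/exact agreement validates the implementation, not the
model. Real collective systems violate these assumptions in known ways
(correlated perception, heterogeneous ability, priors learned rather
than known); passing tests say nothing about those effects, which is
also why the package's scope stops at the conditionally-independent
homogeneous case.

## Numerical choices

- Boundary/equality tolerance 1e-12 in the classifier; tie-integrality
  tolerance 1e-9 on q·N.
- ROC sweeps span [μ₋ − 6σ, μ₊ + 6σ] linearly, pinning endpoint rates
  within 1e-9 of {0, 1}; the exact limiting points (0,0) and (1,1) are
  appended.
- Grid-search oracles in the tests use 1e4–1e6 thresholds over the same
  span; the closed-form optimum must never cost more than the best grid
  point (tolerance 1e-9 on cost).
- JSON output rounds floats to 12 significant digits; CSV writing uses
  the same precision. Reading CSVs back bit-identically requires
  pandas' `float_precision="round_trip"` parser.

## Known limitations

- The asymptotic classification is undefined on boundary sets
  (accuracies or quorums exactly at ½ or at each other); these raise or
  return BOUNDARY instead of a value.
- Exact binomial computation is O(1) per evaluation via regularised
  incomplete-beta tails but loses meaning if a₊ or a₋ underflow to 0/1
  in double precision; extremely separated ecologies (thresholds tens
  of σ from a mean) saturate the stored rates.
- The quorum recommendation targets the large-N regime; for very small
  groups the midpoint quorum is valid but not finite-N optimal.
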