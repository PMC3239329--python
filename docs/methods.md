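# Methods

## Model and procedure

The input is an n × L matrix of significance values in [0, 1], one row per
feature and one column per experiment, with L ≥ 2 inferred from the file
(never a user parameter). A feature is *called* in list *l* at threshold *h*
when its value is ≤ *h* (inclusive). All statistics are evaluated on an
arithmetic threshold grid, by default 0.01, 0.02, …, 1.00; start, stop and
step are configurable for finer scans. The grid deliberately starts at a
fixed small value rather than at the smallest observed p-value: thresholds
where some marginal count is zero carry no information and are simply
reported as undefined.

### Frequentist curve and permutation test

T(h) is the ratio of the observed all-lists count to its independence
expectation ∏_l O_l(h) / n^(L−1). Where the expectation is zero T is
undefined (NaN) and excluded from maximization — 0/0 carries no evidence.
T(h_max) is the maximum of the defined values, with ties broken toward the
*smallest* h (the most stringent list; deterministic and conservative).
At h = 1 every count equals n and T = 1 exactly.

The permutation test holds column 1 fixed and independently permutes every
other column across features in each of B replicates (default B = 1000) —
the direct generalization of the two-list scheme to L lists. Permutation
leaves every marginal count, and hence the expected curve, unchanged; only
the common count is recomputed, which makes a replicate O(n log n). Each
replicate is re-maximized over the grid (the alternative — evaluating
replicates at the observed h_max only — is a different, less conservative
test). The Monte Carlo p-value is the fraction of replicate maxima ≥ the
observed maximum, with no +1 correction; an empirical zero is stored as 0.0
and displayed as "< 1/B". A single seeded NumPy generator drives all
randomness and the seed is recorded in outputs.

### Bayesian model

At each threshold the 2^L joint-pattern counts (bit l set ⇔ called in list
l) are one multinomial observation with a symmetric Dirichlet prior,
α = 1 per cell by default (uniform on the simplex; configurable). The
posterior is Dirichlet(cells + α); R = p_all / ∏ m_l is evaluated on each
posterior draw (default 1000 draws per threshold; headline reproductions use
≥ 50 000 to shrink Monte Carlo error). Draws with a zero sampled marginal —
possible only for empty cells with α < 1 — are dropped with a logged count.
Quantiles (default 2.5%, 50%, 97.5%) use linear interpolation of order
statistics; agreement with published third-decimal figures is limited by the
draw count of the original runs, not by the quantile convention. Each
threshold is analyzed marginally with its own independent draw stream
spawned from the seed; no dependence across thresholds is modelled.

Rule 1 (h_max) maximizes the posterior median over thresholds whose
credible interval excludes 1, smallest h on a plateau (consistent with the
frequentist tie-break). Rule 2 (h_2) takes the largest h with median ≥ 2.
Either rule may be inapplicable and is then reported as such.

### Reporting

`create_table` only carries values over from the curve and the posterior
summaries — nothing is recomputed, so the table is an exact round-trip of
the module outputs; mismatched grids raise a consistency error. Values are
stored at full precision; the 2-decimal rendering (and the "lo - hi" CI
column) is presentation-only. Extracted common lists are sorted
lexicographically by feature ID and written with p-values in scientific
notation.

## Synthetic-data generator

`simulate_matrix` emulates the structure of a multi-tissue differential
expression study. Each feature independently receives a perturbation
pattern: all lists with probability `pi_common`, exactly one given list with
probability `pi_specific` each, otherwise null; arbitrary per-pattern
probabilities over the 2^L patterns are accepted for advanced designs.
Null p-values are Uniform(0, 1); perturbed ones are Beta(a, 1) with
`alt_shape = a ∈ (0, 1)`, chosen for its closed-form CDF h^a, which gives
analytic oracles for the generator's marginal and joint significance
probabilities. Defaults — n = 2912, L = 2, pi_common = pi_specific = 0.05,
a = 0.1 — mirror a moderately powered two-tissue microarray comparison
(a perturbed feature has probability 0.01^0.1 ≈ 0.63 of p ≤ 0.01).

What the generator does *not* emulate: inter-feature correlation (gene
co-expression), p-value miscalibration from upstream testing, list-specific
signal strengths, and partial-overlap patterns beyond single-list/all-lists
(except via explicit `pattern_probs`). Passing tests therefore demonstrate
correctness of the statistics under independent, well-calibrated rows, not
robustness to correlated real data.

`recovery_experiment` runs the full pipeline on replicated synthetic data
and scores each rule's extracted list against the truth: the false-positive
proportion is the fraction of extracted features not truly perturbed in all
lists, the false-negative proportion the fraction of truly-common features
missed. With its defaults (n = 1000, 10 replicates, 1000 draws) it runs in
seconds and shows the expected ordering: h_2 sits at or above h_max and
trades a few more false positives for markedly fewer false negatives.

## Numerical choices

* Counts on the grid are computed by per-column sorting + binary search;
  equality with per-row enumeration is asserted in tests.
* Grid values are rounded to 12 decimals to kill accumulated float drift so
  that printed thresholds like 0.99 compare exactly.
* `find_hmax` raises on an all-undefined curve rather than inventing a
  threshold.
* Seeds derived for sub-streams use `SeedSequence.spawn`, keeping every
  derived seed below 2^31 where an integer seed is exposed.

## Problem sizes used in the checks

The test suite's calibration check uses 200 independent-column datasets of
n = 1000 features with B = 100 permutations each — enough for the nominal
5% rejection rate to be distinguished from miscalibration at binomial
resolution while the whole suite stays fast. Oracle-equivalence checks use
100 random matrices with n ≤ 100 and L ∈ {2, 3}. Posterior reproductions of
the reference count tables use 50 000 draws (tests) and 200 000 draws
(`scripts/acceptance.py`).

## Known limitations

* Thresholds are analyzed marginally; the posterior curves at neighbouring
  h are statistically dependent but no joint model is attempted.
* No asymptotic approximation to the permutation null is offered; B sets the
  p-value resolution.
* Measures other than p-values are accepted only after the user maps them to
  a common [0, 1] scale with small = significant; no rescaling is performed.
* Features perturbed in only a subset of lists are generated and counted,
  but the decision rules target the all-lists pattern exclusively.
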