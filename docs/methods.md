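# Methods

## Model and assumptions

A scanpath is treated as a realization of a stationary stochastic process
`X = (X_1, ..., X_N)` over a finite AOI alphabet of size K (default 4).
Predictability is quantified as active information storage,

    AIS(X_t) = I(X⁻_{t-1}; X_t),    X⁻_{t-1} ⊆ {X_{t-1}, ..., X_{t-kmax}},

the mutual information between the next fixation and a selected set of past
fixations. Gaze transition entropy `GTE = H(X_t | X_{t-1})` is the standard
first-order measure; for a lag-1 past state the identity
`H(X_t) = AIS + GTE` holds sample-exactly for uncorrected plug-in estimates
computed on the same embedded samples, and the package preserves this
identity by evaluating all per-trial quantities on a common sample set.

Key assumptions: stationarity within a trial, a meaningful AOI
discretization, and enough fixations per trial for discrete estimation
(trials with fewer than 10 embedded samples are skipped). AIS is bounded by
`0 ≤ AIS ≤ min(H(X_t), H(X⁻))`; it is zero for memoryless processes.

## Estimation

All information quantities are plug-in estimates in bits: empirical
frequencies substituted into the defining sums, `0 log 0 := 0`,
probabilities over *observed* symbols only (the nominal alphabet size is
kept as metadata but unobserved symbols contribute nothing). Entropies of
joint variables are computed over integer-coded tuples; the
`DistributionTable` container and the fast code paths are verified against
each other and against direct-summation oracles in the test suite.

### Bias correction

Plug-in entropy is negatively biased at finite n. Two analytic first-order
corrections are available behind one switch:

- `mm` (Miller–Madow): add `(S_obs − 1) / (2 n ln 2)` with `S_obs` the
  observed support size.
- `pt` (default): same form, but the support size is first estimated from
  the bin-occupancy pattern by inverting `E[occupied] = R (1 − (1 − 1/R)^n)`
  for R (capped at the observed support when nearly all observations are
  distinct, where the inversion is uninformative). This refinement follows
  the support-estimation idea used in the spike-train literature's bias
  corrections.

MI corrections are composed from the entropy terms,
`corr(I) = corr(H_X) + corr(H_Y) − corr(H_XY)`, which is negative in
typical undersampled settings (plug-in MI is inflated). Corrections are
applied **only to final reported AIS and entropy values**, never inside the
selection statistics or permutation tests: within a permutation family the
correction is constant, so significance is handled entirely by surrogates,
and the group comparisons instead hold the bias constant by construction
(below).

### Past-state selection (non-uniform embedding)

Per trial, candidate lags 1..k_max (default k_max = 5) are evaluated on the
fixed embedding at offset k_max, so the sample count is identical at every
selection step. Greedy forward selection repeats:

1. Compute each remaining candidate's conditional mutual information gain
   `I(X_{t-k}; X_t | selected)`.
2. Take the maximum-gain candidate (ties broken toward the smallest lag —
   parsimony toward the first-order special case).
3. Test it against a null built by uniformly permuting the target column
   with all past tuples fixed; each permutation contributes the **maximum**
   gain over all remaining candidates, which controls the family-wise error
   of the inclusion decision. p-values use the add-one convention
   `p = (1 + #{null ≥ observed}) / (1 + n_perm)` and are never exactly 0.
4. Include if `p < α`, otherwise stop.

Defaults: n_perm = 200 and α = 0.05 at the selection stage (200 bounds the
attainable p at 1/201 < 0.05); the final AIS estimate is re-tested with the
group-level default of 5000 permutations. An empty selection means no
detectable temporal structure: the trial's AIS is reported missing rather
than zero. Permuting the target column is the default surrogate; it is
exact for the null of no past-present dependency given the embedding.
Greedy selection detects structure that is at least partly visible in
marginal gains; purely synergistic dependencies (e.g. a parity rule over
several lags with uniform marginals) are invisible to any forward-selection
scheme and are out of scope for this estimator family.

## Group comparisons

Estimation bias depends on the sample count and the dimension of the
variables entering the estimator, so raw per-trial estimates from trials of
different lengths and different selected lag sets are not comparable.
Before testing conditions within a participant the package:

1. forms the **union** of all selected lag sets of that participant
   (all relevant variables retained, at the price of irrelevant ones);
2. re-embeds every trial with that uniform past state and truncates from
   the **beginning** of each trial to the common count N* = minimum embedded
   length over usable trials (the minimum preserves all trials; trials
   under the 10-sample floor are dropped with a warning).

The equalized table then has constant n and constant past-state dimension
within a participant — asserted as metadata in the tests — and uncorrected
plug-in values are used since any remaining bias is a common offset.
Condition differences in AIS, H(X_t) and AIS/H(X_t) are tested with
independent-samples permutation tests on the difference of means
(default 5000 permutations, two-tailed; one-tailed available). Participants
whose trials never produced a significant past state are excluded and
listed. Per-participant tests are reported unadjusted (a Holm step-down
column is available via `holm=True`). The equalized per-trial table is also
the export hook for external mixed-model fitting; no mixed model is fitted
here.

## Decoding

One scalar feature per trial (AIS, normalized AIS, or GTE). Trials without
a valid estimate are dropped with a logged count; the resulting class
imbalance is part of the problem, so the report always carries the
dataset-specific majority baseline rather than a fixed chance level. The
`aggregate="image"` option averages the feature per (condition, trial id)
over participants instead.

- **1-NN**: absolute distance on the feature; distance ties resolved toward
  the lowest training-row index for bit-for-bit reproducibility.
- **RUSBoost**: AdaBoost-style rounds (default 50) on depth-2 decision
  trees; each round trains on a class-balanced random undersample drawn by
  the current boosting weights, while the weighted error driving the round
  weight is computed on the full training set. Rounds with weighted error
  ≥ 0.5 are skipped. Two-class only.

Both run under R repetitions of F-fold stratified cross-validation
(defaults 10 × 5) and report mean ± SD over the R·F fold accuracies. Paired
feature-set comparisons use the Wilcoxon signed-rank test on fold-wise
accuracy differences (zeros dropped; all-tied input returns p = 1 with a
warning) — this requires both reports to come from the same CV protocol and
seed so folds pair up.

## Preprocessing

IDT fixation detection: a window is grown while its dispersion
`(max x − min x) + (max y − min y)` stays within 50 px (default); windows
spanning ≥ 100 ms are emitted at their centroid, and fixations over 1500 ms
are deleted (not split). The dispersion metric is the classic
range-sum; duration is last-minus-first sample time with half-open
intervals. Samples under confidence 0.9 are removed first; the resulting
gaps break IDT windows when they exceed twice the nominal (median) sampling
interval. Trailing windows that never reach the minimum duration are
discarded. AOI layouts are prioritized axis-aligned rectangles, half-open
`[x0,x1)×[y0,y1)`, origin top-left; higher priority wins on containment, so
target boxes (grown by a 50 px frame) outrank the screen halves they sit
in. Consecutive identical AOI symbols are kept as separate steps.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical skeleton of a two-condition visual
comparison study: 10 participants × 22 trials per condition over 4 AOIs;
a relaxed time-unconstrained condition (TUC) and a stressed time-constrained
condition (TC). Defaults:

- TUC: order-1 cyclic chain, advance probability 0.75 → H(X_t) = 2.0 bits,
  lag-1 AIS ≈ 0.79 bits (normalized ≈ 0.40).
- TC: each row mixes a 40% context-independent pull toward one AOI
  (probability 0.8 on the preferred AOI) with a weakened cycle (0.70) →
  H(X_t) ≈ 1.87 bits, AIS ≈ 0.27 bits (normalized ≈ 0.14). Lower entropy
  *and* lower normalized predictability, the planted observer-state effect.
- Trial lengths: TUC 50–90 fixations, TC 25–45 (a hard time limit at
  ~250 ms per fixation), drawn uniformly.
- Inter-individual variability: per-participant Dirichlet perturbation of
  every transition row (concentration scale 150 — a few percent jitter).

These magnitudes were chosen so the generated study lands in the regime the
method is meant for: roughly half of TC trials retain a detectable past
state (putting the valid-trial majority baseline near 2/3), the condition
effect is detectable per participant with 22 trials, and the AIS feature
decodes the condition above both the baseline and the GTE feature.

What the generator does **not** emulate: image content and saliency-driven
fixation placement, realistic saccade dynamics, smooth pursuit, drift or
blink artifacts, non-stationarity within trials (e.g. a search-then-verify
phase change), and higher-order structure in the *condition* models (the
defaults are order-1; higher-order chains are available separately via
`mixture_lag_model` and used for order-recovery validation). Passing tests
therefore demonstrate correctness of the estimation machinery under the
stated generative assumptions, not that real gaze data satisfies them.

`analytic_ais` is the module's oracle: it enumerates the exact stationary
joint over (max lag + 1)-windows (eigen-solution of the context chain,
guarded at 10^6 states) and evaluates AIS, H(X_t) and GTE exactly. Chains
are initialized from the stationary distribution so finite-sample estimates
converge to these targets without burn-in.

## Numerical choices

- Logarithm base 2 throughout; all quantities in bits.
- Add-one permutation p-values; comparison tolerances of 1e-12 when testing
  `null ≥ observed` to make ties deterministic.
- Ties in greedy selection: smallest lag. Ties in 1-NN: lowest row index.
- Minimum usable embedded sample count: 10.
- Master pipeline seed spawns independent per-stage streams
  (`SeedSequence.spawn`), so changing one stage's settings does not perturb
  the others.

## Validation problem sizes

The acceptance script and end-to-end tests use: exhaustive count tables up
to 4 symbols × 3 dimensions for oracle agreement; 100 random sequences for
the complementarity identity; 100 seeded i.i.d. runs for the
non-significance rate; 50 seeded chains of length 2000 per order (1–3) for
embedding recovery plus 200 i.i.d. runs for false inclusion; 51 seeds per
length (500/2000/8000) for consistency and 200 seeds at n = 500 for the
bias-correction comparison; 500 null simulations for group-test calibration
plus one default-size study for the planted effect; 20 default-size study
replications for the decoding ordering; 100 planted gaze traces for
fixation recovery.

## Known limitations

- Discrete estimators only; continuous (x, y) coordinates must be
  AOI-coded first.
- Forward selection cannot detect purely synergistic past structure.
- The RUSBoost implementation is two-class.
- Per-trial estimation needs on the order of tens of fixations; very short
  trials are skipped rather than pooled.
- The union-past-state/minimum-sample-count equalization discards data
  (beginnings of long trials) by design, trading efficiency for bias
  constancy.
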