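# Methods

This note documents the models, the synthetic-data assumptions, and the
numerical choices behind `transrank`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Task structure

Eight items carry a strict latent ranking; ranks are 1-based with 1 = lowest.
Learning presents a fixed set of eight rank-position pairs — (1,6), (2,3),
(2,5), (3,7), (4,6), (4,7), (5,8), (1,8) — once per block in randomized
order over 4 blocks (four exposures per pair). Testing presents all
C(8,2) = 28 pairs once per block over 10 blocks, without feedback. Every
position occurs in exactly two learned pairs and the learned rank-distance
multiset is {1,2,3,3,3,4,5,7}. Pairs are stored unordered; orientation is
derived from the rank order at use time. The sequential (MEG-style) task
presents a single-item stream sliced from concatenated shuffled 8-item
sequences — the stream is padded with extra shuffled sequences when the
block geometry (default 5 × 81) is not a multiple of 8 — and each item after
a block's first yields one judgment against its predecessor.

## Value models

All learning updates read pre-update values on their right-hand sides and
are applied atomically per trial; learning is response-free, so the pre-test
state is a deterministic function of (model, α, trial order).

**Q-learning.** `Q_m ← Q_m + α[D(m,n) − (Q_m − Q_n)]/2` and symmetrically
for n, with `D(m,n) = (m − n)/(n_items − 1)` and all values initialized to
0. The update is antisymmetric, so Σ Q is conserved exactly — used as a
property test. Choice is logistic in the value difference with inverse
temperature γ ≥ 0.

**Beta-Q.** Item values are Beta(U, L) distributions, initialized at the
uniform Beta(1, 1). For a presented pair oriented by true rank (m above n):
the upper shape of m and lower shape of n grow by the full prediction error
`D(m,n) − (V_m − V_n)` with `V = U/(U+L)`, while the opposing shapes move by
α times the mirrored error. α here acts as a boundary-bias factor in (0, 1].
Choices sample from the two item distributions; the implied probability
`P(X_i > X_j)` is evaluated deterministically by adaptive quadrature of
`pdf_i · cdf_j` (validated against the closed form 5/6 for Beta(2,1) vs
Beta(1,2) and against Monte-Carlo sampling). This sampling policy has no
temperature parameter.

**Betasort.** Beta-Q on the presented pair plus non-presented-item updates,
with every case assignment evaluated on pre-update expected values: items
with V strictly between the pair's V values gain concentration at constant
mean (U += V, L += 1 − V); items below gain (ΔV, α·ΔV); items above gain
(α·ΔV, ΔV). Ties with either endpoint fall into the mean-preserving case,
since strict inequalities leave them undefined. The printed update equations
are followed as stated even where their prose gloss ("pushed downward /
upward") suggests the opposite sign; the implementation is the equations.

**Distance averaging.** A non-learning baseline: Q_i is the mean *raw*
signed rank distance over the learned pairs containing i (e.g. distances +3
and +7 average to +5). The raw-unit convention follows the model's worked
definition; a `normalized=True` switch divides by n_items − 1 for
comparability with the learning models' distance scale. Choice is the same
logistic policy.

**Correct ranking.** Oracle baseline Q_i = rank_i with logistic choice.

Numerical guards: Beta shape parameters are clamped at 1e-6 after every
update (long runs can otherwise drive them non-positive, and the Beta
density requires positive shapes); choice probabilities entering likelihoods
are floored at 1e-12.

## Model fitting

Per-subject maximum likelihood on testing-phase choices. Because learning is
response-free the likelihood has no latent variables: the state is rebuilt
deterministically from the learning schedule, the 28 per-pair choice
probabilities are computed once (cached for the Beta models), and the NLL
reduces to per-pair counts. Free parameters: α ∈ (1e-4, 1] and/or
γ ∈ [0, 100]; the γ cap is a numerical choice — the logistic saturates and
near-perfect subjects otherwise push γ to infinity. Optimization is
L-BFGS-B from Latin-hypercube starts (default 10 restarts; γ starts are
drawn in [0, 20] while the bound itself stays at 100); failure to converge
is flagged, not raised. A built-in recovery harness
(`model_fitting.parameter_recovery`) simulates and refits cohorts; the
acceptance suite runs it at 40 subjects on the default design with 6
restarts and checks mean bias |α̂ − α| ≤ 0.1 and mean γ̂ within 20%.

## Behavioral signatures and error structure

Pair accuracy is the fraction of testing trials choosing the truly
higher-ranked item, per unordered pair; pairs with no trials are flagged
missing rather than scored 0. Subjects with overall accuracy below 0.5 are
excluded before all cohort analyses. The serial-position curve averages a
position's seven pairs; the symbolic-distance slope is the OLS slope of the
28 pair accuracies on rank distance.

Cross-subject accuracy distributions per pair are fitted with a Beta
distribution (MLE, method-of-moments fallback, both recorded). Exact 0/1
values break the boundary of the Beta likelihood and are shrunk by
x′ = (x(N−1) + 0.5)/N before fitting; all-identical samples are flagged
degenerate. Classification follows the shape parameters relative to 1:
both > 1 unimodal, α>1∧β<1 high-accuracy, α<1∧β>1 low-accuracy, both < 1
bimodal (mass at the extremes).

The majority direction of every pair defines a complete tournament;
accuracy exactly 0.5 is resolved toward the error direction (a correct pair
requires accuracy strictly above 50%) and flagged. Circular triads are
counted by the score-sequence identity `N_d = C(n,3) − Σ_i C(w_i, 2)`, with
direct triad enumeration retained as an independent second route; the two
are cross-checked on random tournaments in the tests. The self-consistency
coefficient is `1 − N_d/N_T` with `N_T` the parity-dependent maximum
((n³−n)/24 odd, (n³−4n)/24 even; 20 at n = 8, validated against exhaustive
search for n = 3..5). An all-triads denominator (56 at n = 8) remains
available via a parameter for comparison with older conventions. Subject
categories: *correct* (tournament equals the true order),
*consistent-incorrect* (acyclic but different order), *inconsistent* (any
cycle — one 3-cycle suffices, since longer cycles always contain one).

The group permutation test shuffles each subject's 28 accuracy values
across pair positions (preserving the multiset), rebuilds tournaments, and
compares the observed group-mean coefficient with the shuffled distribution
using the add-one convention p = (1 + #{null ≥ obs})/(1 + B). The group
aggregator (mean of per-subject coefficients) is a design choice. The
per-subject error-consistency score is the mean error proportion over
majority-error pairs — undefined for subjects with none, who belong to the
correct-ranking group; the threshold-count statistic (subjects with ≥ 1
consistent-error pair at thresholds 0.6–1.0) is computed separately.

## Ranking reconstruction

HodgeRank minimizes `Σ (s_i − s_j − Ŷ_ij)²` over the trial-averaged ±1
preference matrix. The implementation solves the graph-Laplacian normal
equations by pseudoinverse, which also covers incomplete comparison graphs
(disconnected graphs raise, naming the components); on the complete testing
design this reduces to s_i = (1/n) Σ_j Ŷ_ij, checked to 1e-10. Scores are
centered to sum 0 (the objective is invariant to constant shifts); score
ties are broken by item-label order and flagged. Reconstruction is applied
to all non-correct subjects. For inter-subject similarity each ranking is
re-expressed over true rank positions — subjects learn differently shuffled
item sequences, so only the position space makes rankings comparable, with
the ground truth mapping to the identity for every subject — and all
pairwise Kendall τ values are reported.

## Synthetic cohorts

The generator's defaults are the study conditions: 8 items, the fixed 8-pair
learning set, 4 learning and 10 testing blocks, 77 behavioral subjects. The
default agent mix is 90% *constructive* / 10% veridical, the regime in which
roughly one subject in ten reproduces the true order while the rest hold
stable idiosyncratic orders. Constructive agents draw a subjective ranking
by perturbing the true ranks with independent Gaussian noise (SD =
`dispersion`, default 1.2 rank units) and re-sorting — a deliberately simple
alternative to Mallows-type samplers; dispersion 0 returns the truth and
expected τ to the truth decreases monotonically in dispersion. They answer
every test pair by the logistic policy applied to their *subjective* ranks
(default γ = 8), so their errors are consistent and transitive by
construction; at γ = ∞ the whole pipeline is exactly predictable and a
frozen gold vector in `tests/data/` pins it. Value-model agents draw α from
(0.2, 0.6) and γ from (3, 8) per subject. All randomness flows from a master
seed through `SeedSequence` spawning, so cohorts are bit-reproducible.

The MEG-like generator emulates only the *statistical structure* the RSA
consumes: per subject and phase, item × sensor × time arrays (default 64
sensors, 100 Hz, −0.2–1.2 s) containing window-gated embeddings of the
shared low-level feature RDM (0.10–0.30 s), the shared size-rank RDM
(0.20–0.48 s), and — post-learning only — the subject's own subjective-rank
RDM (default 0.685–0.775 s), plus i.i.d. Gaussian sensor noise (SD 1.0,
signal amplitude 1.0). Effects are embedded by factorizing K = 1 − d/c (a
valid correlation matrix for these negative-type dissimilarities) into
unit-norm item coordinates and mixing them into sensors through a random
map with orthonormal, zero-sum rows; zero-sum rows give every pattern a zero
sensor mean, so 1 − Pearson between noiseless patterns reproduces the target
RDM exactly up to scale. What this generator does **not** emulate: evoked
morphology, sensor covariance and geometry, oscillations, artifacts, or any
forward model — so passing tests certify the analysis chain's correctness
and calibration, not its performance on real recordings.

## RSA

Neural RDMs are 1 − Pearson between item sensor patterns at each timepoint
(zero-variance patterns yield flagged NaN entries that are dropped from
regression). The three model RDM predictors are z-scored across the 28
upper-triangle entries so β magnitudes are comparable, and enter one OLS
with intercept simultaneously; rank-deficient designs return the
minimum-norm solution with a collinearity flag. The learning contrast is
post − pre for the subjective predictor and the phase mean for low-level and
size. Group inference uses sign-flip cluster permutation: per timepoint
one-sample t against zero, two-sided cluster-defining threshold p < 0.05,
clusters as maximal same-sign suprathreshold runs scored by summed t
(mass), null as the maximum |mass| under random per-subject sign flips,
add-one p values. The subject-shuffle test regresses window-averaged neural
RDMs on (low-level, size, subjective) with subjective assignments permuted
across subjects, comparing the observed group-mean subjective β against the
shuffle distribution. No sensor-space searchlight is provided: it requires a
real sensor neighborhood geometry, which the synthetic generator does not
model; the whole-array time-resolved analysis is the implemented surface.

## Problem sizes and determinism

The shipped analyses use desk-scale sizes chosen to keep full runs fast
while leaving all statistical machinery intact: cohorts of 20–80 subjects,
1,000 permutations for reported p values, and reduced geometries (fewer
sensors, 50 Hz, 100 permutations) for the repeated calibration studies.
Every stochastic routine takes an explicit seed; pipeline runs with equal
configuration are byte-identical.

## Known limitations

- The Beta-model likelihood evaluates 28 numerical double integrals per
  state; fitting those models is an order of magnitude slower than the
  scalar-value models.
- The constructive agent is a generative stand-in with a single dispersion
  knob; it makes no claim about *how* a subjective order is constructed
  during learning.
- Beta-shape classification near α ≈ 1 or β ≈ 1 is unstable at small
  cohorts; categories should be read jointly with the fitted shapes.
- HodgeRank returns only the gradient (least-squares) component; cyclic
  residual structure is summarized by the triad statistics rather than a
  full Hodge decomposition.
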