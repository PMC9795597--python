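# Methods

## Estimand and assumptions

The target is the average treatment effect Δ = E(Y¹) − E(Y⁰) for a binary
treatment A on a continuous outcome Y, identified from observational data
under the standard triad: consistency (Y = AY¹ + (1−A)Y⁰), ignorability
((Y¹, Y⁰) ⫫ A | X) and positivity (0 < P(A=1|X) < 1). Every estimator in
the package presumes these; none is testable from the data alone.

## The multi-index propensity score

Candidate models are deliberately cheap and parametric: K logistic
propensity models and L linear outcome models, each possibly misspecified
in its choice or transform of covariates. Each fitted candidate is reduced
to its index — the fitted linear combination of transformed covariates,
with intercept and treatment coefficient discarded. Stacking the K + L
indices gives the regressor matrix Ŝ, and the integrated propensity score
is the nonparametric regression E[A | Ŝ]. If any single candidate is
correct, its index is a sufficient dimension reduction for either the
treatment or the outcome mechanism, and the Hajek-weighted contrast built
on E[A | Ŝ] recovers Δ; this is the multiple-robustness property the
Monte Carlo suite verifies empirically.

Indices are standardized (mean 0, sd 1, denominator n−1) before scoring,
and the affine parameters are stored for reuse on new rows. Index scale is
an artifact of covariate units, so standardization stabilizes both kernel
bandwidth selection and network training; an unstandardized mode is kept
for kernel oracle tests. Duplicate or collinear indices are retained, not
deduplicated — robustness to redundant candidates is part of the method's
contract. A zero-variance index (e.g. from an all-zero slope vector) is
replaced by a zero column and flagged with a warning.

## Candidate fitting

Logistic candidates are fitted by Newton/IRLS (statsmodels `Logit`), with
convergence declared only when the score vector's max-norm is below 1e−8.
Complete separation is detected two ways — a coefficient norm above 1e3, or
fitted probabilities collapsing onto the labels to within 1e−3 — and marks
the fit non-converged rather than raising, so a simulation replication can
count and skip it. Linear candidates are ordinary least squares; the
treatment enters as a regressor by default, and a group-separate mode
(separate fits on treated and controls, two index columns per candidate)
accommodates treatment–covariate interactions. Rank-deficient designs are
rejected with the collinear terms named.

## Kernel scorer

The kernel path is multivariate Nadaraya–Watson regression with a product
Gaussian kernel and diagonal bandwidth h_j = c · sd_j · n^(−1/(d+4))
(Scott-type rule; undersmoothing factor c defaults to 1, and manual
bandwidths are accepted). The defining sums run over all j including the
own observation; a leave-one-out flag is available. With a strictly
positive kernel the scores are convex combinations of the treatment
indicators and hence stay in [0, 1] in either mode — the only reachable
pathology is a denominator underflowing to zero under an extreme
bandwidth, which raises with the offending row named. An out-of-range
counter is nonetheless maintained on every score vector. Kernel scores are
*not* clipped before weighting by default (a clip flag exists): values
arbitrarily near 0 or 1 are precisely the instability the comparison with
the network scorer is meant to expose.

## Network scorer

The network is a fixed d → 4 → 4 → 1 feed-forward architecture (4d + 20
weights, 9 biases): tanh hidden activations, sigmoid output so that every
score lies strictly in (0, 1). Training is full-batch gradient descent
with momentum on the summed squared error,

  E(w) = Σᵢ (oᵢ − Aᵢ)²,

with learning rate 0.001 and momentum 0.5. The *summed* (LMS) criterion
rather than the per-sample mean is deliberate: classic neural trainers of
this family accumulate the global error, and with the mean criterion the
gradient shrinks by 1/n, so at learning rate 0.001 the network would need
on the order of n times more epochs to move at all — at n = 1000 it stays
near its initialization, the scores collapse toward the constant treated
fraction, and the weighted contrast degenerates to the unadjusted
difference of group means. Binary cross-entropy and mean-MSE remain
available as configuration options.

Weights start uniform on (−0.3, 0.3) from a seeded generator; training is
a pure function of (data, config), so identical seeds give bit-identical
weight trajectories — the property the bootstrap and the simulation
harness rely on for reproducibility. The default schedule is 2000 epochs
with no early stopping, and the epoch count is a genuine bias–variance
dial, not a mere convergence knob. Too few epochs leave attenuation bias:
the scores have not yet learned the treatment–index relationship, pull
toward the constant treated fraction, and drag the weighted contrast
toward the unadjusted difference of means (≈3% of Δ remains at 1000
epochs for the double-index configuration at n = 1000, ≈2% at 2000–3000).
Too many epochs enter a memorization regime: with several collinear
indices the network can isolate individual subjects and push their scores
toward 0 or 1 — the training loss still decreases monotonically, and a
smaller learning rate with proportionally more epochs lands in the same
place, so this is a property of the limit being approached, not of step
size — and a handful of near-boundary scores turn into enormous inverse
weights with heavy-tailed estimates (at 5000 epochs the eight-index
configuration at n = 1000 shows score minima near 5e−4 and a Monte Carlo
SE several times the two-index value). The 2000-epoch default sits in the
stable middle for the n ≈ 300–1000, d ≤ 8 regime this package targets;
both directions are reachable through configuration. A non-finite loss
(possible with the linear-output variant on unscaled targets) raises
immediately with advice to lower the learning rate.

Network propensities are clipped into [1e−6, 1 − 1e−6] before weighting;
the sigmoid already bounds them, so the clip only guards floating-point
saturation.

The same architecture doubles as the raw-covariate comparators: IPW.ANN
regresses A on standardized X, and OR.ANN regresses Y on (X, A) with a
linear output unit, contrasting its fitted means at A = 1 and A = 0.

## Estimators

All weighting estimators use the Hajek (self-normalized) form, so they are
invariant to rescaling all weights within a group and reduce to the
difference of group means under a constant score. Weights are computed
within treatment groups: an isolated treated subject whose kernel score is
exactly 1 is legal (its own weight is 1), whereas a score of 0 on a
treated subject or 1 on a control is an error. The OR estimator averages
the row-wise contrast of fitted means, which for a joint linear fit equals
the fitted treatment coefficient exactly. AIPW is the textbook
unnormalized augmented estimator, included as the doubly robust
comparator.

## Inference

Bootstrap standard errors resample n subjects with replacement and re-run
the complete pipeline — candidate refits and network retraining with a
per-resample derived seed — on every resample; the SE is the sd
(denominator B−1) of the B estimates. Resamples with single-class
treatment, or in which the estimator fails, are redrawn and counted, so B
is preserved. Per-resample seeds derive deterministically from
(master seed, resample index). Defaults: B = 100 for simulation work;
B ≈ 500 is recommended for a single applied analysis. Wald intervals use
the conventional multiplier 1.96 at the 95% level (exact normal quantiles
at other levels; override available).

## Monte Carlo harness

Each replication draws a fresh dataset from the configured generative
process with a counter-derived seed, runs every configured estimator, and
(optionally) its bootstrap. Metrics per estimator: BIAS% =
100·(mean − Δ)/Δ (signed, relative to the truth — the convention under
which reported bias/RMSE/MC-SE triples are mutually consistent via
RMSE² = |bias|² + MC-SE²·(R−1)/R); RMSE about the truth; MC-SE (sd across
replications, denominator R−1); BS-SE (mean bootstrap SE); CI-Cov%
(fraction of replications with |estimate − Δ| ≤ 1.96·SE, using each
replication's bootstrap SE). Failed replications are excluded and counted,
with a configurable failure-rate ceiling. Results are invariant to the
worker count because seeds and aggregation order are fixed per
replication.

## The synthetic generator

The benchmark process draws ten standard-normal covariates (correlation
matrix configurable — identity default, exchangeable and AR(1)
constructors provided), assigns treatment by a logistic model on X1–X7
with slopes (0.16, −0.05, 0.12, −0.10, −0.16, −0.10, 0.15) and intercept
α₀ (0 → ~50% treated; −1.1 → ~25%), and generates
Y = −3.85 − 0.4A − 0.8X₁ − 0.36X₂ − 0.73X₃ − 0.2X₄ + 0.71X₈ − 0.19X₉
+ 0.26X₁₀ + ε with ε ~ N(0, 1). Both potential outcomes share one ε per
subject, so Y¹ − Y⁰ = −0.4 exactly row by row; the marginal distributions
are unchanged and the true ATE is the treatment coefficient, −0.4. The
benchmark candidate sets are PS1/OR1 (correct functional forms), PS2/OR2
(squared covariates, incorrect), and PS3/PS4/OR3/OR4 (three-covariate
extras, incorrect), addressed by a four-digit bitmask with optional
-2PS/-2OR/-2PS2OR suffixes.

What the generator does *not* emulate: covariate measurement error, mixed
continuous/discrete covariates (binary columns can be user-supplied but no
preset is shipped), treatment-effect heterogeneity, nonlinear
treatment-assignment surfaces beyond the logistic index, or non-normal
outcome noise. Passing tests therefore demonstrate the estimators'
behavior under a clean, correctly scaled generative benchmark — not
robustness to the messiness of applied data, where candidate-set
construction and overlap diagnostics remain the analyst's job.

## Problem sizes and numerical choices

The multiply-robust pattern is verified at n = 1000 with 100 replications
(bias thresholds at 5% of Δ) and coverage at n = 1000 with 200
replications and B = 50 — sizes at which the qualitative pattern is stable
while the full suite stays inexpensive; the Monte Carlo error of a BIAS%
reading at these sizes is roughly 1.5–2 percentage points. Tolerances:
closed-form oracles at 1e−12 (kernel double loop, Hajek and AIPW hand
evaluations), likelihood-maximization cross-checks at 1e−4, large-sample
moment checks at ±0.01–0.05 depending on the statistic. Degenerate inputs
(n = 0 covariates, constant treatment, zero-variance indices, single-class
resamples) are handled explicitly rather than left to downstream
arithmetic.

## Known limitations

Candidates must be parametric — the index construction needs explicit
slope vectors, so nonparametric candidate models are out of scope. The
network architecture is fixed rather than searched; there is no GPU path
and no regularization beyond the plain momentum schedule. Only the ATE of
a binary treatment on a continuous outcome is estimated (no ATT/ATO,
survival, or longitudinal extensions), and bootstrap/Wald is the only
inference route (no analytic sandwich or percentile intervals).
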