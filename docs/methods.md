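# Methods

## Belief space and measurement

Beliefs live on a lattice of N = 99 evidence states, state 1 = certainty
in the incorrect motion direction, state 50 = complete uncertainty,
state 99 = certainty in the correct direction.  N is divisible by 3 so
the three rating categories (L, M, H) correspond to equal contiguous
blocks of 33 states, each with a diagonal 0/1 projector M_L, M_M, M_H.
Raw 0–100 ratings are rescored toward the correct direction
(left-moving trials: 100 − rating) and categorized as L = 0–33,
M = 34–66, H = 67–100.

Both models start each trial from the same initial distribution: a
Gaussian over state indices centered on the uncertainty midpoint (state
50) with a standard deviation of 5 lattice steps, truncated at the
lattice boundaries and renormalized.  The quantum initial state takes
real nonnegative amplitudes √φ_j(0) (zero phase).  A global phase is
unobservable and relative phases would add unconstrained structure, so
zero phase is the minimal choice consistent with specifying the initial
state by its probability distribution alone.

## Markov chain

The generator K is tridiagonal: rate α = μγ for a downward step, β =
(1−μ)γ for an upward step, with drift μ = α/(α+β) ∈ (0,1) and diffusion
γ = α+β > 0 (both per second).  Diagonal entries equal minus the total
outgoing rate of their column; at the two boundary states only the
single available move contributes, making K a conservative generator
(columns sum to zero).  A generator whose boundary columns leak mass
would not define probability distributions under the response rules, and
the conservative (reflecting) choice matches standard practice for
bounded diffusion approximations.

Direction convention: with K's index placement (downward moves at rate
α), μ > 1/2 drifts toward *low* states, so drift toward the
correct/high end of the rescored scale corresponds to μ < 1/2.  The
generator, fitting and tests all use this convention consistently.

Transition operators T(t) = exp(tK) are computed with scipy's
Padé/scaling–squaring matrix exponential.  The design's evolution lags
all share a 0.5 s base step, so the fitting hot path computes one
exponential per drift value and builds the remaining lags by the
semigroup property (exact, and ~3× faster for the mixture model).

Response rules: the marginal probability of category l at t₂ is the
category mass of the evolved distribution; the joint probability of k at
t₁ then l at t₂ projects the evolved distribution onto block k (no
renormalization), evolves the projected vector over t₂−t₁, and takes the
block-l mass.  Summing the joint over k reproduces the marginal exactly
(Chapman–Kolmogorov): the chain predicts no interference from the first
rating, and the test suite verifies this to < 1e−10 over a thousand
randomized instances.

## Quantum walk

The Hamiltonian is real symmetric tridiagonal: H_jj = μ·j/N (a linear
potential ramp; j is the 1-based state index) and H_{j,j±1} = σ.  σ may
in principle be complex; it is restricted to real values to keep two free
parameters.  U(t) = exp(−itH) is built from one spectral decomposition of
the tridiagonal matrix (scipy `eigh_tridiagonal`), an orthogonal
similarity that is stable for all parameter values and serves every time
point at once.

Because the nearest-neighbour band E(k) = 2σ·cos k has negative
curvature at k = 0, the wave packet accelerates *up* the potential ramp:
positive μ drifts beliefs toward high states.  This sign convention was
fixed by direct numerical measurement and is used consistently
throughout.

Joint response probabilities follow the projective-collapse rule: evolve
to t₁, project the amplitudes onto the first rating's block (the
unnormalized projected vector carries the joint probability), evolve the
projected vector, project again, and take the squared norm.  The
difference between the collapse-summed marginal and the no-measurement
marginal is the interference effect.  It vanishes identically when σ = 0
(diagonal dynamics commute with the projectors) and is generally nonzero
otherwise.  The documented reference point μ = 10, σ = 50,
(t₁, t₂) = (0.5, 1.5) s gives an H-category interference of −0.0321,
frozen as a regression fixture after verification against a brute-force
scaled-Taylor amplitude computation.

## Drift-variability mixture (Markov-V)

Trial-to-trial drift variability is modeled by mixing the chain's joint
tables over a discrete approximation to Normal(μ_mean, μ_sd²): 21
equally spaced points spanning μ_mean ± 3 μ_sd, weights proportional to
the normal density and renormalized.  Points falling outside (0, 1) are
clipped to (1e−6, 1−1e−6); clipped duplicates are merged with summed
weights.  With μ_sd = 0 the mixture reduces exactly to the plain chain
(verified to 1e−10).  The common diffusion rate is υ.

## Maximum-likelihood fitting and model comparison

Each participant × coherence cell contributes one 3×3 count table per
timing condition; counts are multinomial given the model's predicted
table, and the fit criterion is the log likelihood summed with equal
weight over the two calibration conditions ((0.5, 1.5) and (1.5, 2.5) s).
Predicted cell probabilities are floored at 1e−10 inside the log so empty
predicted cells with observed counts penalize rather than overflow.
Discrepancy is reported as G² = −2·LL.

Optimization is multi-start bounded L-BFGS-B.  Start points sit on a
seeded Latin hypercube over a practical sub-box of the bounds, with
rate-type parameters (γ, σ, υ) sampled on a log scale; bounds are
μ ∈ (0.001, 0.999) and γ, υ ∈ (1e−3, 200) for the chain,
μ ∈ (−50, 50) and σ ∈ (1e−3, 50) for the walk, μ_sd ∈ [0, 0.5) for the
mixture.  The mixture model additionally warm-starts from the plain
Markov solution (its drift and diffusion estimates are consistent
starting values for μ_mean and υ), which lets it run with as few as two
starts.  Fits are deterministic given data and seed.  A coarse
grid-search oracle in the tests confirms the optimizer is never beaten by
more than 1e−3 log-likelihood units.

The generalization criterion applies calibrated parameters unchanged to
the held-out condition (0.5, 2.5) s and scores the held-out table by G².
Model comparisons report G²_diff = G²_a − G²_b (positive favors model b;
by convention the Markov-family model is a and the quantum model is b)
and BIC_diff = G²_diff + p·ln(N_obs), charging model a for p extra
parameters — e.g. one per participant when per-participant fits are
summed across a cohort.

## Cohort statistics

The interference test compares, per participant and coherence, the
3-category marginal of the *second* rating of condition 1 with that of
the *first* rating of condition 2 — both taken 1.5 s into the trial, so
any difference is attributable to the intervening first rating.  The
comparison is a likelihood-ratio G² homogeneity test between two
independent multinomials with pooled-proportion expected counts and the
0·ln 0 := 0 convention; per-participant statistics are summed
(df = 2 per participant; 9-cell joint-table comparisons use df = 8 per
participant).  This construction reproduces the df bookkeeping of the
study design exactly.  The same machinery supports the joint-table
manipulation checks between any two conditions.

Mean rating change from t₁ to t₂ (rescored) is summarized per
participant × coherence and averaged across participants; the
participant-level mean-change vectors are tested against zero with a
one-sample Hotelling T², converted to F = (n−p)/(p(n−1))·T² on
(p, n−p) df — with p = 4 coherence levels and n = 11 participants this
is F(4, 7), the standard formula for a 4-dimensional one-sample test.

**Finite-sample behavior of the summed G².**  Likelihood-ratio
statistics exceed their df in expectation at finite n, and summing 11
per-participant statistics compounds the inflation.  Under an exact
Markov null with all categories well populated, the measured type-I rate
of the df = 22 test at α = 0.05 is ≈ 0.07 with 48 trials per cell,
falling to the nominal 0.05 by 200 trials per cell.  The acceptance
suite therefore verifies calibration at 200 trials per cell (a symmetric
diffuse null, μ = 0.5, γ = 150, chosen so every category has healthy
expected counts), and the acceptance script reports the small-cell rate
alongside.  Conclusions from the test at the study's own cell sizes
should treat p-values near the threshold with caution.

## Synthetic cohorts

The generator emulates the experiment's structure: 11 participants,
4 coherence levels (2, 4, 8, 16 %), 3 timing conditions, 48 trials per
cell by default, half of the trials left-moving, deterministic under a
master seed with per-participant substreams.  Trials are sampled at
state resolution: the first state from the model's state distribution at
t₁; the collapse then happens at *category* resolution (Markov:
probability mass conditioned on the reported category; quantum:
amplitudes projected and renormalized), the collapsed state evolves to
t₂, and the second state is drawn.  The induced 3×3 category tables
equal the models' joint probability tables exactly, which the suite
verifies by goodness of fit at 100 000 trials.  Ratings are emitted as
state indices (1–99 on the 0–100 scale) and un-rescored for left trials
so raw records match the experimental format.  Motor noise on the rating
scale is not simulated.

Default generating parameters (per coherence 2/4/8/16 %): Markov
γ = 30 1/s with μ = 0.47/0.42/0.33/0.18; quantum σ = 45 with
μ = 3/6/10/16; Markov-V adds μ_sd = 0.08 at υ = 30.  These were chosen
once so that mean first ratings rise from near the scale midpoint at 2 %
coherence toward certainty at 16 % (echoing the coherence ordering of
real data), the quantum walk shows its characteristic spread into all
three categories at low drift, and its interference effect is visible
(~0.03).  The fitting pipeline never sees these values; they are ground
truth for recovery studies only.

What the generator does *not* emulate: between-participant parameter
heterogeneity (all participants share the generating parameters, so
cross-participant variance in synthetic cohorts is purely binomial),
session/learning effects, response times, and motor noise.  Passing
recovery and calibration tests on these cohorts therefore demonstrates
correctness of the machinery under the models' own assumptions, not that
real cohorts satisfy those assumptions.

## Problem sizes used by the test and acceptance suites

Simulation sizes are chosen so Monte-Carlo error is small relative to
each tolerance while the suite stays desk-scale:

* no-interference sweep: 1000 randomized (lattice, parameters, times,
  initial distribution) draws, bound 1e−10;
* parameter recovery: cohort-pooled calibration tables (11 participants
  × 48 trials/cell, the study's per-coherence data volume), 100
  replications for the two-parameter models and 40 for Markov-V
  (~7 s per mixture fit); asserted median biases: drift ±0.03 (chain) /
  ±0.5 (walk, scale −50..50) / ±0.05 (mixture mean and sd), rates ±10 %
  (±20 % for υ);
* model recovery: 100 replications per generating model, one participant
  at coherence 4 with 40 trials/cell; the held-out G²_diff favors the
  generating model in the majority of replications (pilot: 80 % for
  Markov-generated, 90 % for quantum-generated);
* interference-test calibration: 500 replications at 200 trials/cell,
  nominal 0.05 within a 3-standard-error band (±0.029).

## Known limitations

* The walk's σ is bounded at 50; generating conditions near that bound
  would pile estimates on the boundary.  The defaults keep σ at 45 with
  pooled-table recovery comfortably unbiased.
* At strong drift the chain is weakly identified from 3-category data:
  when virtually all mass sits in one category (e.g. μ ≈ 0.4 with
  γ ≈ 4), γ is unidentifiable at any sample size.  Recovery claims hold
  at the documented default conditions.
* Open-system (decohering) quantum dynamics and response-time
  predictions are out of scope; the quantum model here is a closed
  system evolving unitarily between projective measurements.
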