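# Methods

This note records the model as implemented, the defaults and why they are
what they are, the numerical conventions, and the limitations a user should
know before trusting a number.

## Model and update rule

The reservoir is a synchronous Random Boolean Network: N binary neurons,
each receiving exactly K = 16 recurrent connections whose weights are drawn
i.i.d. from N(μ, σ). The update is a hard threshold,

    x_i(t) = θ( w_i^in u(t) + Σ_j w_ij x_j(t−1) ),

with θ(0) = 0 taken literally and applied everywhere — in particular a
neuron whose inputs sum to exactly zero stays silent. Since θ(λx) = θ(x)
for λ > 0, rescaling all weights (and, in the driven case, the input
weights with them) leaves the binary trajectory bit-identical; the test
suite asserts this exactly. Consequently the only free parameter of the
free dynamics is σ* = σ/μ, and every simulation runs at the canonical
weight distribution (μ, σ) = (sign σ*, |σ*|). The zero-mean case is
scale-free and is carried as the token `"balanced"`, simulated at (0, 1).

Presynaptic partners are sampled uniformly without replacement and
self-connections are excluded — conventional RBN wiring that avoids trivial
self-latching; the wiring convention is not otherwise constrained by the
model. Input and readout neurons are a uniformly random equal split, fixed
per reservoir; an input-weight "tossing" redraws only the weight values on
the same input half, from U[−0.5, 0.5].

## Free-run statistics and criticality

Runs start from a random state with exactly round(0.2·N) active neurons and
discard a 1,000-step transient; statistics use the following 1,000-step
steady window (matching the transient keeps period detection and BiEntropy
well sampled). Activity is stored as the exact integer count of active
neurons, so periodicity and binarization involve no floating-point ties.

The steady activity is binarized at its own time mean (s(t) = 1 iff
A(t) > Ā, computed in integer arithmetic). The rule is parameter-free and
maps fixed points to all-zero strings and period-2 oscillations to
alternating strings. BiEntropy follows Croll's construction: the entropy of
the string and of each successive XOR derivative, weighted 2^k for strings
of ≤ 32 bits and log₂(k+2) (the TBiEn variant) above, where the power
weights overflow; the 1,000-bit steady windows therefore always use TBiEn.

For each σ* on a grid, an ensemble of reservoirs (each generated and run
once from its own seeded initial state) yields ⟨Ā⟩, ⟨δA²⟩, ⟨H_b⟩ and the
across-reservoir variance ⟨δH_b²⟩, the latter with the population (divide
by n) convention. The critical point is the grid argmax of ⟨δH_b²⟩
(leftmost on ties, flagged); the critical region is the maximal contiguous
grid interval containing the argmax where the variance exceeds 1% of its
peak — a finite-sample proxy for "nonzero variance", which is not a robust
predicate under sampling noise. The variance across reservoirs (not across
reservoirs × time blocks) is the implemented reading.

Desk-scale defaults: N = 2,000 and 20 reservoirs per grid point (40 on the
positive branch, whose transition is much broader and needs more averaging
for a stable argmax), grid step 0.01 near the negative critical point and
0.1 on the positive side. At this scale the negative-branch argmax lands at
σ* ≈ −0.67…−0.69 (the transition sharpens toward −0.66 with N) and the
positive-branch argmax within about ±0.4 of 4.0. The full-scale protocol
(N = 10,000, 100 reservoirs, 100 initial conditions) is available through
`full_scale()` / `--full-scale`.

## Attractor classification

The steady activity sequence is classified as extinguished (all zero),
fixed (constant nonzero, including saturation), cyclic (minimal exact
period 2 ≤ p ≤ W/2) or irregular (no period up to W/2 in a window of
length W). Classification deliberately operates on the scalar activity,
not the full state vector; a cyclic activity can alias a longer state
cycle. On tiny networks (N ≤ 12) the suite enumerates the exact state-space
cycle by hashing full states and checks that activity labels never
contradict it: any activity period divides the true state period, and a
window that contains the true cycle is never labelled irregular. With
W = 1,000, cycles longer than 500 steps are reported irregular by
construction. The dominant attractor of a reservoir is the modal label over
seeded random initial conditions; ties resolve to the lower-complexity
category (extinguished < fixed < cyclic < irregular) and are flagged.

## Task signals

White noise is i.i.d. U[0.1, 0.9]: the bounds keep targets strictly inside
the sigmoid's range with margin; the uncorrelated signal makes the memory
task a pure recall problem. Mackey-Glass uses the standard benchmark form
dx/dt = 0.2·x(t−τ)/(1+x(t−τ)¹⁰) − 0.1·x(t), integrated by classical RK4 at
internal step 0.1 with linear interpolation of the lagged value at half
steps, sampled at unit intervals, with a 1,000-sample warm-up discarded and
the segment affinely rescaled into [0.1, 0.9] (the affine map is stored in
the provenance). The default history is constant 1.2, jittered by a seeded
U[−0.1, 0.1] perturbation so different seeds give different trajectories; a
constant history of exactly 1.0 is an equilibrium of the equation and the
integrator preserves it exactly (all RK4 increments vanish), which the
suite asserts. Halving the internal step moves the τ = 20 trajectory by
under 10⁻³ RMS over 500 samples.

Sampled limit cycles are generically incommensurate with the unit sampling
step, so periodicity of real-valued series is decided by
`detect_period_approx` (smallest lag with RMS self-mismatch below a
tolerance, default 0.01 on the [0.1, 0.9] scale); it cleanly separates
τ = 5 (near-period ≈ 154 samples) from τ = 28 (no lag below tolerance).

## Readout and benchmarks

The readout is one sigmoid unit over the readout half, trained on MSE by
full-batch ADAM (standard moment constants, α = 0.001, 4,000 epochs by
default) from zero-initialized weights — deterministic given its inputs.
ADAM's momentum produces tiny loss oscillations near convergence, so the
descent test bounds upticks at 1% per epoch rather than demanding strict
monotonicity. A closed-form ridge regression on logit(T) serves as an
independent cross-check (agreement within 0.02 correlation on
well-conditioned instances) and as a fast alternative; it is not part of
the benchmark protocol.

Task runs drive the reservoir with the aligned input so that history row t
matches target T(t) = u(t+δ); the first 1,000 aligned samples (washout) are
excluded, the next 4,000 train, and scoring is Corr(y, T) on a held-out
1,000-sample test segment (training-segment scoring is available behind a
flag). Each reservoir's score averages 5 input-weight tossings. Note an
architectural consequence of the disjoint input/readout halves: the input
reaches the readout half only after one propagation step, so the degenerate
δ = 0 white-noise task is unsolvable (corr ≈ 0) and δ = −1 is the easiest
recall — the benchmark shifts (−2, −6, −10) all lie in the reachable range.

## What the generators do and do not emulate

All inputs are synthetic by design — the study's claims are about randomly
generated reservoirs and standard benchmark signals, not recorded data.
The generators reproduce the stated statistical structure exactly (fixed
in-degree Gaussian weights, uniform half-zeroed input weights, 20%-active
initial states, white noise, Mackey-Glass at τ ∈ {5, 20, 28}). They do not
emulate anything a physical reservoir would add: neuron heterogeneity,
weight quantization, measurement noise, or temporal correlations in real
input streams. Passing tests therefore validate the model's internal
claims (critical points, attractor structure, balance–performance links)
at the simulated sizes, not robustness of those claims on hardware
reservoirs or natural signals.

## Numerical conventions and degenerate cases

* Round-half-up for the initially active neuron count.
* Exact integer comparison for all periodicity and binarization decisions.
* Pearson correlation of a zero-variance output or target is defined as 0.
* Ensemble and time variances use the population convention (divide by n).
* The analytic balance saturates to ±1 in floating point for |σ*| ≲ 0.12;
  the balance is antisymmetric in σ* exactly.
* Reservoir generation requires even N (equal halves) and K ≤ N − 1;
  duplicate presynaptic rows are rejection-resampled, deterministically
  given the seed.
* Per-run seeds are pure functions of (master seed, grid index, reservoir
  index, run index) via SeedSequence spawn keys; identical configs
  reproduce every table byte-for-byte.

## Test profile

The suite runs the full pipeline at reduced size: unit and property tests
use N = 200–600; the criticality checks use N = 2,000 with 20–40 reservoirs
per point; benchmark contrasts (difficulty monotonicity, branch spread,
trainer cross-check) use N = 1,000, 5 reservoirs × 2 tossings, 1,500
training samples and 600 ADAM epochs at α = 0.01. These sizes were chosen
once for adequate signal-to-noise of each qualitative effect at desk scale;
the corresponding full-scale settings are the package defaults noted above.

## Known limitations

* The critical-point estimate is a grid argmax of a noisy variance curve;
  on the broad positive branch it wanders by a few grid steps between
  ensembles at desk scale.
* Attractor labels are activity-based and can alias long state cycles;
  periods above W/2 are indistinguishable from irregularity.
* The BiEntropy binarization rule (threshold at the time mean) is a
  reasoned parameter-free choice, not the only possible one; ordered and
  disordered extremes are insensitive to it, the transition region less so.
* The printed closed form for the balance in terms of the error function
  requires the √2 normalization of the Gaussian CDF (b = erf(1/(√2 σ*)));
  the implementation uses the normal CDF directly and reports both the
  analytic and the counted balance so the two can always be compared.
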