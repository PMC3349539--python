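# Methods

## Circuit model

The FFL is modelled as a two-variable ODE system for the intermediate
regulator Y and the output Z, with the signal protein X treated as an
external step: X = 0 before input onset, X = x_active (constant)
afterwards.  X carries no dynamics of its own — the model describes
activation of pre-existing inactive protein, not X expression.  Both
genes follow quasi-equilibrium transcription kinetics: production is a
ratio of regulated to basal occupancy with binding equilibria ω and fold
changes α/β, degradation is linear.  Because Z feeds back on nothing and
Y depends only on X, the circuit is a cascade: for any constant X the
fixed point is unique and available in closed form, which `steady_state`
uses directly (with a residual check at 1e−9 relative to the production
scale).  There is no multistability in this model class; the forward
trajectory from the pre-input state always reaches the unique post-input
state.

Integration uses `scipy.integrate.solve_ivp` with LSODA (the
degradation-rate prior spans four decades, so stiffness ratios up to
~1e4 occur), rtol 1e−8 / atol 1e−10, over a horizon of 20 slowest
relaxation times max(1/δ_y, 1/δ_z), sampled on 2000 points so that
extremum detection in the classifier is grid-robust.  All tolerances and
the horizon are keyword-configurable.

## Response classification

A trajectory is compared against a tolerance band of half-width
rel_tol·z0 (default rel_tol = 0.01) around the pre-input level z0:

* **no-response** — the curve never leaves the band and the post-input
  level z∞ lies inside it;
* **grader (G±)** — the curve's excursion beyond the envelope
  [min(z0, z∞), max(z0, z∞)] never exceeds rel_tol·|z∞ − z0|
  (monotone up to solver ripple); sign from z∞ − z0;
* **pulser (P±T±)** — otherwise; initial-slope sign from the first
  departure beyond the band, target sign from z∞ versus the band.

Near-perfect adaptation (a clear pulse whose endpoint re-enters the
band) is resolved by the strict side of z0 the endpoint lies on; an
exactly tied endpoint is reported `ambiguous`.  Both `no-response` and
`ambiguous` are excluded from probability counts and their frequency is
always reported — the six-class normalization of the reference table
implies the same convention.  Classification is exactly invariant under
rescaling of concentration and time units, since every threshold is
relative.

## Parameter prior

No published parameter ranges exist for the analytic treatment that
produced the reference probability table, so the Monte-Carlo estimator
is a reproduction apparatus with qualitative expectations only, and the
packaged table remains the authoritative input for downstream
statistics.  Defaults: rates (γ, δ) and binding constants ω log-uniform
on [0.01, 100]; x_active log-uniform on [0.1, 10]; regulation factors
log-uniform on [1, 50] (activation) or [1/50, 1] (inhibition);
multimerization degrees n, m uniform on {1, …, 4}.  The joint factor
β^xy is drawn with the product sign of β^x and β^y, so joint regulation
is coherent with the two single-input signs rather than forming an
independent fourth edge.  Sampling uses one master `SeedSequence` with
per-motif child seeds, so any motif's draw is independent of which other
motifs are run.

## Shape statistics

Kurtosis uses the bias-corrected sample estimator with n = 6 and the
n−1 standard deviation (this is also scipy's `kurtosis(..., bias=False)`,
which serves as the independent cross-check in the tests).  The one-hot
row evaluates to exactly 6.  The uniform row has zero variance; its
value is defined by the symmetric-perturbation limit, which for n = 6
gives exactly −10/3.  That exact value is stored (so K₀ = 4/3); the
commonly printed −3.33 is its rounding.  Note the estimator is
standardized and therefore *discontinuous* at the uniform point: rows
merely near uniform can take any kurtosis in the admissible interval
[−10/3, 6], and only the exactly uniform row takes the limit value.

ψ = |K| − K₀ may be negative (|K| below the midpoint); ρ is computed
only when every ψ is strictly positive, since the inverse is otherwise
undefined — `score_table` raises in that case rather than silently
clamping.  All eight reference rows have ψ > 0.  Entropy uses base-2
logarithms with 0·log 0 = 0.

## Mutation protocol

A mutation changes exactly one of the fifteen circuit parameters,
chosen uniformly.  Positive parameters are multiplied by exp(ε), ε
uniform on ±kernel_scale·ln 10 (default scale 1 — mutations span two
decades, "numerically small or large"), resampled to stay inside the
prior range; regulation factors additionally stay on their side of 1,
so the motif topology is never changed.  Integer degrees n, m step ±1
within {1, …, 4}, gated by min(1, kernel_scale) so a vanishing kernel
leaves every parameter untouched (all transition mass then falls on the
diagonal and E = 0, a limit the tests assert).

Single regime: every round mutates the *original* circuit and reverts —
independent single-step trials.  Accumulated regime: mutations persist
and each round bins (previous class → new class).  Mutants that leave
the six classes (no response) are skipped, reverted and logged, never
binned.  Iteration stops at max_rounds or once no bin frequency moves
more than 1e−3 over a 500-round window.  Counts are normalized by total
binned events, so the 36 entries are joint frequencies summing to 1.

The reference transition matrices were derived from qualitative
(nullcline-geometry) mutations in the analytic formalism, not from
parameter perturbation; simulated matrices are therefore compared to
them only structurally (diagonal dominance, determinism, limits), never
entry-by-entry, and the packaged tables are the quantitative source for
robustness and evolvability.  One printed block (C3, single mutations)
totals 1.106 rather than ≈ 1; it is kept verbatim, and validation bounds
accommodate it.

## Synthetic data

Random probability tables draw rows from a symmetric Dirichlet whose
concentration tunes peakedness (small → one-hot-like, large → uniform).
Synthetic abundance vectors mix the standardized score vector with an
exactly orthogonalized noise vector at the target correlation, then
shift/scale onto the simplex; since Pearson correlation is affine-
invariant, the achieved r equals the target exactly, making recovery
checks sharp.  Toy trajectories superpose an exponential relaxation
with an early bump of controlled sign and amplitude, so the class label
is known by construction.  None of these emulate real transcription
networks: passing tests demonstrate internal consistency of the
pipeline, not agreement with any organism's motif census.  The packaged
abundance fixture is an approximate, figure-derived stand-in (marked
`synthetic` in its filename and sources) used only for ranking checks;
quantitative abundance comparisons require user-supplied counts.

## Problem sizes

The convergence check estimates the landscape at 250/500/1000 parameter
sets per motif (14,000 simulations, ~90 s on one core) — sufficient for
the total-variation distance between successive doublings to shrink
clearly.  Classifier–generator agreement uses 10,000 toy trajectories.
Simulated transition matrices in the test suite and analysis drivers use
tens of circuits and tens of rounds; the mutation-protocol defaults
(1000 circuits per motif, up to 10,000 rounds) remain available through
`MutationConfig` for full-scale runs.

## Known limitations

* The Monte-Carlo landscape depends on the prior; with the default
  broad prior the modal class matches the reference table for most but
  not all motifs, and no attempt is made to fit the prior to the table.
* Parameter-level mutation cannot distinguish the two kinds of neutral
  change (invisible vs visible to the qualitative backbone), so
  simulated diagonals are systematically inflated relative to the
  reference matrices.
* Single isolated motifs only: no embedding in larger networks, no
  stochastic gene expression, no X dynamics.
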