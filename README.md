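# fflscape

Why are some feed-forward loop (FFL) motifs so much more common than others
in transcription networks?  `fflscape` is an analysis package for systems
biologists studying that question through the motif-function landscape: it
simulates the step response of all eight FFL sign topologies (C1–C4
coherent, I1–I4 incoherent) with a two-ODE gene-regulation model,
classifies each response into one of six qualitative dynamical classes,
and derives per-motif statistics — functional plasticity, predicted
abundance, mutational robustness and evolvability — that together
reconstruct the natural abundance bias toward C1 and I1.

## The model and statistics

An FFL couples a signal protein X to a target gene G_Z directly and
through an intermediate regulator Y.  With X an external step input
(0 before onset, constant x_active after), the circuit dynamics are

    dY/dt = γ_Y (1 + α^x ω_yx Xⁿ) / (1 + ω_yx Xⁿ) − δ_y Y
    dZ/dt = γ_Z (1 + β^x ω_zx Xⁿ + β^y ω_zy Yᵐ + β^xy ω_zxy Xⁿ Yᵐ)
                / (1 + ω_zx Xⁿ + ω_zy Yᵐ + ω_zxy Xⁿ Yᵐ) − δ_z Z

where γ are basal production rates, ω binding equilibria, δ degradation
rates, n, m multimerization degrees, and the regulation factors α^x, β^x,
β^y, β^xy are fold changes (> 1 activation, < 1 inhibition) fixing the
motif's edge signs.  The output time course Z(t) is classified as a
*grader* (monotone approach to the new steady state; G+ or G−) or a
*pulser* (transient excursion; P±T± by initial-slope and final-target
sign), giving six classes φ_j.

For each motif Γ_i the conditional probabilities P(φ_j | Γ_i) form a
6-class distribution whose shape is summarized by the bias-corrected
sample kurtosis K (one-hot row: K = 6, maximal specialization; uniform
row: K = −10/3, maximal flexibility) and by Shannon entropy H.
Plasticity and predicted abundance are

    ψ(Γ_i) = |K(Γ_i)| − K₀,   K₀ = (6 − 10/3)/2 = 4/3
    ρ(Γ_i) = ψ(Γ_i)⁻¹ / Σ_j ψ(Γ_j)⁻¹

so motifs balanced between specialization and flexibility (small ψ) are
predicted common.  Mutational transition matrices Ω (class-before ×
class-after frequencies under single vs accumulated single-parameter
mutations) give robustness R = tr Ω and evolvability

    E = 1 − R_accumulated / R_single.

The package ships the reference conditional-probability table, per-motif
score table and all sixteen transition matrices as machine-readable CSV
fixtures, plus generators for synthetic test inputs (random simplex
tables, abundance vectors at a controlled Pearson correlation, toy
trajectories with known class).

## Worked example

Running the numbered analysis stages

    python analysis/01_landscape.py
    python analysis/02_plasticity.py
    python analysis/03_evolvability.py
    python analysis/04_compare.py

produces, from the reference landscape (stage 2):

    motif  kurtosis  entropy_bits     psi     rho
    C1       1.6305        1.8748  0.2972  0.3425
    I1      -1.7214        1.9242  0.3880  0.2623
    ...
    predicted most abundant motifs: C1, I1 (rho = 0.342, 0.262)

— the two motifs with near-balanced kurtosis carry the highest predicted
abundance, matching the dominance of C1 and I1 in real transcription
networks.  Stage 3 computes robustness and evolvability per motif
(all single-mutation robustness values ≥ 0.82; E largest for I1 at 0.413
and C1 at 0.315), and stage 4 reports the headline anticorrelation

    evolvability vs plasticity: r = -0.917

i.e. the motifs with balanced plasticity are precisely the ones whose
function drifts most readily under accumulated mutations.  The same
stages accept user-supplied probability tables and abundance CSVs
(columns `motif,abundance,source`) through the `fflscape` command-line
interface (`fflscape landscape | stats | evolvability | compare |
fixtures`).

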