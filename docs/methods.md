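# Methods

This note documents the models implemented in cimkit, the conventions and
parameter choices they depend on, what the synthetic generators do and do
not emulate, and the limitations a user should know before extrapolating
from passing tests to real hardware or real data.

## Ising and QUBO conventions

The Ising energy is `H(σ) = −Σ_{i<j} J_ij σ_i σ_j − Σ_i h_i σ_i + offset`,
with each unordered pair counted **once** and `J` stored symmetric with a
zero diagonal. Double-counting conventions differ across the literature;
since every benchmark here depends only on the argmin, the choice is pure
bookkeeping, but it is fixed and enforced so energies are reproducible.

The binary/spin map is `x = (1+σ)/2` (σ=+1 ⇔ x=1). QUBO → Ising conversion
is exact on every assignment: quadratic terms land in `J`, linear terms in
`h`, constants in `offset`. The machine Hamiltonian itself carries no field
term, so `ising_with_fields_to_fieldless` absorbs `h` into one ancilla spin
coupled by `J[anc][i] = h_i`; the σ → −σ gauge maps the ancilla-down sector
onto the ancilla-up sector, so optima are preserved and solutions are read
out after flipping the configuration to make the ancilla +1.

Max-Cut uses `J = −w`. The auditable identity `cut = (W_total − H)/2` holds
for every configuration and is property-tested.

## The measurement-feedback CIM model

The simulator is a discrete round-trip mean-field model of a
measurement-feedback CIM. Per round trip t:

    σ(t)  = sign(c(t))                      (tie at 0 reads +1)
    f     = r · J σ(t)                      (feedback from the digitized readout)
    c(t+1)= clip( c(t) + dt·[(p(t)−1)c(t) − c(t)³] + f + η ),  η ~ N(0, noise²)

with a linear pump ramp `p(t)` from `pump_start` to `pump_end` (threshold at
1) and initial amplitudes drawn from the same noise distribution. Feedback
is computed from the sign readout, not the raw amplitudes, mirroring the
digital measurement-and-feedback loop of the hardware. The sign of the
feedback is fixed to be the descent direction of the energy above; with the
Max-Cut encoding `J = −w` this reproduces the conventional hardware formula
`f_i = −r Σ_j w_ij σ_j` literally.

### Schedule parameters

All knobs live in `CIMSchedule`, with defaults in
`cimkit/data/default_schedule.yaml` (dimensionless units; one round trip is
the time unit):

| parameter      | default | meaning |
|----------------|---------|---------|
| rounds         | 1000    | round trips per trajectory |
| pump_start/end | 0.5→1.5 | linear pump ramp through threshold |
| feedback_gain r| 0.1     | coupling strength of the injected feedback |
| noise          | 0.3     | per-round Gaussian amplitude noise (std) |
| dt             | 0.4     | integration step of the gain/saturation terms |
| clip           | 0.6     | amplitude saturation bound |

The defaults are a single calibrated operating point used by every benchmark
in the package. They were chosen, once, to satisfy two competing demands:
high success on the structured Möbius-ladder family (which favours weak
amplitude inertia, i.e. small `clip/r`, and substantial noise so that
domain walls keep moving) and exact-optimum recovery on small dense random
graphs (which favours enough inertia to de-synchronize the parallel spin
updates). At this point the simulator reaches the optimum of the V = 20/40/
60/80/100 Möbius ladders in ≈ 100/100/100/90/77 % of 100 seeded
trajectories and matches the enumerated optimum on 20/20 random V ≤ 16
Max-Cut instances (best of 10 seeds). Success is always scored on the best
readout over the whole trajectory.

Determinism: a trajectory is a pure function of (problem, schedule, seed);
per-run seeds in multi-run harnesses are spawned from a master seed via
`numpy.random.SeedSequence`.

### First-passage behaviour and a known limitation

On Möbius ladders the optimum configuration consists of an alternating
pattern with two antipodal domain walls. In this discrete mean-field model
the walls produced by the initial transient move by noise-activated,
essentially diffusive hops, so the first round trip at which the optimum is
reached grows quickly with V: at V = 100 the median first-passage time of
successful trajectories is a few hundred round trips. Hardware CIMs are
reported to converge within tens of circulations; that behaviour arises
from analog in-cavity dynamics that the digitized mean-field update does
not capture. Schedules that force very fast convergence (strong quench)
collapse the success rate to a few percent, so the package ships the
high-success operating point and reports first-passage statistics honestly.
No schedule found in an extensive search of this model family achieves both
the hardware-level success rates and tens-of-round convergence at V = 100.

### Simulated-annealing baseline

`run_sa` is single-flip Metropolis with a geometric inverse-temperature
ladder (`beta_start` → `beta_end`, default 0.1 → 10), N proposed flips per
sweep at uniformly random sites, and elitist bookkeeping. It is a baseline,
not a tuned competitor.

## DOPO master equation and Wigner analysis

The single-DOPO model (pump adiabatically eliminated) is

    dρ/dt = (S/2)[a†² − a², ρ] + ( γ_s [a, ρ a†] + (B/2)[a², ρ a†²] + h.c. )

with squeezing rate `S = κF/γ_p`, signal damping γ_s (normalized to 1 as
the time unit in all sweeps, so S is the only swept knob) and two-photon
loss B. B is required for a bounded steady state above threshold
(S > γ_s); it is exposed as an explicit parameter with default
`B = κ²/(2γ_p)`, the standard adiabatic-elimination value, and the
figure-style sweeps use B = 0.1 so the lobes are well separated.

Numerics: the Liouvillian is assembled from sparse Kronecker products
acting on the row-major vectorization of ρ and is exactly trace preserving
by construction (each dissipator uses the same truncated jump operator in
both its sandwich and anticommutator parts). The steady state solves
`L ρ = 0` with the ρ₀₀ equation replaced by the trace constraint, followed
by Hermitization, normalization, a residual check (‖Lρ‖ ≤ 1e−8) and a tail
check (population in the top two Fock levels ≤ 1e−6, warning or error on
request). The default truncation n_max = 40 covers S ≤ 2 at B ≥ 0.1
(⟨n⟩ ≈ 10 at S = 2, B = 0.1); doubling n_max changes ⟨n⟩ by < 1e−6 at the
tested operating points. Because the generator couples only Fock elements
with the same parity of m − n, the steady state is block diagonal in photon
parity; this is asserted, not assumed.

The Wigner function uses the convention `x = (a+a†)/√2` (vacuum peak 1/π,
symmetric ground-state lobes on the x axis) and is evaluated from the
Laguerre-polynomial expansion of the displaced-parity kernel, with log-space
prefactors for numerical stability at large n. Lobe separation is the
distance between the two highest strict local maxima on a grid whose
half-width scales with `4·sqrt(⟨n⟩+1)` (minimum 6); unimodal states report
separation 0. At γ_s = 1 the state is unimodal at S = 1 (threshold) and
bimodal above, with separation increasing in S and decreasing in γ_s.

## Docking QUBO

Variables `x_ij` (atom i on grid point j, atom-major flattening). The
objective adds caller-supplied matching energies `w_ij` on the diagonal and
two penalty families over **all unordered variable pairs**: `K_dist` when
both atoms are distinct and the intra-ligand distance differs from the
grid-pair distance by more than ε (default 0.5 Å, configurable), and
`K_mono` when a pair reuses an atom or a grid point. Restricting the pair
sums to `l > j`, as sometimes written, would silently drop the `j = l`
monogamy pairs ("one atom per grid point"); the implementation sums over
all pairs and documents this as a deliberate correction. Scoring functions
are out of scope by design: `w` is an input, and the synthetic fixture
plants `w = −1` on the true atom-site pairs with penalties
`K = 2Σ|w| + 1`, which makes every ground state constraint-feasible and the
planted matching optimal (verified by enumeration up to 20 variables at
build time). Decoded poses are never repaired: infeasible solutions come
back with an explicit violation list so solver quality stays measurable.

RMSD is computed in the receptor frame with no superposition, as is
standard for docking; mRMSD is the minimum over feasible, fully assigned
poses, with the accepted/not-accepted verdict at 2 Å.

What the fixture does **not** emulate: real scoring-function landscapes
(the planted `w` is binary), receptor flexibility, ligand torsions, and the
pose multiplicity of real grids. Passing the end-to-end fixture test shows
the encoding, solver plumbing and decoding are correct — not that the
package docks real ligands.

## Feature-selection QUBO

Relevance `ρV_j` defaults to the Pearson correlation of feature j with the
binary label (the relevance function is pluggable); redundancy `ρ_jk` is
the feature-feature Pearson matrix, with zero-variance features treated as
uncorrelated (warned). The ordered double sum in the objective counts every
unordered pair twice, so the QUBO carries pair coefficients
`2(1−α)|ρ_jk|`; objective values therefore match the formula as written.
Limiting cases are exact: α = 1 selects every feature with nonzero
relevance; α = 0 has optimum value 0 (any pairwise-uncorrelated subset,
including the empty set). Problems with n ≤ 20 are solved by vectorized
enumeration; larger ones (or `force_cim=True`) go through the QUBO → Ising
→ ancilla → CIM path.

No classifier is trained: KS statistics are computed on a z-scored,
relevance-weighted linear score over the selected features, with an obvious
hook for plugging in an external model. The synthetic table draws
independent standard-normal informative features, a logistic label model
(effect 1.5 per informative feature, scaled by √n_inf), redundant features
as correlation-0.95 noisy copies, and independent noise features. It does
not emulate real credit data: no mixed types, no missingness, no class
imbalance, no nonlinear feature-label structure. The redundancy-removal
property (intermediate α keeps ≥ 80 % of informative features on average
while removing ≥ half of the redundant copies) is tested at α = 0.85 with
1000-sample tables, where relevance estimates are accurate enough to
separate originals from their noisy copies.

## Benchmark harness

Möbius benchmarks use exhaustive references for V ≤ 20 and the closed-form
family optimum otherwise; the closed form is itself cross-validated against
enumeration for V ≤ 20 in the test suite. Random-graph benchmarks use
exhaustive references up to V = 24 and accept caller-supplied optima above
that (the original large-graph references came from an external exact
solver and are out of desk scale here). A run counts toward the x %-of-
optimum tier when its cut is ≥ ceil(x · GS) — the strictest reading of "x %
of the optimum or higher" on integer cuts. Success-rate uncertainty is the
exact Clopper–Pearson interval. Every report embeds the full configuration,
the master seed and a SHA-256 configuration hash; identical configurations
produce bit-identical reports.

Problem sizes in the shipped tests (100-trajectory benchmarks at
V ≤ 100, 20-instance oracle suites at V ≤ 16, feature tables with ≤ 16
features, docking fixtures with ≤ 20 QUBO variables) were chosen so the
whole suite exercises every claim with exact references where exactness is
asserted.
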