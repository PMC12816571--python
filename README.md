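# cimkit

A simulation and application toolkit for **coherent Ising machines** (CIMs):
optical networks of degenerate optical parametric oscillator (DOPO) pulses
whose minimum-loss oscillation pattern encodes the ground state of an Ising
Hamiltonian. The package is aimed at people studying CIM-style heuristics for
combinatorial optimization — Max-Cut benchmarking, QUBO applications in
molecular docking and feature selection — and at people who want the
single-DOPO quantum optics (master equation, Wigner function) that underpins
the spin encoding.

## What is inside

**Problem core** (`cimkit.problems`, `cimkit.io`, `cimkit.graphs`). Ising
problems `H(σ) = −Σ_{i<j} J_ij σ_i σ_j − Σ_i h_i σ_i + offset` over spins
σ ∈ {±1}, QUBO objectives `Σ_{j≤k} Q_jk x_j x_k + offset` over bits, and
weighted graphs for Max-Cut (encoded with `J = −w` so that minimum energy ⇔
maximum cut, with the identity `cut = (W_total − H)/2`). Exact conversions
(QUBO ↔ Ising via `x = (1+σ)/2`, field absorption into an ancilla spin),
exhaustive ground-state oracles up to 24 spins, and rudy-style edge-list /
sparse QUBO text formats. Graph families: Möbius ladders (cycle plus
antipodal chords; known optimal cuts `3V/2` or `3V/2 − 2`) and uniform
G(V, m) random graphs parameterized by edge density `d = 2|E|/V(V−1)`.

**CIM simulator** (`cimkit.cim`). A mean-field, measurement-feedback
round-trip model: each spin is the in-phase amplitude `c_i` of a DOPO pulse,

    c_i ← clip( c_i + dt·[(p(t) − 1) c_i − c_i³] + r·Σ_j J_ij σ_j + η_i ),

with digitized readout `σ = sign(c)`, Gaussian injection noise η, and a pump
`p(t)` ramped linearly through the oscillation threshold. With the Max-Cut
encoding `J = −w` the feedback term is exactly the hardware formula
`f_i = −r Σ_j w_ij σ_j`. A simulated-annealing baseline and a seeded
success-rate harness with exact binomial confidence intervals are included.

**DOPO quantum model** (`cimkit.dopo`). The Lindblad master equation of a
single DOPO signal mode with squeezing rate `S = κF/γ_p`, linear damping γ_s
and two-photon loss B, built as a sparse Liouvillian in a truncated Fock
space; steady states, Wigner functions, and the bimodality (lobe-separation)
analysis showing how the 0/π phase states separate as S grows.

**Applications** (`cimkit.docking`, `cimkit.features`). Molecular-docking
pose sampling as an atom-to-grid matching QUBO (distance-legality and
monogamy penalty terms, pose decoding with explicit feasibility reports,
RMSD/mRMSD evaluation with the standard 2 Å acceptance threshold), and
correlation-based feature selection
`f(x) = −(α Σ x_j|ρV_j| − (1−α) Σ_{k≠j} x_j x_k |ρ_jk|)` with Kolmogorov–
Smirnov evaluation of class separation. Both ship planted synthetic
generators so everything is testable end to end without external data.

**Workbench** (`cimkit.workbench`, `cimkit.cli`). Benchmark harnesses and a
`cimkit` command with verbs `gen-graph`, `solve-maxcut`, `solve-qubo`,
`dock`, `select-features`, `dopo-wigner`, `benchmark-mobius`,
`benchmark-random`; every report embeds its seed and configuration hash.

## Worked example

```python
from cimkit import mobius_ladder, maxcut_to_ising, CIMSchedule, run_cim

g = mobius_ladder(20)                      # 30 edges, optimal cut 28
p = maxcut_to_ising(g)
traj = run_cim(p, CIMSchedule.default(), seed=42)
cut = (g.total_weight - traj.best_energy) / 2
print(traj.best_energy, cut)               # -26.0 28.0
```

The trajectory's best readout has Ising energy −26; through the cut identity
that is a cut of (30 − (−26))/2 = 28 edges — the known optimum for the
20-vertex Möbius ladder.

The benchmark harness prints the success-rate table with exact binomial
confidence intervals and the median round trip at which successful runs
first reach the optimum:

```
$ cimkit benchmark-mobius --sizes 20,40 --runs 20 --seed 0
    V  opt cut   success            95% CI  med rounds
   20       28   100.0%     [0.832,1.000]        12.0
   40       58   100.0%     [0.832,1.000]        59.5
config hash: 4b904cbfeff9d3ae
```

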