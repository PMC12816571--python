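"""Software analogue of the measurement-feedback coherent Ising machine.

Each spin is the in-phase amplitude ``c_i`` of a DOPO pulse. One cavity round
trip applies a discretized gain/saturation step, the measured-spin feedback
injection, and Gaussian noise:

    c_i <- clip( c_i + dt * [ (p(t) - 1) c_i - c_i^3 ] + f_i(sigma(t)) + eta_i )

with ``sigma(t) = sign(c(t))`` (tie at 0 read as +1), ``eta_i ~ N(0, noise^2)``
and the pump ``p(t)`` ramped linearly through the oscillation threshold at 1.
The feedback injection is

    f_i = r * sum_j J_ij sigma_j

i.e. the descent direction on the Ising energy ``-sum_{i<j} J_ij s_i s_j``.
With the Max-Cut encoding ``J = -w`` this is exactly the hardware formula
``f_i = -r sum_j w_ij sigma_j``. Feedback is computed from the digitized sign
readout, mirroring the measurement-and-feedback FPGA loop, not from the raw
amplitudes.

A simulated-annealing baseline (single-flip Metropolis, geometric inverse-
temperature ladder) and a seeded success-rate harness with exact binomial
confidence intervals complete the benchmarking surface.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml
from scipy.stats import binomtest

from .problems import IsingProblem, ising_energy

__all__ = [
    "CIMSchedule",
    "Trajectory",
    "feedback_signal",
    "run_cim",
    "run_sa",
    "success_rate",
    "SuccessRate",
]


def _default_schedule_params() -> dict:
    text = (
        importlib.resources.files("cimkit") / "data" / "default_schedule.yaml"
    ).read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class CIMSchedule:
    """Round-trip schedule of the simulated CIM.

    Defaults live in ``cimkit/data/default_schedule.yaml``; they are the
    calibrated operating point used by every benchmark in this package.
    """

    rounds: int = 1000
    pump_start: float = 0.5
    pump_end: float = 1.5
    feedback_gain: float = 0.1
    noise: float = 0.3
    dt: float = 0.4
    clip: float = 0.6
    seed: int | None = None

    def __post_init__(self):
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.clip <= 0:
            raise ValueError("clip must be positive")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")

    @classmethod
    def default(cls, **overrides) -> "CIMSchedule":
        """Schedule from the packaged YAML defaults, with keyword overrides."""
        params = _default_schedule_params()
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path) -> "CIMSchedule":
        with open(path) as fh:
            params = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(params) - known
        if unknown:
            raise ValueError(f"unknown schedule keys: {sorted(unknown)}")
        return cls(**params)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_seed(self, seed) -> "CIMSchedule":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class Trajectory:
    """Per-round-trip record of one CIM run."""

    amplitudes: np.ndarray  # (rounds, N) in-phase components
    spins: np.ndarray  # (rounds, N) sign readout, int8
    energies: np.ndarray  # (rounds,) Ising energy of the readout
    best_energy: float
    best_spins: np.ndarray
    rounds_to_ground: int | None  # first round reaching the reference, if given

    @property
    def rounds(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def N(self) -> int:
        return self.amplitudes.shape[1]


def feedback_signal(p: IsingProblem, spins, r: float) -> np.ndarray:
    """Feedback injection ``f = r * J @ sigma`` (descent direction on the energy)."""
    s = np.asarray(spins, dtype=float)
    if s.shape != (p.N,):
        raise ValueError(f"expected {p.N} spins, got shape {s.shape}")
    return r * (p.J @ s)


def _readout(c: np.ndarray) -> np.ndarray:
    """Digitize amplitudes to spins; the tie at exactly zero reads +1."""
    return np.where(c >= 0, 1, -1).astype(np.int8)


def run_cim(
    p: IsingProblem,
    schedule: CIMSchedule | None = None,
    seed=None,
    reference_energy: float | None = None,
) -> Trajectory:
    """Simulate one CIM trajectory; deterministic given (problem, schedule, seed).

    The machine Hamiltonian carries no field term: problems with local fields
    must be reduced with :func:`cimkit.problems.ising_with_fields_to_fieldless`
    first.
    """
    if p.has_fields:
        raise ValueError(
            "run_cim requires a fieldless problem; apply "
            "ising_with_fields_to_fieldless first"
        )
    s = schedule or CIMSchedule.default()
    rng = np.random.default_rng(seed if seed is not None else s.seed)
    N, T = p.N, s.rounds
    J = np.ascontiguousarray(p.J)
    pump = np.linspace(s.pump_start, s.pump_end, T)
    c = rng.normal(0.0, s.noise, size=N)

    amplitudes = np.empty((T, N))
    spins = np.empty((T, N), dtype=np.int8)
    energies = np.empty(T)
    best_energy = np.inf
    best_spins = None
    rounds_to_ground = None

    for t in range(T):
        sigma = _readout(c)
        f = s.feedback_gain * (J @ sigma)
        eta = rng.normal(0.0, s.noise, size=N)
        c = c + s.dt * ((pump[t] - 1.0) * c - c**3) + f + eta
        np.clip(c, -s.clip, s.clip, out=c)
        if not np.all(np.isfinite(c)):
            raise FloatingPointError(f"non-finite amplitude at round {t}")
        sigma = _readout(c)
        e = float(-0.5 * sigma @ J @ sigma + p.offset)
        amplitudes[t] = c
        spins[t] = sigma
        energies[t] = e
        if e < best_energy:
            best_energy = e
            best_spins = sigma.copy()
        if (
            rounds_to_ground is None
            and reference_energy is not None
            and e <= reference_energy + 1e-9
        ):
            rounds_to_ground = t
    return Trajectory(
        amplitudes=amplitudes,
        spins=spins,
        energies=energies,
        best_energy=best_energy,
        best_spins=best_spins,
        rounds_to_ground=rounds_to_ground,
    )


def run_sa(
    p: IsingProblem,
    sweeps: int = 1000,
    beta_start: float = 0.1,
    beta_end: float = 10.0,
    seed=None,
):
    """Single-flip Metropolis annealing with a geometric beta ladder.

    Returns ``(best_spins, best_energy)``; bookkeeping is elitist, so the
    result never exceeds the energy of the initial random configuration.
    """
    rng = np.random.default_rng(seed)
    N = p.N
    s = rng.choice([-1, 1], size=N).astype(np.int8)
    betas = np.geomspace(beta_start, beta_end, sweeps)
    energy = ising_energy(p, s)
    best_energy, best_s = energy, s.copy()
    local = p.J @ s.astype(float) + p.h  # effective field at each site
    for beta in betas:
        sites = rng.integers(0, N, size=N)
        u = rng.random(N)
        for i, ui in zip(sites, u):
            dE = 2.0 * s[i] * local[i]
            if dE <= 0 or ui < np.exp(-beta * dE):
                s[i] = -s[i]
                energy += dE
                local += 2.0 * s[i] * p.J[:, i]
                if energy < best_energy:
                    best_energy = energy
                    best_s = s.copy()
    return best_s, float(best_energy)


@dataclass(frozen=True)
class SuccessRate:
    """Success fraction over independent runs with an exact binomial CI."""

    successes: int
    runs: int
    ci_low: float
    ci_high: float
    rounds_to_ground: tuple = field(default_factory=tuple)

    @property
    def rate(self) -> float:
        return self.successes / self.runs


def success_rate(
    p: IsingProblem,
    schedule: CIMSchedule,
    runs: int,
    reference_energy: float,
    master_seed: int = 0,
    ci_level: float = 0.95,
) -> SuccessRate:
    """Fraction of seeded trajectories whose best energy reaches the reference.

    Per-run seeds are spawned from the master seed; ``rounds_to_ground``
    collects, for successful runs, the first round-trip index attaining the
    reference energy.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(runs)
    successes = 0
    rtg = []
    for child in children:
        traj = run_cim(p, schedule, seed=child, reference_energy=reference_energy)
        if traj.best_energy <= reference_energy + 1e-9:
            successes += 1
            rtg.append(traj.rounds_to_ground)
    ci = binomtest(successes, runs).proportion_ci(
        confidence_level=ci_level, method="exact"
    )
    return SuccessRate(
        successes=successes,
        runs=runs,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        rounds_to_ground=tuple(rtg),
    )
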