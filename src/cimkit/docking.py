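"""Molecular-docking pose sampling as an atom-to-grid-point matching QUBO.

A ligand of ``n`` atoms is matched to ``N`` candidate lattice points in the
receptor frame. Binary variable ``x_ij`` says atom ``i`` sits on grid point
``j``; the objective is

    H = sum_ij w_ij x_ij
        + K_dist * sum_{(ij)<(kl)} u_ijkl x_ij x_kl
        + K_mono * sum_{(ij)<(kl)} v_ijkl x_ij x_kl

where ``u_ijkl = 1`` iff ``i != k`` and the intra-ligand distance
``|a_i - a_k|`` differs from the grid distance ``|g_j - g_l|`` by more than
``epsilon`` (geometric legality), and ``v_ijkl = 1`` iff the pair reuses an
atom or a grid point (monogamy). Quadratic sums run over all unordered
variable pairs; this corrects the printed index range ``l = j+1..N``, which
would miss the ``j = l`` monogamy pairs needed for "at most one atom per
grid point". The matching-energy matrix ``w`` is caller-supplied (scoring
functions are out of scope); fixtures plant a known pose.

Pose quality is the root-mean-square deviation against the crystal
coordinates, with no superposition step — both poses live in the receptor
frame. The minimum RMSD over sampled poses (mRMSD) below 2 Angstrom is the
standard acceptance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .problems import QUBOProblem, brute_force_qubo, qubo_energy

__all__ = [
    "DockingProblem",
    "Pose",
    "build_docking_qubo",
    "decode_pose",
    "rmsd",
    "mrmsd",
    "MRMSDResult",
    "synth_docking_fixture",
    "read_xyz",
    "write_xyz",
    "read_pdb_coordinates",
]


@dataclass(frozen=True)
class DockingProblem:
    """Atoms, candidate grid points, matching energies and penalty constants."""

    atoms: np.ndarray  # (n, 3) ligand coordinates, Angstrom
    grid: np.ndarray  # (N, 3) lattice-point coordinates, Angstrom
    w: np.ndarray  # (n, N) matching energy coefficients
    K_dist: float = 10.0
    K_mono: float = 10.0
    epsilon: float = 0.5

    def __post_init__(self):
        atoms = np.atleast_2d(np.asarray(self.atoms, dtype=float))
        grid = np.atleast_2d(np.asarray(self.grid, dtype=float))
        w = np.atleast_2d(np.asarray(self.w, dtype=float))
        if atoms.shape[1] != 3 or grid.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3) arrays")
        if not (np.all(np.isfinite(atoms)) and np.all(np.isfinite(grid))):
            raise ValueError("coordinates must be finite")
        n, N = atoms.shape[0], grid.shape[0]
        if n < 1 or N < n:
            raise ValueError("need n >= 1 atoms and N >= n grid points")
        if w.shape != (n, N):
            raise ValueError(f"w must have shape ({n}, {N})")
        if self.epsilon <= 0 or self.K_dist <= 0 or self.K_mono <= 0:
            raise ValueError("epsilon and penalties must be positive")
        gd = cdist(grid, grid)
        if np.any(gd[np.triu_indices(N, 1)] < 1e-9):
            warnings.warn("duplicate grid coordinates: degenerate distances", stacklevel=2)
        for name, val in (("atoms", atoms), ("grid", grid), ("w", w)):
            val = val.copy()
            val.flags.writeable = False
            object.__setattr__(self, name, val)

    @property
    def n(self) -> int:
        return self.atoms.shape[0]

    @property
    def N(self) -> int:
        return self.grid.shape[0]

    def var_index(self, i: int, j: int) -> int:
        """Flat QUBO index of x_ij (atom-major ordering)."""
        return i * self.N + j


@dataclass(frozen=True)
class Pose:
    """Decoded assignment with its feasibility report (no silent repair)."""

    assignment: dict  # atom index -> grid index
    coordinates: np.ndarray | None  # (n_assigned, 3) in atom-index order
    violations: tuple = field(default_factory=tuple)
    unassigned: tuple = field(default_factory=tuple)

    @property
    def feasible(self) -> bool:
        return not self.violations

    @property
    def complete(self) -> bool:
        return not self.unassigned


def build_docking_qubo(p: DockingProblem) -> QUBOProblem:
    """Assemble the matching QUBO over the n*N variables x_ij (atom-major)."""
    n, N = p.n, p.N
    nv = n * N
    Q = np.zeros((nv, nv))
    Q[np.arange(nv), np.arange(nv)] = p.w.reshape(-1)
    da = cdist(p.atoms, p.atoms)
    dg = cdist(p.grid, p.grid)
    for v1 in range(nv):
        i, j = divmod(v1, N)
        for v2 in range(v1 + 1, nv):
            k, l = divmod(v2, N)
            coeff = 0.0
            if i != k and abs(da[i, k] - dg[j, l]) > p.epsilon:
                coeff += p.K_dist
            if (i == k and j != l) or (j == l and i != k):
                coeff += p.K_mono
            if coeff:
                Q[v1, v2] = coeff
    return QUBOProblem(Q=Q)


def decode_pose(x, p: DockingProblem) -> Pose:
    """Map a QUBO assignment back to a pose, reporting every violated constraint."""
    x = np.asarray(x).reshape(-1)
    if x.shape[0] != p.n * p.N:
        raise ValueError(f"expected {p.n * p.N} variables, got {x.shape[0]}")
    bits = x.reshape(p.n, p.N)
    violations = []
    assignment = {}
    for i in range(p.n):
        sites = np.flatnonzero(bits[i])
        if len(sites) > 1:
            violations.append(f"atom {i} matched to {len(sites)} grid points")
        if len(sites) >= 1:
            assignment[i] = int(sites[0])
    for j in range(p.N):
        users = np.flatnonzero(bits[:, j])
        if len(users) > 1:
            violations.append(f"grid point {j} matched to {len(users)} atoms")
    da = cdist(p.atoms, p.atoms)
    dg = cdist(p.grid, p.grid)
    items = sorted(assignment.items())
    for ai, (i, j) in enumerate(items):
        for k, l in items[ai + 1 :]:
            if abs(da[i, k] - dg[j, l]) > p.epsilon:
                violations.append(
                    f"distance violation atoms ({i},{k}): "
                    f"|{da[i, k]:.3f} - {dg[j, l]:.3f}| > {p.epsilon}"
                )
    unassigned = tuple(i for i in range(p.n) if i not in assignment)
    coords = (
        np.array([p.grid[j] for _, j in items]) if items else None
    )
    return Pose(
        assignment=dict(items),
        coordinates=coords,
        violations=tuple(violations),
        unassigned=unassigned,
    )


def rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation of matched coordinate lists, no alignment."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass(frozen=True)
class MRMSDResult:
    """Minimum RMSD over feasible complete poses with the 2-Angstrom verdict."""

    mrmsd: float | None
    accepted: bool
    n_poses: int
    n_feasible: int

    @property
    def no_solution(self) -> bool:
        return self.mrmsd is None


ACCEPTANCE_RMSD = 2.0  # Angstrom


def mrmsd(poses, crystal) -> MRMSDResult:
    """Minimum RMSD of feasible, fully assigned poses against the crystal pose."""
    poses = list(poses)
    crystal = np.atleast_2d(np.asarray(crystal, dtype=float))
    values = []
    for pose in poses:
        if pose.feasible and pose.complete:
            values.append(rmsd(pose.coordinates, crystal))
    if not values:
        return MRMSDResult(mrmsd=None, accepted=False, n_poses=len(poses), n_feasible=0)
    best = min(values)
    return MRMSDResult(
        mrmsd=best,
        accepted=best < ACCEPTANCE_RMSD,
        n_poses=len(poses),
        n_feasible=len(values),
    )


def synth_docking_fixture(
    n_atoms: int,
    n_decoys: int,
    jitter: float = 0.0,
    seed=0,
    box: float = 6.0,
    min_sep: float = 1.2,
    verify: bool = True,
):
    """Planted docking problem: grid = (jittered) crystal sites plus decoys.

    ``w`` rewards each atom on its own crystal site with -1 (0 elsewhere),
    and penalties default to ``2 * sum|w| + 1`` so every ground state is
    constraint-feasible. For ``n_atoms * (n_atoms + n_decoys) <= 20`` the
    planted matching is verified to be the QUBO optimum by enumeration.

    Returns ``(problem, crystal_coordinates)``.
    """
    if n_atoms > 6:
        raise ValueError("fixture limited to n_atoms <= 6 for verifiability")
    rng = np.random.default_rng(seed)
    # rejection-sample ligand atoms with a minimum separation
    atoms = [rng.uniform(0, box, size=3)]
    while len(atoms) < n_atoms:
        cand = rng.uniform(0, box, size=3)
        if min(np.linalg.norm(cand - a) for a in atoms) >= min_sep:
            atoms.append(cand)
    atoms = np.array(atoms)
    sites = atoms + (rng.normal(0, jitter, size=atoms.shape) if jitter > 0 else 0.0)
    decoys = []
    while len(decoys) < n_decoys:
        cand = rng.uniform(-box, 2 * box, size=3)
        ref = np.vstack([sites] + ([np.array(decoys)] if decoys else []))
        if min(np.linalg.norm(cand - r) for r in ref) >= min_sep:
            decoys.append(cand)
    grid = np.vstack([sites] + ([np.array(decoys)] if decoys else []))
    n, N = n_atoms, grid.shape[0]
    w = np.zeros((n, N))
    w[np.arange(n), np.arange(n)] = -1.0
    K = 2.0 * np.abs(w).sum() + 1.0
    epsilon = max(0.5, 4.0 * jitter)
    problem = DockingProblem(atoms=atoms, grid=grid, w=w, K_dist=K, K_mono=K, epsilon=epsilon)
    if verify and n * N <= 20:
        q = build_docking_qubo(problem)
        planted = np.zeros(n * N, dtype=np.int8)
        planted[[problem.var_index(i, i) for i in range(n)]] = 1
        e_planted = qubo_energy(q, planted)
        best, _ = brute_force_qubo(q)
        if e_planted > best + 1e-9:
            raise RuntimeError("planted matching is not the QUBO ground state")
    return problem, atoms


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Read an XYZ file; returns (labels, (n, 3) coordinates)."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines()]
    if not lines:
        raise ValueError("empty XYZ file")
    count = int(lines[0].split()[0])
    rows = lines[2 : 2 + count]
    if len(rows) < count:
        raise ValueError(f"XYZ header declares {count} atoms, found {len(rows)}")
    labels, coords = [], []
    for ln in rows:
        tok = ln.split()
        labels.append(tok[0])
        coords.append([float(tok[1]), float(tok[2]), float(tok[3])])
    return labels, np.array(coords)


def write_xyz(path, labels, coords, comment: str = "") -> None:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    with open(path, "w") as fh:
        fh.write(f"{coords.shape[0]}\n{comment}\n")
        for lab, (x, y, z) in zip(labels, coords):
            fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def read_pdb_coordinates(path, hetatm: bool = True):
    """Names and coordinates of ATOM/HETATM records via Biopython.

    Returns ``(names, (n, 3) array)`` in file order; only coordinates and
    atom names are exposed (no topology, no receptor preparation).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("mol", path)
    names, coords = [], []
    for atom in structure.get_atoms():
        het = atom.get_parent().get_id()[0].strip()
        if het and not hetatm:
            continue
        names.append(atom.get_name())
        coords.append(atom.get_coord())
    return names, np.array(coords, dtype=float)
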