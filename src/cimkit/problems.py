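"""Ising, QUBO and Max-Cut problem representations with exact conversions.

Conventions fixed here and relied on everywhere else in the package:

* Ising energy counts each unordered spin pair once:
  ``H(sigma) = -sum_{i<j} J_ij s_i s_j - sum_i h_i s_i + offset``.
* Binary/spin map is ``x = (1 + sigma) / 2`` (``sigma = +1`` means ``x = 1``).
* Max-Cut is encoded with ``J = -w`` so that minimizing the Ising energy
  maximizes the cut; the identity ``cut = (W_total - H) / 2`` holds for every
  configuration and makes the sign convention auditable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IsingProblem",
    "QUBOProblem",
    "WeightedGraph",
    "ising_energy",
    "qubo_energy",
    "qubo_to_ising",
    "ising_with_fields_to_fieldless",
    "maxcut_to_ising",
    "cut_value",
    "brute_force_ground",
]

#: hard cap for exhaustive enumeration (2^24 configurations)
BRUTE_FORCE_LIMIT = 24


def _as_spins(values, n: int | None = None) -> np.ndarray:
    s = np.asarray(values)
    if s.ndim != 1:
        raise ValueError("spin configuration must be a 1-D vector")
    if n is not None and s.shape[0] != n:
        raise ValueError(f"expected {n} spins, got {s.shape[0]}")
    if not np.all(np.abs(s) == 1):
        raise ValueError("spins must be +1 or -1")
    return s.astype(np.int8)


def _as_binary(values, n: int | None = None) -> np.ndarray:
    x = np.asarray(values)
    if x.ndim != 1:
        raise ValueError("binary vector must be 1-D")
    if n is not None and x.shape[0] != n:
        raise ValueError(f"expected {n} variables, got {x.shape[0]}")
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("entries must be 0 or 1")
    return x.astype(np.int8)


@dataclass(frozen=True)
class IsingProblem:
    """Spin-glass problem: symmetric couplings ``J``, local fields ``h``, constant.

    ``J`` must be symmetric with zero diagonal; ``h`` defaults to all zeros.
    The field vector does not belong to the fieldless machine Hamiltonian — it
    exists to receive the linear terms produced by QUBO conversion and can be
    folded into an ancilla spin with :func:`ising_with_fields_to_fieldless`.
    """

    J: np.ndarray
    h: np.ndarray | None = None
    offset: float = 0.0

    def __post_init__(self):
        J = np.asarray(self.J, dtype=float)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError("J must be a square matrix")
        if J.shape[0] < 1:
            raise ValueError("need at least one spin")
        if not np.allclose(J, J.T):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(J) != 0):
            raise ValueError("J must have a zero diagonal")
        h = self.h
        if h is None:
            h = np.zeros(J.shape[0])
        h = np.asarray(h, dtype=float)
        if h.shape != (J.shape[0],):
            raise ValueError("h must have length N")
        J = J.copy()
        J.flags.writeable = False
        h = h.copy()
        h.flags.writeable = False
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "offset", float(self.offset))

    @property
    def N(self) -> int:
        return self.J.shape[0]

    @property
    def has_fields(self) -> bool:
        return bool(np.any(self.h != 0))


@dataclass(frozen=True)
class QUBOProblem:
    """Quadratic unconstrained binary objective ``sum_{j<=k} Q_jk x_j x_k + offset``.

    ``Q`` is stored upper-triangular; diagonal entries are the linear terms
    (``x^2 = x`` for binary variables).
    """

    Q: np.ndarray
    offset: float = 0.0

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be a square matrix")
        if Q.shape[0] < 1:
            raise ValueError("need at least one variable")
        if np.any(np.tril(Q, -1) != 0):
            raise ValueError("Q must be upper-triangular (strict lower part zero)")
        Q = Q.copy()
        Q.flags.writeable = False
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "offset", float(self.offset))

    @property
    def n(self) -> int:
        return self.Q.shape[0]


@dataclass(frozen=True)
class WeightedGraph:
    """Simple weighted undirected graph; 0-based vertices, edges ``(i, j, w)`` with i<j."""

    V: int
    edges: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.V < 1:
            raise ValueError("graph needs at least one vertex")
        canon = []
        seen = set()
        for e in self.edges:
            i, j, w = int(e[0]), int(e[1]), float(e[2])
            if i == j:
                raise ValueError(f"self-loop on vertex {i}")
            if i > j:
                i, j = j, i
            if not (0 <= i < j < self.V):
                raise ValueError(f"edge ({i},{j}) out of range for V={self.V}")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i},{j})")
            seen.add((i, j))
            canon.append((i, j, w))
        canon.sort()
        object.__setattr__(self, "edges", tuple(canon))

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    @property
    def density(self) -> float:
        """Edge density d = 2|E| / (V (V-1))."""
        if self.V < 2:
            return 0.0
        return 2.0 * self.num_edges / (self.V * (self.V - 1))

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.V, self.V))
        for i, j, w in self.edges:
            A[i, j] = A[j, i] = w
        return A


def ising_energy(problem: IsingProblem, spins) -> float:
    """Evaluate ``-sum_{i<j} J_ij s_i s_j - sum_i h_i s_i + offset``."""
    s = _as_spins(spins, problem.N).astype(float)
    # J symmetric, zero diagonal: sum over i<j equals s.J.s / 2
    return float(-0.5 * s @ problem.J @ s - problem.h @ s + problem.offset)


def qubo_energy(problem: QUBOProblem, x) -> float:
    """Evaluate ``sum_{j<=k} Q_jk x_j x_k + offset`` for a binary vector."""
    xb = _as_binary(x, problem.n).astype(float)
    return float(xb @ problem.Q @ xb + problem.offset)


def qubo_to_ising(q: QUBOProblem) -> IsingProblem:
    """Exact QUBO -> Ising conversion under ``x = (1 + sigma) / 2``.

    Energy is preserved on every assignment; quadratic terms land in ``J``,
    linear terms in ``h``, the constant in ``offset``.
    """
    n = q.n
    Qu = np.triu(q.Q, 1)  # strict upper: pair coefficients
    diag = np.diag(q.Q)
    J = -(Qu + Qu.T) / 4.0
    # expanding sum Q_jk (1+s_j)(1+s_k)/4 + sum Q_jj (1+s_j)/2 + offset against
    # -sum_{i<j} J s s - sum h s + offset'
    h = -(diag / 2.0 + (Qu + Qu.T).sum(axis=1) / 4.0)
    offset = q.offset + Qu.sum() / 4.0 + diag.sum() / 2.0
    return IsingProblem(J=J, h=h, offset=offset)


def ising_with_fields_to_fieldless(p: IsingProblem) -> IsingProblem:
    """Absorb local fields into one ancilla spin (appended last).

    For every configuration with ``sigma_ancilla = +1`` the energy matches the
    input; the global spin-flip gauge maps the ``-1`` sector onto the ``+1``
    sector, so optima are preserved.
    """
    N = p.N
    J = np.zeros((N + 1, N + 1))
    J[:N, :N] = p.J
    J[N, :N] = p.h
    J[:N, N] = p.h
    return IsingProblem(J=J, h=np.zeros(N + 1), offset=p.offset)


def maxcut_to_ising(g: WeightedGraph) -> IsingProblem:
    """Encode Max-Cut with ``J_ij = -w_ij``: minimum energy <=> maximum cut."""
    J = -g.adjacency()
    return IsingProblem(J=J, h=np.zeros(g.V), offset=0.0)


def cut_value(g: WeightedGraph, spins) -> float:
    """Total weight of edges whose endpoints carry opposite spins."""
    s = _as_spins(spins, g.V)
    return float(sum(w for i, j, w in g.edges if s[i] != s[j]))


def _all_spin_matrix(nbits: int, lo: int, hi: int) -> np.ndarray:
    """Rows = spin vectors for configuration indices ``lo..hi-1`` (bit k -> spin k)."""
    idx = np.arange(lo, hi, dtype=np.int64)[:, None]
    bits = (idx >> np.arange(nbits, dtype=np.int64)[None, :]) & 1
    return (2 * bits - 1).astype(np.int8)


def brute_force_ground(p: IsingProblem, chunk: int = 1 << 16):
    """Exact ground energy and all minimizing configurations by enumeration.

    Guarded to ``N <= 24``. When ``h == 0`` the spin-flip gauge is used: the
    last spin is fixed to +1, halving the search; all returned optima carry
    ``sigma_N = +1`` and represent both gauge copies.

    Returns ``(energy, configs)`` where ``configs`` is a list of +-1 vectors.
    """
    N = p.N
    if N > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute force limited to N <= {BRUTE_FORCE_LIMIT} spins (got {N})"
        )
    gauge = not p.has_fields
    nbits = N - 1 if gauge else N
    best = np.inf
    best_configs: list[np.ndarray] = []
    total = 1 << nbits
    for lo in range(0, total, chunk):
        hi = min(lo + chunk, total)
        S = _all_spin_matrix(nbits, lo, hi).astype(np.float64)
        if gauge:
            S = np.hstack([S, np.ones((S.shape[0], 1))])
        E = -0.5 * np.einsum("ij,jk,ik->i", S, p.J, S) - S @ p.h + p.offset
        m = E.min()
        if m < best - 1e-12:
            best = m
            best_configs = []
        mask = np.abs(E - best) <= 1e-12
        if np.any(mask) and m <= best + 1e-12:
            for row in S[mask]:
                best_configs.append(row.astype(np.int8))
    return float(best), best_configs


def brute_force_qubo(q: QUBOProblem, chunk: int = 1 << 16):
    """Exact QUBO minimum by vectorized enumeration (n <= 20).

    Returns ``(energy, x)`` for the first-in-order optimal assignment.
    """
    n = q.n
    if n > 20:
        raise ValueError(f"QUBO brute force limited to n <= 20 (got {n})")
    best = np.inf
    best_x = None
    total = 1 << n
    for lo in range(0, total, chunk):
        hi = min(lo + chunk, total)
        idx = np.arange(lo, hi, dtype=np.int64)[:, None]
        X = ((idx >> np.arange(n, dtype=np.int64)[None, :]) & 1).astype(np.float64)
        E = np.einsum("ij,jk,ik->i", X, q.Q, X) + q.offset
        k = int(E.argmin())
        if E[k] < best - 1e-15:
            best = float(E[k])
            best_x = X[k].astype(np.int8)
    return best, best_x


def enumerate_binary(n: int):
    """Yield all binary vectors of length n (test-surface helper, n small)."""
    for bits in itertools.product((0, 1), repeat=n):
        yield np.array(bits, dtype=np.int8)
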