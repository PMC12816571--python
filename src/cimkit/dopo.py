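"""Single-DOPO open-quantum-system analysis in a truncated Fock space.

The signal mode of a degenerate optical parametric oscillator, after
adiabatic elimination of the pump, obeys the master equation

    drho/dt = (S/2) [a^dag^2 - a^2, rho]
              + ( gamma_s [a, rho a^dag] + (B/2) [a^2, rho a^dag^2] + h.c. )

where ``S = kappa * F / gamma_p`` is the squeezing (parametric gain) rate,
``gamma_s`` the signal damping rate and ``B`` the effective two-photon loss
coefficient. ``B`` is not an independent physical constant here: its default
is the adiabatic-elimination value ``kappa^2 / (2 gamma_p)``, overridable.

Above threshold (``S > gamma_s``) the steady-state Wigner function splits
into two lobes on the in-phase axis — the 0/pi phase states that encode the
Ising spin. ``lobe_separation`` quantifies that bimodality as a function of
S. Quadrature convention: ``x = (a + a^dag)/sqrt(2)``, so the vacuum Wigner
function is ``exp(-(x^2+p^2))/pi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import eval_genlaguerre, gammaln

__all__ = [
    "DOPOParams",
    "QuantumState",
    "destroy",
    "build_liouvillian",
    "steady_state",
    "wigner",
    "wigner_peaks",
    "lobe_separation",
]


@dataclass(frozen=True)
class DOPOParams:
    """Physical rates of a single DOPO (signal mode, pump eliminated)."""

    kappa: float
    F: float
    gamma_s: float = 1.0
    gamma_p: float = 1.0
    B: float | None = None
    n_max: int = 40

    def __post_init__(self):
        for name in ("kappa", "F", "gamma_s", "gamma_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_max < 4:
            raise ValueError("n_max must be >= 4")
        if self.B is None:
            object.__setattr__(self, "B", self.kappa**2 / (2.0 * self.gamma_p))
        elif self.B < 0:
            raise ValueError("B must be non-negative")

    @property
    def S(self) -> float:
        """Squeezing rate kappa * F / gamma_p."""
        return self.kappa * self.F / self.gamma_p

    @classmethod
    def from_squeezing(
        cls,
        S: float,
        B: float | None = None,
        gamma_s: float = 1.0,
        n_max: int = 40,
    ) -> "DOPOParams":
        """Parameterize directly by S (kappa = gamma_p = 1, F = S)."""
        return cls(kappa=1.0, F=S, gamma_s=gamma_s, gamma_p=1.0, B=B, n_max=n_max)


@dataclass(frozen=True)
class QuantumState:
    """Density matrix of the signal mode in the Fock basis."""

    rho: np.ndarray

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=complex)
        if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
            raise ValueError("rho must be a square matrix")
        if not np.allclose(rho, rho.conj().T, atol=1e-9):
            raise ValueError("rho must be Hermitian")
        if abs(np.trace(rho).real - 1.0) > 1e-9:
            raise ValueError("rho must have unit trace")
        evals = np.linalg.eigvalsh(rho)
        if evals.min() < -1e-9:
            raise ValueError(f"rho must be positive semidefinite (min eig {evals.min():.2e})")
        rho = rho.copy()
        rho.flags.writeable = False
        object.__setattr__(self, "rho", rho)

    @property
    def n_max(self) -> int:
        return self.rho.shape[0]

    def photon_number(self) -> float:
        return float(np.real(np.trace(self.rho * np.arange(self.n_max))))


def destroy(n_max: int) -> np.ndarray:
    """Truncated annihilation operator."""
    return np.diag(np.sqrt(np.arange(1, n_max)), k=1)


def _spre(A: sp.spmatrix, n: int) -> sp.csr_matrix:
    return sp.kron(A, sp.identity(n), format="csr")


def _spost(A: sp.spmatrix, n: int) -> sp.csr_matrix:
    return sp.kron(sp.identity(n), A.T, format="csr")


def build_liouvillian(params: DOPOParams) -> sp.csr_matrix:
    """Master-equation generator as an n_max^2 x n_max^2 sparse matrix.

    Acts on the row-major vectorization of rho. The generator is exactly
    trace preserving: every column of the returned matrix sums to zero on
    the trace functional.
    """
    n = params.n_max
    a = sp.csr_matrix(destroy(n))
    ad = a.T.conj().tocsr()
    a2 = (a @ a).tocsr()
    ad2 = (ad @ ad).tocsr()

    def pre(A):
        return _spre(A, n)

    def post(A):
        return _spost(A, n)

    S, g, B = params.S, params.gamma_s, params.B
    X = ad2 - a2
    L = (S / 2.0) * (pre(X) - post(X))
    # gamma_s ( [a, rho a^dag] + h.c. )
    L = L + g * (pre(a) @ post(ad) - post(ad @ a))
    L = L + g * (pre(a) @ post(ad) - pre(ad @ a))
    # (B/2) ( [a^2, rho a^dag^2] + h.c. )
    L = L + (B / 2.0) * (pre(a2) @ post(ad2) - post(ad2 @ a2))
    L = L + (B / 2.0) * (pre(a2) @ post(ad2) - pre(ad2 @ a2))
    return L.tocsr()


def steady_state(
    params: DOPOParams,
    tail_tol: float = 1e-6,
    residual_tol: float = 1e-8,
    on_truncation: str = "warn",
) -> QuantumState:
    """Stationary density matrix: the trace-one null vector of the Liouvillian.

    Solved as a sparse linear system with the trace row replacing one
    redundant equation. Raises if ``B == 0`` and ``S > gamma_s`` (no bounded
    steady state above threshold without two-photon loss), and checks both
    the Liouvillian residual and the tail population at the truncation edge.
    """
    if params.B == 0 and params.S > params.gamma_s:
        raise ValueError("B > 0 required above threshold (S > gamma_s)")
    n = params.n_max
    L = build_liouvillian(params).tolil()
    trace_idx = [i * n + i for i in range(n)]
    # replace the first row (equation for rho_00) by the trace condition
    L[0, :] = 0.0
    for idx in trace_idx:
        L[0, idx] = 1.0
    b = np.zeros(n * n, dtype=complex)
    b[0] = 1.0
    vec = spla.spsolve(L.tocsc(), b)
    rho = vec.reshape(n, n)
    rho = 0.5 * (rho + rho.conj().T)
    rho = rho / np.trace(rho).real

    Lfull = build_liouvillian(params)
    residual = np.linalg.norm(Lfull @ rho.reshape(-1))
    if residual > residual_tol:
        raise RuntimeError(f"steady-state residual {residual:.2e} > {residual_tol:.0e}")
    tail = float(np.real(rho[n - 1, n - 1] + rho[n - 2, n - 2]))
    if tail > tail_tol:
        msg = (
            f"tail population {tail:.2e} exceeds {tail_tol:.0e}: "
            f"n_max={n} too small for these parameters"
        )
        if on_truncation == "error":
            raise RuntimeError(msg)
        warnings.warn(msg, stacklevel=2)
    # clip numerically negative eigenvalues at the validation tolerance
    evals, vecs = np.linalg.eigh(rho)
    if evals.min() < -1e-9:
        evals = np.clip(evals, 0.0, None)
        rho = (vecs * evals) @ vecs.conj().T
        rho = rho / np.trace(rho).real
    return QuantumState(rho=rho)


def _wigner_basis_term(m: int, k: int, rr: np.ndarray) -> np.ndarray:
    """|W_{m,m+k}| radial part: sqrt(m!/(m+k)!) (2r)^k e^{-2r^2} L_m^k(4 r^2)."""
    logpref = 0.5 * (gammaln(m + 1) - gammaln(m + k + 1))
    with np.errstate(divide="ignore"):
        logr = k * np.log(np.where(rr > 0, 2.0 * rr, 1.0))
    out = np.exp(logpref + logr - 2.0 * rr**2) * eval_genlaguerre(m, k, 4.0 * rr**2)
    if k > 0:
        out = np.where(rr > 0, out, 0.0)
    return out


def wigner(state: QuantumState, xs: np.ndarray, ps: np.ndarray) -> np.ndarray:
    """Wigner quasi-probability on a rectangular (x, p) grid.

    Returns a real array of shape ``(len(ps), len(xs))`` (p varies along
    rows). Convention ``x = (a + a^dag)/sqrt(2)``; the vacuum gives
    ``W(0,0) = 1/pi`` and the grid integral of any state is 1 up to
    truncation and grid error.
    """
    xs = np.asarray(xs, dtype=float)
    ps = np.asarray(ps, dtype=float)
    X, P = np.meshgrid(xs, ps)
    alpha = (X + 1j * P) / np.sqrt(2.0)
    rr = np.abs(alpha)
    phi = np.angle(alpha)
    n = state.n_max
    W = np.zeros_like(rr, dtype=complex)
    rho = state.rho
    for m in range(n):
        for nn in range(m, n):
            if abs(rho[m, nn]) < 1e-14:
                continue
            k = nn - m
            base = (-1) ** m * _wigner_basis_term(m, k, rr)
            if k == 0:
                W += rho[m, m].real * base
            else:
                # rho_{mn} W_{nm} + rho_{nm} W_{mn} = 2 Re[rho_{mn} e^{-i k phi}] * base
                W += 2.0 * np.real(rho[m, nn] * np.exp(-1j * k * phi)) * base
    return np.real(W) / np.pi


def wigner_peaks(W: np.ndarray, xs: np.ndarray, ps: np.ndarray, rel_height: float = 1e-3):
    """Strict local maxima of a Wigner field, sorted by height (highest first).

    Returns a list of ``(x, p, height)``; peaks below ``rel_height`` of the
    global maximum are ignored.
    """
    peaks = []
    hmax = W.max()
    for i in range(1, W.shape[0] - 1):
        for j in range(1, W.shape[1] - 1):
            w = W[i, j]
            if w < rel_height * hmax:
                continue
            patch = W[i - 1 : i + 2, j - 1 : j + 2]
            if w >= patch.max() and (patch < w).sum() >= 7:
                peaks.append((float(xs[j]), float(ps[i]), float(w)))
    peaks.sort(key=lambda t: -t[2])
    return peaks


def lobe_separation(
    params_list,
    grid_halfwidth: float | None = None,
    grid_points: int = 201,
) -> list[float]:
    """Distance between the two dominant Wigner maxima for each parameter set.

    Unimodal states report 0. The grid half-width defaults to
    ``max(6, 4 * sqrt(<n> + 1))`` standard-deviation-scaled units so that the
    state is well covered.
    """
    seps = []
    for params in params_list:
        state = steady_state(params)
        hw = grid_halfwidth
        if hw is None:
            hw = max(6.0, 4.0 * np.sqrt(state.photon_number() + 1.0))
        xs = np.linspace(-hw, hw, grid_points)
        ps = np.linspace(-hw, hw, grid_points)
        W = wigner(state, xs, ps)
        peaks = wigner_peaks(W, xs, ps)
        if len(peaks) < 2:
            seps.append(0.0)
            continue
        (x1, p1, _), (x2, p2, _) = peaks[0], peaks[1]
        seps.append(float(np.hypot(x1 - x2, p1 - p2)))
    return seps
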