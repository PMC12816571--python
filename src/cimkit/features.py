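"""Correlation-based feature selection as a QUBO, with KS-statistic scoring.

The selection objective over binary indicators ``x_j`` (feature j kept) is

    f(x) = -( alpha * sum_j x_j |rhoV_j|
              - (1 - alpha) * sum_j sum_{k != j} x_j x_k |rho_jk| )

balancing per-feature relevance ``rhoV_j`` (default: Pearson correlation of
feature j with the label; pluggable) against pairwise redundancy ``rho_jk``
(feature-feature Pearson correlation). The ordered double sum counts each
unordered pair twice, so the assembled QUBO carries off-diagonal
coefficients ``2 (1 - alpha) |rho_jk|``; objective values are therefore
directly comparable with the formula as written.

Scoring quality of a selected subset is summarized by the two-sample
Kolmogorov-Smirnov statistic between the score distributions of the two
label classes (computed on a simple linear relevance-weighted score here; a
trained classifier can be plugged in by the caller).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .cim import CIMSchedule, run_cim
from .problems import (
    QUBOProblem,
    brute_force_qubo,
    ising_with_fields_to_fieldless,
    qubo_energy,
    qubo_to_ising,
)

__all__ = [
    "FeatureTable",
    "SelectionModel",
    "SelectionResult",
    "compute_relevance_and_correlation",
    "build_selection_qubo",
    "select_features",
    "ks_statistic",
    "linear_score",
    "synth_feature_table",
    "DEFAULT_ALPHA_GRID",
]

#: default sweep grid: 21 evenly spaced values plus the operating point 0.9975
DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 21), 3)) + (0.9975,)


@dataclass(frozen=True)
class FeatureTable:
    """Samples-by-features matrix with binary labels."""

    X: np.ndarray
    y: np.ndarray
    names: tuple

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (samples, features) aligned with y")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values")
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("labels must be binary 0/1")
        names = tuple(self.names) if self.names else tuple(f"f{j}" for j in range(X.shape[1]))
        if len(names) != X.shape[1]:
            raise ValueError("one name per feature required")
        X = X.copy()
        X.flags.writeable = False
        y = y.astype(np.int8)
        y.flags.writeable = False
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "names", names)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_csv(cls, path, label_column: str | None = None) -> "FeatureTable":
        """Read a header-ed CSV; the label is the last column unless named."""
        df = pd.read_csv(path)
        label = label_column if label_column is not None else df.columns[-1]
        y = df[label].to_numpy()
        Xdf = df.drop(columns=[label])
        return cls(X=Xdf.to_numpy(dtype=float), y=y, names=tuple(Xdf.columns))


@dataclass(frozen=True)
class SelectionModel:
    """Inputs of the selection objective at a given alpha."""

    alpha: float
    rhoV: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        rhoV = np.asarray(self.rhoV, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        n = rhoV.shape[0]
        if rho.shape != (n, n):
            raise ValueError("rho must be n x n")
        if not np.allclose(rho, rho.T):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(rho), 1.0):
            raise ValueError("rho must have unit diagonal")
        if np.any(np.abs(rho) > 1 + 1e-9) or np.any(np.abs(rhoV) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        for name, val in (("rhoV", rhoV), ("rho", rho)):
            val = val.copy()
            val.flags.writeable = False
            object.__setattr__(self, name, val)

    @property
    def n(self) -> int:
        return self.rhoV.shape[0]


def compute_relevance_and_correlation(
    t: FeatureTable, relevance=None
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson relevance-to-label vector and feature-feature correlation matrix.

    ``relevance`` may be a callable ``(X, y) -> vector`` to swap in another
    relevance measure (mutual information etc.); Pearson is the default.
    Zero-variance features get correlation 0 with a warning.
    """
    if t.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X, y = t.X, t.y.astype(float)
    sd = X.std(axis=0)
    degenerate = sd == 0
    if np.any(degenerate):
        warnings.warn(
            f"zero-variance features treated as uncorrelated: "
            f"{[t.names[j] for j in np.flatnonzero(degenerate)]}",
            stacklevel=2,
        )
    Xs = np.where(degenerate, 0.0, (X - X.mean(axis=0)) / np.where(degenerate, 1.0, sd))
    ysd = y.std()
    if relevance is not None:
        rhoV = np.asarray(relevance(X, t.y), dtype=float)
    elif ysd == 0:
        raise ValueError("labels are single-class; relevance undefined")
    else:
        rhoV = Xs.T @ ((y - y.mean()) / ysd) / t.n_samples
    rho = (Xs.T @ Xs) / t.n_samples
    np.fill_diagonal(rho, 1.0)
    return rhoV, rho


def build_selection_qubo(m: SelectionModel) -> QUBOProblem:
    """QUBO for the selection objective; pair coefficients are 2(1-alpha)|rho_jk|."""
    n = m.n
    Q = np.zeros((n, n))
    Q[np.arange(n), np.arange(n)] = -m.alpha * np.abs(m.rhoV)
    iu = np.triu_indices(n, 1)
    Q[iu] = 2.0 * (1.0 - m.alpha) * np.abs(m.rho)[iu]
    return QUBOProblem(Q=Q)


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple  # feature indices
    names: tuple
    objective: float
    alpha: float
    solver: str
    metadata: dict


_BRUTE_FORCE_MAX = 20


def select_features(
    t: FeatureTable,
    alpha: float,
    schedule: CIMSchedule | None = None,
    n_seeds: int = 10,
    master_seed: int = 0,
    relevance=None,
    force_cim: bool = False,
) -> SelectionResult:
    """Solve the selection QUBO; exact enumeration for n <= 20, CIM otherwise.

    The CIM path converts the QUBO to a fieldless Ising problem (ancilla
    spin) and keeps the best readout over ``n_seeds`` seeded trajectories.
    """
    rhoV, rho = compute_relevance_and_correlation(t, relevance=relevance)
    model = SelectionModel(alpha=alpha, rhoV=rhoV, rho=rho)
    q = build_selection_qubo(model)
    n = q.n
    if n <= _BRUTE_FORCE_MAX and not force_cim:
        best_e, best_x = brute_force_qubo(q)
        solver, meta = "brute_force", {}
    else:
        ising = qubo_to_ising(q)
        fieldless = ising_with_fields_to_fieldless(ising)
        schedule = schedule or CIMSchedule.default()
        best_x, best_e = None, np.inf
        children = np.random.SeedSequence(master_seed).spawn(n_seeds)
        for child in children:
            traj = run_cim(fieldless, schedule, seed=child)
            spins = traj.best_spins
            if spins[-1] < 0:  # gauge: ancilla must read +1
                spins = -spins
            x = ((1 + spins[:-1]) // 2).astype(np.int8)
            e = qubo_energy(q, x)
            if e < best_e - 1e-12:
                best_e, best_x = e, x
        solver = "cim"
        meta = {"n_seeds": n_seeds, "schedule": schedule.to_dict(), "master_seed": master_seed}
    idx = tuple(int(j) for j in np.flatnonzero(best_x))
    return SelectionResult(
        selected=idx,
        names=tuple(t.names[j] for j in idx),
        objective=float(best_e),
        alpha=alpha,
        solver=solver,
        metadata=meta,
    )


def linear_score(t: FeatureTable, selected, rhoV=None) -> np.ndarray:
    """Relevance-weighted linear score over the selected features (z-scored)."""
    selected = list(selected)
    if rhoV is None:
        rhoV, _ = compute_relevance_and_correlation(t)
    X = t.X[:, selected]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    return Z @ np.asarray(rhoV)[selected]


def ks_statistic(scores, y) -> float:
    """Two-sample KS statistic between the score distributions of each class."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    s0, s1 = scores[y == 0], scores[y == 1]
    if len(s0) == 0 or len(s1) == 0:
        raise ValueError("both label classes must be non-empty")
    return float(ks_2samp(s0, s1).statistic)


def synth_feature_table(
    n_informative: int = 4,
    n_redundant: int = 4,
    n_noise: int = 8,
    samples: int = 1000,
    correlation: float = 0.95,
    effect: float = 1.5,
    seed=0,
) -> FeatureTable:
    """Synthetic credit-scoring-style table with planted structure.

    Informative features are independent standard normals driving a logistic
    label model with coefficient ``effect``; redundant features are noisy
    copies of informative ones at the given target correlation; noise
    features are independent. Generator parameters are recorded in the
    feature names (``inf*``, ``red*``, ``noise*``).
    """
    if samples < 50:
        raise ValueError("need at least 50 samples")
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(samples, n_informative))
    logits = effect * Z.sum(axis=1) / np.sqrt(n_informative)
    y = (rng.random(samples) < 1.0 / (1.0 + np.exp(-logits))).astype(np.int8)
    cols = [Z]
    names = [f"inf{j}" for j in range(n_informative)]
    if n_redundant:
        src = np.arange(n_redundant) % n_informative
        R = correlation * Z[:, src] + np.sqrt(1 - correlation**2) * rng.normal(
            size=(samples, n_redundant)
        )
        cols.append(R)
        names += [f"red{j}_of_inf{src[j]}" for j in range(n_redundant)]
    if n_noise:
        cols.append(rng.normal(size=(samples, n_noise)))
        names += [f"noise{j}" for j in range(n_noise)]
    return FeatureTable(X=np.hstack(cols), y=y, names=tuple(names))
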