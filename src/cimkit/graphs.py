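"""Benchmark graph families: Mobius ladders and uniform random G(V, m) graphs.

The Mobius ladder on ``V`` vertices (``V`` even) is the cycle 0..V-1 plus the
V/2 antipodal chords ``(i, i + V/2)``. It is 3-regular and vertex-transitive,
and its maximum cut is known in closed form: ``3V/2`` when ``V/2`` is odd
(the graph is bipartite) and ``3V/2 - 2`` when ``V/2`` is even. The closed
form is cross-validated against exhaustive search in the test suite.

Random graphs are uniform draws of exactly ``round(d * V(V-1)/2)`` edges,
matching the edge-density parameterisation ``d = 2|E| / V(V-1)``.
"""

from __future__ import annotations

import numpy as np

from .problems import WeightedGraph

__all__ = ["mobius_ladder", "mobius_max_cut", "random_graph"]


def mobius_ladder(V: int) -> WeightedGraph:
    """Unit-weight Mobius ladder: cycle edges plus antipodal chords; |E| = 3V/2."""
    if V < 4 or V % 2:
        raise ValueError("Mobius ladder requires an even vertex count V >= 4")
    edges = [(i, (i + 1) % V, 1.0) for i in range(V)]
    edges += [(i, i + V // 2, 1.0) for i in range(V // 2)]
    return WeightedGraph(V=V, edges=tuple(edges))


def mobius_max_cut(V: int) -> int:
    """Closed-form maximum cut of the Mobius ladder.

    Bipartite (all 3V/2 edges cut) when V/2 is odd; otherwise the best
    partition leaves exactly two edges uncut.
    """
    if V < 4 or V % 2:
        raise ValueError("V must be even and >= 4")
    half = V // 2
    return 3 * half if half % 2 else 3 * half - 2


def random_graph(V: int, density: float, seed) -> WeightedGraph:
    """Uniform unit-weight G(V, m) with m = round(d * V(V-1)/2), ties up."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    max_edges = V * (V - 1) // 2
    m = int(np.floor(density * max_edges + 0.5))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(max_edges, size=m, replace=False))
    ii, jj = np.triu_indices(V, k=1)
    edges = tuple((int(ii[p]), int(jj[p]), 1.0) for p in chosen)
    return WeightedGraph(V=V, edges=edges)
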