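"""Plain-text file formats: rudy-style edge lists and sparse QUBO files.

Graph file (Biq-Mac / rudy dialect): first line ``V E``, then ``E`` lines
``i j w`` with 1-based vertex indices. QUBO file: first line ``n m``, then
``m`` lines ``j k q`` with 1-based indices and ``j <= k``; diagonal entries
are linear coefficients. Both readers reject malformed lines with the line
number; writers emit entries sorted by index.
"""

from __future__ import annotations

import numpy as np

from .problems import QUBOProblem, WeightedGraph

__all__ = ["read_graph", "write_graph", "read_qubo", "write_qubo"]


class ParseError(ValueError):
    pass


def _tokenized_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line.split()


def read_graph(path) -> WeightedGraph:
    with open(path) as fh:
        text = fh.read()
    lines = _tokenized_lines(text)
    try:
        lineno, header = next(lines)
    except StopIteration:
        raise ParseError("empty graph file") from None
    if len(header) != 2:
        raise ParseError(f"line {lineno}: expected header 'V E'")
    V, E = int(header[0]), int(header[1])
    edges = []
    for lineno, tok in lines:
        if len(tok) != 3:
            raise ParseError(f"line {lineno}: expected 'i j w'")
        try:
            i, j, w = int(tok[0]), int(tok[1]), float(tok[2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if not (1 <= i <= V and 1 <= j <= V):
            raise ParseError(f"line {lineno}: vertex index out of range 1..{V}")
        if i == j:
            raise ParseError(f"line {lineno}: self-loop on vertex {i}")
        edges.append((i - 1, j - 1, w))
    if len(edges) != E:
        raise ParseError(f"header declares {E} edges, found {len(edges)}")
    try:
        return WeightedGraph(V=V, edges=tuple(edges))
    except ValueError as exc:
        raise ParseError(str(exc)) from None


def _fmt_weight(w: float) -> str:
    w = float(w)
    return str(int(w)) if w.is_integer() else repr(w)


def write_graph(g: WeightedGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{g.V} {g.num_edges}\n")
        for i, j, w in g.edges:  # already sorted by (i, j)
            fh.write(f"{i + 1} {j + 1} {_fmt_weight(w)}\n")


def read_qubo(path) -> QUBOProblem:
    with open(path) as fh:
        text = fh.read()
    lines = _tokenized_lines(text)
    try:
        lineno, header = next(lines)
    except StopIteration:
        raise ParseError("empty QUBO file") from None
    if len(header) != 2:
        raise ParseError(f"line {lineno}: expected header 'n m'")
    n, m = int(header[0]), int(header[1])
    Q = np.zeros((n, n))
    count = 0
    for lineno, tok in lines:
        if len(tok) != 3:
            raise ParseError(f"line {lineno}: expected 'j k q'")
        j, k, qv = int(tok[0]), int(tok[1]), float(tok[2])
        if not (1 <= j <= k <= n):
            raise ParseError(f"line {lineno}: require 1 <= j <= k <= {n}")
        if Q[j - 1, k - 1] != 0:
            raise ParseError(f"line {lineno}: duplicate entry ({j},{k})")
        Q[j - 1, k - 1] = qv
        count += 1
    if count != m:
        raise ParseError(f"header declares {m} entries, found {count}")
    return QUBOProblem(Q=Q)


def write_qubo(q: QUBOProblem, path) -> None:
    entries = [
        (j, k, q.Q[j, k])
        for j in range(q.n)
        for k in range(j, q.n)
        if q.Q[j, k] != 0
    ]
    with open(path, "w") as fh:
        fh.write(f"{q.n} {len(entries)}\n")
        for j, k, qv in entries:
            fh.write(f"{j + 1} {k + 1} {_fmt_weight(qv)}\n")
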