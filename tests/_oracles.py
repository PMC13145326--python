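"""Independent brute-force oracles used to pin library behaviour.

Everything here is deliberately written with plain Python loops and no
calls into the package's computational paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def set_partitions(items):
    """All partitions of a list into non-empty unordered blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield part + [[first]]


def modularity_oracle(values: np.ndarray, blocks) -> float:
    """Q of one partition by direct cell-by-cell summation.

    Nodes are ("r", i) and ("c", j); blocks is a list of node lists.
    """
    A = np.asarray(values, dtype=float)
    W = A.sum()
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    q = 0.0
    for block in blocks:
        rows = [i for kind, i in block if kind == "r"]
        cols = [j for kind, j in block if kind == "c"]
        for i in rows:
            for j in cols:
                q += (A[i, j] - r[i] * c[j] / W) / W
    return q


def exhaustive_best_q(values: np.ndarray):
    """Maximum Q over every partition of all nodes; returns (q, blocks)."""
    R, C = np.asarray(values).shape
    nodes = [("r", i) for i in range(R)] + [("c", j) for j in range(C)]
    best = (-np.inf, None)
    for blocks in set_partitions(nodes):
        q = modularity_oracle(values, blocks)
        if q > best[0]:
            best = (q, blocks)
    return best


def wnoda_oracle(values: np.ndarray) -> float:
    """Pairwise weighted nestedness by direct enumeration."""
    A = np.asarray(values, dtype=float)

    def side_scores(M):
        scores = []
        totals = [sum(row) for row in M]
        for u, v in itertools.combinations(range(len(M)), 2):
            if totals[u] == totals[v]:
                scores.append(0.0)
                continue
            big, small = (u, v) if totals[u] > totals[v] else (v, u)
            nz = [k for k in range(len(M[small])) if M[small][k] > 0]
            if not nz:
                scores.append(0.0)
                continue
            hits = sum(
                1 for k in nz if M[big][k] > 0 and M[small][k] < M[big][k]
            )
            scores.append(100.0 * hits / len(nz))
        return scores

    rows = side_scores(A.tolist())
    cols = side_scores(A.T.tolist())
    return sum(rows + cols) / (len(rows) + len(cols))


def gower_oracle(records, types):
    """Pairwise Gower distances from a list of per-consumer dicts."""
    quant = [t for t, k in types.items() if k == "quantitative"]
    ranges = {
        t: max(r[t] for r in records) - min(r[t] for r in records) for t in quant
    }
    n = len(records)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            parts = []
            for t, k in types.items():
                if k == "quantitative":
                    if ranges[t] == 0:
                        continue
                    parts.append(abs(records[a][t] - records[b][t]) / ranges[t])
                else:
                    parts.append(0.0 if records[a][t] == records[b][t] else 1.0)
            D[a, b] = sum(parts) / len(parts)
    return D


def random_valid_matrix(rng, shape, max_weight=3):
    """Random integer matrix with no empty row/column."""
    R, C = shape
    while True:
        A = rng.integers(0, max_weight + 1, size=(R, C))
        if (A.sum(axis=1) > 0).all() and (A.sum(axis=0) > 0).all():
            return A.astype(float)
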