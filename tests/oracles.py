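"""Independent brute-force oracles used to validate the implementation.

These are written against the problem definitions, not against the package
internals: a 3-matrix affine-gap DP for local alignment scores, a sweep
union for interval pooling, BFS connected components for single-linkage
grouping, and a grid search for JTT maximum-likelihood distances.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def brute_force_sw(query: str, subject: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Exact affine-gap Smith-Waterman score via the explicit 3-matrix
    recursion. A gap of length k costs gap_open + k * gap_extend."""
    m, n = len(query), len(subject)
    NEG = -(10 ** 9)
    M = [[0] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = matrix[query[i - 1], subject[j - 1]]
            M[i][j] = max(
                0,
                max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s,
            )
            Ix[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend
            )
            best = max(best, M[i][j])
    return int(best)


def sweep_union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals by sweep line; >=1 unit overlap merges, bookended
    intervals stay separate."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s < out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def bfs_components(ids: list[str], d: np.ndarray, threshold: float) -> list[list[str]]:
    """Connected components of the sub-threshold distance graph."""
    n = len(ids)
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            i = queue.pop()
            comp.append(ids[i])
            for j in range(n):
                if not seen[j] and d[i, j] < threshold:
                    seen[j] = True
                    queue.append(j)
        comps.append(sorted(comp))
    return sorted(comps, key=lambda c: min(c))


def _jtt_q() -> tuple[np.ndarray, np.ndarray]:
    """Normalized JTT rate matrix assembled directly from the model
    constants (shared model definition; independent of the package's
    eigendecomposition shortcut)."""
    from groupii import _jtt

    pi = _jtt.FREQUENCIES
    S = _jtt.exchangeability_matrix()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -(pi * np.diag(Q)).sum()
    return Q, pi


def grid_jtt_distance(a: str, b: str, t_max: float = 2.0) -> float:
    """JTT ML distance by two-stage grid search over branch length, with
    transition matrices from scipy's matrix exponential."""
    from groupii import _jtt

    Q, pi = _jtt_q()
    idx = {aa: i for i, aa in enumerate(_jtt.AA_ORDER)}
    pairs = [
        (idx[x], idx[y]) for x, y in zip(a, b) if x in idx and y in idx
    ]
    if not pairs:
        raise ValueError("no comparable columns")

    def loglik(t: float) -> float:
        P = np.clip(scipy.linalg.expm(Q * t), 1e-300, None)
        logP = np.log(P)
        return sum(np.log(pi[i]) + logP[i, j] for i, j in pairs)

    coarse = np.arange(0.002, t_max, 0.01)
    best = coarse[int(np.argmax([loglik(t) for t in coarse]))]
    fine = np.arange(max(1e-4, best - 0.01), best + 0.01, 0.0002)
    return float(fine[int(np.argmax([loglik(t) for t in fine]))])
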