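"""Independent persistent-homology oracle.

A from-scratch, deliberately naive GF(2) persistence computation used only to
cross-check the package's reduction engine: the full boundary matrix is built
as a dense boolean array over all simplices in filtration order and reduced
left-to-right by repeated column addition.  O(n^3) and proud of it.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def naive_persistence(simplices: dict[tuple, float]) -> list[tuple[int, float, float]]:
    """Persistence intervals ``(dim, birth, death)`` of a filtered complex.

    ``simplices`` maps sorted vertex tuples to filtration values; every face
    must be present with a value <= its cofaces.  Zero-length intervals are
    dropped; infinite deaths are ``math.inf``.
    """
    order = sorted(simplices, key=lambda s: (simplices[s], len(s), s))
    index = {s: i for i, s in enumerate(order)}
    n = len(order)
    cols = []
    for s in order:
        col = np.zeros(n, dtype=bool)
        if len(s) > 1:
            for f in combinations(s, len(s) - 1):
                col[index[f]] = True
        cols.append(col)

    def low(c: np.ndarray) -> int:
        nz = np.nonzero(c)[0]
        return int(nz[-1]) if len(nz) else -1

    lows: dict[int, int] = {}
    pairs: dict[int, int] = {}
    for j in range(n):
        lj = low(cols[j])
        while lj >= 0 and lj in lows:
            cols[j] = cols[j] ^ cols[lows[lj]]
            lj = low(cols[j])
        if lj >= 0:
            lows[lj] = j
            pairs[lj] = j

    dying = set(pairs.keys())      # rows killed by a later column
    killers = set(pairs.values())  # columns that kill (create nothing)
    intervals = []
    for i, s in enumerate(order):
        if i not in dying and i not in killers:
            intervals.append((len(s) - 1, simplices[s], math.inf))
    for i, j in pairs.items():
        birth = simplices[order[i]]
        death = simplices[order[j]]
        if birth < death:
            intervals.append((len(order[i]) - 1, birth, death))
    return sorted(intervals)


def betti_at(intervals: list[tuple[int, float, float]], t: float, dim: int) -> int:
    return sum(1 for d, b, e in intervals if d == dim and b <= t < e)


def random_filtered_flag_complex(rng: np.random.Generator, n_max: int = 12,
                                 max_dim: int = 3):
    """A random graph with random edge times, expanded to a filtered clique
    complex (vertices at time 0, cliques at the max of their edge times)."""
    n = int(rng.integers(3, n_max + 1))
    p = rng.uniform(0.3, 0.8)
    times = {}
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        times[(i,)] = 0.0
    for i, j in combinations(range(n), 2):
        if rng.uniform() < p:
            adj[i, j] = adj[j, i] = True
            times[(i, j)] = float(np.round(rng.uniform(0.5, 5.0), 2))
    for size in range(3, max_dim + 2):
        for s in combinations(range(n), size):
            if all(adj[a, b] for a, b in combinations(s, 2)):
                times[s] = max(times[(a, b)] for a, b in combinations(s, 2))
    return times
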