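"""Time-filtered coactivity graphs, clique complexes and persistent homology.

Detected pairwise coactivity events accumulate into a *coactivity graph*:
vertices are cells that produced at least one (retained) spike, edges are cell
pairs whose coactivity was detected at least once.  Its cliques, each stamped
with the time by which all of its pairwise coactivities have been seen, form a
time-filtered clique (flag) complex — the model's cell-assembly complex.
Persistent homology of this filtration yields the barcode, Betti-number
timelines, the learning time (the time from which the Betti numbers
permanently match those of the environment), and the statistics of spurious
(finite-lifetime) one-dimensional loops.

Homology is computed over GF(2) with a hand-rolled boundary-matrix reduction
(dimension 0 uses a union-find with the elder rule instead).  Final Betti
numbers of large dense graphs are obtained after a *strong collapse*
(iterated removal of dominated vertices), which preserves the homotopy type
of the flag complex while typically shrinking it by orders of magnitude.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import networkx as nx

from ._reduction import gf2_rank, reduce_boundary
from .cells import SpikeTrain, SpikingConfig
from .synapses import CoactivityEvent

__all__ = [
    "CoactivityGraph",
    "FilteredCliqueComplex",
    "Interval",
    "Barcode",
    "BettiTimeline",
    "LearningOutcome",
    "LoopStats",
    "build_graph",
    "clique_filtration",
    "persistence",
    "betti_timeline",
    "learning_time",
    "loop_stats",
    "complex_size",
    "strong_collapse",
    "flag_betti_numbers",
    "final_betti",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CoactivityGraph:
    """Coactivity graph: vertex attrs ``time`` (first-activity window start, s)
    and ``weight`` (total retained spikes); edge attrs ``time`` (first
    detection window start, s) and ``weight`` (pairwise correlation)."""

    graph: nx.Graph

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_at(self, t: float) -> list[tuple[int, int]]:
        return [
            (u, v) for u, v, d in self.graph.edges(data=True) if d["time"] <= t
        ]

    def to_edgelist(self, path) -> None:
        pd.DataFrame(
            [
                {"i": u, "j": v, "t_first": d["time"], "weight": d["weight"]}
                for u, v, d in self.graph.edges(data=True)
            ]
        ).to_csv(path, index=False)


@dataclass
class FilteredCliqueComplex:
    """Simplices (sorted vertex tuples) with first-appearance times."""

    simplices: dict[tuple[int, ...], float]
    max_dim: int

    def validate(self) -> None:
        """Raise if some face is missing or appears after its coface."""
        for s, t in self.simplices.items():
            if len(s) == 1:
                continue
            for f in combinations(s, len(s) - 1):
                tf = self.simplices.get(f)
                if tf is None:
                    raise ValueError(f"missing face {f} of {s}")
                if tf > t:
                    raise ValueError(f"non-monotone filtration at {s}")

    def by_dim(self, dim: int) -> list[tuple[tuple[int, ...], float]]:
        return sorted(
            ((s, t) for s, t in self.simplices.items() if len(s) == dim + 1),
            key=lambda st: (st[1], st[0]),
        )

    def counts(self, t: float = math.inf) -> dict[int, int]:
        out: dict[int, int] = {d: 0 for d in range(self.max_dim + 1)}
        for s, ts in self.simplices.items():
            if ts <= t:
                out[len(s) - 1] = out.get(len(s) - 1, 0) + 1
        return out


@dataclass(frozen=True)
class Interval:
    dim: int
    birth: float
    death: float  # math.inf for persistent classes
    representative: tuple[tuple[int, int], ...] | None = None

    @property
    def lifetime(self) -> float:
        return self.death - self.birth

    @property
    def length(self) -> int | None:
        return None if self.representative is None else len(self.representative)


@dataclass
class Barcode:
    intervals: list[Interval]

    def in_dim(self, dim: int) -> list[Interval]:
        return [iv for iv in self.intervals if iv.dim == dim]

    def betti_at(self, t: float, dim: int) -> int:
        return sum(
            1 for iv in self.intervals
            if iv.dim == dim and iv.birth <= t < iv.death
        )

    def final_betti(self, dim: int) -> int:
        return sum(
            1 for iv in self.intervals
            if iv.dim == dim and math.isinf(iv.death)
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {"dim": iv.dim, "birth": iv.birth,
                 "death": "inf" if math.isinf(iv.death) else iv.death}
                for iv in self.intervals
            ]
        ).to_csv(path, index=False)


@dataclass
class BettiTimeline:
    """Step functions ``b_k(t)`` sampled on an increasing time grid."""

    times: np.ndarray
    betti: dict[int, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.times}
        for k in sorted(self.betti):
            data[f"b{k}"] = self.betti[k]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class LearningOutcome:
    t_min: float | None
    final_betti: tuple[int, ...]
    correct: bool
    loop_stats: "LoopStats | None" = None
    n2: int | None = None


@dataclass(frozen=True)
class LoopStats:
    n_loops: int
    n_spurious: int
    mean_birth: float
    mean_death: float
    mean_lifetime: float
    mean_length: float


# ---------------------------------------------------------------------------
# graph and complex construction


def build_graph(
    events: list[CoactivityEvent],
    trains: list[SpikeTrain],
    cfg: SpikingConfig = SpikingConfig(),
    duration: float | None = None,
) -> CoactivityGraph:
    """Assemble the coactivity graph from detected events and retained trains.

    Vertex weight = retained spike count; vertex time = start of the window of
    the first retained spike.  Edge time = start of the first detection
    window; edge weight = Pearson correlation of the two cells' per-window
    spike-count vectors (NaN-safe: zero-variance rows give weight 0).
    """
    w = cfg.window
    active = [tr for tr in trains if len(tr) > 0]
    ids = [tr.cell_id for tr in active]
    if duration is None:
        tmax = max((tr.times[-1] for tr in active), default=0.0)
        tmax = max(tmax, max((ev.time for ev in events), default=0.0))
        n_win = int(math.floor(tmax / w)) + 1 if (active or events) else 1
    else:
        n_win = max(1, int(math.ceil(duration / w)))
    counts = np.zeros((len(active), n_win))
    g = nx.Graph()
    for row, tr in enumerate(active):
        wins = np.minimum((tr.times / w).astype(int), n_win - 1)
        np.add.at(counts, (row,), np.bincount(wins, minlength=n_win))
        g.add_node(tr.cell_id, time=float(wins.min()) * w, weight=len(tr))
    # correlation matrix of per-window counts, only read where edges exist
    if len(active) > 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(counts)
        corr = np.nan_to_num(corr, nan=0.0)
    else:
        corr = np.ones((len(active), len(active)))
    row_of = {cid: r for r, cid in enumerate(ids)}
    first: dict[tuple[int, int], int] = {}
    for ev in events:
        key = (ev.i, ev.j)
        if key not in first or ev.window_index < first[key]:
            first[key] = ev.window_index
    for (i, j), win in first.items():
        if i not in row_of or j not in row_of:
            raise ValueError("event endpoints must have retained spikes")
        g.add_edge(i, j, time=win * w, weight=float(corr[row_of[i], row_of[j]]))
    return CoactivityGraph(graph=g)


def clique_filtration(graph: CoactivityGraph, max_dim: int = 2) -> FilteredCliqueComplex:
    """Clique (flag) complex of the coactivity graph, filtered by time.

    A clique enters the filtration at the max of its edges' first-detection
    times: an assembly counts once all of its pairwise coactivities have ever
    been detected (cumulative, not simultaneous).  ``max_dim`` caps the
    simplex dimension (``max_dim = 2`` keeps vertices/edges/triangles, enough
    for b0 and b1).
    """
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    g = graph.graph
    nodes = sorted(g.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    simplices: dict[tuple[int, ...], float] = {}
    for v in nodes:
        simplices[(v,)] = float(g.nodes[v]["time"])
    adj = np.zeros((n, n), dtype=bool)
    etime = np.full((n, n), np.inf)
    for u, v, d in g.edges(data=True):
        iu, iv = idx[u], idx[v]
        adj[iu, iv] = adj[iv, iu] = True
        etime[iu, iv] = etime[iv, iu] = d["time"]
        simplices[tuple(sorted((u, v)))] = float(d["time"])
    if max_dim >= 2 and n:
        frontier: list[tuple[tuple[int, ...], float]] = [
            (tuple(sorted((idx[u], idx[v]))), float(d["time"]))
            for u, v, d in g.edges(data=True)
        ]
        for dim in range(2, max_dim + 1):
            nxt: list[tuple[tuple[int, ...], float]] = []
            for simplex, t in frontier:
                mask = adj[simplex[0]].copy()
                for v in simplex[1:]:
                    mask &= adj[v]
                mask[: simplex[-1] + 1] = False
                for k in np.nonzero(mask)[0]:
                    tk = max(t, float(etime[list(simplex), k].max()))
                    nxt.append((simplex + (int(k),), tk))
            for s, t in nxt:
                simplices[tuple(nodes[v] for v in s)] = t
            if not nxt:
                break
            frontier = nxt
    return FilteredCliqueComplex(simplices=simplices, max_dim=max_dim)


# ---------------------------------------------------------------------------
# persistence


def _representative(
    edge: tuple[int, int],
    birth: float,
    edges_by_time: list[tuple[float, tuple[int, int]]],
) -> tuple[tuple[int, int], ...]:
    """Shortest cycle through ``edge`` in the 1-skeleton at its birth time:
    BFS path between the endpoints over edges of time <= birth, excluding the
    birth edge itself, closed by the edge."""
    u0, v0 = edge
    adj: dict[int, list[int]] = {}
    for t, (a, b) in edges_by_time:
        if t > birth:
            break
        if (a, b) == edge:
            continue
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    prev: dict[int, int | None] = {u0: None}
    dq = deque([u0])
    while dq:
        x = dq.popleft()
        if x == v0:
            break
        for y in adj.get(x, ()):
            if y not in prev:
                prev[y] = x
                dq.append(y)
    if v0 not in prev:  # should not happen for a positive edge
        return (edge,)
    path = []
    x: int | None = v0
    while prev[x] is not None:
        path.append(tuple(sorted((x, prev[x]))))
        x = prev[x]
    return tuple([tuple(sorted(edge))] + path)


def persistence(
    complex: FilteredCliqueComplex,
    *,
    validate: bool = True,
    representatives: bool = True,
    max_homology_dim: int | None = None,
) -> Barcode:
    """Persistent homology barcode (GF(2)) of a filtered clique complex.

    Computes homology dimensions ``0 .. max_homology_dim``; the default cap
    is ``max_dim - 1`` because a dimension-capped clique complex cannot
    distinguish real ``max_dim``-cycles from truncation artifacts (pass the
    complex's full dimension explicitly for untruncated complexes).
    Zero-length intervals (birth == death) are discarded.  Dimension 0 uses
    union-find with the elder rule; higher dimensions use sparse bit-vector
    column reduction.  Representative cycles (for dimension-1 intervals) are
    shortest cycles through the creating edge in the birth-time 1-skeleton.
    """
    if validate:
        complex.validate()
    if max_homology_dim is None:
        max_homology_dim = max(complex.max_dim - 1, 0)
    intervals: list[Interval] = []

    verts = complex.by_dim(0)
    edges = complex.by_dim(1)

    # --- dimension 0: union-find, elder rule
    parent: dict[int, int] = {}
    birth: dict[int, float] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (v,), t in verts:
        parent[v] = v
        birth[v] = t
    negative_edges: set[tuple[int, ...]] = set()
    for (u, v), t in edges:
        ru, rv = find(u), find(v)
        if ru == rv:
            continue
        negative_edges.add((u, v))
        # the younger component dies; survivor keeps the elder birth
        if birth[ru] > birth[rv] or (birth[ru] == birth[rv] and ru > rv):
            ru, rv = rv, ru
        if birth[rv] < t:
            intervals.append(Interval(dim=0, birth=birth[rv], death=t))
        parent[rv] = ru
    roots = {find(v) for (v,), _ in verts}
    for r in roots:
        intervals.append(Interval(dim=0, birth=birth[r], death=math.inf))

    # --- dimensions >= 1: reduce (k+1)-columns over k-rows, dimension by
    # dimension; the positive k-simplices (columns reducing to zero) create
    # the dimension-k classes paired at level k+1
    edges_by_time = [(t, s) for s, t in edges]
    # positive edges: those that do not merge components
    positive = [k for k, (e, _) in enumerate(edges) if e not in negative_edges]
    rows = edges
    for k in range(1, max_homology_dim + 1):
        cofaces = complex.by_dim(k + 1)
        rindex = {s: i for i, (s, _) in enumerate(rows)}
        cols = []
        for s, _ in cofaces:
            col = 0
            for f in combinations(s, k + 1):
                col |= 1 << rindex[f]
            cols.append(col)
        pivots, positive_next = reduce_boundary(cols)
        paired = set(pivots)
        for p, j in pivots.items():
            tb, td = rows[p][1], cofaces[j][1]
            if tb < td:
                rep = None
                if k == 1 and representatives:
                    rep = _representative(rows[p][0], tb, edges_by_time)
                intervals.append(Interval(dim=k, birth=tb, death=td,
                                          representative=rep))
        for i in positive:
            if i not in paired:
                tb = rows[i][1]
                rep = None
                if k == 1 and representatives:
                    rep = _representative(rows[i][0], tb, edges_by_time)
                intervals.append(Interval(dim=k, birth=tb, death=math.inf,
                                          representative=rep))
        rows = cofaces
        positive = positive_next
    return Barcode(intervals=intervals)


# ---------------------------------------------------------------------------
# timelines, learning time, loop statistics


def betti_timeline(
    source: Barcode | FilteredCliqueComplex,
    sample_times: np.ndarray,
    dims: tuple[int, ...] = (0, 1),
) -> BettiTimeline:
    """Betti numbers ``b_k(t)`` on a sampling grid (one sample per coactivity
    window in the standard pipeline)."""
    barcode = source if isinstance(source, Barcode) else persistence(source)
    times = np.asarray(sample_times, dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    betti = {}
    for k in dims:
        vals = np.zeros(len(times), dtype=int)
        for iv in barcode.in_dim(k):
            vals += (times >= iv.birth) & (times < iv.death)
        betti[k] = vals
    return BettiTimeline(times=times, betti=betti)


def learning_time(
    timeline: BettiTimeline,
    target: tuple[int, ...],
    horizon: float | None = None,
) -> LearningOutcome:
    """Smallest sampled time from which every sampled ``b_k`` equals the
    target for the rest of the horizon; undefined if the timeline never locks
    onto the target."""
    times = timeline.times
    n = len(times)
    mask = np.ones(n, dtype=bool)
    if horizon is not None:
        mask = times <= horizon
    ok = np.ones(n, dtype=bool)
    for k, bk in enumerate(target):
        if k in timeline.betti:
            ok &= timeline.betti[k] == bk
    ok = ok[mask]
    ts = times[mask]
    final = tuple(
        int(timeline.betti[k][mask][-1]) if k in timeline.betti else 0
        for k in range(len(target))
    )
    if not ok[-1]:
        return LearningOutcome(t_min=None, final_betti=final, correct=False)
    bad = np.nonzero(~ok)[0]
    if len(bad) == 0:
        return LearningOutcome(t_min=0.0, final_betti=final, correct=True)
    t_min = float(ts[bad[-1] + 1]) if bad[-1] + 1 < len(ts) else float(ts[-1])
    return LearningOutcome(t_min=t_min, final_betti=final, correct=True)


def loop_stats(barcode: Barcode) -> LoopStats:
    """Birth/death/lifetime/length statistics of 1D loops; spurious loops are
    the finite dimension-1 intervals."""
    loops = barcode.in_dim(1)
    spurious = [iv for iv in loops if math.isfinite(iv.death)]
    lengths = [iv.length for iv in loops if iv.length is not None]

    def _mean(xs):
        return float(np.mean(xs)) if xs else float("nan")

    return LoopStats(
        n_loops=len(loops),
        n_spurious=len(spurious),
        mean_birth=_mean([iv.birth for iv in spurious]),
        mean_death=_mean([iv.death for iv in spurious]),
        mean_lifetime=_mean([iv.lifetime for iv in spurious]),
        mean_length=_mean(lengths),
    )


def complex_size(complex: FilteredCliqueComplex, t: float = math.inf) -> dict[int, int]:
    """Simplex counts per dimension at filtration time ``t``."""
    return complex.counts(t)


# ---------------------------------------------------------------------------
# strong collapse and final Betti numbers


def strong_collapse(graph: nx.Graph) -> nx.Graph:
    """Core of the flag complex under strong collapses.

    A vertex ``v`` is dominated if its closed neighbourhood is contained in
    the closed neighbourhood of another vertex; removing dominated vertices
    preserves the homotopy type of the flag complex.  Iterates to a fixed
    point.
    """
    nodes = list(graph.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    nbr = [0] * len(nodes)
    for u, v in graph.edges:
        nbr[idx[u]] |= 1 << idx[v]
        nbr[idx[v]] |= 1 << idx[u]
    alive = set(range(len(nodes)))
    closed = {k: nbr[k] | (1 << k) for k in alive}
    changed = True
    while changed and len(alive) > 1:
        changed = False
        for v in sorted(alive):
            cv = closed[v]
            cand = nbr[v]
            while cand:
                u = cand.bit_length() - 1
                cand ^= 1 << u
                if u in alive and u != v and (cv & ~closed[u]) == 0:
                    # v dominated by u: delete v
                    alive.discard(v)
                    mask = ~(1 << v)
                    w = nbr[v]
                    while w:
                        x = w.bit_length() - 1
                        w ^= 1 << x
                        if x in alive:
                            nbr[x] &= mask
                            closed[x] &= mask
                    changed = True
                    break
    return graph.subgraph([nodes[k] for k in alive]).copy()


def flag_betti_numbers(graph: nx.Graph, max_dim: int = 2,
                       max_simplices: int = 5_000_000) -> tuple[int, ...]:
    """Betti numbers ``b_0 .. b_max_dim`` of the flag complex of a graph,
    computed by GF(2) boundary ranks after a strong collapse."""
    core = strong_collapse(graph)
    nodes = sorted(core.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in core.edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = True
    # enumerate cliques per dimension up to max_dim + 1
    by_dim: list[list[tuple[int, ...]]] = [[(k,) for k in range(len(nodes))]]
    total = len(nodes)
    for dim in range(1, max_dim + 2):
        cur: list[tuple[int, ...]] = []
        for s in by_dim[dim - 1]:
            mask = np.ones(len(nodes), dtype=bool)
            for v in s:
                mask &= adj[v]
            mask[: s[-1] + 1] = False
            for k in np.nonzero(mask)[0]:
                cur.append(s + (int(k),))
        total += len(cur)
        if total > max_simplices:
            raise RuntimeError("flag complex too large even after collapse")
        by_dim.append(cur)
        if not cur:
            by_dim.extend([[] for _ in range(max_dim + 1 - dim)])
            break
    ranks = [0]
    for dim in range(1, max_dim + 2):
        index = {s: k for k, s in enumerate(by_dim[dim - 1])}
        cols = []
        for s in by_dim[dim]:
            col = 0
            for f in combinations(s, dim):
                col |= 1 << index[f]
            cols.append(col)
        ranks.append(gf2_rank(cols))
    betti = []
    for dim in range(max_dim + 1):
        betti.append(len(by_dim[dim]) - ranks[dim] - ranks[dim + 1])
    return tuple(betti)


def final_betti(graph: CoactivityGraph, max_dim: int = 2) -> tuple[int, ...]:
    """Final Betti numbers of the fully-grown coactivity complex."""
    return flag_betti_numbers(graph.graph, max_dim=max_dim)
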