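"""Forman curvature of the weighted coactivity graph.

For an undirected edge ``e = (v1, v2)`` with weight ``w(e)`` and vertex
weights ``w(v1)``, ``w(v2)`` the Forman curvature is

    R_F(e) = w(v1) + w(v2)
             - sum over other edges e' at v1 of w(v1) * sqrt(w(e) / w(e'))
             - sum over other edges e' at v2 of w(v2) * sqrt(w(e) / w(e')),

and the vertex curvature ``R_F(v)`` is the mean over the edges meeting at
``v``.  With all weights equal to one this reduces to the combinatorial form
``R_F(e) = 4 - deg(v1) - deg(v2)``.  In the coactivity graph, vertex weights
are spike counts and edge weights are pairwise spike-count correlations
(floored at a small positive value, since the formula requires positive
weights under the square root); high-curvature vertices and edges mark the
most visited, most correlated parts of the map, and they are the ones that
survive synaptic weakening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "CurvatureResult",
    "edge_curvature",
    "vertex_curvature",
    "forman_curvature",
    "curvature_decay",
    "EDGE_WEIGHT_FLOOR",
]

EDGE_WEIGHT_FLOOR = 1e-3  # applied to non-positive correlation weights


@dataclass
class CurvatureResult:
    edge: dict[tuple[int, int], float]
    vertex: dict[int, float]  # isolated vertices are absent (undefined mean)

    @property
    def mean_edge(self) -> float:
        return float(np.mean(list(self.edge.values()))) if self.edge else float("nan")

    @property
    def mean_vertex(self) -> float:
        return float(np.mean(list(self.vertex.values()))) if self.vertex else float("nan")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ef = pd.DataFrame(
            [{"i": i, "j": j, "R_F": r} for (i, j), r in self.edge.items()]
        )
        vf = pd.DataFrame([{"v": v, "R_F": r} for v, r in self.vertex.items()])
        return ef, vf


def _weights(g: nx.Graph, floor: float) -> tuple[dict, dict]:
    vw = {}
    for v, d in g.nodes(data=True):
        w = float(d.get("weight", 1.0))
        if w <= 0:
            raise ValueError(f"non-positive vertex weight at {v}")
        vw[v] = w
    ew = {}
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        ew[tuple(sorted((u, v)))] = w if w > 0 else floor
    return vw, ew


def edge_curvature(
    g: nx.Graph, e: tuple[int, int], floor: float = EDGE_WEIGHT_FLOOR
) -> float:
    """Forman curvature of a single edge of a weighted graph."""
    vw, ew = _weights(g, floor)
    return _edge_curvature(g, tuple(sorted(e)), vw, ew)


def _edge_curvature(g, e, vw, ew) -> float:
    u, v = e
    we = ew[e]
    r = vw[u] + vw[v]
    for x, other in ((u, v), (v, u)):
        for y in g.neighbors(x):
            if y == other:
                continue
            r -= vw[x] * np.sqrt(we / ew[tuple(sorted((x, y)))])
    return float(r)


def vertex_curvature(result: CurvatureResult, v: int) -> float:
    """Mean curvature of the edges meeting at ``v`` (KeyError if isolated)."""
    return result.vertex[v]


def forman_curvature(g: nx.Graph, floor: float = EDGE_WEIGHT_FLOOR) -> CurvatureResult:
    """Forman curvature of every edge and vertex of a weighted graph.

    Vertex/edge weights are read from the ``weight`` attributes (default 1);
    non-positive edge weights are floored at ``floor``.
    """
    vw, ew = _weights(g, floor)
    edge_r = {e: _edge_curvature(g, e, vw, ew) for e in ew}
    vertex_r = {}
    for v in g.nodes:
        inc = [edge_r[tuple(sorted((v, y)))] for y in g.neighbors(v)]
        if inc:
            vertex_r[v] = float(np.mean(inc))
    return CurvatureResult(edge=edge_r, vertex=vertex_r)


def curvature_decay(session, p_hats, q_hat: float = 1.0,
                    c_p: float = 0.04, c_q: float = 0.04) -> pd.DataFrame:
    """Effective-graph size and mean Forman curvature along a transmission
    sweep over the *same* base spike trains (common random numbers).

    Returns one row per ``p_hat`` with the effective edge count and the mean
    edge/vertex curvatures; edge counts are non-increasing as ``p_hat``
    decreases because the effective graphs are nested.
    """
    from .pipeline import run_effective  # local import avoids a cycle
    from .synapses import SynapticModel

    rows = []
    for p_hat in p_hats:
        run = run_effective(
            session,
            SynapticModel(p_hat=float(p_hat), q_hat=q_hat, c_p=c_p, c_q=c_q),
            representatives=False,
        )
        cur = forman_curvature(run.graph.graph)
        rows.append(
            {
                "p_hat": float(p_hat),
                "n_edges": run.graph.n_edges,
                "n_vertices": run.graph.n_vertices,
                "mean_R_F_vertex": cur.mean_vertex,
                "mean_R_F_edge": cur.mean_edge,
            }
        )
    return pd.DataFrame(rows)
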