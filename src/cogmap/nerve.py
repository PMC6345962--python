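"""Geometric nerve complex of a place-field map.

The nerve of a cover has one k-simplex per (k+1)-wise overlap of cover
elements; by the nerve theorem (for good covers) it has the topological shape
of the covered space.  Here the cover elements are the level-set discs of the
Gaussian place fields — disc of cell ``c`` = region where
``lambda_c >= level * f_c``, i.e. radius ``s_c * sqrt(-2 ln level)``.  This
static complex serves as a geometric cross-check for the spike-driven
coactivity complexes.

Overlap tests use exact polygonal approximations of the discs (shapely); for
discs, pairwise intersection gives the edges and higher simplices are checked
by explicit k-wise region intersection (Helly's theorem in the plane only
guarantees triples => higher overlaps, so triples are tested directly).
"""

from __future__ import annotations

import math
from itertools import combinations

from shapely.geometry import Point

from .cells import PlaceCell
from .topology import FilteredCliqueComplex

__all__ = ["nerve_complex", "field_radius"]


def field_radius(cell: PlaceCell, level: float) -> float:
    """Radius of the place-field disc at a given rate fraction ``level``."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    return cell.size * math.sqrt(-2.0 * math.log(level))


def nerve_complex(
    cells: list[PlaceCell],
    level: float = math.exp(-2.0),
    max_dim: int = 3,
    quad_segs: int = 64,
) -> FilteredCliqueComplex:
    """Static nerve complex of the place-field discs (all filtration values 0).

    The default ``level = e^-2`` puts the disc radius at ``2 s_c``, i.e. a
    field extent of about ``3-4 s_c`` in diameter, matching the usual reading
    of "place-field size".
    """
    discs = [Point(c.center).buffer(field_radius(c, level), quad_segs=quad_segs)
             for c in cells]
    n = len(cells)
    simplices: dict[tuple[int, ...], float] = {(i,): 0.0 for i in range(n)}
    # edges by pairwise intersection
    edges = []
    for i, j in combinations(range(n), 2):
        if discs[i].intersects(discs[j]):
            simplices[(i, j)] = 0.0
            edges.append((i, j))
    adj = [set() for _ in range(n)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    # higher simplices: common point of all member discs, built incrementally
    # from (k-1)-simplices whose running intersection region is non-empty
    frontier = {}
    for i, j in edges:
        frontier[(i, j)] = discs[i].intersection(discs[j])
    for dim in range(2, max_dim + 1):
        nxt = {}
        for simplex, region in frontier.items():
            last = simplex[-1]
            common = set.intersection(*(adj[v] for v in simplex))
            for k in sorted(common):
                if k <= last:
                    continue
                inter = region.intersection(discs[k])
                if not inter.is_empty and inter.area > 0:
                    nxt[simplex + (k,)] = inter
        for s in nxt:
            simplices[s] = 0.0
        if not nxt:
            break
        frontier = nxt
    return FilteredCliqueComplex(simplices=simplices, max_dim=max_dim)
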