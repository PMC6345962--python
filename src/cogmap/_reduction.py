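"""Sparse GF(2) column reduction for persistent homology.

Columns are Python integers used as bit vectors over the row index set (bit i
set <=> row i present in the column).  The standard persistence algorithm
processes columns in filtration order and repeatedly adds (XORs) the stored
column with the same pivot (highest set bit) until the column is either empty
(a *positive* column, creating a homology class one dimension down from its
own) or claims a fresh pivot (a *negative* column, killing the class created
by the row simplex of its pivot).
"""

from __future__ import annotations

__all__ = ["reduce_boundary"]


def reduce_boundary(columns: list[int]) -> tuple[dict[int, int], list[int]]:
    """Reduce boundary columns given in filtration order.

    Returns ``(pivots, positive)`` where ``pivots`` maps a row index to the
    index (into ``columns``) of the column whose reduced form has that pivot,
    and ``positive`` lists the indices of columns that reduced to zero.
    """
    pivots: dict[int, int] = {}
    reduced: dict[int, int] = {}  # pivot row -> reduced column bitmask
    positive: list[int] = []
    for j, col in enumerate(columns):
        while col:
            p = col.bit_length() - 1
            if p in reduced:
                col ^= reduced[p]
            else:
                reduced[p] = col
                pivots[p] = j
                break
        else:
            positive.append(j)
    return pivots, positive


def gf2_rank(columns: list[int]) -> int:
    """Rank of a GF(2) matrix given as bit-vector columns (any order)."""
    pivots: dict[int, int] = {}
    rank = 0
    for col in columns:
        while col:
            p = col.bit_length() - 1
            if p in pivots:
                col ^= pivots[p]
            else:
                pivots[p] = col
                rank += 1
                break
    return rank
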