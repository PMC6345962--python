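"""Deterministic nine-field annular toy.

A miniature map for illustrating and testing topological learning: nine place
fields arranged around a central obstacle — seven on a ring and two on an
outer bulge — traversed by a scripted trajectory in the order of their ids.
Fed through the ideal-synapse pipeline it reproduces the canonical learning
story:

* one persistent connected component (the fields are traversed in sequence,
  so the coactivity graph stays connected);
* one persistent 1D loop, born when the exploration first closes around the
  obstacle — its birth time is the learning time of the toy;
* at least one short-lived *spurious* loop: the outer bulge cells close a
  quadrilateral (ring cell 0 — bulge cells 1, 2 — ring cell 3) whose
  diagonal coactivities are only detected later; until then the quadrilateral
  is an extra, physically meaningless hole.  It dies the moment a diagonal
  pair is caught coactive, which the trajectory guarantees by parking on the
  diagonal's overlap zone after the loop closes.

The trajectory is a deterministic waypoint script (constant speed per
segment, with parking dwells on specific field overlaps); the only
randomness is Poisson spiking, fixed by :data:`TOY_SEED`.
"""

from __future__ import annotations

import math

import numpy as np

from .arena import Arena, Trajectory, make_arena
from .cells import PlaceCell

__all__ = ["make_fig2_fixture", "run_toy", "TOY_SEED"]

TOY_SEED = 0  # default spike seed for the toy pipeline

_RING_RADIUS = 24.0
_OUTER_RADIUS = 40.0
_RING_WIDTH = 6.0    # Gaussian width of the ring fields (cm)
_OUTER_WIDTH = 5.5
_RING_RATE = 10.0
_OUTER_RATE = 25.0
_OBSTACLE_RADIUS = 12.0
_N_RING = 7


def _toy_cells(center: np.ndarray) -> list[PlaceCell]:
    step = 360.0 / _N_RING  # 51.43 deg between ring fields
    polar = [
        (0, _RING_RADIUS, 0.0, _RING_WIDTH, _RING_RATE),   # ring cell A
        (1, 45.0, 8.0, _OUTER_WIDTH, _OUTER_RATE),         # bulge C
        (2, 42.0, 33.0, _OUTER_WIDTH, _OUTER_RATE),        # bulge D
        (3, _RING_RADIUS, step, _RING_WIDTH, _RING_RATE),  # ring cell B
    ] + [
        (4 + k, _RING_RADIUS, step * (2 + k), _RING_WIDTH, _RING_RATE)
        for k in range(_N_RING - 2)
    ]
    cells = []
    for cid, r, ang, width, rate in polar:
        a = math.radians(ang)
        cells.append(
            PlaceCell(id=cid,
                      center=(center[0] + r * math.cos(a),
                              center[1] + r * math.sin(a)),
                      size=width, peak_rate=rate)
        )
    return cells


def _polar(center: np.ndarray, r: float, ang_deg: float) -> np.ndarray:
    a = math.radians(ang_deg)
    return center + r * np.array([math.cos(a), math.sin(a)])


def _toy_path(center: np.ndarray, cells: list[PlaceCell]) -> tuple[np.ndarray, np.ndarray]:
    """Waypoints and per-segment speeds of the scripted exploration."""
    pos = {c.id: np.asarray(c.center) for c in cells}
    step = 360.0 / _N_RING

    points: list[np.ndarray] = []
    speeds: list[float] = []

    def go(p: np.ndarray, speed: float = 10.0) -> None:
        if points:
            points.append(p)
            speeds.append(speed)
        else:
            points.append(p)

    def park(p: np.ndarray, seconds: float) -> None:
        # a short there-and-back jitter traversed slowly emulates standing still
        go(p)
        eps = np.array([0.4, 0.0])
        slow = 0.8 / seconds
        go(p + eps, slow)
        go(p, slow)

    def arc(a0: float, a1: float, r: float = _RING_RADIUS,
            speed: float = 6.0, n: int = 60) -> None:
        for a in np.linspace(a0, a1, n)[1:]:
            go(_polar(center, r, a), speed)

    # phase 1: up the outer bulge 0 -> 1 -> 2 -> 3, parking on each overlap
    go(pos[0])
    park((pos[0] + pos[1]) / 2, 4.0)
    go(pos[1])
    park((pos[1] + pos[2]) / 2, 3.0)
    go(pos[2])
    park((pos[2] + pos[3]) / 2, 4.0)
    go(pos[3], 8.0)

    # phase 2: around the ring 3 -> 4 -> ... -> 8 -> 0, then on to the
    # (0, 3) overlap zone (the inner chord midpoint, well away from the bulge
    # fields), closing both the annulus and the outer quad
    arc(step, 360.0, speed=5.0, n=140)
    arc(360.0, 360.0 + step / 2, speed=6.0, n=20)
    park((pos[0] + pos[3]) / 2, 3.5)

    # phase 3: park on the diagonal (0, 2) overlap to kill the spurious quad
    diag = pos[0] + 14.0 / np.linalg.norm(pos[2] - pos[0]) * (pos[2] - pos[0])
    park(diag, 12.0)

    # phase 4: four consolidating ring laps
    go(_polar(center, _RING_RADIUS, step / 2 + 5.0), 8.0)
    arc(step / 2 + 5.0, step / 2 + 5.0 + 4 * 360.0, speed=5.0, n=650)
    return np.array(points), np.array(speeds)


def _resample(points: np.ndarray, speeds: np.ndarray, dt: float) -> np.ndarray:
    """Resample a polyline at piecewise-constant per-segment speed."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = seg > 1e-12
    seg, speeds = seg[keep], speeds[keep]
    pts = np.vstack([points[0], points[1:][keep]])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    cum_t = np.concatenate([[0.0], np.cumsum(seg / speeds)])
    tq = np.arange(0.0, cum_t[-1], dt)
    sq = np.interp(tq, cum_t, cum)
    return np.stack(
        [np.interp(sq, cum, pts[:, 0]), np.interp(sq, cum, pts[:, 1])], axis=1
    )


def make_fig2_fixture(
    arena_side: float = 100.0,
    dt: float = 0.025,
) -> tuple[Arena, list[PlaceCell], Trajectory]:
    """Nine annular place fields around a central obstacle plus the scripted
    trajectory traversing them in id order.

    Returns ``(arena, cells, trajectory)``; run the ideal pipeline on it with
    spike seed :data:`TOY_SEED` to reproduce the toy barcode.
    """
    arena = make_arena(arena_side, arena_side, _OBSTACLE_RADIUS)
    c = np.array([arena_side / 2.0, arena_side / 2.0])
    cells = _toy_cells(c)
    points, speeds = _toy_path(c, cells)
    positions = _resample(points, speeds, dt)
    return arena, cells, Trajectory(dt=dt, positions=positions)


def run_toy(seed: int = TOY_SEED):
    """Run the toy through the ideal-synapse pipeline.

    Returns ``(graph, barcode, timeline, outcome)`` for the default toy at
    the given spike seed.
    """
    from .cells import SpikingConfig, generate_spikes
    from .synapses import SynapticModel, detect_coactivity, sample_probabilities, screen_spikes
    from .topology import betti_timeline, build_graph, clique_filtration, learning_time, persistence

    arena, cells, traj = make_fig2_fixture()
    cfg = SpikingConfig()
    spikes = generate_spikes(cells, traj, cfg, seed=seed)
    sample = sample_probabilities(SynapticModel(c_p=0.0, c_q=0.0), len(cells), seed=seed)
    spikes = screen_spikes(spikes, sample, seed=seed)  # identity at p = 1
    events = detect_coactivity(spikes, cfg, sample, seed=seed, duration=traj.duration)
    graph = build_graph(events, spikes, cfg, duration=traj.duration)
    barcode = persistence(clique_filtration(graph, max_dim=2))
    n_win = int(math.ceil(traj.duration / cfg.window))
    timeline = betti_timeline(barcode, np.arange(n_win) * cfg.window)
    outcome = learning_time(timeline, (1, 1), horizon=traj.duration)
    return graph, barcode, timeline, outcome
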