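"""Arena geometry, exploratory trajectories and occupancy maps.

The environment is a rectangular open-field arena, optionally with disc-shaped
obstacles (the canonical configuration is a 1 m x 1 m box with one central
"hole", matching typical rodent electrophysiology arenas).  Trajectories are
correlated random walks meant to emulate non-preferential exploratory
behaviour: speed fluctuates around a mean, heading diffuses like a
mean-reverting angular process, and the walker reflects specularly off walls
and obstacle rims.  Nothing in the walk favours one part of the arena over
another, so long sessions cover every accessible spatial bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Arena",
    "Trajectory",
    "OccupancyMap",
    "make_arena",
    "simulate_trajectory",
    "occupancy_map",
    "save_trajectory",
    "load_trajectory",
]


@dataclass(frozen=True)
class Arena:
    """Rectangular arena with disc obstacles.

    Parameters
    ----------
    width, height:
        Side lengths in cm.
    obstacles:
        List of ``(cx, cy, radius)`` discs in cm.  Discs must lie strictly
        inside the rectangle and be pairwise disjoint.
    """

    width: float
    height: float
    obstacles: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena sides must be positive")
        for cx, cy, r in self.obstacles:
            if r < 0:
                raise ValueError("obstacle radius must be non-negative")
            if r > 0 and not (
                r < cx < self.width - r and r < cy < self.height - r
            ):
                raise ValueError("obstacle must lie strictly inside the arena")
        obs = [o for o in self.obstacles if o[2] > 0]
        for i in range(len(obs)):
            for j in range(i + 1, len(obs)):
                d = math.hypot(obs[i][0] - obs[j][0], obs[i][1] - obs[j][1])
                if d <= obs[i][2] + obs[j][2]:
                    raise ValueError("obstacles must be pairwise disjoint")

    @property
    def area(self) -> float:
        """Accessible area in cm^2."""
        return self.width * self.height - sum(
            math.pi * r * r for _, _, r in self.obstacles
        )

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Vectorised membership test for the accessible region."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ok = (
            (xy[:, 0] >= 0)
            & (xy[:, 0] <= self.width)
            & (xy[:, 1] >= 0)
            & (xy[:, 1] <= self.height)
        )
        for cx, cy, r in self.obstacles:
            if r > 0:
                d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
                ok &= d2 >= r * r
        return ok


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped positions sampled at a fixed timestep.

    ``positions`` has shape ``(n_steps + 1, 2)`` where
    ``n_steps = round(duration / dt)``; row ``k`` is the position at time
    ``k * dt`` in cm.
    """

    dt: float
    positions: np.ndarray
    duration: float = field(default=0.0)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if self.duration == 0.0:
            object.__setattr__(self, "duration", (len(pos) - 1) * self.dt)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) * self.dt

    def position_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the position at arbitrary times."""
        t = np.asarray(t, dtype=float)
        x = np.interp(t, self.times, self.positions[:, 0])
        y = np.interp(t, self.times, self.positions[:, 1])
        return np.stack([x, y], axis=-1)


@dataclass(frozen=True)
class OccupancyMap:
    """Dwell time (s) per spatial bin; ``counts[ix, iy]`` covers the half-open
    square ``[ix*b, (ix+1)*b) x [iy*b, (iy+1)*b)``."""

    bin_size: float
    counts: np.ndarray

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def make_arena(width: float, height: float, obstacle_radius: float = 0.0) -> Arena:
    """Build a rectangular arena with a single centred disc obstacle.

    ``obstacle_radius = 0`` yields an open field.  An obstacle touching the
    boundary is rejected.
    """
    if width <= 0 or height <= 0:
        raise ValueError("arena sides must be positive")
    if obstacle_radius < 0 or obstacle_radius >= min(width, height) / 2:
        raise ValueError("obstacle radius must satisfy 0 <= r < min(w, h)/2")
    obstacles = ()
    if obstacle_radius > 0:
        obstacles = ((width / 2.0, height / 2.0, obstacle_radius),)
    return Arena(width=width, height=height, obstacles=obstacles)


def _reflect_step(arena: Arena, p: np.ndarray, step: np.ndarray) -> tuple[np.ndarray, float]:
    """Take one step from ``p``; reflect off walls/obstacles if needed.

    Returns the new position and the (possibly adjusted) heading.  Reflection
    is specular in direction; if the reflected candidate is still outside the
    accessible region (corner cases), the walker stays put and the heading is
    reversed.
    """
    q = p + step
    d = step.copy()
    # walls: mirror the coordinate and flip the step component
    if q[0] < 0:
        q[0] = -q[0]
        d[0] = -d[0]
    elif q[0] > arena.width:
        q[0] = 2 * arena.width - q[0]
        d[0] = -d[0]
    if q[1] < 0:
        q[1] = -q[1]
        d[1] = -d[1]
    elif q[1] > arena.height:
        q[1] = 2 * arena.height - q[1]
        d[1] = -d[1]
    # obstacles: reflect about the tangent at the rim crossing
    for cx, cy, r in arena.obstacles:
        if r <= 0:
            continue
        v = q - np.array([cx, cy])
        dist = math.hypot(v[0], v[1])
        if dist < r:
            if dist < 1e-9:
                q = p.copy()
                d = -d
                break
            # push the point back outside, mirrored across the rim
            q = np.array([cx, cy]) + v * ((2 * r - dist) / dist)
            n = v / dist
            d = d - 2 * np.dot(d, n) * n
    if not arena.contains(q[None, :])[0]:
        return p.copy(), math.atan2(-d[1], -d[0])
    return q, math.atan2(d[1], d[0])


def simulate_trajectory(
    arena: Arena,
    duration: float,
    dt: float = 0.025,
    speed_mean: float = 20.0,
    seed: int = 0,
    *,
    speed_cv: float = 0.3,
    turn_rate: float = 2.0,
    start: tuple[float, float] | None = None,
) -> Trajectory:
    """Simulate a correlated-random-walk exploratory trajectory.

    Speed at each step is lognormal around ``speed_mean`` (cm/s) with
    coefficient of variation ``speed_cv``; the heading performs a
    mean-reverting-free angular diffusion with standard deviation
    ``turn_rate * sqrt(dt)`` rad per step; walls and obstacle rims reflect
    specularly.  Identical ``(arguments, seed)`` give identical trajectories.
    """
    if duration <= 0 or dt <= 0 or speed_mean <= 0:
        raise ValueError("duration, dt and speed_mean must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA2E7A]))
    n = int(round(duration / dt))
    # lognormal speed parameters from mean/CV
    sig2 = math.log(1.0 + speed_cv**2)
    mu = math.log(speed_mean) - sig2 / 2.0
    speeds = np.exp(rng.normal(mu, math.sqrt(sig2), size=n))
    turns = rng.normal(0.0, turn_rate * math.sqrt(dt), size=n)

    if start is None:
        while True:
            p = rng.uniform([0, 0], [arena.width, arena.height])
            if arena.contains(p[None, :])[0]:
                break
    else:
        p = np.asarray(start, dtype=float)
        if not arena.contains(p[None, :])[0]:
            raise ValueError("start position outside accessible region")
    heading = rng.uniform(0, 2 * math.pi)

    out = np.empty((n + 1, 2))
    out[0] = p
    for k in range(n):
        heading += turns[k]
        step = speeds[k] * dt * np.array([math.cos(heading), math.sin(heading)])
        p, heading = _reflect_step(arena, p, step)
        out[k + 1] = p
    return Trajectory(dt=dt, positions=out, duration=n * dt)


def occupancy_map(traj: Trajectory, arena: Arena, bin_size: float) -> OccupancyMap:
    """Dwell time per spatial bin; each sample contributes one ``dt`` to the
    bin containing it (the final sample contributes nothing, so the total
    equals the duration exactly)."""
    nx = int(round(arena.width / bin_size))
    ny = int(round(arena.height / bin_size))
    if abs(nx * bin_size - arena.width) > 1e-9 or abs(ny * bin_size - arena.height) > 1e-9:
        raise ValueError("bin_size must divide the arena dimensions")
    pos = traj.positions[:-1]
    ix = np.clip((pos[:, 0] / bin_size).astype(int), 0, nx - 1)
    iy = np.clip((pos[:, 1] / bin_size).astype(int), 0, ny - 1)
    counts = np.zeros((nx, ny))
    np.add.at(counts, (ix, iy), traj.dt)
    return OccupancyMap(bin_size=bin_size, counts=counts)


def save_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame(
        {"t": traj.times, "x": traj.positions[:, 0], "y": traj.positions[:, 1]}
    )
    df.to_csv(path, index=False)


def load_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    dt = float(df["t"].iloc[1] - df["t"].iloc[0]) if len(df) > 1 else 1.0
    return Trajectory(dt=dt, positions=df[["x", "y"]].to_numpy())
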