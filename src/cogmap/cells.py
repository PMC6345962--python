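"""Place-cell ensembles and theta-modulated Poisson spike trains.

Each place cell ``c`` fires as an inhomogeneous Poisson process with a
Gaussian spatial rate

    lambda_c(r) = f_c * exp(-|r - r_c|^2 / (2 s_c^2)),

where ``f_c`` is the peak rate (Hz), ``s_c`` the Gaussian width of the place
field (cm) and ``r_c`` its centre.  The *place-field size* — the field's
visible extent, the quantity usually reported for recorded place cells — is
about three Gaussian widths (``size_c = 3 s_c``): outside 1.5 widths from the
centre the rate has dropped below ~33% of the peak.

Across an ensemble the peak rates and field sizes are lognormal, right-skewed
as observed in hippocampal recordings: means ``(f, s)`` with variances
``(a*f, b*s)`` (defaults a = 1.2 Hz, b = 1.7 cm, i.e. variance grows linearly
with the mean).  Centres are uniform over the accessible region of the arena.
Spiking probability is modulated multiplicatively by an 8 Hz theta wave whose
phase is random per cell; the modulation time-averages to one so it
redistributes spikes within theta cycles without changing mean rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import Arena, Trajectory

__all__ = [
    "EnsembleParams",
    "PlaceCell",
    "SpikeTrain",
    "SpikingConfig",
    "lognormal_from_mean_sd",
    "sample_ensemble",
    "rate_at",
    "generate_spikes",
    "save_ensemble",
    "load_ensemble",
    "save_spikes",
    "load_spikes",
]


#: ratio of the place-field size (extent) to the Gaussian width of the rate
SIZE_TO_WIDTH = 3.0


@dataclass(frozen=True)
class EnsembleParams:
    """Ensemble-level spiking parameters.

    ``N`` cells; ``f`` is the mean peak firing rate (Hz) and ``s`` the mean
    place-field *size* (extent, cm; the Gaussian width of the rate is
    ``s / 3``).  ``a`` and ``b`` are the dispersion coefficients: the
    lognormal variances are ``Var(f_c) = a * f`` (Hz^2) and
    ``Var(size_c) = b * s`` (cm^2).
    """

    N: int
    f: float = 20.0
    s: float = 15.0
    a: float = 1.2
    b: float = 1.7

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.f <= 0 or self.s <= 0:
            raise ValueError("f and s must be positive")
        if self.a < 0 or self.b < 0:
            raise ValueError("dispersion factors must be non-negative")


@dataclass(frozen=True)
class PlaceCell:
    id: int
    center: tuple[float, float]
    size: float
    peak_rate: float

    def __post_init__(self) -> None:
        if self.size <= 0 or self.peak_rate < 0:
            raise ValueError("invalid place-cell parameters")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) of one cell."""

    cell_id: int
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SpikingConfig:
    """Theta modulation and coactivity-window parameters.

    ``window`` is the coactivity detection window (s), about two theta
    periods; it also sets the timestep of the topological computations.
    """

    theta_freq: float = 8.0
    theta_depth: float = 0.7
    window: float = 0.250

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0.0 <= self.theta_depth <= 1.0:
            raise ValueError("theta_depth must be in [0, 1]")


def lognormal_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Lognormal ``(mu, sigma)`` matching a given mean and standard deviation."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    sig2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sig2 / 2.0
    return mu, math.sqrt(sig2)


def sample_ensemble(params: EnsembleParams, arena: Arena, seed: int = 0) -> list[PlaceCell]:
    """Sample ``N`` place cells: lognormal peak rates and field sizes
    (moment-matched to mean ``f`` / ``s`` and variance ``a*f`` / ``b*s``),
    centres uniform over the accessible region.  The stored ``size`` of each
    cell is the Gaussian width of its rate, i.e. field size / 3."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCE11]))
    if params.a > 0:
        mu_f, sg_f = lognormal_from_mean_sd(params.f, math.sqrt(params.a * params.f))
        rates = np.exp(rng.normal(mu_f, sg_f, size=params.N))
    else:
        rates = np.full(params.N, params.f)
    if params.b > 0:
        mu_s, sg_s = lognormal_from_mean_sd(params.s, math.sqrt(params.b * params.s))
        sizes = np.exp(rng.normal(mu_s, sg_s, size=params.N))
    else:
        sizes = np.full(params.N, params.s)
    sizes = sizes / SIZE_TO_WIDTH  # store the Gaussian width
    centers = np.empty((params.N, 2))
    got = 0
    while got < params.N:
        cand = rng.uniform([0, 0], [arena.width, arena.height], size=(params.N, 2))
        ok = arena.contains(cand)
        take = min(int(ok.sum()), params.N - got)
        centers[got : got + take] = cand[ok][:take]
        got += take
    return [
        PlaceCell(id=i, center=(centers[i, 0], centers[i, 1]),
                  size=float(sizes[i]), peak_rate=float(rates[i]))
        for i in range(params.N)
    ]


def rate_at(cell: PlaceCell, position) -> float | np.ndarray:
    """Gaussian place-field rate ``lambda_c`` at one or many positions."""
    pos = np.asarray(position, dtype=float)
    d2 = ((pos - np.asarray(cell.center)) ** 2).sum(axis=-1)
    return cell.peak_rate * np.exp(-d2 / (2.0 * cell.size**2))


def generate_spikes(
    cells: list[PlaceCell],
    traj: Trajectory,
    cfg: SpikingConfig = SpikingConfig(),
    seed: int = 0,
) -> list[SpikeTrain]:
    """Theta-modulated inhomogeneous Poisson spike trains along a trajectory.

    The rate is treated as constant within each trajectory timestep ``dt``
    (piecewise-constant thinning): per step the spike count is Poisson with
    mean ``lambda_c(r_t) * m(t) * dt`` and spikes are placed uniformly within
    the step.  ``m(t) = 1 + depth * cos(2 pi f_theta t + phi_c)`` with a
    uniform random per-cell phase ``phi_c``.  Fully deterministic per seed.
    """
    dt = traj.dt
    tmid = traj.times[:-1] + dt / 2.0
    pos = traj.positions[:-1]
    out: list[SpikeTrain] = []
    for c in cells:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x59C1, c.id]))
        phase = rng.uniform(0, 2 * math.pi)
        lam = np.asarray(rate_at(c, pos), dtype=float)
        if cfg.theta_depth > 0:
            lam = lam * (1.0 + cfg.theta_depth * np.cos(2 * math.pi * cfg.theta_freq * tmid + phase))
        # skip negligible-rate steps for speed; threshold well below one
        # expected spike per session
        mask = lam > 1e-12
        counts = np.zeros(len(lam), dtype=int)
        counts[mask] = rng.poisson(lam[mask] * dt)
        idx = np.repeat(np.nonzero(counts)[0], counts[counts > 0])
        times = idx * dt + rng.uniform(0.0, dt, size=len(idx))
        times = np.sort(times)
        # enforce strictly increasing times (coincidences have measure zero
        # but float ties are possible)
        if len(times) > 1:
            keep = np.concatenate([[True], np.diff(times) > 0])
            times = times[keep]
        out.append(SpikeTrain(cell_id=c.id, times=times))
    return out


def save_ensemble(cells: list[PlaceCell], path) -> None:
    pd.DataFrame(
        [
            {"id": c.id, "x_c": c.center[0], "y_c": c.center[1],
             "s_c": c.size, "f_c": c.peak_rate}
            for c in cells
        ]
    ).to_csv(path, index=False)


def load_ensemble(path) -> list[PlaceCell]:
    df = pd.read_csv(path)
    return [
        PlaceCell(id=int(r.id), center=(float(r.x_c), float(r.y_c)),
                  size=float(r.s_c), peak_rate=float(r.f_c))
        for r in df.itertuples()
    ]


def save_spikes(trains: list[SpikeTrain], path) -> None:
    rows = [(tr.cell_id, t) for tr in trains for t in tr.times]
    df = pd.DataFrame(rows, columns=["cell_id", "t"]).sort_values("t")
    df.to_csv(path, index=False)


def load_spikes(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(cell_id=int(cid), times=np.sort(grp["t"].to_numpy()))
        for cid, grp in df.groupby("cell_id")
    ]
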