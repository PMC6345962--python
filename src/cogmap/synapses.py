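"""Probabilistic synaptic transmission and coactivity readout.

Synaptic phenomenology is reduced to two families of probabilities: a
transmission probability ``p_k`` per place cell (the chance that one of its
spikes induces a sufficient postsynaptic potential in the readout neuron) and
a response probability ``q`` per readout neuron, one readout per cell pair
(the chance that the readout spikes when its pair is coactive within a
window).  Both are lognormal random variables, parameterised by their *modes*
``p_hat`` / ``q_hat`` and variances proportional to the squared modes
(``var = c * mode^2``), truncated to the probability range (0, 1].

Spike trains generated with ideal synapses are *screened*: each spike of cell
``k`` is kept independently with probability ``p_k``, and each within-window
pairwise coactivity of the screened trains is detected with probability
``q`` of that pair's readout.  All randomness is counter-based and keyed by
``(seed, cell)`` or ``(pair, window)``, so sweeps over ``p_hat`` or ``q_hat``
at a fixed seed are coupled by common random numbers: lower modes yield
nested subsets of retained spikes and detected events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .cells import SpikeTrain, SpikingConfig

__all__ = [
    "SynapticModel",
    "SynapticSample",
    "CoactivityEvent",
    "lognormal_mode_variance",
    "sample_probabilities",
    "screen_spikes",
    "detect_coactivity",
    "save_events",
    "pair_index",
]


@dataclass(frozen=True)
class SynapticModel:
    """Modes and variance coefficients of the synaptic probability
    distributions: ``var_p = c_p * p_hat^2`` and likewise for q."""

    p_hat: float = 1.0
    q_hat: float = 1.0
    c_p: float = 0.04
    c_q: float = 0.04

    def __post_init__(self) -> None:
        if not (0.0 < self.p_hat <= 1.0 and 0.0 < self.q_hat <= 1.0):
            raise ValueError("modes must lie in (0, 1]")
        if self.c_p < 0 or self.c_q < 0:
            raise ValueError("variance coefficients must be non-negative")


def lognormal_mode_variance(mode: float, variance: float) -> tuple[float, float]:
    """Lognormal ``(mu, sigma)`` from the mode and the variance.

    With ``variance = c * mode^2`` the shape equation
    ``(e^{s2} - 1) e^{3 s2} = c`` fixes ``sigma`` independently of the mode
    (the distribution scales with it); the smallest-``sigma^2`` root is taken
    (the equation is monotone, so it is unique).
    """
    if mode <= 0:
        raise ValueError("mode must be positive")
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if variance == 0:
        return math.log(mode), 0.0
    c = variance / mode**2
    s2 = brentq(lambda x: math.expm1(x) * math.exp(3 * x) - c, 1e-15, 30.0)
    return math.log(mode) + s2, math.sqrt(s2)


def _truncated_lognormal(u: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Inverse-CDF sample of a lognormal conditioned on being <= 1.

    Quantile coupling: for a fixed uniform ``u`` the result is monotone
    non-decreasing in the mode, which underpins the common-random-number
    coupling of parameter sweeps.
    """
    if sigma == 0.0:
        return np.minimum(np.exp(mu), 1.0) * np.ones_like(u)
    mass = ndtr(-mu / sigma)  # P(X <= 1)
    return np.exp(mu + sigma * ndtri(u * mass))


@dataclass(frozen=True)
class SynapticSample:
    """Realised per-cell transmission probabilities ``p[k]`` and per-readout
    response probabilities ``q`` (one readout per unordered cell pair)."""

    p: np.ndarray
    q: np.ndarray
    n_cells: int

    def q_for(self, i, j) -> np.ndarray:
        return self.q[pair_index(np.asarray(i), np.asarray(j), self.n_cells)]

    def to_csv(self, p_path, q_path) -> None:
        pd.DataFrame({"cell_id": np.arange(self.n_cells), "p_k": self.p}).to_csv(
            p_path, index=False
        )
        ii, jj = np.triu_indices(self.n_cells, k=1)
        pd.DataFrame({"i": ii, "j": jj, "q": self.q_for(ii, jj)}).to_csv(
            q_path, index=False
        )


def pair_index(i, j, n: int):
    """Index of the unordered pair (i < j) in lexicographic enumeration."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    return lo * (2 * n - lo - 1) // 2 + (hi - lo - 1)


def sample_probabilities(
    model: SynapticModel, n_cells: int, n_readouts: int | None = None, seed: int = 0
) -> SynapticSample:
    """Draw per-cell ``p_k`` and per-readout ``q`` from truncated lognormals.

    ``n_readouts`` defaults to one readout per unordered pair of cells.  The
    underlying uniforms depend only on ``(seed, unit index)``, so re-sampling
    with a different mode but the same seed gives quantile-coupled values.
    """
    if n_readouts is None:
        n_readouts = n_cells * (n_cells - 1) // 2
    if n_cells < 1 or n_readouts < 0:
        raise ValueError("need at least one cell")
    rng_p = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A1, 1]))
    rng_q = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A1, 2]))
    mu_p, sg_p = lognormal_mode_variance(model.p_hat, model.c_p * model.p_hat**2)
    mu_q, sg_q = lognormal_mode_variance(model.q_hat, model.c_q * model.q_hat**2)
    # open-interval uniforms keep the inverse CDF finite
    u_p = rng_p.uniform(1e-12, 1.0 - 1e-12, size=n_cells)
    u_q = rng_q.uniform(1e-12, 1.0 - 1e-12, size=n_readouts)
    return SynapticSample(
        p=_truncated_lognormal(u_p, mu_p, sg_p),
        q=_truncated_lognormal(u_q, mu_q, sg_q),
        n_cells=n_cells,
    )


def screen_spikes(
    trains: list[SpikeTrain], sample: SynapticSample, seed: int = 0
) -> list[SpikeTrain]:
    """Keep each spike of cell ``k`` independently with probability ``p_k``.

    The per-spike uniforms are a fixed function of ``(seed, cell, spike
    index)`` on the *base* train, so screening at a lower ``p_k`` retains a
    subset of the spikes retained at a higher one.
    """
    out = []
    for tr in trains:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 0x5C12E, int(tr.cell_id)])
        )
        u = rng.uniform(size=len(tr))
        out.append(SpikeTrain(cell_id=tr.cell_id, times=tr.times[u < sample.p[tr.cell_id]]))
    return out


class CoactivityEvent(NamedTuple):
    """A detected pairwise coactivity: cells ``i < j`` both fired at least one
    retained spike in window ``window_index``; ``time`` is the window start."""

    i: int
    j: int
    window_index: int
    time: float


# splitmix64 constants for the counter-based per-(pair, window) uniforms
_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + _SM_GAMMA).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x *= _SM_M1
    x ^= x >> np.uint64(27)
    x *= _SM_M2
    x ^= x >> np.uint64(31)
    return x


def _pair_window_uniform(i, j, win, seed: int) -> np.ndarray:
    """Deterministic uniform in [0,1) per (pair, window), independent of the
    order of enumeration — the readout-response coin flips."""
    key = _splitmix64(np.full(1, seed & 0xFFFFFFFFFFFFFFFF, np.uint64))[0]
    h = _splitmix64(i.astype(np.uint64) ^ key)
    h = _splitmix64(h ^ j.astype(np.uint64))
    h = _splitmix64(h ^ win.astype(np.uint64))
    return (h >> np.uint64(11)).astype(np.float64) / float(1 << 53)


def detect_coactivity(
    trains: list[SpikeTrain],
    cfg: SpikingConfig,
    sample: SynapticSample,
    seed: int = 0,
    duration: float | None = None,
) -> list[CoactivityEvent]:
    """Detect pairwise coactivity of screened trains through the readouts.

    The time axis is partitioned into consecutive windows of width
    ``cfg.window``; every (pair, window) with at least one retained spike from
    each cell is a candidate event, accepted with probability ``q`` of that
    pair's readout.  Events are returned sorted by (window, i, j).
    """
    w = cfg.window
    rows = []
    for tr in trains:
        if len(tr) == 0:
            continue
        wins = (tr.times / w).astype(np.int64)
        if duration is not None:
            wins = np.minimum(wins, int(math.ceil(duration / w)) - 1)
        uw = np.unique(wins)
        rows.append(np.stack([np.full(len(uw), tr.cell_id, dtype=np.int64), uw], axis=1))
    if not rows:
        return []
    cw = np.concatenate(rows)  # (cell, window) incidences
    order = np.lexsort((cw[:, 0], cw[:, 1]))
    cw = cw[order]
    wins, starts = np.unique(cw[:, 1], return_index=True)
    starts = np.append(starts, len(cw))
    I, J, W = [], [], []
    for k in range(len(wins)):
        active = cw[starts[k] : starts[k + 1], 0]
        if len(active) < 2:
            continue
        a, b = np.triu_indices(len(active), k=1)
        I.append(active[a])
        J.append(active[b])
        W.append(np.full(len(a), wins[k], dtype=np.int64))
    if not I:
        return []
    I = np.concatenate(I)
    J = np.concatenate(J)
    W = np.concatenate(W)
    u = _pair_window_uniform(I, J, W, seed)
    accept = u < sample.q_for(I, J)
    return [
        CoactivityEvent(int(i), int(j), int(win), float(win * w))
        for i, j, win in zip(I[accept], J[accept], W[accept])
    ]


def save_events(events: list[CoactivityEvent], path) -> None:
    """Write detected events as CSV (i, j, window_index, t)."""
    pd.DataFrame(events, columns=["i", "j", "window_index", "t"]).to_csv(
        path, index=False
    )
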