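"""End-to-end simulation pipeline.

A *session* is one exploration of an arena by a simulated animal with a fixed
place-cell ensemble: trajectory, sampled cells and ideal-synapse ("clamped")
spike trains.  An *effective run* screens those base trains through a
synaptic model (transmission probabilities per cell, readout probabilities
per pair), detects windowed coactivity, builds the filtered clique complex
and computes its persistence, Betti timelines and learning outcome.  Keeping
the session fixed while varying the synaptic modes couples the runs by common
random numbers: the effective graph at a lower transmission mode is a
subgraph of the one at a higher mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .arena import Arena, Trajectory, make_arena, simulate_trajectory
from .cells import (
    EnsembleParams,
    PlaceCell,
    SpikeTrain,
    SpikingConfig,
    generate_spikes,
    sample_ensemble,
)
from .synapses import (
    CoactivityEvent,
    SynapticModel,
    SynapticSample,
    detect_coactivity,
    sample_probabilities,
    screen_spikes,
)
from .topology import (
    Barcode,
    BettiTimeline,
    CoactivityGraph,
    FilteredCliqueComplex,
    LearningOutcome,
    LoopStats,
    betti_timeline,
    build_graph,
    clique_filtration,
    final_betti,
    learning_time,
    loop_stats,
    persistence,
)

__all__ = ["SessionConfig", "Session", "EffectiveRun", "simulate_session", "run_effective"]


@dataclass(frozen=True)
class SessionConfig:
    """Study conditions for one simulated exploration session.

    Defaults describe the standard desk-scale setup: a 100 x 100 cm arena
    with a central 20 cm-radius obstacle, 30 simulated minutes of exploration
    at 20 cm/s, and an ensemble of 150 cells with mean peak rate 20 Hz and
    mean place-field width 15 cm.
    """

    arena_width: float = 100.0
    arena_height: float = 100.0
    obstacle_radius: float = 20.0
    duration: float = 1800.0
    dt: float = 0.025
    speed_mean: float = 20.0
    ensemble: EnsembleParams = field(default_factory=lambda: EnsembleParams(N=150))
    spiking: SpikingConfig = field(default_factory=SpikingConfig)
    max_dim: int = 2
    target_betti: tuple[int, int] = (1, 1)

    def make_arena(self) -> Arena:
        return make_arena(self.arena_width, self.arena_height, self.obstacle_radius)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        arena = raw.get("arena", {})
        kw["arena_width"] = arena.get("width", 100.0)
        kw["arena_height"] = arena.get("height", 100.0)
        kw["obstacle_radius"] = arena.get("obstacle_radius", 20.0)
        traj = raw.get("trajectory", {})
        kw["duration"] = traj.get("duration", 1800.0)
        kw["dt"] = traj.get("dt", 0.025)
        kw["speed_mean"] = traj.get("speed_mean", 20.0)
        ens = raw.get("ensemble", {})
        kw["ensemble"] = EnsembleParams(
            N=ens.get("N", 150), f=ens.get("f", 20.0), s=ens.get("s", 15.0),
            a=ens.get("a", 1.2), b=ens.get("b", 1.7),
        )
        spk = raw.get("spiking", {})
        kw["spiking"] = SpikingConfig(
            theta_freq=spk.get("theta_freq", 8.0),
            theta_depth=spk.get("theta_depth", 0.7),
            window=spk.get("window", 0.250),
        )
        kw["max_dim"] = raw.get("max_dim", 2)
        return cls(**kw)

    def with_ensemble(self, **kwargs) -> "SessionConfig":
        return replace(self, ensemble=replace(self.ensemble, **kwargs))


@dataclass
class Session:
    config: SessionConfig
    seed: int
    arena: Arena
    trajectory: Trajectory
    cells: list[PlaceCell]
    base_trains: list[SpikeTrain]

    @property
    def n_windows(self) -> int:
        return int(math.ceil(self.config.duration / self.config.spiking.window))

    @property
    def window_times(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.config.spiking.window


@dataclass
class EffectiveRun:
    """Everything derived from one session under one synaptic model."""

    session: Session
    model: SynapticModel
    sample: SynapticSample
    trains: list[SpikeTrain]
    events: list[CoactivityEvent]
    graph: CoactivityGraph
    complex: FilteredCliqueComplex
    barcode: Barcode
    timeline: BettiTimeline
    outcome: LearningOutcome
    stats: LoopStats
    final_betti_collapsed: tuple[int, ...] | None = None

    @property
    def n_edges(self) -> int:
        return self.graph.n_edges

    @property
    def n2(self) -> int:
        """Number of 2-simplices (triangles) of the fully-grown complex."""
        return self.complex.counts().get(2, 0)


def simulate_session(config: SessionConfig, seed: int = 0) -> Session:
    """Simulate arena, trajectory, ensemble and ideal-synapse spike trains."""
    arena = config.make_arena()
    traj = simulate_trajectory(
        arena, config.duration, config.dt, config.speed_mean, seed=seed
    )
    cells = sample_ensemble(config.ensemble, arena, seed=seed)
    trains = generate_spikes(cells, traj, config.spiking, seed=seed)
    return Session(
        config=config, seed=seed, arena=arena, trajectory=traj,
        cells=cells, base_trains=trains,
    )


def run_effective(
    session: Session,
    model: SynapticModel = SynapticModel(),
    synapse_seed: int | None = None,
    *,
    check_b2: bool = False,
    representatives: bool = True,
) -> EffectiveRun:
    """Screen a session's spikes through a synaptic model and analyse the
    resulting effective coactivity complex."""
    cfg = session.config
    seed = session.seed if synapse_seed is None else synapse_seed
    sample = sample_probabilities(model, n_cells=cfg.ensemble.N, seed=seed)
    trains = screen_spikes(session.base_trains, sample, seed=seed)
    events = detect_coactivity(trains, cfg.spiking, sample, seed=seed,
                               duration=cfg.duration)
    graph = build_graph(events, trains, cfg.spiking, duration=cfg.duration)
    cx = clique_filtration(graph, max_dim=cfg.max_dim)
    barcode = persistence(cx, validate=False, representatives=representatives)
    dims = tuple(range(cfg.max_dim)) if cfg.max_dim >= 2 else (0,)
    timeline = betti_timeline(barcode, session.window_times, dims=dims)
    outcome = learning_time(timeline, cfg.target_betti, horizon=cfg.duration)
    stats = loop_stats(barcode)
    fb = final_betti(graph, max_dim=2) if check_b2 else None
    return EffectiveRun(
        session=session, model=model, sample=sample, trains=trains,
        events=events, graph=graph, complex=cx, barcode=barcode,
        timeline=timeline, outcome=outcome, stats=stats,
        final_betti_collapsed=fb,
    )
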