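import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from cogmap.cells import SpikeTrain, SpikingConfig
from cogmap.synapses import CoactivityEvent
from cogmap.topology import (
    Barcode,
    FilteredCliqueComplex,
    betti_timeline,
    build_graph,
    clique_filtration,
    complex_size,
    flag_betti_numbers,
    learning_time,
    loop_stats,
    persistence,
    strong_collapse,
)

from gf2_oracle import naive_persistence, random_filtered_flag_complex

CFG = SpikingConfig()


def graph_from_edges(edges, vertex_times=None):
    """CoactivityGraph-like wrapper from {(u, v): time}."""
    from cogmap.topology import CoactivityGraph

    g = nx.Graph()
    verts = sorted({v for e in edges for v in e} | set(vertex_times or {}))
    for v in verts:
        t = (vertex_times or {}).get(v, 0.0)
        g.add_node(v, time=t, weight=1)
    for (u, v), t in edges.items():
        g.add_edge(u, v, time=t, weight=1.0)
    return CoactivityGraph(graph=g)


def intervals_set(barcode: Barcode):
    return sorted((iv.dim, iv.birth, iv.death) for iv in barcode.intervals)


class TestBuildGraph:
    def test_no_events_isolated_vertices(self):
        trains = [SpikeTrain(cell_id=k, times=np.array([0.1 + k])) for k in range(3)]
        g = build_graph([], trains, CFG)
        assert g.n_vertices == 3 and g.n_edges == 0

    def test_single_event_edge_time(self):
        trains = [
            SpikeTrain(cell_id=0, times=np.array([0.80])),
            SpikeTrain(cell_id=1, times=np.array([0.81])),
        ]
        events = [CoactivityEvent(0, 1, 3, 0.75)]
        g = build_graph(events, trains, CFG)
        assert g.graph.edges[0, 1]["time"] == pytest.approx(3 * 0.25)

    def test_identical_trains_weight_one(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 20, 100))
        trains = [SpikeTrain(cell_id=0, times=t), SpikeTrain(cell_id=1, times=t)]
        events = [CoactivityEvent(0, 1, int(t[0] / 0.25), 0.0)]
        g = build_graph(events, trains, CFG, duration=20.0)
        assert g.graph.edges[0, 1]["weight"] == pytest.approx(1.0)

    def test_vertex_weight_is_spike_count(self):
        trains = [SpikeTrain(cell_id=5, times=np.arange(7) * 0.1)]
        g = build_graph([], trains, CFG)
        assert g.graph.nodes[5]["weight"] == 7

    def test_silent_cells_excluded(self):
        trains = [
            SpikeTrain(cell_id=0, times=np.array([0.1])),
            SpikeTrain(cell_id=1, times=np.array([])),
        ]
        g = build_graph([], trains, CFG)
        assert set(g.graph.nodes) == {0}


class TestCliqueFiltration:
    def test_k4_simplex_counts(self):
        edges = {e: 1.0 for e in combinations(range(4), 2)}
        cx = clique_filtration(graph_from_edges(edges, {v: 1.0 for v in range(4)}), max_dim=3)
        assert cx.counts() == {0: 4, 1: 6, 2: 4, 3: 1}
        assert all(t == 1.0 for s, t in cx.simplices.items() if len(s) > 1)

    def test_c5_has_one_loop(self):
        edges = {(k, (k + 1) % 5): float(k + 1) for k in range(5)}
        cx = clique_filtration(graph_from_edges(edges), max_dim=2)
        bc = persistence(cx)
        oracle = naive_persistence(cx.simplices)
        assert bc.final_betti(1) == 1
        assert intervals_set(bc) == oracle

    def test_k4_is_contractible(self):
        edges = {e: 1.0 for e in combinations(range(4), 2)}
        cx = clique_filtration(graph_from_edges(edges), max_dim=3)
        bc = persistence(cx)
        assert (bc.final_betti(0), bc.final_betti(1), bc.final_betti(2)) == (1, 0, 0)

    def test_filtration_value_is_max_edge_time(self):
        edges = {(0, 1): 1.0, (1, 2): 2.0, (0, 2): 3.0}
        cx = clique_filtration(graph_from_edges(edges), max_dim=2)
        assert cx.simplices[(0, 1, 2)] == 3.0


class TestPersistence:
    def test_triangle_filling_narrative(self):
        """Three cells appear, edges close a loop, the triangle fills it:
        H0 gets one immortal class plus two merged ones, H1 a short bar."""
        simplices = {
            (0,): 1.0, (1,): 1.0, (2,): 1.0,
            (0, 1): 2.0, (1, 2): 3.0, (0, 2): 4.0,
            (0, 1, 2): 5.0,
        }
        cx = FilteredCliqueComplex(simplices=simplices, max_dim=2)
        bc = persistence(cx)
        assert intervals_set(bc) == [
            (0, 1.0, 2.0), (0, 1.0, 3.0), (0, 1.0, math.inf), (1, 4.0, 5.0),
        ]
        tl = betti_timeline(bc, np.array([0.5, 2.5, 4.5, 5.5]), dims=(0, 1))
        assert tl.betti[0].tolist() == [0, 2, 1, 1]
        assert tl.betti[1].tolist() == [0, 0, 1, 0]

    def test_empty_complex(self):
        bc = persistence(FilteredCliqueComplex(simplices={}, max_dim=2))
        assert bc.intervals == []

    def test_non_monotone_rejected(self):
        cx = FilteredCliqueComplex(simplices={(0,): 1.0, (1,): 1.0, (0, 1): 0.5}, max_dim=2)
        with pytest.raises(ValueError):
            persistence(cx)

    def test_missing_face_rejected(self):
        cx = FilteredCliqueComplex(simplices={(0,): 0.0, (0, 1): 1.0}, max_dim=2)
        with pytest.raises(ValueError):
            persistence(cx)

    def test_matches_oracle_on_random_flag_complexes(self, rng):
        """Reduction engine agrees exactly with the naive dense GF(2) oracle
        on random filtered clique complexes (including dimension 2)."""
        for _ in range(25):
            simplices = random_filtered_flag_complex(rng, n_max=9, max_dim=3)
            top = max(len(s) for s in simplices) - 1
            cx = FilteredCliqueComplex(simplices=simplices, max_dim=top)
            bc = persistence(cx, representatives=False, max_homology_dim=top)
            assert intervals_set(bc) == naive_persistence(simplices)

    def test_representative_is_shortest_cycle(self):
        """C5 closed late: the 1D class's representative is the full 5-cycle."""
        edges = {(k, (k + 1) % 5): 1.0 for k in range(4)}
        edges[(0, 4)] = 2.0
        cx = clique_filtration(graph_from_edges(edges), max_dim=2)
        bc = persistence(cx)
        loops = bc.in_dim(1)
        assert len(loops) == 1 and loops[0].length == 5


class TestLearningTime:
    def grid(self):
        return np.arange(10) * 1.0

    def test_target_throughout(self):
        # timeline identically (0, 0); target (0, 0) is met from t = 0
        tl = betti_timeline(Barcode([]), self.grid())
        out = learning_time(tl, (0, 0), horizon=9.0)
        assert out.t_min == 0.0 and out.correct

    def test_stabilisation_time(self):
        from cogmap.topology import Interval

        bc = Barcode([
            Interval(dim=0, birth=0.0, death=math.inf),
            Interval(dim=1, birth=2.0, death=4.0),
            Interval(dim=1, birth=5.0, death=math.inf),
        ])
        tl = betti_timeline(bc, self.grid())
        out = learning_time(tl, (1, 1), horizon=9.0)
        assert out.t_min == 5.0 and out.correct

    def test_never_stabilises(self):
        from cogmap.topology import Interval

        bc = Barcode([
            Interval(dim=0, birth=0.0, death=math.inf),
            Interval(dim=0, birth=1.0, death=math.inf),
        ])
        tl = betti_timeline(bc, self.grid())
        out = learning_time(tl, (1, 1), horizon=9.0)
        assert out.t_min is None and not out.correct


class TestLoopStats:
    def test_single_finite_interval(self):
        from cogmap.topology import Interval

        bc = Barcode([Interval(dim=1, birth=4.0, death=5.0)])
        st = loop_stats(bc)
        assert (st.n_spurious, st.mean_birth, st.mean_death, st.mean_lifetime) == (1, 4.0, 5.0, 1.0)

    def test_no_finite_intervals(self):
        from cogmap.topology import Interval

        st = loop_stats(Barcode([Interval(dim=1, birth=1.0, death=math.inf)]))
        assert st.n_spurious == 0

    def test_triangle_boundary_length(self):
        # triangle filled one step after its boundary closes
        simplices = {
            (0,): 0.0, (1,): 0.0, (2,): 0.0,
            (0, 1): 1.0, (1, 2): 1.0, (0, 2): 2.0,
            (0, 1, 2): 3.0,
        }
        bc = persistence(FilteredCliqueComplex(simplices=simplices, max_dim=2))
        st = loop_stats(bc)
        assert st.n_spurious == 1
        assert st.mean_length == pytest.approx(3.0)


class TestComplexSize:
    def test_k4_counts(self):
        edges = {e: 1.0 for e in combinations(range(4), 2)}
        cx = clique_filtration(graph_from_edges(edges), max_dim=3)
        assert complex_size(cx, 1.0) == {0: 4, 1: 6, 2: 4, 3: 1}
        assert complex_size(cx, 0.5) == {0: 4, 1: 0, 2: 0, 3: 0}

    def test_euler_poincare_on_random_complexes(self, rng):
        """Alternating simplex-count sum equals alternating Betti sum at
        every sampled filtration time."""
        for _ in range(10):
            simplices = random_filtered_flag_complex(rng, n_max=8, max_dim=6)
            max_dim = max(len(s) for s in simplices) - 1
            cx = FilteredCliqueComplex(simplices=simplices, max_dim=max_dim)
            bc = persistence(cx, representatives=False, max_homology_dim=max_dim)
            for t in np.unique([v for v in simplices.values()]):
                counts = complex_size(cx, t)
                chi_counts = sum((-1) ** d * c for d, c in counts.items())
                chi_betti = sum(
                    (-1) ** d * bc.betti_at(t, d) for d in range(max_dim + 1)
                )
                assert chi_counts == chi_betti


class TestStrongCollapse:
    def test_cycle_is_its_own_core(self):
        g = nx.cycle_graph(6)
        core = strong_collapse(g)
        assert core.number_of_nodes() == 6

    def test_tree_collapses_to_point(self):
        g = nx.random_labeled_tree(15, seed=3)
        core = strong_collapse(g)
        assert core.number_of_nodes() == 1

    def test_flag_betti_matches_persistence(self, rng):
        for _ in range(15):
            g = nx.gnp_random_graph(10, 0.45, seed=int(rng.integers(1 << 30)))
            simplices = {(v,): 0.0 for v in g.nodes}
            for u, v in g.edges:
                simplices[tuple(sorted((u, v)))] = 0.0
            for size in (3, 4, 5):
                for s in combinations(sorted(g.nodes), size):
                    if all(g.has_edge(a, b) for a, b in combinations(s, 2)):
                        simplices[s] = 0.0
            bc = persistence(
                FilteredCliqueComplex(simplices=simplices, max_dim=4),
                representatives=False,
            )
            betti = flag_betti_numbers(g, max_dim=2)
            assert betti == (bc.final_betti(0), bc.final_betti(1), bc.final_betti(2))
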