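import math

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from cogmap.cells import SpikeTrain, SpikingConfig
from cogmap.synapses import (
    SynapticModel,
    SynapticSample,
    detect_coactivity,
    lognormal_mode_variance,
    pair_index,
    sample_probabilities,
    screen_spikes,
)


def make_sample(p, q, n_cells):
    n_pairs = n_cells * (n_cells - 1) // 2
    return SynapticSample(
        p=np.full(n_cells, p), q=np.full(n_pairs, q), n_cells=n_cells
    )


class TestLognormalModeVariance:
    def test_zero_variance(self):
        mu, sigma = lognormal_mode_variance(0.7, 0.0)
        assert sigma == 0.0 and math.exp(mu) == pytest.approx(0.7)

    @pytest.mark.parametrize("mode,c", [(0.5, 0.04), (0.8, 0.1), (0.3, 0.01)])
    def test_mode_and_variance_equations(self, mode, c):
        """The solved (mu, sigma) satisfy mode = e^{mu - sigma^2} and
        Var = (e^{sigma^2}-1) e^{2 mu + sigma^2} = c * mode^2."""
        mu, sigma = lognormal_mode_variance(mode, c * mode**2)
        assert math.exp(mu - sigma**2) == pytest.approx(mode, rel=1e-9)
        var = math.expm1(sigma**2) * math.exp(2 * mu + sigma**2)
        assert var == pytest.approx(c * mode**2, rel=1e-6)

    def test_sampled_mode_location(self):
        """Histogram mode of a large truncated sample sits at p_hat."""
        model = SynapticModel(p_hat=0.5, q_hat=0.5, c_p=0.04)
        s = sample_probabilities(model, n_cells=100_000, n_readouts=1, seed=8)
        grid = np.linspace(0.2, 0.9, 300)
        dens = gaussian_kde(s.p)(grid)
        assert grid[np.argmax(dens)] == pytest.approx(0.5, abs=0.02)

    def test_truncation_to_unit_interval(self):
        s = sample_probabilities(SynapticModel(p_hat=1.0, q_hat=1.0), 5000, 5000, seed=1)
        for arr in (s.p, s.q):
            assert (arr > 0).all() and (arr <= 1).all()

    def test_zero_variance_sample_is_constant(self):
        s = sample_probabilities(
            SynapticModel(p_hat=0.6, q_hat=0.9, c_p=0.0, c_q=0.0), 10, seed=2
        )
        assert np.allclose(s.p, 0.6) and np.allclose(s.q, 0.9)

    def test_quantile_coupling_monotone_in_mode(self):
        """Same seed, lower mode => every sampled probability is lower."""
        hi = sample_probabilities(SynapticModel(p_hat=0.9, q_hat=0.9), 2000, seed=3)
        lo = sample_probabilities(SynapticModel(p_hat=0.6, q_hat=0.6), 2000, seed=3)
        assert (lo.p <= hi.p + 1e-12).all()
        assert (lo.q <= hi.q + 1e-12).all()


class TestScreenSpikes:
    def test_identity_at_unit_probability(self):
        tr = SpikeTrain(cell_id=0, times=np.sort(np.random.default_rng(0).uniform(0, 10, 100)))
        out = screen_spikes([tr], make_sample(1.0, 1.0, 1), seed=5)
        np.testing.assert_array_equal(out[0].times, tr.times)

    def test_binomial_retention(self):
        tr = SpikeTrain(cell_id=0, times=np.arange(1000) * 0.01)
        out = screen_spikes([tr], make_sample(0.5, 1.0, 1), seed=6)
        assert abs(len(out[0]) - 500) < 3 * math.sqrt(250)

    def test_near_zero_probability(self):
        tr = SpikeTrain(cell_id=0, times=np.arange(200) * 0.01)
        out = screen_spikes([tr], make_sample(1e-6, 1.0, 1), seed=7)
        assert len(out[0]) <= 2

    def test_nested_retention_under_coupling(self):
        tr = SpikeTrain(cell_id=0, times=np.arange(2000) * 0.01)
        hi = screen_spikes([tr], make_sample(0.8, 1.0, 1), seed=8)[0]
        lo = screen_spikes([tr], make_sample(0.4, 1.0, 1), seed=8)[0]
        assert set(lo.times).issubset(set(hi.times))


class TestDetectCoactivity:
    cfg = SpikingConfig()

    def test_same_window_event(self):
        trains = [
            SpikeTrain(cell_id=0, times=np.array([0.1])),
            SpikeTrain(cell_id=1, times=np.array([0.2])),
        ]
        events = detect_coactivity(trains, self.cfg, make_sample(1.0, 1.0, 2), seed=0)
        assert len(events) == 1
        assert (events[0].i, events[0].j, events[0].window_index) == (0, 1, 0)

    def test_different_windows_no_event(self):
        trains = [
            SpikeTrain(cell_id=0, times=np.array([0.1])),
            SpikeTrain(cell_id=1, times=np.array([0.4])),
        ]
        assert detect_coactivity(trains, self.cfg, make_sample(1.0, 1.0, 2), seed=0) == []

    def test_readout_binomial(self):
        """1000 co-firing windows at q = 0.5 yield about 500 events."""
        t = np.arange(1000) * 0.25 + 0.1
        trains = [SpikeTrain(cell_id=0, times=t), SpikeTrain(cell_id=1, times=t + 0.01)]
        events = detect_coactivity(trains, self.cfg, make_sample(1.0, 0.5, 2), seed=9)
        assert abs(len(events) - 500) < 3 * math.sqrt(250)

    def test_ideal_pipeline_reproduces_every_cowindow(self):
        rng = np.random.default_rng(10)
        trains = [
            SpikeTrain(cell_id=k, times=np.sort(rng.uniform(0, 50, 300)))
            for k in range(3)
        ]
        events = detect_coactivity(trains, self.cfg, make_sample(1.0, 1.0, 3), seed=1)
        expected = set()
        wins = [set((tr.times / 0.25).astype(int)) for tr in trains]
        for i in range(3):
            for j in range(i + 1, 3):
                for w in wins[i] & wins[j]:
                    expected.add((i, j, w))
        assert {(e.i, e.j, e.window_index) for e in events} == expected

    def test_event_rate_scales_with_p_i_p_j_q(self):
        """Observed event count matches the per-window analytic expectation
        q * (1 - (1-p_i)^n_i) * (1 - (1-p_j)^n_j) summed over windows."""
        rng = np.random.default_rng(11)
        base = [
            SpikeTrain(cell_id=0, times=np.sort(rng.uniform(0, 500, 4000))),
            SpikeTrain(cell_id=1, times=np.sort(rng.uniform(0, 500, 4000))),
        ]
        p = np.array([0.6, 0.7])
        q = 0.5
        sample = SynapticSample(p=p, q=np.array([q]), n_cells=2)
        screened = screen_spikes(base, sample, seed=12)
        events = detect_coactivity(screened, self.cfg, sample, seed=12)
        exp = 0.0
        var = 0.0
        for w in range(2000):
            n0 = ((base[0].times >= w * 0.25) & (base[0].times < (w + 1) * 0.25)).sum()
            n1 = ((base[1].times >= w * 0.25) & (base[1].times < (w + 1) * 0.25)).sum()
            pw = q * (1 - (1 - p[0]) ** n0) * (1 - (1 - p[1]) ** n1)
            exp += pw
            var += pw * (1 - pw)
        assert abs(len(events) - exp) < 4 * math.sqrt(var)

    def test_monotone_in_transmission_mode(self):
        """Under common random numbers, fewer events at lower p_hat, and the
        detected (pair, window) sets are nested."""
        rng = np.random.default_rng(13)
        base = [
            SpikeTrain(cell_id=k, times=np.sort(rng.uniform(0, 200, 1500)))
            for k in range(4)
        ]
        keys = []
        for p_hat in (1.0, 0.8, 0.5, 0.2):
            sample = sample_probabilities(
                SynapticModel(p_hat=p_hat, q_hat=0.8), 4, seed=14
            )
            screened = screen_spikes(base, sample, seed=14)
            events = detect_coactivity(screened, self.cfg, sample, seed=14)
            keys.append({(e.i, e.j, e.window_index) for e in events})
        for hi, lo in zip(keys, keys[1:]):
            assert lo.issubset(hi)


def test_pair_index_is_a_bijection():
    n = 13
    seen = set()
    for i in range(n):
        for j in range(i + 1, n):
            seen.add(int(pair_index(i, j, n)))
    assert seen == set(range(n * (n - 1) // 2))
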