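import numpy as np
import pytest
from hypothesis import given, strategies as st

from einet import (CoherenceConfig, NetworkParams, Protocol, StimulusSpec,
                   bin_spikes, coherence_of_trains, half_power_frequency,
                   mean_firing_rate, psd_analytic, psd_empirical,
                   simulate, spike_coherence)
from einet.metrics import EMPIRICAL_TO_ANALYTIC
from einet.simulation import SpikeRaster


def _raster_from_trains(trains_e, dt=1.0, n_i=0):
    """Build a raster from explicit per-cell spike-time lists (ms)."""
    steps, cells = [], []
    for c, ts in enumerate(trains_e):
        for t in ts:
            steps.append(int(round(t / dt)))
            cells.append(c)
    order = np.argsort(steps, kind="stable")
    return SpikeRaster(dt=dt, n_e=len(trains_e), n_i=max(n_i, 1),
                       steps_e=np.asarray(steps)[order] if steps else np.empty(0, int),
                       cells_e=np.asarray(cells)[order] if cells else np.empty(0, int),
                       steps_i=np.empty(0, int), cells_i=np.empty(0, int))


class TestBinSpikes:
    def test_one_spike_per_bin(self):
        assert list(bin_spikes([5, 25, 45], 20.0, 0.0, 60.0)) == [1, 1, 1]

    def test_no_spikes_all_zero(self):
        assert not np.any(bin_spikes([], 20.0, 0.0, 200.0))

    def test_indicator_not_count(self):
        assert list(bin_spikes([3, 7], 20.0, 0.0, 20.0)) == [1]

    def test_partial_last_bin_dropped(self):
        assert len(bin_spikes([0], 20.0, 0.0, 70.0)) == 3

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            bin_spikes([], 20.0, 10.0, 10.0)


class TestCoherence:
    def test_identical_trains_give_one(self):
        x = np.array([1, 0, 1, 1, 0], dtype=float)
        assert coherence_of_trains(x, x) == 1.0

    def test_disjoint_trains_give_zero(self):
        a = np.array([1, 0, 1, 0])
        b = np.array([0, 1, 0, 1])
        assert coherence_of_trains(a, b) == 0.0

    def test_half_overlap_reference(self):
        # occupancy {1,2} vs {2,3}: one shared bin, norm sqrt(2*2) = 2
        a = np.array([0, 1, 1, 0])
        b = np.array([0, 0, 1, 1])
        assert coherence_of_trains(a, b) == 0.5

    @given(st.lists(st.integers(0, 1), min_size=2, max_size=40),
           st.lists(st.integers(0, 1), min_size=2, max_size=40))
    def test_symmetric_and_bounded(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n], float), np.array(ys[:n], float)
        c = coherence_of_trains(x, y)
        assert c == coherence_of_trains(y, x)
        assert 0.0 <= c <= 1.0  # Cauchy-Schwarz on indicator sequences

    def test_independent_bernoulli_trains_concentrate_at_p(self, rng):
        # for dense independent trains the expectation is ~p, not 0
        p = 0.3
        x = (rng.random(20000) < p).astype(float)
        y = (rng.random(20000) < p).astype(float)
        assert coherence_of_trains(x, y) == pytest.approx(p, abs=0.02)

    def test_raster_coherence_identical_cells(self):
        times = list(np.arange(5.0, 2000.0, 100.0))
        raster = _raster_from_trains([times] * 4)
        cfg = CoherenceConfig(bin_ms=20.0, n_pairs=10, seed=0)
        assert spike_coherence(raster, cfg, (0.0, 2000.0)) == 1.0

    def test_raster_coherence_empty_returns_zero(self):
        raster = _raster_from_trains([[], [], []])
        cfg = CoherenceConfig(n_pairs=5, seed=0)
        assert spike_coherence(raster, cfg, (0.0, 1000.0)) == 0.0

    def test_raster_coherence_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        trains = [list(np.sort(rng.choice(np.arange(0, 2000, 5.0), 40,
                                          replace=False)))
                  for _ in range(10)]
        raster = _raster_from_trains(trains)
        cfg = CoherenceConfig(n_pairs=20, seed=4)
        a = spike_coherence(raster, cfg, (0.0, 2000.0))
        b = spike_coherence(raster, cfg, (0.0, 2000.0))
        assert a == b

    def test_window_shorter_than_two_bins_rejected(self):
        raster = _raster_from_trains([[1.0], [2.0]])
        with pytest.raises(ValueError):
            spike_coherence(raster, CoherenceConfig(), (0.0, 30.0))


class TestMeanFiringRate:
    def test_reference_rate(self):
        trains = [list(np.arange(0.0, 1000.0, 100.0))] * 200  # 10 spikes/s
        raster = _raster_from_trains(trains)
        assert mean_firing_rate(raster, "e", (0.0, 1000.0)) == pytest.approx(10.0)

    def test_empty_raster_zero(self):
        raster = _raster_from_trains([[], []])
        assert mean_firing_rate(raster, "e", (0.0, 500.0)) == 0.0

    def test_saturated_cells_fire_every_step(self):
        # u pinned far above threshold: Bernoulli(1) per 1 ms step = 1000 Hz
        p = NetworkParams(N_e=10, N_i=2, w_ee=0, w_ei=0, w_ie=0, w_ii=0,
                          I_e=1.0, I_i=1.0, D=0.0)
        proto = Protocol(t_total=600.0, t_step=300.0, burn_in=100.0,
                         measure_window=200.0, seed=0)
        res = simulate(p, proto, u0_e=1.0, u0_i=1.0)
        assert mean_firing_rate(res.raster, "e", (100.0, 600.0)) == \
            pytest.approx(1000.0)

    def test_additive_over_disjoint_windows(self, rng):
        trains = [list(np.sort(rng.uniform(0, 1000, 30))) for _ in range(5)]
        raster = _raster_from_trains(trains)
        r_all = mean_firing_rate(raster, "e", (0.0, 1000.0))
        r1 = mean_firing_rate(raster, "e", (0.0, 400.0))
        r2 = mean_firing_rate(raster, "e", (400.0, 1000.0))
        assert r_all == pytest.approx(0.4 * r1 + 0.6 * r2)


class TestAnalyticSpectra:
    A_E, A_I, D, T = 100.0, 200.0, 200.0, 2.0

    def _spec(self, family, **kw):
        base = dict(S0=np.sqrt(0.5), f_s=50.0)
        base.update(kw)
        if family == "ou_noise":
            return StimulusSpec(family=family, D_s=50.0, f_c=100.0, seed=0)
        return StimulusSpec(family=family, **base)

    @pytest.mark.parametrize("family", ["ou_noise", "pulse", "biphasic",
                                        "sinusoid"])
    def test_inhibitory_power_dominates(self, family):
        s = psd_analytic(self._spec(family), self.A_E, self.A_I, self.D, self.T)
        assert np.all(s.power_i[1:] > s.power_e[1:])

    def test_sinusoid_single_line(self):
        s = psd_analytic(self._spec("sinusoid"), self.A_E, self.A_I, self.D,
                         self.T)
        base = psd_analytic(StimulusSpec(family="none"), self.A_E, self.A_I,
                            self.D, self.T)
        excess = s.power_e - base.power_e
        lines = np.nonzero(excess > 1e-9)[0]
        assert list(lines) == [int(50.0 * self.T)]  # n = f_s * T only

    def test_pulse_comb_at_multiples_of_repetition_frequency(self):
        s = psd_analytic(self._spec("pulse"), self.A_E, self.A_I, self.D,
                         self.T)
        base = psd_analytic(StimulusSpec(family="none"), self.A_E, self.A_I,
                            self.D, self.T)
        excess = s.power_e / base.power_e * self.D - self.D
        k = int(50.0 * self.T)
        peaks = np.nonzero(excess > excess.max() * 1e-3)[0]
        assert np.all(peaks % k == 0)

    def test_noise_family_has_no_line(self):
        s = psd_analytic(self._spec("ou_noise"), self.A_E, self.A_I, self.D,
                         self.T)
        assert np.all(np.diff(s.power_e) < 0)  # strictly decaying envelope

    @pytest.mark.parametrize("family", ["pulse", "biphasic", "sinusoid"])
    def test_zero_stimulus_reduces_to_lorentzian(self, family):
        s = psd_analytic(self._spec(family, S0=0.0), self.A_E, self.A_I,
                         self.D, self.T)
        omega = 2 * np.pi * s.frequencies
        lorentz = self.A_E ** 2 * self.D / (self.A_E ** 2 + omega ** 2)
        np.testing.assert_allclose(s.power_e, lorentz, rtol=1e-12)

    def test_off_grid_repetition_frequency_rejected(self):
        with pytest.raises(ValueError):
            psd_analytic(self._spec("pulse", f_s=50.3), self.A_E, self.A_I,
                         self.D, self.T)


class TestEmpiricalSpectrum:
    def test_parseval(self, rng):
        x = rng.standard_normal(4096)
        s = psd_empirical(x, 1.0)
        df = s.frequencies[1] - s.frequencies[0]
        assert np.sum(s.power_e) * df == pytest.approx(x.var(), rel=0.01)

    def test_pure_sinusoid_line(self):
        t = np.arange(0, 2.0, 1e-3)
        x = np.sin(2 * np.pi * 50.0 * t)
        s = psd_empirical(x, 1.0)
        assert s.frequencies[np.argmax(s.power_e)] == pytest.approx(50.0)

    def test_ou_trace_matches_lorentzian_envelope(self):
        from einet.experiments import simulate_decoupled_cell
        a, D = 100.0, 0.02
        trace = simulate_decoupled_cell(a, D, np.zeros(400_000), 0.1, seed=6)
        s = psd_empirical(trace, 0.1, n_segments=200)
        omega = 2 * np.pi * s.frequencies[1:]
        model = a * a * D / (a * a + omega ** 2) * EMPIRICAL_TO_ANALYTIC
        keep = s.frequencies[1:] < 500.0
        rms = np.sqrt(np.mean((np.log(s.power_e[1:][keep])
                               - np.log(model[keep])) ** 2))
        assert rms < 0.10


class TestHalfPower:
    def test_cutoff_equals_rate_constant(self):
        s = psd_analytic(StimulusSpec(family="none"), 100.0, 200.0, 1.0, 2.0)
        assert half_power_frequency(s, "e") == pytest.approx(100.0, rel=1e-6)
        assert half_power_frequency(s, "i") == pytest.approx(200.0, rel=1e-6)

    def test_cutoff_scales_with_rate_constant(self):
        s1 = psd_analytic(StimulusSpec(family="none"), 80.0, 160.0, 1.0, 2.0)
        s2 = psd_analytic(StimulusSpec(family="none"), 160.0, 320.0, 1.0, 2.0)
        assert half_power_frequency(s2, "e") == pytest.approx(
            2 * half_power_frequency(s1, "e"), rel=1e-9)

    def test_comb_spectrum_rejected(self):
        s = psd_analytic(StimulusSpec(family="pulse", S0=1.0, f_s=50.0),
                         100.0, 200.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            half_power_frequency(s, "e")

    def test_discrete_envelope_fallback(self):
        # an empirical-style spectrum with no envelope callable
        from einet.metrics import SpectrumResult
        f = np.linspace(0, 500, 2001)
        w = 2 * np.pi * f
        a = 120.0 * 2 * np.pi  # cutoff at 120 Hz in angular units
        s = SpectrumResult(frequencies=f, power_e=a * a / (a * a + w * w),
                           power_i=None, T=2.0)
        assert half_power_frequency(s, "e") == pytest.approx(a, rel=1e-4)
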