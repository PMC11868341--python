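"""Network construction, synaptic bookkeeping, and simulation invariants."""

import math

import numpy as np
import pytest

from adexz import (
    NetworkState,
    NeuronState,
    SynapseParams,
    build_network,
    classify_region,
    deliver_spikes,
    integrate_neuron,
    integrate_network,
    max_population_rates,
    population_rate,
)
from adexz.network import POP_FS, POP_RS_HEALTHY, POP_RS_IMPAIRED
from adexz.pattern_fixtures import poisson_train


class TestBuild:
    def test_population_split_at_full_size(self):
        m = build_network(N=10000, p=0.0, N_SC=500, seed=0)
        assert m.population_size(POP_RS_IMPAIRED) == 500
        assert m.population_size(POP_RS_HEALTHY) == 7500
        assert m.population_size(POP_FS) == 2000
        assert m.is_exc.sum() == 8000

    def test_degenerate_probabilities(self):
        assert build_network(N=50, p=0.0, seed=1).n_edges == 0
        assert build_network(N=50, p=1.0, seed=1).n_edges == 50 * 49

    def test_no_self_connections(self):
        m = build_network(N=100, p=0.5, seed=3)
        for i in range(100):
            assert i not in m.targets[m.indptr[i]:m.indptr[i + 1]]

    def test_edge_count_is_binomial(self):
        """Mean edge count over seeds within 5 sigma of Binomial(N(N-1), p)."""
        N, p, n_seeds = 2000, 0.05, 100
        counts = [build_network(N=N, p=p, seed=s).n_edges for s in range(n_seeds)]
        n_pairs = N * (N - 1)
        sigma_of_mean = math.sqrt(n_pairs * p * (1 - p) / n_seeds)
        assert abs(np.mean(counts) - n_pairs * p) < 5 * sigma_of_mean

    def test_impaired_cells_are_excitatory_and_get_Z0(self):
        m = build_network(N=200, p=0.05, N_SC=30, Z0_impaired=-45.0, seed=7)
        imp = m.labels == POP_RS_IMPAIRED
        assert imp.sum() == 30
        assert np.all(m.is_exc[imp])
        assert np.all(m.Z0[imp] == -45.0)
        assert np.all(m.Z0[~imp] == -65.0)

    def test_reproducible_from_seed(self):
        a = build_network(N=300, p=0.05, N_SC=20, seed=11)
        b = build_network(N=300, p=0.05, N_SC=20, seed=11)
        assert np.array_equal(a.targets, b.targets)
        assert np.array_equal(a.Z0, b.Z0)

    def test_nsc_exceeding_excitatory_pool_rejected(self):
        with pytest.raises(ValueError):
            build_network(N=100, N_SC=90, seed=0)


class TestDeliverSpikes:
    @pytest.fixture()
    def dense(self):
        # all-to-all so every cell is a target of every other
        return build_network(N=10, p=1.0, N_SC=2, seed=0)

    def test_excitatory_quantum(self, dense):
        syn = SynapseParams()
        state = NetworkState.resting(dense)
        deliver_spikes(state, [0], dense, syn)  # cell 0 is excitatory
        assert state.g_E[1] == syn.Q_E == 1.5
        assert state.g_E[0] == 0.0  # no self-connection
        assert np.all(state.g_I == 0.0)

    def test_inhibitory_quantum(self, dense):
        syn = SynapseParams()
        state = NetworkState.resting(dense)
        deliver_spikes(state, [9], dense, syn)  # cell 9 is FS
        assert state.g_I[0] == syn.Q_I == 5.0
        assert np.all(state.g_E == 0.0)

    def test_simultaneous_afferents_accumulate(self, dense):
        syn = SynapseParams()
        state = NetworkState.resting(dense)
        k = 5
        deliver_spikes(state, list(range(k)), dense, syn)
        assert state.g_E[7] == pytest.approx(k * syn.Q_E)


class TestIntegration:
    def test_healthy_network_without_drive_is_silent(self):
        m = build_network(N=1000, p=0.05, N_SC=0, seed=2)
        r = integrate_network(m, duration=2000.0, dt=0.1, seed=3)
        assert len(r) == 0

    def test_exact_exponential_conductance_decay(self):
        m = build_network(N=50, p=0.0, N_SC=0, seed=0)
        syn = SynapseParams()
        init = NetworkState.resting(m)
        g0 = 7.5
        init.g_E[:] = g0
        init.g_I[:] = 2 * g0
        duration = 200.0
        integrate_network(m, syn, duration=duration, dt=0.1, init=init)
        expected = g0 * math.exp(-duration / syn.tau_syn)
        assert np.allclose(init.g_E, expected, rtol=1e-10)
        assert np.allclose(init.g_I, 2 * expected, rtol=1e-10)
        assert np.all(init.g_E >= 0) and np.all(init.g_I >= 0)

    def test_decoupled_network_equals_single_neuron_bitwise(self, params):
        """With all synaptic quanta zero, each impaired cell reproduces the
        isolated-neuron trajectory sample for sample."""
        m = build_network(N=20, p=0.5, N_SC=6, Z0_impaired=-40.0, seed=5,
                          params=params)
        syn = SynapseParams(Q_E=0.0, Q_I=0.0)
        init = NetworkState.ignition(m, seed=8)
        V0 = init.V.copy()
        z0 = init.z.copy()
        r = integrate_network(m, syn, duration=3000.0, dt=0.1, init=init,
                              record_cells=np.arange(20), record_every=1.0)
        imp = np.flatnonzero(m.labels == POP_RS_IMPAIRED)
        for cid in imp[:3]:
            p = params.replace(Z0=-40.0)
            trace, _ = integrate_neuron(
                p, 3000.0, dt=0.1,
                init=NeuronState(V=V0[cid], w=0.0, z=z0[cid]),
                sample_every=1.0,
            )
            net_trace = r.traces[int(cid)]
            assert np.array_equal(net_trace.V, trace.V)
            assert np.array_equal(net_trace.w, trace.w)
            assert np.array_equal(net_trace.z, trace.z)

    def test_seed_reproducibility_bit_equality(self):
        m = build_network(N=400, p=0.05, N_SC=40, Z0_impaired=-40.0, seed=21)
        a = integrate_network(m, duration=1500.0, dt=0.1, seed=9)
        b = integrate_network(m, duration=1500.0, dt=0.1, seed=9)
        assert np.array_equal(a.cells, b.cells)
        assert np.array_equal(a.times, b.times)
        assert len(a) > 0

    def test_spike_count_conservation(self):
        m = build_network(N=400, p=0.05, N_SC=40, Z0_impaired=-40.0, seed=21)
        r = integrate_network(m, duration=1500.0, dt=0.1, seed=9)
        assert r.spike_counts().sum() == len(r)

    def test_refractory_floor_in_network(self):
        m = build_network(N=400, p=0.05, N_SC=40, Z0_impaired=-30.0, seed=2)
        r = integrate_network(m, duration=1500.0, dt=0.1, seed=2)
        for cid in np.unique(r.cells)[:20]:
            t = r.times[r.cells == cid]
            if t.size > 1:
                assert np.diff(t).min() >= m.params.t_ref

    def test_dt_guard(self):
        m = build_network(N=20, p=0.1, seed=0)
        with pytest.raises(ValueError):
            integrate_network(m, duration=100.0, dt=0.5)


class TestRates:
    def test_empty_raster_gives_zero_trace(self):
        m = build_network(N=100, p=0.05, N_SC=0, seed=0)
        r = integrate_network(m, duration=500.0, dt=0.1, seed=0)
        t, rate = population_rate(r, m, POP_RS_HEALTHY)
        assert np.all(rate == 0.0)
        assert len(t) == len(rate)

    def test_poisson_rate_recovery(self):
        """100 cells firing homogeneous-Poisson at 10 Hz for 10 s: the mean of
        the estimated rate trace recovers 10 Hz within 3 sigma."""
        from adexz.network import RasterResult

        m = build_network(N=125, p=0.0, N_SC=0, seed=0)  # 100 RS_healthy cells
        healthy = np.flatnonzero(m.labels == POP_RS_HEALTHY)
        rate_hz, duration = 10.0, 10000.0
        cells, times = [], []
        for k, cid in enumerate(healthy):
            train = poisson_train(rate_hz, duration, seed=100 + k)
            cells.extend([cid] * len(train))
            times.extend(train.times)
        order = np.argsort(times)
        r = RasterResult(
            cells=np.array(cells)[order], times=np.array(times)[order],
            duration=duration, dt=0.1, model_seed=0,
            population_sizes={}, config={"N": m.N},
        )
        _, rate = population_rate(r, m, POP_RS_HEALTHY)
        n_spikes_expected = rate_hz * len(healthy) * duration / 1000.0
        sigma = rate_hz / math.sqrt(n_spikes_expected)
        assert abs(rate.mean() - rate_hz) < 3 * sigma

    def test_unknown_population_rejected(self):
        m = build_network(N=50, p=0.0, seed=0)
        r = integrate_network(m, duration=100.0, dt=0.1)
        with pytest.raises(ValueError):
            population_rate(r, m, "granule")


class TestRegions:
    def test_silence_is_contained(self):
        assert classify_region({POP_RS_IMPAIRED: 0.0, POP_RS_HEALTHY: 0.0, POP_FS: 0.0}) == 1

    def test_inhibition_contained_oscillation(self):
        rates = {POP_RS_IMPAIRED: 120.0, POP_FS: 80.0, POP_RS_HEALTHY: 4.0}
        assert classify_region(rates) == 2

    def test_global_propagation(self):
        rates = {POP_RS_IMPAIRED: 120.0, POP_FS: 80.0, POP_RS_HEALTHY: 60.0}
        assert classify_region(rates) == 3

    def test_propagation_point_is_region_three_across_seeds(self):
        """At strong impairment with half the excitatory pool impaired the
        pathological activity reaches the healthy population for at least
        4 of 5 network realisations."""
        hits = 0
        for seed in range(5):
            m = build_network(N=10000, p=0.05, N_SC=4000, Z0_impaired=-50.0,
                              seed=seed)
            r = integrate_network(m, duration=8000.0, dt=0.1, seed=seed + 100)
            rates = max_population_rates(r, m)
            hits += classify_region(rates) == 3
        assert hits >= 4
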