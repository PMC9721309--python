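"""Rates, propagation verdicts, coarse-graining and Kuramoto measures."""

import numpy as np
import pytest

from seizprop import (NetworkConfig, PerturbationParams, build_network)
from seizprop.engine import SimulationResult
from seizprop.observables import (
    classify_propagation, compute_group_profiles, degree_rate_correlation,
    group_by_inhibitory_indegree, group_mean_potential, kuramoto_order,
    population_rate, single_neuron_rates, sort_raster, group_profiles_frame,
)


def make_result(spikes_rs=(), duration=1000.0, n_rs=100, n_fs=25,
                vm=None, vm_times=None):
    """Hand-built SimulationResult for observable unit tests."""
    ids = np.asarray([s[0] for s in spikes_rs], dtype=np.int32)
    times = np.asarray([s[1] for s in spikes_rs], dtype=float)
    empty = (np.empty(0, np.int32), np.empty(0, float))
    return SimulationResult(
        spikes={"RS": (ids, times), "FS": empty, "EXT": empty},
        vm={} if vm is None else vm,
        vm_times=np.empty(0) if vm_times is None else vm_times,
        drive_times=np.empty(0), drive_rate=np.empty(0),
        duration=duration, dt=0.1,
        config_echo={"populations": {"RS": n_rs, "FS": n_fs, "EXT": n_rs}},
    )


class TestPopulationRate:
    def test_empty_spike_list_all_zero(self):
        r = population_rate(make_result(), "RS", 5.0)
        assert (r.rate == 0).all()

    def test_single_spike_bin_value(self):
        # 1 spike among 100 neurons in a 5 ms bin -> 1/(100*0.005 s) = 2 Hz
        r = population_rate(make_result([(3, 2.0)]), "RS", 5.0)
        assert r.rate[0] == pytest.approx(2.0)
        assert r.rate[1:].sum() == 0

    def test_all_neurons_once_per_bin_hits_ceiling(self):
        spikes = [(i, 2.5) for i in range(100)]
        r = population_rate(make_result(spikes), "RS", 5.0)
        assert r.rate[0] == pytest.approx(200.0)


class TestClassifyPropagation:
    def setup_method(self):
        self.pert = PerturbationParams(alpha=80.0, T1=200.0, T2=800.0)

    def test_silenced_network_is_non_propagative(self):
        v = classify_propagation(make_result(duration=1000.0), self.pert)
        assert v.label == "non_propagative"
        assert v.delta_rate == pytest.approx(-86.0)

    def test_saturated_network_is_propagative(self):
        spikes = [(i, t) for t in np.arange(202.5, 800.0, 5.0)
                  for i in range(100)]
        v = classify_propagation(make_result(spikes, duration=1000.0),
                                 self.pert)
        assert v.propagative
        assert v.delta_rate == pytest.approx(200.0 - 86.0, rel=0.01)

    def test_exact_equality_is_non_propagative(self):
        # strict inequality at the boundary
        v = classify_propagation(make_result(duration=1000.0),
                                 PerturbationParams(beta=0.0, alpha=0.0,
                                                    T1=200.0, T2=800.0))
        assert v.label == "non_propagative"

    def test_window_outside_run_rejected(self):
        with pytest.raises(ValueError):
            classify_propagation(make_result(duration=500.0), self.pert)

    def test_monotone_in_added_excitatory_spikes(self):
        base = [(i, 300.0 + i) for i in range(40)]
        extra = base + [(i, 500.0 + i) for i in range(40)]
        v1 = classify_propagation(make_result(base, duration=1000.0), self.pert)
        v2 = classify_propagation(make_result(extra, duration=1000.0), self.pert)
        assert v2.delta_rate > v1.delta_rate


class TestSingleNeuronRates:
    def test_rate_after_transient(self):
        spikes = [(0, 600.0 + 200 * k) for k in range(10)]
        res = make_result(spikes, duration=2500.0)
        rates = single_neuron_rates(res, "RS", transient=500.0)
        assert rates[0] == pytest.approx(10 / 2.0)
        assert rates[1:].sum() == 0

    def test_transient_covering_run_rejected(self):
        with pytest.raises(ValueError):
            single_neuron_rates(make_result(duration=500.0), "RS",
                                transient=500.0)


class TestDegreeRateCorrelation:
    def test_perfect_linear(self):
        deg = np.arange(50, 150)
        assert degree_rate_correlation(3.0 * deg, deg) == pytest.approx(1.0)
        assert degree_rate_correlation(-2.0 * deg, deg) == pytest.approx(-1.0)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=8000)
        b = rng.normal(size=8000)
        assert abs(degree_rate_correlation(a, b)) < 0.05


class TestGrouping:
    def test_groups_partition_population(self, desk_network):
        groups = group_by_inhibitory_indegree(desk_network, "RS")
        sizes = sum(g.members.size for g in groups)
        assert sizes == desk_network.n_rs
        all_ids = np.concatenate([g.members for g in groups])
        assert np.unique(all_ids).size == desk_network.n_rs
        keys = [g.group_key for g in groups]
        assert keys == sorted(keys)

    def test_full_inhibitory_block_single_group(self):
        net = build_network(NetworkConfig(N_total=100, p_default=0.5,
                                          p_ie=1.0, p_ii=1.0,
                                          connectivity_seed=3))
        groups = group_by_inhibitory_indegree(net, "RS")
        assert len(groups) == 1
        assert groups[0].group_key == net.n_fs

    def test_default_realization_group_count(self, desk_network):
        # in-degrees ~ Binomial with mean 100: on the order of 60 groups
        groups = group_by_inhibitory_indegree(desk_network, "RS")
        assert 35 <= len(groups) <= 85


class TestGroupMeanPotential:
    def test_two_member_average(self):
        vm = {"RS": np.array([[-70.0, -60.0, -55.0]], dtype=np.float32)}
        res = make_result(vm=vm, vm_times=np.array([0.0]), n_rs=3)
        from seizprop.observables import GroupProfile
        groups = [GroupProfile(group_key=5, members=np.array([0, 1])),
                  GroupProfile(group_key=9, members=np.array([2]))]
        mu = group_mean_potential(res, groups, "RS")
        assert mu[0, 0] == pytest.approx(-65.0)
        assert mu[1, 0] == pytest.approx(-55.0)  # singleton: its own V


class TestKuramoto:
    VR, VD = -65.0, -40.0

    def test_full_alignment(self):
        R, Psi = kuramoto_order(np.full(50, -52.0), self.VR, self.VD)
        assert R == pytest.approx(1.0)

    def test_antipodal_pair_cancels(self):
        R, _ = kuramoto_order(np.array([self.VR, self.VD]), self.VR, self.VD)
        assert R == pytest.approx(0.0, abs=1e-12)

    def test_quarter_phase_mixture(self):
        # phases {0, pi/2, pi/2, pi}: resultant 2i/4 -> R = 0.5, Psi = pi/2
        V_half = self.VR + 0.5 * (self.VD - self.VR)
        R, Psi = kuramoto_order(
            np.array([self.VR, V_half, V_half, self.VD]), self.VR, self.VD)
        assert R == pytest.approx(0.5)
        assert Psi == pytest.approx(np.pi / 2)

    def test_clipping_out_of_range_potentials(self):
        R1, _ = kuramoto_order(np.array([-100.0, 20.0]), self.VR, self.VD)
        R2, _ = kuramoto_order(np.array([self.VR, self.VD]), self.VR, self.VD)
        assert R1 == pytest.approx(R2)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(5)
        V = rng.uniform(self.VR, self.VD, size=40)
        R1, P1 = kuramoto_order(V, self.VR, self.VD)
        R2, P2 = kuramoto_order(np.tile(V, 3), self.VR, self.VD)
        assert R1 == pytest.approx(R2)
        assert P1 == pytest.approx(P2)

    def test_r_bounded_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            V = rng.uniform(-90, 0, size=rng.integers(1, 30))
            R, Psi = kuramoto_order(V, self.VR, self.VD)
            assert 0.0 <= R <= 1.0
            assert 0.0 <= Psi <= np.pi

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kuramoto_order(np.empty(0), self.VR, self.VD)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            kuramoto_order(np.array([-60.0]), -40.0, -65.0)


class TestProfilesPipeline:
    def test_profiles_and_tidy_frame(self, desk_network):
        from seizprop import RecordSpec, run_simulation
        res = run_simulation(desk_network, PerturbationParams(alpha=0.0),
                             duration=200.0, dt=0.1, drive_seed=2,
                             record=RecordSpec(vm_populations=("RS",)))
        groups = group_by_inhibitory_indegree(desk_network, "RS")
        profiles = compute_group_profiles(res, groups, "RS")
        assert all(0 <= g.R.min() and g.R.max() <= 1 for g in profiles)
        frame = group_profiles_frame(profiles)
        assert set(frame.columns) == {"realization", "group_key", "t",
                                      "mu_V", "R", "Psi"}
        assert frame.group_key.nunique() == len(profiles)


class TestSortRaster:
    def test_all_equal_keys_identity(self):
        res = make_result(n_rs=10)
        perm = sort_raster(res, "RS", "spike_count")
        assert np.array_equal(perm, np.arange(10))

    def test_distinct_counts_strictly_ordered(self):
        spikes = [(i, 10.0 * k) for i in range(5) for k in range(5 - i)]
        res = make_result(spikes, n_rs=5)
        perm = sort_raster(res, "RS", "spike_count")
        assert np.array_equal(perm, np.array([4, 3, 2, 1, 0]))

    def test_indegree_sort_matches_degrees(self, desk_network):
        res = make_result(n_rs=desk_network.n_rs, n_fs=desk_network.n_fs)
        perm = sort_raster(res, "RS", "inhibitory_indegree", net=desk_network)
        deg = desk_network.inhibitory_in_degrees("RS")
        assert (np.diff(deg[perm]) >= 0).all()

    def test_sorting_sorted_data_is_identity(self):
        # resorting already-sorted counts leaves the order unchanged
        spikes = [(i, 10.0 * k) for i in range(5) for k in range(i + 1)]
        res = make_result(spikes, n_rs=5)
        counts = res.spike_counts("RS", 5)
        perm = sort_raster(res, "RS", "spike_count")
        assert np.array_equal(counts[perm], np.sort(counts))
        assert np.array_equal(np.argsort(counts[perm], kind="stable"),
                              np.arange(5))

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            sort_raster(make_result(), "RS", "voltage")
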