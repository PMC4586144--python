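import numpy as np
import pytest
from scipy.integrate import solve_ivp

import afgc
from afgc.network_sim import SPECIES, _limit_cycle_point, _propensities


class TestTopologies:
    def test_chain3_edges(self):
        net = afgc.make_topology("chain3")
        assert net.edge_set == {(0, 1), (1, 2)}

    def test_bypass4_edges(self):
        net = afgc.make_topology("bypass4")
        assert net.edge_set == {(0, 1), (0, 2), (1, 2), (2, 3)}

    def test_custom_empty_runs_uncoupled(self):
        net = afgc.make_topology("custom", n_cells=2, kind_params={"edges": []})
        assert net.edges == ()
        traj = afgc.simulate(net, afgc.SimulationParams(seed=0, t_end=2.0))
        assert traj.counts.shape[1] == 2

    def test_unknown_kind_and_cell_mismatch(self):
        with pytest.raises(ValueError):
            afgc.make_topology("ring99")
        with pytest.raises(ValueError):
            afgc.make_topology("chain3", n_cells=5)

    def test_no_self_edges_or_out_of_range(self):
        with pytest.raises(ValueError):
            afgc.DirectedNetwork(3, ((1, 1),))
        with pytest.raises(ValueError):
            afgc.DirectedNetwork(3, ((0, 3),))

    def test_mini_scn_structure(self):
        net = afgc.make_topology("mini_scn20", seed=4)
        within = {(a, b) for a, b in net.edges if (a < 10) == (b < 10)}
        across = set(net.edges) - within
        assert len(within) == 2 * 10 * 9          # two all-to-all groups
        assert len(across) == 4
        assert all(a < 10 <= b for a, b in across)

    def test_random_topologies_reproducible(self):
        for kind in ("mini_scn20", "barabasi_albert", "watts_strogatz"):
            a = afgc.make_topology(kind, seed=7)
            b = afgc.make_topology(kind, seed=7)
            assert a.edges == b.edges
        c = afgc.make_topology("barabasi_albert", seed=8)
        assert c.edges != afgc.make_topology("barabasi_albert", seed=9).edges

    def test_barabasi_albert_degree(self):
        net = afgc.make_topology("barabasi_albert", seed=1)
        assert net.n_cells == 100
        # m = 1 attachment: n-1 edges, average out-degree ~1
        assert len(net.edges) == 99

    def test_watts_strogatz_degree(self):
        net = afgc.make_topology("watts_strogatz", seed=1)
        assert net.n_cells == 100
        assert len(net.edges) == 100   # ring of degree 2, one direction each

    def test_edgelist_roundtrip(self, tmp_path, dual10_net):
        path = tmp_path / "edges.csv"
        dual10_net.write_edgelist(path)
        back = afgc.DirectedNetwork.read_edgelist(path, n_cells=10)
        assert back.edge_set == dual10_net.edge_set

    def test_graphml_roundtrip(self, tmp_path, dual10_net):
        path = tmp_path / "net.graphml"
        dual10_net.write_graphml(path)
        back = afgc.DirectedNetwork.read_graphml(path)
        assert back.edge_set == dual10_net.edge_set


class TestSimulate:
    def test_bit_reproducible(self, chain3_net):
        p = afgc.SimulationParams(seed=5, t_end=10.0)
        a = afgc.simulate(chain3_net, p)
        b = afgc.simulate(chain3_net, p)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_counts_nonnegative_and_integer(self, chain3_traj):
        assert chain3_traj.counts.min() >= 0
        assert np.all(chain3_traj.counts == np.rint(chain3_traj.counts))

    def test_sampling_grid(self, chain3_traj):
        dt = np.diff(chain3_traj.times)
        np.testing.assert_allclose(dt, chain3_traj.sample_interval / 60.0)

    def test_circadian_period(self, chain3_traj):
        """Cell traces oscillate with a ~24 h period at default parameters."""
        m = chain3_traj.species_matrix("M")[:, 0]
        sm = np.convolve(m, np.ones(121) / 121, "same")
        x = sm - sm.mean()
        ac = np.correlate(x, x, "full")[len(x) - 1:]
        ac /= ac[0]
        # first autocorrelation peak between 18 h and 30 h
        lo, hi = 18 * 60, 30 * 60
        peak = lo + np.argmax(ac[lo:hi])
        assert 19 * 60 < peak < 29 * 60

    def test_propensity_formulas(self, dual10_net):
        """SSA propensities match an independent computation of the six
        reaction channels."""
        p = afgc.SimulationParams()
        rng = np.random.default_rng(0)
        M = rng.integers(5, 200, 10).astype(float)
        PC = rng.integers(5, 150, 10).astype(float)
        PN = rng.integers(5, 100, 10).astype(float)
        adj_idx, adj_ptr = dual10_net.in_neighbors_csr()
        a = np.zeros(60)
        _propensities(M, PC, PN, adj_idx, adj_ptr, a, p.vs_base, p.L, p.alpha,
                      p.vm, p.Km, p.ks, p.vd, p.Kd, p.k1, p.k2,
                      p.K1 ** p.n, float(p.n), p.omega)
        w = p.omega
        for i in range(10):
            nb = adj_idx[adj_ptr[i]: adj_ptr[i + 1]]
            vs = p.vs_base + p.alpha * (M[nb].mean() - M[i]) / w
            vs = max(vs, 0.0)
            expected = [
                w * vs * p.K1 ** 4 / (p.K1 ** 4 + (PN[i] / w) ** 4),
                w * p.vm * (M[i] / w) / (p.Km + M[i] / w),
                p.ks * M[i],
                w * p.vd * (PC[i] / w) / (p.Kd + PC[i] / w),
                p.k1 * PC[i],
                p.k2 * PN[i],
            ]
            np.testing.assert_allclose(a[6 * i: 6 * i + 6], expected, rtol=1e-12)

    def test_rising_differences_slightly_positive_bounded(self, dual10_net):
        """Minute-to-minute changes of M on rising segments: mean slightly
        positive, range within about [-4, 4]."""
        params = afgc.SimulationParams(seed=2, t_end=72.0)
        traj = afgc.simulate(dual10_net, params)
        iv = afgc.detect_rising_intervals(traj)
        panel = afgc.difference_and_concatenate(traj, iv)
        d = panel.values
        assert 0.0 < d.mean() < 0.8
        assert np.percentile(d, 1) >= -4.5
        assert np.percentile(d, 99) <= 4.5
        assert d.min() >= -7 and d.max() <= 7

    def test_uncoupled_cells_desynchronize(self):
        """With no coupling, two cells started in phase drift apart."""
        net = afgc.make_topology("custom", n_cells=2, kind_params={"edges": []})
        params = afgc.SimulationParams(seed=9, t_end=150.0, alpha=0.0)
        traj = afgc.simulate(net, params)
        m = traj.species_matrix("M")
        gap = m[:, 0] - m[:, 1]
        early = gap[: 24 * 60].std()
        late = gap[-24 * 60:].std()
        assert late > 2 * early

    def test_deterministic_limit(self):
        """At large omega the scaled trajectory tracks the ODE solution
        within 2% sup-norm over one cycle (omega large enough that phase
        diffusion over the cycle is negligible)."""
        net = afgc.make_topology("custom", n_cells=1, kind_params={"edges": []})
        params = afgc.SimulationParams(seed=1, t_end=24.0, omega=20000.0)
        traj = afgc.simulate(net, params)
        p = params
        y0 = np.rint(_limit_cycle_point(p) * p.omega) / p.omega

        def rhs(t, y):
            M, PC, PN = y
            return [p.vs_base * p.K1 ** 4 / (p.K1 ** 4 + PN ** 4)
                    - p.vm * M / (p.Km + M),
                    p.ks * M - p.vd * PC / (p.Kd + PC) - p.k1 * PC + p.k2 * PN,
                    p.k1 * PC - p.k2 * PN]

        sol = solve_ivp(rhs, (0, 24.0), y0, t_eval=traj.times,
                        rtol=1e-9, atol=1e-11, method="LSODA")
        m_ode = sol.y[0]
        m_ssa = traj.species_matrix("M")[:, 0] / p.omega
        assert np.max(np.abs(m_ssa - m_ode)) <= 0.02 * np.max(np.abs(m_ode))

    def test_fluctuation_shrinks_with_omega(self):
        """Relative per-step fluctuation of M decreases monotonically with
        omega (larger volume = less intrinsic noise)."""
        net = afgc.make_topology("custom", n_cells=1, kind_params={"edges": []})
        rel = []
        for omega in (10.0, 50.0, 200.0, 1000.0):
            ratios = []
            for seed in range(5):
                params = afgc.SimulationParams(seed=seed, t_end=24.0,
                                               omega=omega)
                m = afgc.simulate(net, params).species_matrix("M")[:, 0]
                ratios.append(np.diff(m).std() / m.mean())
            rel.append(np.mean(ratios))
        assert all(a > b for a, b in zip(rel, rel[1:]))

    def test_tau_leap_nonnegative_and_oscillates(self, chain3_net):
        params = afgc.SimulationParams(seed=4, t_end=48.0, method="tau-leap")
        traj = afgc.simulate(chain3_net, params)
        assert traj.counts.min() >= 0
        m = traj.species_matrix("M")[:, 0]
        assert m.max() > 2 * max(m.min(), 1.0)

    def test_coupled_alpha_zero_matches_single_cell_stats(self, chain3_net):
        """With alpha = 0 the per-cell dynamics equal uncoupled dynamics:
        mean and SD of M over several cycles agree within Monte-Carlo
        error with a single-cell run."""
        params = afgc.SimulationParams(seed=6, t_end=100.0, alpha=0.0)
        multi = afgc.simulate(chain3_net, params).species_matrix("M")
        single_net = afgc.make_topology("custom", n_cells=1,
                                        kind_params={"edges": []})
        singles = [afgc.simulate(single_net,
                                 params.with_(seed=100 + s)
                                 ).species_matrix("M")[:, 0]
                   for s in range(3)]
        mu_multi = multi.mean(axis=0)
        mu_single = np.mean([s.mean() for s in singles])
        sd_single = np.std([s.mean() for s in singles], ddof=1)
        tol = max(4 * sd_single, 0.15 * mu_single)
        assert np.all(np.abs(mu_multi - mu_single) < tol)


class TestMeasurementNoise:
    def test_zero_fraction_identity(self, chain3_traj):
        out = afgc.add_measurement_noise(chain3_traj, 0.0, seed=1)
        np.testing.assert_array_equal(out.counts, chain3_traj.counts)

    def test_negative_fraction_rejected(self, chain3_traj):
        with pytest.raises(ValueError):
            afgc.add_measurement_noise(chain3_traj, -0.1)

    def test_noise_sd_matches_reference(self):
        """fraction 0.5 with reference SD 10 adds noise of SD ~= 5."""
        n = 10000
        counts = np.zeros((n, 2, 3))
        rng = np.random.default_rng(0)
        base = 10.0 * rng.standard_normal(n)
        base *= 10.0 / base.std(ddof=1)        # cell 0: SD exactly 10
        counts[:, 0, :] = base[:, None]
        counts[:, 1, :] = 100.0                # cell 1: constant
        traj = afgc.Trajectory(
            times=np.arange(n) / 60.0, counts=counts,
            params=afgc.SimulationParams(t_end=n / 60.0),
            network=afgc.DirectedNetwork(2, ()))
        noisy = afgc.add_measurement_noise(traj, 0.5, seed=3)
        added = noisy.counts[:, 1, 0] - 100.0
        assert abs(added.std(ddof=1) - 5.0) / 5.0 < 0.05

    def test_output_real_valued(self, chain3_traj):
        noisy = afgc.add_measurement_noise(chain3_traj, 0.3, seed=2)
        assert np.any(noisy.counts != np.rint(noisy.counts))


class TestTrajectoryIO:
    def test_long_csv_roundtrip(self, tmp_path, chain3_net):
        params = afgc.SimulationParams(seed=1, t_end=2.0)
        traj = afgc.simulate(chain3_net, params)
        path = tmp_path / "traj.csv"
        traj.write_csv(path, layout="long")
        back = afgc.Trajectory.read_csv(path)
        np.testing.assert_array_equal(back.counts, traj.counts)
        np.testing.assert_allclose(back.times, traj.times, atol=1e-6)

    def test_wide_csv_preserves_reals(self, tmp_path, chain3_net):
        params = afgc.SimulationParams(seed=1, t_end=2.0)
        traj = afgc.add_measurement_noise(
            afgc.simulate(chain3_net, params), 0.2, seed=0)
        path = tmp_path / "wide.csv"
        traj.write_csv(path, layout="wide", species="M")
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(data[:, 1:], traj.species_matrix("M"),
                                   rtol=0, atol=1e-12)


class TestParamsValidation:
    @pytest.mark.parametrize("kw", [
        {"omega": 0.0}, {"n": 0}, {"sample_interval": 0.0},
        {"vm": -1.0}, {"method": "leapfrog"}, {"t_end": -5.0},
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            afgc.SimulationParams(**kw)
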