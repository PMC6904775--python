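"""Simulation: conservation, closed-form limits, ATP handling, steady states."""

import numpy as np
import pytest

from fumet.network import (ObservableMap, ParameterRegistry, Reaction,
                           ReactionNetwork, Species, build_network,
                           linear_chain_network)
from fumet.simulator import (ATPModel, flux_report, simulate, steady_state)


def _zero_all_rates(net):
    reg = net.registry
    for (g, n) in list(reg.entries()):
        if n in ("V", "Vf", "Vr"):
            reg.set(g, n, 0.0, force=True)


class TestSimulate:
    def test_all_rates_zero_gives_constant_trajectory(self, net):
        # with every maximal rate zeroed nothing reacts; the integrated
        # species stay put (forced ATP/ADP are inputs, not states)
        _zero_all_rates(net)
        traj = simulate(net)
        integrated = [i for i, s in enumerate(net.species_ids)
                      if s not in ("ATP", "ADP")]
        assert np.allclose(traj.states[:, integrated],
                           traj.states[0, integrated][None, :])
        atp = ATPModel(mode="dynamic", k_sink=0.0)
        traj = simulate(net, None, None, atp)
        assert np.allclose(traj.states, traj.states[0][None, :])

    def test_total_fluorine_conserved(self, default_trajectory):
        obs = default_trajectory.observables()
        tot = obs["totalF"].to_numpy()
        assert np.abs(tot - tot[0]).max() / tot[0] < 1e-6
        assert default_trajectory.conservation_drift < 1e-6

    def test_linearized_exponential_decay_limit(self):
        # one irreversible MM step with Km >> S behaves as dS/dt = -(V/Km) S
        V, Km, S0 = 50.0, 1e6, 100.0
        toy = linear_chain_network([(V, Km)], [S0, 0.0])
        t = np.linspace(0, 10, 21)
        traj = simulate(toy, None, t)
        expected = S0 * np.exp(-(V / Km) * t)
        assert np.abs(traj.states[:, 0] - expected).max() / S0 < 1e-4

    def test_decreasing_grid_rejected(self, net):
        with pytest.raises(ValueError, match="increasing"):
            simulate(net, None, np.array([0.0, 2.0, 1.0]))

    def test_negative_initial_state_rejected(self, net):
        x0 = net.initial_state()
        x0[0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            simulate(net, x0)

    def test_grid_refinement_convergence(self, chain):
        t = np.linspace(0, 17, 18)
        a = simulate(chain, None, t, rtol=1e-8, atol=1e-9).states
        b = simulate(chain, None, t, rtol=4e-9, atol=5e-10).states
        assert np.abs(a - b).max() / np.abs(a).max() < 1e-4

    def test_dynamic_mode_conserves_atp_plus_adp_without_sink(self, net):
        atp = ATPModel(mode="dynamic", k_sink=0.0)
        traj = simulate(net, None, np.linspace(0, 17, 18), atp)
        i_atp = net.species_index("ATP")
        i_adp = net.species_index("ADP")
        pool = traj.states[:, i_atp] + traj.states[:, i_adp]
        assert np.abs(pool - pool[0]).max() / pool[0] < 1e-6

    def test_forced_mode_tracks_decay_curve(self, default_trajectory, net):
        atp = ATPModel()
        i_atp = net.species_index("ATP")
        assert np.allclose(default_trajectory.states[:, i_atp],
                           atp.atp_um(default_trajectory.times))


class TestATPModel:
    def test_forced_curve_shape(self):
        atp = ATPModel()
        assert atp.relative(0.0) == 1.0
        assert atp.relative(1.0) <= 0.5
        assert atp.relative(4.0) < 0.05
        t = np.linspace(0, 20, 200)
        assert np.all(np.diff(atp.relative(t)) <= 0)

    def test_adp_complements_atp(self):
        atp = ATPModel(atp0_um=800.0, adp0_um=100.0)
        t = np.linspace(0, 10, 50)
        assert np.allclose(atp.atp_um(t) + atp.adp_um(t), 900.0)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ATPModel(mode="oscillating")
        with pytest.raises(ValueError):
            ATPModel(t_half=-1.0)


class TestFluxReport:
    def test_all_zero_fluxes_give_empty_ranking(self, net):
        _zero_all_rates(net)
        traj = simulate(net)
        report = flux_report(traj, [(1.0, 17.0)])
        assert len(report[(1.0, 17.0)]) == 0

    def test_single_active_reaction_ranked_first(self):
        toy = linear_chain_network([(100.0, 50.0)], [500.0, 0.0])
        traj = simulate(toy, None, np.linspace(0, 5, 11))
        report = flux_report(traj, [(0.0, 5.0)])[(0.0, 5.0)]
        assert report.iloc[0]["reaction"] == "R1"
        assert report.iloc[0]["direction"] == "forward"

    def test_udp_reductase_flux_decays_late(self, default_trajectory):
        # the deoxy-production flux (R10) collapses once its substrate drains
        j = list(default_trajectory.reaction_labels).index("R10")
        flux = default_trajectory.fluxes[:, j]
        t = default_trajectory.times
        assert abs(flux[t == 17.0][0]) < 0.05 * abs(flux).max()

    def test_empty_window_rejected(self, default_trajectory):
        with pytest.raises(ValueError, match="window"):
            flux_report(default_trajectory, [(100.0, 101.0)])


def _two_species_reversible_net(Vf, Vr, Kms, Kmp, s0, p0):
    reg = ParameterRegistry()
    for n, v in (("Vf", Vf), ("Vr", Vr), ("Kms", Kms), ("Kmp", Kmp)):
        reg.add("r1", n, v)
    rxn = Reaction(1, "toy", "reversible isomerase", (("S", 1),), (("P", 1),),
                   "rev_mm", "r1")
    species = [Species("S", s0, True), Species("P", p0, True)]
    obs = ObservableMap({"S": ("S",), "P": ("P",)}, ("S", "P"))
    return ReactionNetwork(species, [rxn], reg, obs)


class TestSteadyState:
    def test_zero_initial_state_is_fixed_point(self, net):
        ss = steady_state(net, x0=np.zeros(16))
        assert ss.converged
        free = [i for i, s in enumerate(net.species_ids)
                if s not in ("ATP", "ADP")]
        assert np.allclose(ss.state[free], 0.0)

    def test_reversible_mm_haldane_equilibrium_ratio(self):
        Vf, Vr, Kms, Kmp = 8.0, 3.0, 40.0, 15.0
        toy = _two_species_reversible_net(Vf, Vr, Kms, Kmp, 120.0, 30.0)
        ss = steady_state(toy, tol=1e-12)
        assert ss.converged
        S, P = ss.state
        # zero net flux: Vf S / Kms = Vr P / Kmp
        assert S / P == pytest.approx((Vr * Kms) / (Vf * Kmp), rel=1e-6)

    def test_catabolic_end_state_sign_pattern(self, default_steady_state):
        # the long-run state keeps free 5-FU, its nucleoside, and ADP
        for sid in ("5FU", "FUDR", "ADP"):
            assert sid in default_steady_state.nonvanishing

    def test_residual_below_tolerance(self, default_steady_state):
        assert default_steady_state.residual < 1e-9

    def test_nonconvergence_is_reported_not_silent(self, net):
        # an unreachable tolerance on the cycling end state must yield an
        # explicit failure result, never a silent pass
        res = steady_state(net, tol=1e-300, t_max=100.0)
        assert not res.converged
        assert "residual" in res.message


def test_trajectory_frames_roundtrip(default_trajectory):
    df = default_trajectory.to_frame()
    assert "time" in df.columns
    assert "5FU" in df.columns and "flux_R1" in df.columns
    assert len(df) == len(default_trajectory.times)
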