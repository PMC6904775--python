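"""Metabolic control analysis: elasticities, control coefficients, theorems."""

import numpy as np
import pytest

from fumet.mca import control_coefficients, elasticities, mca_extremes, MCAResult
from fumet.network import (ObservableMap, ParameterRegistry, Reaction,
                           ReactionNetwork, Species)
from fumet.simulator import steady_state
import pandas as pd


def _two_step_cycle(V1, Km1, V2, Km2, total=100.0):
    """X0 -> X1 -> X0: an unbranched loop carrying steady cyclic flux."""
    reg = ParameterRegistry()
    reg.add("r1", "V", V1)
    reg.add("r1", "Km", Km1)
    reg.add("r2", "V", V2)
    reg.add("r2", "Km", Km2)
    rxns = [Reaction(1, "f", "forward step", (("X0", 1),), (("X1", 1),),
                     "irr_mm", "r1"),
            Reaction(2, "b", "return step", (("X1", 1),), (("X0", 1),),
                     "irr_mm", "r2")]
    species = [Species("X0", total / 2, True), Species("X1", total / 2, True)]
    obs = ObservableMap({"X0": ("X0",), "X1": ("X1",)}, ("X0", "X1"))
    return ReactionNetwork(species, rxns, reg, obs)


class TestElasticities:
    def test_irr_mm_closed_form(self, net):
        # scaled elasticity of an irreversible MM step is Km/(Km+S)
        x = net.initial_state()
        res = elasticities(net, x)
        S = x[net.species_index("FUTP")]
        Km = net.registry.get("r4", "Km")
        assert res.scaled.loc["R4", "FUTP"] == pytest.approx(Km / (Km + S))
        assert 0 < res.scaled.loc["R4", "FUTP"] < 1

    def test_irr_mm_half_saturation_gives_half(self, net):
        x = net.initial_state()
        x[net.species_index("FUTP")] = net.registry.get("r4", "Km")
        res = elasticities(net, x)
        assert res.scaled.loc["R4", "FUTP"] == pytest.approx(0.5)

    def test_zero_rate_rows_are_flagged_undefined(self, net):
        x = np.zeros(16)
        res = elasticities(net, x)
        assert not res.defined.to_numpy().any()
        assert np.isnan(res.scaled.to_numpy()).all()

    def test_ping_pong_matches_finite_differences(self, net, rng):
        x = 10 ** rng.uniform(0, 3, 16)
        res = elasticities(net, x)
        v = net.rates(x)
        j = 2  # R3, ping-pong
        for sid in ("ATP", "FUDP", "ADP", "FUTP"):
            i = net.species_index(sid)
            h = 1e-6 * x[i]
            up, dn = x.copy(), x.copy()
            up[i] += h
            dn[i] -= h
            fd = (net.rates(up)[j] - net.rates(dn)[j]) / (2 * h) * x[i] / v[j]
            assert res.scaled.loc["R3", sid] == pytest.approx(fd, rel=1e-4)

    def test_negative_state_rejected(self, net):
        with pytest.raises(ValueError):
            elasticities(net, -np.ones(16))


class TestControlCoefficients:
    def test_two_step_loop_matches_closed_form(self):
        toy = _two_step_cycle(50.0, 30.0, 30.0, 60.0)
        ss = steady_state(toy, tol=1e-12)
        assert ss.converged
        res = control_coefficients(toy, ss)
        # independent closed form: with g_i the unscaled substrate
        # derivatives at the fixed point, C^J_1 = g2/(g1+g2)
        X0, X1 = ss.state
        g1 = 50.0 * 30.0 / (30.0 + X0) ** 2
        g2 = 30.0 * 60.0 / (60.0 + X1) ** 2
        assert res.FCC.loc["R1", "R1"] == pytest.approx(g2 / (g1 + g2), rel=1e-4)
        assert res.FCC.loc["R1", "R2"] == pytest.approx(g1 / (g1 + g2), rel=1e-4)

    def test_perturbation_route_agrees_with_structural(self):
        toy = _two_step_cycle(50.0, 30.0, 30.0, 60.0)
        ss = steady_state(toy, tol=1e-12)
        a = control_coefficients(toy, ss, method="structural")
        b = control_coefficients(toy, ss, method="perturbation")
        assert np.allclose(a.FCC.to_numpy(), b.FCC.to_numpy(), atol=5e-4)
        assert np.allclose(a.CCC.to_numpy(), b.CCC.to_numpy(), atol=5e-3)

    def test_summation_theorems_on_full_model(self, net, default_steady_state):
        res = control_coefficients(net, default_steady_state)
        assert res.fcc_rowsum_max_dev < 1e-6
        assert res.ccc_rowsum_max_dev < 1e-6

    def test_active_subnetwork_is_the_salvage_triangle(self, net,
                                                       default_steady_state):
        # asymptotically the flux circulates 5FU -> FUMP -> FUDR -> 5FU
        res = control_coefficients(net, default_steady_state)
        assert set(res.active_reactions) == {"R1", "R7", "R9"}
        assert set(res.active_species) == {"5FU", "FUMP", "FUDR"}

    def test_fcc_extremes_bounded_on_unbranched_segment(self, net,
                                                        default_steady_state):
        res = control_coefficients(net, default_steady_state)
        assert np.abs(res.FCC.to_numpy()).max() <= 1 + 1e-6

    def test_off_steady_state_warns(self, net):
        with pytest.warns(UserWarning, match="residual"):
            control_coefficients(net, net.initial_state())


class TestExtremes:
    @staticmethod
    def _result(fcc, ccc):
        dummy = pd.DataFrame(np.zeros((1, 1)), index=["R1"], columns=["X"])
        return MCAResult(EC=dummy, FCC=fcc, CCC=ccc, reference_state={},
                         reference_fluxes={}, active_reactions=("R1",),
                         active_species=("X",), fcc_rowsum_max_dev=0.0,
                         ccc_rowsum_max_dev=0.0)

    def test_all_zero_matrices_flagged_degenerate(self):
        z = pd.DataFrame(np.zeros((2, 2)), index=["R1", "R2"],
                         columns=["R1", "R2"])
        out = mca_extremes(self._result(z, z))
        assert out["degenerate"].all()

    def test_single_entry_is_both_extremes(self):
        m = pd.DataFrame(np.zeros((2, 2)), index=["R1", "R2"],
                         columns=["R1", "R2"])
        m.iloc[0, 1] = 0.7
        out = mca_extremes(self._result(m, m))
        fcc = out[out.coefficient == "FCC"]
        assert set(fcc["kind"]) == {"max_pos", "max_neg"}
        assert (fcc["value"] == 0.7).all()
        assert (fcc["cause"] == "R2").all()

    def test_full_model_extremes_have_cause_and_effect(self, net,
                                                       default_steady_state):
        res = control_coefficients(net, default_steady_state)
        out = mca_extremes(res)
        real = out[~out["degenerate"]]
        assert len(real) > 0
        assert real["cause"].notna().all() and real["effect"].notna().all()
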