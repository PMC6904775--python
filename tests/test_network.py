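"""Network assembly: structure, parameter census, sharing, observables."""

import numpy as np
import pytest

from fumet.network import (ObservableMap, ParameterRegistry, ReactionNetwork,
                           build_network, count_free_and_total_parameters,
                           linear_chain_network)


class TestStructure:
    def test_species_and_reaction_counts(self, net):
        assert net.n_species == 16
        assert net.n_reactions == 22

    def test_fluorinated_census(self, net):
        fl = [s.id for s in net.species if s.fluorinated]
        assert len(fl) == 14
        assert set(net.species_ids) - set(fl) == {"ATP", "ADP"}

    def test_hypothetical_reactions(self, net):
        assert [r.index for r in net.reactions if r.hypothetical] == [7, 15, 17]

    def test_every_reaction_converts_one_fluorinated_species(self, net):
        fl = {s.id for s in net.species if s.fluorinated}
        for r in net.reactions:
            assert sum(c for s, c in r.substrates if s in fl) == 1
            assert sum(c for s, c in r.products if s in fl) == 1

    def test_kinases_exchange_atp_adp_one_to_one(self, net):
        for r in net.reactions:
            if r.rate_law == "ping_pong":
                assert ("ATP", 1) in r.substrates
                assert ("ADP", 1) in r.products


class TestParameterCensus:
    def test_full_model_totals_113(self, net):
        census = count_free_and_total_parameters(net)
        assert census["total"] == 113

    def test_free_count_excludes_fixed_and_shared(self, net):
        # 33 aliased duplicates (r11, r15, r18, r20, r21, r22), the shared
        # phosphohydrolase V, and the two fixed literature Km values
        census = count_free_and_total_parameters(net)
        assert census["free"] == 113 - 33 - 1 - 2

    def test_empty_network(self):
        empty = ReactionNetwork([], [], ParameterRegistry())
        assert count_free_and_total_parameters(empty) == {"total": 0, "free": 0}

    def test_two_species_one_reaction_toy(self):
        toy = linear_chain_network([(1.0, 1.0)])
        assert count_free_and_total_parameters(toy) == {"total": 4, "free": 4}


class TestStoichiometry:
    def test_reaction_3_column(self, net):
        N = net.stoichiometry_matrix()
        col = N[:, 2]
        expected = {"ATP": -1, "FUDP": -1, "ADP": 1, "FUTP": 1}
        for sid in net.species_ids:
            assert col[net.species_index(sid)] == expected.get(sid, 0)

    def test_fluorine_moiety_balance_every_column(self, net):
        N = net.stoichiometry_matrix()
        fl = np.array([s.fluorinated for s in net.species], dtype=int)
        assert np.all(fl @ N == 0)

    def test_fluorine_indicator_in_left_null_space(self, net):
        # rank oracle on the 16x22 matrix: N^T has a nontrivial null space
        # and annihilates the fluorinated-species indicator exactly
        N = net.stoichiometry_matrix().astype(float)
        fl = np.array([s.fluorinated for s in net.species], dtype=float)
        rank = np.linalg.matrix_rank(N)
        assert rank < net.n_species
        assert np.allclose(N.T @ fl, 0.0)

    def test_atp_adp_moiety_balance_of_kinase_columns(self, net):
        N = net.stoichiometry_matrix()
        moiety = np.zeros(net.n_species)
        moiety[net.species_index("ATP")] = 1
        moiety[net.species_index("ADP")] = 1
        for j, r in enumerate(net.reactions):
            if r.index in (2, 3, 8, 11, 13, 18, 20):
                assert (moiety @ N[:, j]) == 0


class TestSharingAndFixing:
    def test_sharing_is_by_reference(self, net):
        net.registry.set("r3", "Vf", 1234.5)
        assert net.registry.get("r11", "Vf") == 1234.5
        assert net.registry.get("r18", "Vf") == 1234.5

    def test_chained_alias_r22_to_r5_v(self, net):
        # r22 -> r6 (group) and r6.V -> r5.V (parameter)
        net.registry.set("r5", "V", 99.0)
        assert net.registry.get("r22", "V") == 99.0
        assert net.registry.get("r6", "V") == 99.0

    def test_fixed_km_values(self, net):
        assert net.registry.get("r5", "Km") == 15.0
        assert net.registry.get("r21", "Km") == 15.0
        assert net.registry.get("r6", "Km") == 12.5
        assert net.registry.get("r22", "Km") == 12.5
        assert net.registry.is_fixed("r21", "Km")

    def test_fixed_parameter_rejects_plain_set(self, net):
        with pytest.raises(ValueError, match="fixed"):
            net.registry.set("r5", "Km", 20.0)
        net.registry.set("r5", "Km", 20.0, force=True)
        assert net.registry.get("r21", "Km") == 20.0


class TestObservables:
    def test_groups_partition_fluorinated_species(self, net):
        members = [s for g in net.observables.groups.values() for s in g]
        assert sorted(members) == sorted(
            s.id for s in net.species if s.fluorinated)

    def test_all_zero_state(self, net):
        obs = net.apply_observables(np.zeros(16))
        assert all(v == 0.0 for v in obs.values())

    def test_pure_5fu_state(self, net):
        x = np.zeros(16)
        x[net.species_index("5FU")] = 1000.0
        obs = net.apply_observables(x)
        assert obs["5FU"] == 1000.0
        assert obs["totalF"] == 1000.0

    def test_totalf_is_sum_of_groups(self, net, rng):
        x = rng.uniform(0, 500, 16)
        obs = net.apply_observables(x)
        groups = [v for k, v in obs.items() if k != "totalF"]
        assert obs["totalF"] == pytest.approx(sum(groups), rel=1e-12)

    def test_missing_species_rejected(self, net):
        with pytest.raises(KeyError, match="FUTP"):
            net.apply_observables({"5FU": 1.0})

    def test_non_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            ObservableMap({"a": ("X0",)}, ("X0", "X1"))


def test_default_initial_state_is_normalized(net):
    x = net.initial_state()
    fl = np.array([s.fluorinated for s in net.species])
    assert x[fl].sum() == pytest.approx(1000.0)
    assert np.all(x >= 0)
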