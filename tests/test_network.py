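"""Core reaction-network machinery: rate laws, stoichiometry, ODE assembly,
conserved moieties and validation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import redoxsim as rx
from redoxsim.network import NetworkConfigError

from conftest import random_states


def simple_ab(k=1.0):
    return rx.ReactionNetwork(
        "ab",
        [rx.Species("A", initial_concentration=2.0), rx.Species("B")],
        [rx.Reaction("r", reactants=[("A", 1)], products=[("B", 1)],
                     rate_law=rx.mass_action(k))])


class TestEvaluateRate:
    @pytest.mark.parametrize("law, conc, expected", [
        (rx.mass_action(2.0, [("A", 1), ("B", 1)]), {"A": 3.0, "B": 4.0}, 24.0),
        (rx.michaelis_menten(10.0, 5.0, "S"), {"S": 5.0}, 5.0),
        (rx.constant_flux(0.7), {}, 0.7),
        (rx.mass_action(0.5, [("A", 2)]), {"A": 3.0}, 4.5),
    ])
    def test_reference_values(self, law, conc, expected):
        assert rx.evaluate_rate(law, conc) == pytest.approx(expected)

    @given(s=st.floats(0.0, 1e6), vmax=st.floats(0.0, 1e3),
           km=st.floats(1e-6, 1e6))
    def test_hill_with_unit_coefficient_reduces_to_michaelis_menten(self, s, vmax, km):
        mm = rx.evaluate_rate(rx.michaelis_menten(vmax, km, "S"), {"S": s})
        h = rx.evaluate_rate(rx.hill(vmax, km, 1.0, "S"), {"S": s})
        assert h == pytest.approx(mm, rel=1e-12, abs=1e-300)
        assert 0.0 <= h <= vmax + 1e-12

    def test_missing_species_is_configuration_error(self):
        with pytest.raises(NetworkConfigError, match="X"):
            rx.evaluate_rate(rx.michaelis_menten(1.0, 1.0, "X"), {"S": 1.0})

    def test_negative_concentration_is_domain_error(self):
        with pytest.raises(ValueError, match="negative"):
            rx.evaluate_rate(rx.mass_action(1.0, [("A", 1)]), {"A": -1.0})


class TestStoichiometry:
    def test_single_conversion_column(self):
        S = rx.stoichiometry_matrix(simple_ab())
        assert S.tolist() == [[-1.0], [1.0]]

    def test_coefficient_two(self):
        net = rx.ReactionNetwork(
            "x", [rx.Species("A"), rx.Species("B")],
            [rx.Reaction("r", reactants=[("A", 2)], products=[("B", 1)],
                         rate_law=rx.mass_action(1.0))])
        assert rx.stoichiometry_matrix(net).tolist() == [[-2.0], [1.0]]

    def test_clamped_water_row_is_zero(self, ros_network):
        S = rx.stoichiometry_matrix(ros_network)
        i = ros_network.species_index()["H2O"]
        assert not S[i].any()


class TestAssembleRhs:
    def test_simple_conversion_derivative(self):
        rhs = rx.assemble_rhs(simple_ab(k=1.0))
        np.testing.assert_allclose(rhs(np.array([2.0, 0.0])), [-2.0, 2.0])

    def test_zero_state_has_zero_derivative_without_sources(self):
        rhs = rx.assemble_rhs(simple_ab())
        np.testing.assert_allclose(rhs(np.zeros(2)), 0.0)

    def test_state_length_mismatch(self):
        rhs = rx.assemble_rhs(simple_ab())
        with pytest.raises(ValueError):
            rhs(np.zeros(3))

    def test_rhs_equals_stoichiometry_times_flux(self, ros_network):
        rhs = rx.assemble_rhs(ros_network)
        S = rx.stoichiometry_matrix(ros_network)
        for state in random_states(ros_network, 100, seed=7):
            np.testing.assert_array_equal(rhs(state),
                                          S @ rx.flux_vector(ros_network, state))

    def test_rhs_matches_trajectory_finite_differences(self):
        """The assembled derivative agrees with central differences of the
        integrated trajectory of a random 5-species mass-action network."""
        rng = np.random.default_rng(3)
        ids = [f"S{i}" for i in range(5)]
        species = [rx.Species(s, initial_concentration=rng.uniform(5, 50))
                   for s in ids]
        reactions = [
            rx.Reaction(f"r{j}",
                        reactants=[(ids[rng.integers(5)], 1)],
                        products=[(ids[rng.integers(5)], 1)],
                        rate_law=rx.mass_action(rng.uniform(1e-4, 1e-3)))
            for j in range(6)]
        net = rx.ReactionNetwork("rand", species, reactions)
        settings = rx.SimulationSettings(horizon=2000.0, n_report_points=20001,
                                         relative_tolerance=1e-10,
                                         absolute_tolerance=1e-14)
        res = rx.integrate(net, settings)
        rhs = rx.assemble_rhs(net)
        dt = res.times[1] - res.times[0]
        m = 5000  # interior grid point
        state = np.array([res.trajectories[s][m] for s in ids])
        fd = np.array([(res.trajectories[s][m + 1] - res.trajectories[s][m - 1])
                       / (2 * dt) for s in ids])
        np.testing.assert_allclose(rhs(state), fd, rtol=1e-6, atol=1e-12)


class TestConservedMoieties:
    @staticmethod
    def _span_contains(basis, vector):
        if not basis:
            return not np.any(vector)
        M = np.array(basis).T
        coef, *_ = np.linalg.lstsq(M, vector, rcond=None)
        return np.allclose(M @ coef, vector, atol=1e-9)

    def test_reversible_pair_conserves_sum(self):
        net = rx.ReactionNetwork(
            "ab", [rx.Species("A"), rx.Species("B")],
            [rx.Reaction("f", [("A", 1)], [("B", 1)], rate_law=rx.mass_action(1)),
             rx.Reaction("b", [("B", 1)], [("A", 1)], rate_law=rx.mass_action(1))])
        basis = rx.conserved_moieties(net)
        assert len(basis) == 1
        assert self._span_contains(basis, np.array([1.0, 1.0]))

    def test_binding_network_has_two_conservations(self):
        net = rx.ReactionNetwork(
            "abc", [rx.Species("A"), rx.Species("B"), rx.Species("C")],
            [rx.Reaction("f", [("A", 1), ("B", 1)], [("C", 1)],
                         rate_law=rx.mass_action(1)),
             rx.Reaction("b", [("C", 1)], [("A", 1), ("B", 1)],
                         rate_law=rx.mass_action(1))])
        basis = rx.conserved_moieties(net)
        # independent oracle: brute-force left null space of the 3x2 matrix
        S = rx.stoichiometry_matrix(net)
        assert np.linalg.matrix_rank(S) == 1
        assert len(basis) == 3 - np.linalg.matrix_rank(S)
        for v in (np.array([1.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0])):
            assert abs(S.T @ v).max() == 0
            assert self._span_contains(basis, v)

    def test_empty_reaction_list_conserves_everything(self):
        net = rx.ReactionNetwork("empty", [rx.Species("A"), rx.Species("B")], [])
        basis = rx.conserved_moieties(net)
        assert len(basis) == 2
        for v in np.eye(2):
            assert self._span_contains(basis, v)

    def test_every_basis_vector_annihilates_stoichiometry(self, antiox_network):
        S = rx.stoichiometry_matrix(antiox_network)
        for v in rx.conserved_moieties(antiox_network):
            assert np.abs(v @ S).max() == 0


class TestValidation:
    def test_well_formed_network_has_no_findings(self):
        assert rx.validate_network(simple_ab()) == []

    def test_unknown_species_reference_is_reported(self):
        net = simple_ab()
        net.reactions[0].products.append(("X", 1))
        findings = rx.validate_network(net)
        assert len(findings) == 1 and "X" in findings[0]

    def test_negative_initial_concentration_is_reported(self):
        net = simple_ab()
        net.species[0].initial_concentration = -1.0
        assert len(rx.validate_network(net)) == 1

    def test_duplicate_reaction_ids_rejected(self):
        net = simple_ab()
        net.reactions.append(net.reactions[0])
        assert any("duplicate reaction" in f for f in rx.validate_network(net))

    def test_reactantless_non_source_reaction_is_reported(self):
        net = simple_ab()
        net.reactions.append(rx.Reaction("bad", products=[("B", 1)],
                                         rate_law=rx.mass_action(1.0, [])))
        assert any("constant-flux" in f for f in rx.validate_network(net))
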