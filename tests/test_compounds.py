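"""Phytonutrient layer: mechanism constraints, dose->serum mapping,
network perturbation semantics, and combination behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import redoxsim as rx
from redoxsim import compounds as cp
from redoxsim import ros as rs
from redoxsim.network import NetworkConfigError

from conftest import random_states


@pytest.fixture(scope="module")
def registry():
    return cp.load_compound_registry()


class TestMechanismConstraints:
    def test_six_compounds_defined(self, registry):
        assert set(registry) == set(cp.COMPOUND_NAMES)

    def test_all_compounds_scavenge_ros(self, registry):
        for rec in registry.values():
            assert "ros_scavenging" in rec.mechanism.targets

    def test_only_cyanidin_lacks_an_nrf2_axis_target(self, registry):
        axis = {name for name, rec in registry.items()
                if set(rec.mechanism.targets) & set(cp.NRF2_AXIS_TARGETS)}
        assert axis == set(cp.COMPOUND_NAMES) - {"cyanidin"}

    def test_cyanidin_with_axis_target_rejected(self):
        with pytest.raises(NetworkConfigError):
            cp.CompoundMechanism("cyanidin",
                                 ("ros_scavenging", "nrf2_activation"))


class TestDoseToSerum:
    def test_zero_dose_gives_zero_serum(self):
        assert cp.dose_to_serum(cp.DoseSpec("rutin", 0.0, 200.0, 10.0)) == 0.0

    def test_reference_dose_gives_cmax(self):
        assert cp.dose_to_serum(cp.DoseSpec("rutin", 10.0, 200.0, 10.0)) == 200.0

    def test_linear_scaling_above_reference(self):
        spec = cp.DoseSpec("rutin", 25.0, 200.0, 10.0)
        assert cp.dose_to_serum(spec) == pytest.approx(2.5 * 200.0)

    def test_saturation_cap(self):
        spec = cp.DoseSpec("rutin", 1000.0, 200.0, 10.0, saturation=5000.0)
        assert cp.dose_to_serum(spec) == 5000.0

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            cp.dose_to_serum(cp.DoseSpec("rutin", -1.0, 200.0, 10.0))

    @given(st.floats(0.0, 1e3))
    def test_linearity_property(self, dose):
        spec = cp.DoseSpec("rutin", dose, 200.0, 10.0)
        assert cp.dose_to_serum(spec) == pytest.approx(dose * 20.0)


class TestSaturatingFactor:
    @given(s=st.floats(0.0, 1e9), a=st.floats(0.0, 1e3),
           b=st.floats(1e-3, 1e6))
    def test_bounded_and_monotone(self, s, a, b):
        f = cp.saturating_factor(s, a, b)
        assert 1.0 <= f <= 1.0 + a + 1e-12
        assert cp.saturating_factor(s + 1.0, a, b) >= f - 1e-12

    def test_zero_serum_is_identity(self):
        assert cp.saturating_factor(0.0, 5.0, 10.0) == 1.0


class TestApplyCompound:
    def test_zero_serum_is_flux_identity(self, aged_ros_network, registry):
        mech = registry["delphinidin"].mechanism
        out = cp.apply_compound(aged_ros_network, mech, 0.0)
        for state in random_states(aged_ros_network, 100, seed=2):
            np.testing.assert_array_equal(
                rx.flux_vector(out, state),
                rx.flux_vector(aged_ros_network, state))

    def test_cyanidin_adds_exactly_one_reaction(self, aged_ros_network, registry):
        mech = registry["cyanidin"].mechanism
        out = cp.apply_compound(aged_ros_network, mech, 50.0)
        assert len(out.reactions) == len(aged_ros_network.reactions) + 1
        added = out.reactions[-1]
        assert added.id == "ros_scavenging_cyanidin"
        assert out.get_species("compound_cyanidin").constant
        assert out.get_species("scavenged_cyanidin").sink

    def test_axis_targets_leave_antioxidant_reaction_count_unchanged(
            self, antiox_network, registry):
        mech = registry["delphinidin"].mechanism
        out = cp.apply_compound(antiox_network, mech, 100.0,
                                targets=["nrf2_activation"])
        assert len(out.reactions) == len(antiox_network.reactions)
        # only the import rate changed
        changed = [r.id for r, r0 in zip(out.reactions, antiox_network.reactions)
                   if r.rate_law.parameters != r0.rate_law.parameters]
        assert changed == ["nrf2_import"]

    def test_dose_dependent_ros_reduction(self, aged_ros_network, registry):
        mech = registry["delphinidin"].mechanism
        levels = []
        for serum in (0.0, 200.0, 600.0):
            net = cp.apply_compound(aged_ros_network, mech, serum,
                                    targets=["ros_scavenging"])
            _, state = rx.detect_steady_state(rx.integrate(net))
            levels.append(state["O2m"])
        assert levels[0] > levels[1] > levels[2]

    def test_undeclared_target_is_configuration_error(self, antiox_network, registry):
        with pytest.raises(NetworkConfigError):
            cp.apply_compound(antiox_network, registry["cyanidin"].mechanism,
                              10.0, targets=["nrf2_activation"])

    def test_unresolvable_mechanism_is_configuration_error(self, antiox_network,
                                                           registry):
        # cyanidin only scavenges; the antioxidant model has no ROS pool
        with pytest.raises(NetworkConfigError):
            cp.apply_compound(antiox_network, registry["cyanidin"].mechanism, 10.0)

    def test_scavenged_mass_equals_integrated_scavenging_flux(
            self, aged_ros_network, registry):
        mech = registry["cyanidin"].mechanism
        serum = 500.0
        net = cp.apply_compound(aged_ros_network, mech, serum,
                                targets=["ros_scavenging"])
        res = rx.integrate(net)
        k = mech.effect_constants["scavenging_k"]
        flux = k * serum * res.trajectories["O2m"]
        integral = np.trapezoid(flux, res.times)
        sink = res.trajectories["scavenged_cyanidin"][-1]
        assert sink == pytest.approx(integral, rel=5e-3)


class TestApplyCombination:
    def test_empty_combination_is_identity(self, aged_ros_network):
        out = cp.apply_combination(aged_ros_network, [])
        for state in random_states(aged_ros_network, 20, seed=9):
            np.testing.assert_array_equal(rx.flux_vector(out, state),
                                          rx.flux_vector(aged_ros_network, state))

    def test_order_independence(self, antiox_network, registry):
        pairs = [(registry["delphinidin"].mechanism, 300.0),
                 (registry["rutin"].mechanism, 500.0)]
        a = cp.apply_combination(antiox_network, pairs)
        b = cp.apply_combination(antiox_network, pairs[::-1])
        for state in random_states(antiox_network, 50, seed=10):
            np.testing.assert_allclose(rx.flux_vector(a, state),
                                       rx.flux_vector(b, state), rtol=1e-12)

    def test_duplicate_compound_rejected(self, aged_ros_network, registry):
        pairs = [(registry["rutin"].mechanism, 1.0)] * 2
        with pytest.raises(NetworkConfigError):
            cp.apply_combination(aged_ros_network, pairs)

    def test_removing_a_compound_never_strengthens_the_effect(
            self, aged_ros_network, registry):
        """Superset monotonicity on the compound lattice, spot-checked on
        random subsets: ROS with a subset >= ROS with the full set."""
        rng = np.random.default_rng(42)
        all_pairs = [(rec.mechanism, rec.max_serum())
                     for rec in registry.values()]

        def steady_ros(pairs):
            net = cp.apply_combination(aged_ros_network, pairs,
                                       targets=["ros_scavenging"])
            _, state = rx.detect_steady_state(rx.integrate(net))
            return state["O2m"]

        full = steady_ros(all_pairs)
        for _ in range(5):
            keep = rng.random(6) < 0.6
            subset = [p for p, k in zip(all_pairs, keep) if k]
            assert steady_ros(subset) >= full - 1e-9
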