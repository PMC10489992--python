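"""Nrf2/ARE model: published initial state, conservation structure, model
coupling, the algebraic steady-state solver, and baseline calibration."""

import numpy as np
import pytest

import redoxsim as rx
from redoxsim import antioxidant as ax
from redoxsim import ros as rs
from redoxsim.network import NetworkConfigError

TABLE2_NM = {"Maf": 4000.0, "Keap1": 2000.0, "Nrf2": 1800.0, "H2O2i": 1500.0}


class TestBuild:
    def test_default_initial_state_matches_published_table(self, antiox_network):
        for sid, value in TABLE2_NM.items():
            assert antiox_network.get_species(sid).initial_concentration == value

    def test_enzymes_start_at_zero(self, antiox_network):
        for enz in ax.ENZYMES:
            assert antiox_network.get_species(enz).initial_concentration == 0.0

    def test_zero_nrf2_means_zero_activated_synthesis_at_t0(self):
        cfg = ax.load_default_antioxidant_config()
        cfg.initial_concentrations["Nrf2"] = 0.0
        cfg.kinetic_constants["k_nrf2_syn"] = 1e-300  # no basal supply
        net = ax.build_antioxidant_network(cfg)
        fluxes = rx.flux_vector(net, net.initial_state_map())
        rids = [r.id for r in net.reactions]
        for enz in ax.ENZYMES:
            assert fluxes[rids.index(ax.ENZYME_SYNTHESIS_IDS[enz])] == 0.0

    def test_total_maf_and_keap1_are_conserved(self, antiox_network):
        idx = antiox_network.species_index()
        basis = rx.conserved_moieties(antiox_network)
        M = np.array(basis).T
        for pools in (("Maf", "NM"), ("Keap1", "KN")):
            target = np.zeros(len(antiox_network.species))
            for sid in pools:
                target[idx[sid]] = 1.0
            coef, *_ = np.linalg.lstsq(M, target, rcond=None)
            assert np.allclose(M @ coef, target, atol=1e-9), pools

    def test_missing_constant_is_configuration_error(self):
        cfg = ax.load_default_antioxidant_config()
        del cfg.kinetic_constants["k_maf_bind"]
        with pytest.raises(NetworkConfigError, match="k_maf_bind"):
            ax.AntioxidantModelConfig(cfg.initial_concentrations,
                                      cfg.kinetic_constants)


class TestSteadyStateStructure:
    def test_algebraic_solver_matches_integrated_steady_state(
            self, antiox_control_state):
        cfg = ax.load_default_antioxidant_config()
        ss = ax.nrf2_axis_steady_state(dict(cfg.kinetic_constants),
                                       TABLE2_NM["Keap1"], TABLE2_NM["Maf"],
                                       TABLE2_NM["H2O2i"])
        for sid in ("Nrf2", "KN", "Nrf2n", "NM", "Maf", "Keap1", *ax.ENZYMES):
            assert antiox_control_state[sid] == pytest.approx(
                ss[sid], rel=2e-4), sid

    def test_enzymes_decay_to_zero_without_synthesis(self):
        cfg = ax.load_default_antioxidant_config()
        for enz in ax.ENZYMES:
            cfg.kinetic_constants[f"k_syn_{enz}"] = 1e-300
        net = ax.build_antioxidant_network(cfg)
        for enz in ax.ENZYMES:
            net.get_species(enz).initial_concentration = 50.0
        res = rx.integrate(net)
        for enz in ax.ENZYMES:
            tr = res.trajectories[enz]
            assert (np.diff(tr) <= 1e-9).all() and tr[-1] < 1e-3

    def test_enzyme_level_increases_with_nuclear_activity(self):
        cfg = ax.load_default_antioxidant_config()
        k = dict(cfg.kinetic_constants)
        levels = []
        for scale in (1.0, 2.0, 5.0):
            k2 = dict(k)
            k2["k_nrf2_import"] *= scale
            ss = ax.nrf2_axis_steady_state(k2, 2000.0, 4000.0, 1500.0)
            levels.append(ss["CAT"])
        assert levels[0] < levels[1] < levels[2]


class TestCoupling:
    def test_independent_union_keeps_all_species(self, ros_network, antiox_network):
        combined, diag = ax.couple_models(ros_network, antiox_network,
                                          mode="independent")
        assert len(combined.species) == \
            len(ros_network.species) + len(antiox_network.species)
        # colliding enzyme pools are prefixed and reported
        assert set(diag["renamed"]) >= {"CAT", "SOD"}

    def test_shared_h2o2_merges_four_pools(self, ros_network, antiox_network):
        combined, diag = ax.couple_models(ros_network, antiox_network,
                                          mode="shared_h2o2")
        merged = {"H2O2i", "CAT", "SOD", "GPx"}
        assert set(diag["merged"]) == merged
        assert len(combined.species) == \
            len(ros_network.species) + len(antiox_network.species) - len(merged)
        assert rx.validate_network(combined) == []

    def test_oxidant_load_drives_enzyme_synthesis_in_shared_mode(self):
        """More NOX activity -> more merged H2O2 -> more ARE output."""
        h2o2, cat = [], []
        for fold in (1.0, 2.0, 4.0):
            ros_net = rs.apply_aging_condition(rs.build_ros_network(), fold)
            net, _ = ax.couple_models(ros_net, ax.build_antioxidant_network(),
                                      mode="shared_h2o2")
            final = rx.integrate(net).final_state()
            h2o2.append(final["H2O2"])
            cat.append(final["antiox__CAT"] if "antiox__CAT" in final
                       else final["CAT"])
        assert h2o2[0] < h2o2[1] < h2o2[2]
        assert cat[0] < cat[1] < cat[2]

    def test_missing_h2o2_pool_is_error(self, antiox_network):
        with pytest.raises(NetworkConfigError):
            ax.couple_models(antiox_network, antiox_network, mode="shared_h2o2")


class TestCalibration:
    def _single_enzyme_net(self, k_syn, k_deg):
        return rx.ReactionNetwork(
            "one_enzyme",
            [rx.Species("X", initial_concentration=0.0)],
            [rx.Reaction("X_synthesis", products=[("X", 1)],
                         rate_law=rx.constant_flux(k_syn)),
             rx.Reaction("X_degradation", reactants=[("X", 1)],
                         rate_law=rx.mass_action(k_deg))])

    def test_closed_form_synthesis_rate(self):
        """First-order turnover: k_syn = k_deg * target at steady state."""
        net = self._single_enzyme_net(k_syn=1e-3, k_deg=1e-5)
        result = ax.calibrate_baselines(net, {"X": 42.0}, tolerance=1e-6)
        assert result["k_syn_X"] == pytest.approx(4.2e-4, rel=1e-12)

    def test_identity_when_targets_equal_current_steady_state(self, antiox_network,
                                                              antiox_control_state):
        targets = {e: antiox_control_state[e] for e in ax.ENZYMES}
        result = ax.calibrate_baselines(antiox_network, targets)
        cfg = ax.load_default_antioxidant_config()
        for enz in ax.ENZYMES:
            assert result[f"k_syn_{enz}"] == pytest.approx(
                cfg.kinetic_constants[f"k_syn_{enz}"], rel=1e-3)

    def test_recovery_from_tenfold_perturbed_start(self, antiox_control_state):
        cfg = ax.load_default_antioxidant_config()
        true = {e: cfg.kinetic_constants[f"k_syn_{e}"] for e in ax.ENZYMES}
        for enz in ax.ENZYMES:
            cfg.kinetic_constants[f"k_syn_{enz}"] *= 10.0
        net = ax.build_antioxidant_network(cfg)
        targets = {e: antiox_control_state[e] for e in ax.ENZYMES}
        result = ax.calibrate_baselines(net, targets, tolerance=1e-4)
        for enz in ax.ENZYMES:
            assert result[f"k_syn_{enz}"] == pytest.approx(true[enz], rel=1e-2)

    def test_nonpositive_target_rejected(self, antiox_network):
        with pytest.raises(ValueError):
            ax.calibrate_baselines(antiox_network, {"CAT": 0.0})
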