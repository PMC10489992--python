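# Antioxidant-enzyme production pathway parameterisation (Keap1–Nrf2–Maf/ARE).
#
# initial_concentrations mirror the published model inputs verbatim (nM);
# the four ARE-driven enzymes start at zero and are produced by the model.
# Binding/release/translocation constants are set at magnitudes typical of
# reduced Keap1–Nrf2 models; the saturation constant K_A of the ARE synthesis
# law and the per-enzyme synthesis rates carry the values produced by
# fit_effect_constants / calibrate_baselines against the reported baselines
# and percent responses (re-derivable from scratch with those operations).
name: antioxidant_production
initial_concentrations:
  Maf: 4000.0
  Keap1: 2000.0
  Nrf2: 1800.0
  H2O2i: 1500.0
clamped_species: [H2O2i]
kinetic_constants:
  k_keap1_bind: 1.0e-3     # nM^-1 s^-1, Keap1 + Nrf2 association
  k_keap1_unbind: 1.0e-4   # s^-1, complex dissociation
  k_oxidative_release: 1.0e-7  # nM^-1 s^-1, H2O2-driven Nrf2 release from Keap1
  k_nrf2_deg_keap1: 5.8e-4 # s^-1, Keap1-promoted Nrf2 degradation (in complex)
  k_nrf2_syn: 1.0          # nM s^-1, Nrf2 synthesis
  k_nrf2_import: 3.86e-4   # s^-1, Nrf2 nuclear import
  k_nrf2n_deg: 1.0e-4      # s^-1, nuclear Nrf2 turnover
  k_maf_bind: 6.26e-8      # nM^-1 s^-1, nuclear Nrf2 + Maf dimerisation
  k_maf_unbind: 1.0e-3     # s^-1, Nrf2.Maf dissociation
  k_enz_deg: 2.0e-5        # s^-1, first-order enzyme turnover (shared default)
  K_A: 6.508591832701493   # nM, ARE activation saturation in [Nrf2.Maf]
  k_syn_CAT: 1.9474053436e-3  # nM s^-1, calibrated to the CAT baseline
  k_syn_HO1: 5.1930809162e-4  # nM s^-1, calibrated to the HO-1 baseline
  k_syn_SOD: 1.2940972176e-1  # nM s^-1, calibrated to the SOD baseline
  k_syn_GPx: 7.2879326643e-1  # nM s^-1, calibrated to the GPx baseline
enzyme_baselines:          # nM, reported 7-day control panel
  CAT: 42.0
  HO1: 11.2
  SOD: 2791.0
  GPx: 15718.0
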