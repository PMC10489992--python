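# Phytonutrient mechanism and dosing fixture (one record per compound).
#
# targets follow the published mechanism table: every compound scavenges ROS;
# all but cyanidin additionally act on the Nrf2 axis (delphinidin/malvidin:
# nuclear-translocation upregulation; ellagic acid: Keap1 downregulation;
# kaempferol: inhibition of Nrf2 degradation; rutin: p21-mediated activation,
# lumped into the translocation factor because p21 is not a state variable).
#
# SYNTHETIC dose/Cmax stand-ins: the published dose and Cmax tables live in
# supplementary material that is not available here, so doses are expressed
# in uM (the unit the results section itself uses), with a 10 uM reference
# dose and low-nM peak-serum values typical of polyphenol pharmacokinetics.
# nrf2_effect (dimensionless a) values are the output of
# fit_effect_constants against the reported percent increases; nrf2_ec50 for
# ellagic acid is located from its reported 80 uM response plateau.
# scavenging_k (nM^-1 s^-1) magnitudes order the ROS reductions as reported
# (delphinidin, ellagic acid, malvidin strongest).
dose_unit: uM
# reported max-dose enzyme-panel percent increases (calibration targets for
# fit_effect_constants) and the reported all-compound combination response
enzyme_response_pct:
  delphinidin: 120.0
  ellagic_acid: 98.0
  kaempferol: 3.0
  malvidin: 25.0
  rutin: 40.0
combination_response_pct: 128.0
ellagic_plateau_dose: 80.0   # uM; responses beyond this dose stay flat
compounds:
  cyanidin:
    targets: [ros_scavenging]
    scavenging_k: 6.0e-4
    cmax: 100.0          # nM at the reference dose
    reference_dose: 10.0 # uM
    max_dose: 50.0       # uM
  delphinidin:
    targets: [ros_scavenging, nrf2_activation]
    scavenging_k: 2.0e-3
    nrf2_effect: 38.90440096031634
    nrf2_ec50: 100.0     # nM serum
    cmax: 120.0
    reference_dose: 10.0
    max_dose: 50.0
  ellagic_acid:
    targets: [ros_scavenging, keap1_downregulation]
    scavenging_k: 4.0e-4
    nrf2_effect: 0.1543602789204324
    nrf2_ec50: 8.0
    cmax: 300.0
    reference_dose: 10.0
    max_dose: 120.0
  kaempferol:
    targets: [ros_scavenging, nrf2_degradation_inhibition]
    scavenging_k: 3.0e-4
    nrf2_effect: 0.009149146290550492
    nrf2_ec50: 100.0
    cmax: 150.0
    reference_dose: 10.0
    max_dose: 50.0
  malvidin:
    targets: [ros_scavenging, nrf2_activation]
    scavenging_k: 1.5e-3
    nrf2_effect: 0.6347911215439086
    nrf2_ec50: 100.0
    cmax: 140.0
    reference_dose: 10.0
    max_dose: 50.0
  rutin:
    targets: [ros_scavenging, p21_upregulation]
    scavenging_k: 2.5e-4
    nrf2_effect: 1.145343461043959
    nrf2_ec50: 100.0
    cmax: 200.0
    reference_dose: 10.0
    max_dose: 50.0
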