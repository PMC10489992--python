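# ROS-production pathway parameterisation.
#
# initial_concentrations mirror the published model inputs verbatim (nM).
# kinetic_constants: second-order constants for SOD dismutation, catalase and
# the Fenton reaction sit at literature magnitudes (effective, per-enzyme
# lumped); the NADPH-oxidase turnover k_nox is calibrated so that the aged
# control (two-fold NOX) settles at the reported 7.32 nM superoxide pool, and
# k_fe_red balances iron recycling at the aged-control H2O2 level so the
# Fe2+/Fe3+ split starts at its stationary point.
name: ros_production
initial_concentrations:
  LH: 351000.0
  O2: 10000.0
  H2O: 5.5e+7
  Fe2+: 100.0
  Fe3+: 6800.0
  SOD: 700.0
  H2O2: 0.38
  Catalase: 41.03
  GSH: 1000.0
  GPr: 1.0
  NADPH Oxidase: 3.06e-4
clamped_species: [H2O, O2, NADPH Oxidase]
kinetic_constants:
  k_nox: 2.6792156862745098   # nM^-1 s^-1, NOX superoxide turnover (base, fold 1)
  k_sod: 1.6e-3               # nM^-1 s^-1, SOD-catalysed dismutation (effective)
  k_cat: 8.5e-3               # nM^-1 s^-1, catalase H2O2 decomposition (effective)
  k_gpx: 5.6e-6               # nM^-2 s^-1, GPx H2O2 reduction (per GPr, per GSH)
  k_fenton: 7.6e-8            # nM^-1 s^-1, Fe2+ + H2O2 -> Fe3+ + OH.
  k_fe_red: 1.3032e-8         # s^-1, reductant-mediated Fe3+ -> Fe2+ recycling
  k_lh: 1.0e-4                # nM^-1 s^-1, OH. + LH hydrogen abstraction (effective)
  k_lo2: 1.0e-4               # nM^-1 s^-1, L. + O2 -> LOO.
  k_prop: 1.0e-8              # nM^-1 s^-1, LOO. + LH chain propagation
  k_term: 1.0e-2              # nM^-1 s^-1, 2 LOO. radical-radical termination
  k_looh_clear: 1.0e-3        # s^-1, LOOH reduction/clearance
  k_gsh_syn: 1.0              # nM s^-1, glutathione synthesis
  k_gsh_deg: 1.0e-3           # s^-1, glutathione turnover
  k_gssg_red: 1.0e-3          # s^-1, glutathione-reductase recycling GSSG -> 2 GSH
aging_fold: 2.0
ros_readout:
  O2m: 1.0
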