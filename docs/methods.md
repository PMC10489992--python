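# Methods

## Model overview

`redoxsim` simulates two reaction networks of cellular redox regulation and
their perturbation by six dietary phytonutrients.  All concentrations are
in nM and time in seconds; the standard horizon is 7 days (604,800 s), by
which every readout of the shipped parameterisation is stationary.  The
governing equations are `dc/dt = S·v(c)` with an integer stoichiometry
matrix `S` (rows of clamped species zeroed) and rate laws restricted to
four forms: mass action, Michaelis–Menten, Hill, constant flux.  Any
enzyme-catalysed step is written as mass action with the enzyme as a
first-order modifier, which keeps the right-hand-side assembler total and
the network analysable (conserved moieties are the exact rational left
null space of `S` over dynamic species, computed with sympy).

### ROS production network

NADPH oxidase (NOX, clamped at its tabulated level) converts dissolved O2
(clamped) into superoxide.  Superoxide is removed by SOD-catalysed
dismutation (2 O2·⁻ → H2O2 + O2, rate `k_sod·[SOD]·[O2·⁻]`).  H2O2 is
cleared by catalase and by the glutathione cycle (GPx-catalysed, rate
third-order in GPr, H2O2 and GSH so the flux vanishes as GSH is depleted;
GSSG is re-reduced by a lumped glutathione-reductase step and GSH has
synthesis/turnover so the pool self-regulates).  Fenton chemistry
(Fe²⁺ + H2O2 → Fe³⁺ + OH·) feeds a lipid-peroxidation chain on the LH pool
(initiation, oxygenation, propagation, radical–radical termination, LOOH
clearance); a reductant-mediated first-order Fe³⁺ → Fe²⁺ step closes the
iron cycle so total iron is conserved.  The "ROS" biomarker is the
superoxide pool by default (configurable as a weighted radical sum): it is
the direct NOX product and the species every compound scavenges.

The aged control condition multiplies the NOX catalytic constant by 2
(equivalent to doubling the enzyme level for a law linear in the enzyme).
Controls in this package are always the aged state at zero dose.

### Antioxidant-enzyme production network

Cytosolic Nrf2 (constant-flux synthesis Φ) binds Keap1 reversibly; the
complex is the dominant degradation route (Keap1-promoted, first order in
the complex) and is also opened by intracellular H2O2 (second-order
oxidative release with H2O2i clamped at its tabulated basal level).  Free
Nrf2 is imported into the nucleus, turns over there, and binds Maf
reversibly; total Maf and total Keap1 are conserved moieties.  Each of
CAT, HO-1, SOD and GPx is synthesised by a saturating ARE law
`k_syn·g`, `g = [Nrf2·Maf]/(K_A + [Nrf2·Maf])`, and degraded first order
with a shared rate constant `k_enz_deg = 2×10⁻⁵ s⁻¹` (half-life ≈ 9.6 h,
chosen so the enzymes traverse ≈12 e-folds within the 7-day horizon and
the trailing-window steady-state test passes cleanly).  Transcription and
translation are deliberately lumped into the single synthesis flux: only
protein-level outputs are reported.

Because the activation factor `g` is shared, every compound produces the
same relative enzyme response across the four-enzyme panel — which is also
how the reproduced study reports its results (one percent increase per
compound "for all enzymes").

This axis has an exact algebraic steady state (monotone 1-D bracketing for
free cytosolic Nrf2, then closed forms through import, Maf binding with
conservation, and the ARE law).  The ODE solution and the algebraic
solution agree to ≈10⁻⁴ relative in the tests; the algebraic route powers
the deterministic fitting described below, the ODE route produces every
reported number.

### Coupling modes

The default mode is `independent`: the two models are simulated separately
and biomarkers read per pathway, matching the separate reporting of the
reproduced study (colliding species ids are prefixed and reported).
`shared_h2o2` merges the ROS-model H2O2 with the antioxidant model's basal
H2O2i pool and replaces the ROS model's fixed CAT/SOD/GPx pools with the
ARE-produced enzymes, giving the fully coupled reading: raising NOX
activity then raises H2O2 and, through Keap1 oxidation, the enzyme output
(verified as a monotone chain in the tests).  The two models' GPx pools
differ by four orders of magnitude in the source tables ("GPr" 1 nM vs a
15,718 nM baseline); they are treated as distinct pools per pathway and
merged only in `shared_h2o2` mode.

## Phytonutrient layer

Dosing is constant administration: the compound is clamped at its serum
level for the whole horizon.  Serum level = (dose / reference dose)·Cmax,
linear with an optional saturation cap.  Doses are expressed in µM (the
unit the reproduced results themselves use), with a 10 µM reference dose
per compound and low-nM Cmax values typical of polyphenol pharmacokinetics;
these dose/Cmax entries are synthetic stand-ins for tabulated values that
were not available, and are isolated in `data/compounds.yaml`.

Mechanisms follow the published target table: all six compounds scavenge
superoxide (added second-order reaction into a bookkeeping sink, rate
`k_scav·[O2·⁻]·[compound]`); delphinidin and malvidin amplify Nrf2 nuclear
import; ellagic acid downregulates the Keap1 pool; kaempferol inhibits the
Keap1-routed Nrf2 degradation; rutin's p21-mediated activation is lumped
into the import factor because p21 is not a state variable.  Every
Nrf2-axis effect uses the saturating factor `f(s) = 1 + a·s/(b + s)`:
continuous, monotone, finite at any dose.  Saturation is what produces the
ellagic-acid high-dose plateau; its EC50 `b = 8 nM` serum is placed so the
response is flat (< 1 percentage point of further change) beyond the 80 µM
dose at which the plateau is reported.  Scavenging rate constants are
ordered so delphinidin, ellagic acid and malvidin produce the three
largest ROS reductions, as reported; no printed values exist for the ROS
percentages, so only the ordering is asserted.

## Parameter provenance and calibration

Initial concentrations reproduce the published input tables verbatim
(ROS model: LH 351,000; O2 10,000; H2O 5.5×10⁷; Fe²⁺ 100; Fe³⁺ 6,800;
SOD 700; H2O2 0.38; catalase 41.03; GSH 1,000; GPr 1; NOX 3.06×10⁻⁴ nM —
antioxidant model: Maf 4,000; Keap1 2,000; Nrf2 1,800; H2O2i 1,500 nM).
The kinetic constants were assembled as follows:

* Second-order constants with literature anchors (catalase–H2O2, Fenton)
  sit at their reported magnitudes; enzyme-mediated constants are
  *effective* lumped values chosen so that relaxation times stay within a
  numerically comfortable band (fastest ≈0.4 s, slowest ≈10⁵ s).  The
  hydroxyl-radical transfer constants in particular are throughput-limited
  (the radical chain flux is set by the Fenton flux, not by these
  constants), so they were set to keep component stiffness below ≈10⁶
  without changing any steady-state readout.
* `k_nox` is calibrated in closed form so the aged control settles at the
  reported 7.32 nM superoxide: at steady state
  `[O2·⁻] = fold·k_nox·[NOX]·[O2]/(2·k_sod·[SOD])`, exact because SOD is
  the only superoxide sink at zero dose.
* `k_fe_red` balances iron recycling at the aged-control H2O2 level, so
  the tabulated Fe²⁺/Fe³⁺ split is already stationary.
* Per-enzyme synthesis rates come from `calibrate_baselines`: for
  constant-flux synthesis with sole first-order degradation the closed
  form `k_syn = k_deg·target` is applied exactly without simulation; for
  the ARE-activated laws the steady state is linear in `k_syn`, so the
  rescale `k_syn ← k_syn·target/current` converges in one simulation pass
  (iterated to a 10⁻⁴ relative tolerance).
* Compound Emax constants `a` and the shared ARE saturation `K_A` come
  from `fit_effect_constants`: each published per-compound enzyme response
  (120/98/3/25/40%) fixes one `a` by monotone bracketing on the algebraic
  steady state, and the single global `K_A` is located in an outer
  bracketing loop so the joint application of all compounds reproduces
  the published combination response (+128%).  The procedure is exact,
  deterministic and seed-free.  The shipped YAML files carry these fitted
  values; the acceptance pipeline re-derives them from scratch.  Because
  the effect constants are fitted to the published responses, the dosing
  results validate the self-consistency of the fitting + forward pipeline
  (this is also stated in every run manifest).

## Numerical choices

* Integration: `scipy.integrate.solve_ivp`, BDF by default (LSODA and
  Radau selectable; a cross-method agreement test bounds the difference at
  0.5%), rtol 10⁻⁸, atol 10⁻¹² nM, adaptive internal steps, output on an
  even 5-minute grid (2,017 points over 7 days).
* Negativity: rates treat negative inputs as zero; trajectories are
  clipped to zero for reporting; any excursion below −10⁻⁹ nM
  (10³ × atol) raises, as that signals a modelling error rather than
  round-off.  A blow-up guard rejects any state above 10¹² nM.
* Steady-state detection: a species is stationary when its relative range
  over the trailing 10% of the horizon is below 10⁻⁴, with the window mean
  as denominator floored at 10⁻⁶ nM so femtomolar trace radicals (where
  solver noise dominates) cannot veto steadiness.  Reported biomarkers are
  trailing-window means.  Pure bookkeeping accumulators (scavenged-mass
  sinks, marked `sink`) grow without bound by design and are exempt.
* Duplicate reaction or species ids are validation errors, never silently
  renamed; model coupling prefixes colliding ids and reports the renames.
* SBML L3 export writes explicit kinetic-law formulas with local
  parameters; import reconstructs the law form from the parameter names
  and formula structure.  Round-trips preserve the stoichiometry matrix
  exactly and initial concentrations to the double-precision digit.

## Synthetic fixtures and what the tests show

`synthetic.make_toy_network` provides four closed-form fixtures (pure
decay, synthesis/decay, a Lotka–Volterra oscillator that must *fail*
steady-state detection, and a clamped-scavenger chain mirroring the dosing
mechanism); the integrator matches their closed forms to 10⁻⁶ relative.
`perturb_parameters` applies seeded median-1 log-normal factors
(σ = √log(1+cv²)) emulating the uncertainty of kinetic constants compiled
from heterogeneous experiments; a smoke test requires ≥95% of 100 draws at
cv = 0.5 to keep the aged-control biomarker positive and finite.  These
fixtures exercise every pipeline stage without the pathway
parameterisation, but they do not emulate biological variability between
cell types or conditions: passing tests demonstrate numerical and
structural correctness of the models, not predictive accuracy for any
particular experimental system.

Default problem sizes: the test and acceptance campaigns use 2–4-point
dose grids per compound (the dose–response surface is monotone and
saturating, so interior points add no information), full 7-day horizons
throughout, and the 17-species / 11-species pathway networks.

## Known limitations

* The ROS "level" is a model readout of the superoxide pool; absolute
  radical concentrations depend on the effective lumped constants and
  should be read comparatively (treated vs control), not as predictions
  of in-vivo radical levels.
* No pharmacokinetics beyond the linear Cmax mapping: absorption,
  elimination and metabolite chemistry are out of scope, as are
  compound–compound chemical interactions.
* The model is deterministic; no stochastic (Gillespie) simulation and no
  spatial/compartmental transport.
* Downstream damage systems (DNA/protein/lipid/telomere damage,
  senescence, mitochondrial dysfunction) are outside the model boundary.
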