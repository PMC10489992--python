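"""Aged-control baselines: the five oxidative-stress biomarkers at day 7.

Builds both pathway models, applies the aged condition (two-fold NADPH-
oxidase activity) to the ROS model, integrates over 7 days and reports the
steady-state biomarker panel.  These are the reference values every dosing
experiment is compared against.
"""

import redoxsim as rx
from redoxsim import experiments as ex

plan = ex.ExperimentPlan.default(model="both", n_doses=2)
panel = ex.run_control(plan)

print("Aged control (NOX x2, zero dose), 7-day steady state:")
print(f"  ROS  {panel.ros:10.2f} nM   (superoxide pool)")
print(f"  CAT  {panel.cat:10.1f} nM   (catalase)")
print(f"  HO-1 {panel.ho1:10.1f} nM   (heme oxygenase-1)")
print(f"  SOD  {panel.sod:10.1f} nM   (superoxide dismutase)")
print(f"  GPx  {panel.gpx:10.1f} nM   (glutathione peroxidase)")
print("Steady state reached:", panel.percent_vs_control)
print("\nA rise in ROS or a drop in the enzyme panel marks oxidative stress;"
      "\nphytonutrient dosing should move both in the protective direction.")
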