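"""Dose–response of one phytonutrient on both pathway models.

Sweeps delphinidin over its dose grid: the serum level (via the Cmax
mapping) scavenges superoxide in the ROS model and amplifies Nrf2 nuclear
import in the antioxidant model, so ROS falls and all four enzymes rise,
dose-dependently.
"""

from redoxsim import experiments as ex

plan = ex.ExperimentPlan.default(model="both", n_doses=4)
table = ex.run_dose_response(plan, "delphinidin")

print(table[["dose", "serum_nM", "biomarker", "treated_value",
             "percent_change"]].to_string(index=False,
                                          float_format=lambda v: f"{v:10.2f}"))
print("\nMonotone in dose per biomarker:", table.attrs["monotone"])
print("Negative percent = less ROS; positive = more antioxidant enzyme.")
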