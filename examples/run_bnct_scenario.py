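"""Run one complete BNCT scenario and print its regional survival fractions.

Chains infiltration field → boron map → 4-run surrogate dose ensemble →
RBE weighting and 73.4 RBE-Gy prescription calibration → heterogeneous
linear-quadratic survival → regional survival fractions with run-to-run
uncertainties, on a reduced-resolution grid.
"""

from bnctsim import ScenarioConfig, run_scenario

config = ScenarioConfig(modality="bnct", ctv_margin_cm=2.0, master_seed=1)
result = run_scenario(config)

print(f"scenario: {result.report['scenario']}")
print(f"dose calibration scale applied: {result.calibration_scale:.3f}")
for key, entry in result.report["sf_percent"].items():
    print(f"  {key:16s} {entry['mean']:.4f} +/- {entry['sd']:.4f} %")
print(
    "Survival fractions are percentages of the initial tumour burden "
    "(sum of MEP over the grid) surviving in each region; +/- is the "
    "1-sigma spread over the 4 independent dose-noise runs."
)
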