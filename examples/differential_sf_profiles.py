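"""Compare the radial survival signatures of BNCT and X-ray EBRT.

Computes the differential survival fraction (per 0.5 mm shell about the
tumour centre) for both modalities on identical geometry.  BNCT survival
rises towards the field edge as boron concentration falls; EBRT with a
hypoxic core and GTV boost instead peaks inside the GTV.
"""

import dataclasses

from bnctsim import ScenarioConfig, run_scenario
from bnctsim.config import BNCTDoseConfig, EBRTConfig, GridConfig, RadiosensitivityConfig

base = ScenarioConfig(
    master_seed=1,
    grid=GridConfig(n_x=181, n_y=181, cell_size_um=500.0),
    bnct_dose=BNCTDoseConfig(noise_rel=0.0, n_runs=2),
    ebrt=EBRTConfig(noise_rel=0.0, n_runs=2),
    # homogeneous radiosensitivity isolates the dose-driven radial pattern
    radiosensitivity=RadiosensitivityConfig(alpha_sd=0.0, beta_sd=0.0),
)

for modality in ("bnct", "ebrt"):
    res = run_scenario(dataclasses.replace(base, modality=modality))
    table = res.sf_report.differential
    print(f"\n{modality.upper()} differential SF (selected shells):")
    for shell in (0, 4, 10, 20, 40, 49, 54):
        row = table.iloc[shell]
        sf = row["sf_percent"]
        label = f"{sf:.3e} %" if sf == sf else "undefined"
        print(f"  shell {shell:3d}  r = {row['r_centre_mm']:5.2f} mm  SF = {label}")
print(
    "\nBNCT survival grows monotonically with distance inside the beam "
    "(r <= 25 mm); EBRT survival is highest in the central (hypoxic, "
    "boosted) shell, then plateaus low until the penumbra (r > 25 mm)."
)
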