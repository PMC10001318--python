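"""Build an infiltration probability field and its boron biodistribution.

Constructs the isotropic microscopic-extension-probability (MEP) field on
a reduced-resolution 9 cm slice and maps it to per-cell boron
concentration with the linear uptake model B = 32.5·MEP + 13 μg/g.
"""

import numpy as np

from bnctsim import boron_from_mep, build_grid, mep_circular, radial_distance_field

grid = build_grid(451, 451, 200.0)  # 9 cm slice, 0.2 mm cells
mep = mep_circular(grid, gtv_radius_mm=0.5, me_extent_mm=41.0)
boron = boron_from_mep(mep)
r = radial_distance_field(grid)

print(f"grid: {grid.n_x} x {grid.n_y} cells of {grid.cell_size_um:g} um")
print(f"boron in solid tumour (MEP=1): {boron.values.max():.1f} ug/g")
print(f"boron in normal brain (MEP=0): {boron.values.min():.1f} ug/g")
print(f"tumour-to-normal uptake ratio: {boron.values.max() / boron.values.min():.2f}")
for dist in (0.0, 5.0, 10.0, 20.0, 41.5):
    i, j = np.unravel_index(np.argmin(np.abs(r - dist)), r.shape)
    print(
        f"  r = {dist:5.1f} mm  MEP = {mep.values[i, j]:.4f}  "
        f"B = {boron.values[i, j]:.2f} ug/g"
    )
print(
    "MEP is the probability that a cell is a tumour clonogen; boron uptake "
    "falls with it from 45.5 to the 13 ug/g brain baseline."
)
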