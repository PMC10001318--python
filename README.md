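# bnctsim

Cell-level treatment modelling of boron neutron capture therapy (BNCT)
versus fractionated X-ray external-beam radiotherapy (EBRT) for
diffusely infiltrating glioblastoma (GBM).

GBM infiltrates centimetres beyond its visible gross tumour volume
(GTV), so the choice of clinical target volume (CTV) margin trades
tumour control against normal-brain toxicity. `bnctsim` models a 2-D
slice of cells through the tumour and asks, per cell, what fraction of
the clonogenic population survives a treatment — and how much is gained
by widening the CTV margin from 2.0 to 2.5 cm — for three infiltration
geometries (circular, elliptical, irregular) and both modalities.

The package is a library: import it from Python, or use the thin
`bnctsim` CLI for the two end-to-end workflows. Short narrative scripts
live in `examples/`.

## Model

Every cell `ij` on the slice carries:

- **MEP_ij** — the microscopic extension probability, i.e. the
  probability that the cell is a tumour clonogen: 1 inside the GTV
  (1 mm diameter disc), decaying exponentially with distance, 0 beyond
  the 4.1 cm infiltration boundary.
- **B_ij = 32.5·MEP_ij + 13** — ¹⁰B concentration in μg/g: 45.5 in
  solid tumour, 13 in normal brain (a 3.5 : 1 uptake ratio).
- Four surrogate physical dose components (alpha, ⁷Li, gamma, residual
  neutron): the boron-capture components are proportional to
  B_ij × a lateral thermal-fluence profile; gamma and neutron doses
  follow broader boron-independent profiles; per-cell multiplicative
  noise emulates Monte Carlo scoring statistics across independent runs.
- An RBE-weighted biological dose
  `d = w_B·(D_α + D_Li) + w_γ·D_γ + w_n·D_n`, calibrated so the maximum
  tumour dose equals the single-fraction prescription of 73.4 RBE-Gy.
- Per-cell linear-quadratic radiosensitivity (α_ij, β_ij) drawn from
  truncated Gaussians (tumour heterogeneity).

Survival per cell is `SP_ij = MEP_ij · exp(−(α_ij d_ij + β_ij d_ij²))`
for single-fraction BNCT, and
`SP_ij = MEP_ij · exp(−n_ij (α_ij d_eff + β_ij d_eff²))` for EBRT with
30 × 2 Gy to the PTV, a 10 Gy GTV boost, and `d_eff` the per-fraction
dose divided by the local oxygen enhancement ratio (OER; 1 for the
high-LET BNCT products, up to 3 in the hypoxic EBRT tumour core).

Survival fractions (SF) are sums of SP over a region divided by the
initial tumour burden ΣMEP, reported per region (in-beam, 5 mm
penumbra, out-of-field, total) and per 0.5 mm radial shell
(differential SF). The margin statistic is
`SFchange = 100·(SF_2.0cm − SF_2.5cm)/SF_2.0cm`, with its expectation
and SD from 10 uniform Monte Carlo draws over the range of per-run
values, and a Welch t-test comparing modalities.

The dosimetry is an explicit surrogate for neutron transport: spatial
patterns and analytics are faithful, absolute SF values are not claimed
to match any transport calculation.

## Worked example

```python
from bnctsim import ScenarioConfig, run_scenario

config = ScenarioConfig(modality="bnct", ctv_margin_cm=2.0, master_seed=1)
result = run_scenario(config)
for key, entry in result.report["sf_percent"].items():
    print(f"{key:16s} {entry['mean']:.4f} +/- {entry['sd']:.4f} %")
```

prints

```
sf_in_beam       0.0012 +/- 0.0000 %
sf_penumbra      0.0162 +/- 0.0000 %
sf_out_of_field  0.2769 +/- 0.0000 %
sf_total         0.2943 +/- 0.0000 %
```

i.e. on the default reduced-resolution grid (450 × 450 cells of 200 μm)
about 0.29 % of the initial tumour burden survives the calibrated BNCT
treatment, almost all of it outside the irradiated field where
infiltrating cells receive no dose; ± is the 1σ spread over the 4
independent dose-noise runs. `examples/margin_study.py` extends this to
the full 3-geometry × 2-modality margin comparison (SFchange 64–77 %
with the default surrogate dosimetry), and
`examples/differential_sf_profiles.py` shows the opposing radial
survival signatures of the two modalities.

The same workflows from the shell:

```sh
bnctsim scenario --modality bnct --mep-model circular --seed 1 --outdir out/
bnctsim margin-study --modality ebrt --seed 1
```

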