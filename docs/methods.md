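# Methods

## Geometry

The model is two-dimensional: a square slice of side 9 cm through the
tumour centre, at the approximate depth of dose maximum (2 cm, metadata
only — no depth-dose curve is applied). Cells are square; at full
resolution the side is 20 μm, matching the slice thickness. All
analyses here and in the tests run on reduced-resolution grids
(typically 200–1000 μm cells) with the same physical extent; every
operation is resolution-configurable.

The tumour centre sits at the geometric grid centre, distances are
measured between cell centres in millimetres, and a cell belongs to a
circular region iff its centre does (no partial-area weighting).
Regions: GTV disc of radius 0.5 mm (the in-slice section of the 1 mm
diameter gross tumour — we take the equatorial disc); microscopic
extension (ME) annulus reaching 41 mm beyond the GTV surface; the
in-beam disc (beam radius 25 mm for the 2.0 cm CTV margin, 30 mm for
2.5 cm); a 5 mm penumbra annulus outside the beam; out-of-field is the
remainder. "Spherical shells" of the differential analysis are realised
as concentric 0.5 mm annuli in the slice, indexed floor(r/width).

## Infiltration (MEP) fields

The per-cell tumour probability uses a parameterised exponential
surrogate profile

    MEP(r) = 1                          r ≤ r_GTV
           = e^{−λ (r − r_GTV)}         otherwise, tapered linearly to
                                        0 over the last 0.5 mm before
                                        the ME boundary

with λ = ln(100)/20 mm⁻¹ by default, so MEP ≈ 0.01 at the 2.0 cm CTV
radius. The taper keeps the field continuous at the boundary. The
published infiltration histograms this family stands in for are not
reproduced numerically; the profile is declared a configurable
surrogate.

Anisotropy: the *elliptical* model evaluates the same profile on an
effective radius after rotating into the ellipse frame and scaling the
axes by √ratio and 1/√ratio (area-preserving; exactly circular at
ratio 1 — the rotation is skipped in that case so the reduction is
bit-exact). The *irregular* model modulates the radial extent by a
low-order cosine series in angle, m(θ) = 1 + A·Σ c_k cos(kθ+φ_k) with
c_k ∝ 1/k normalised to Σ|c_k| = 1, phases drawn once from the seed;
A ∈ [0, 1) bounds m away from zero and A = 0 reduces exactly to the
circular model. Defaults: axis ratio 2, four lobes, A = 0.3 — chosen as
visibly anisotropic while keeping the ME region inside the slice.

Boron: B = 32.5·MEP + 13 μg/g grid-wide (normal brain retains the
13 μg/g baseline), i.e. 45.5 μg/g in solid tumour, a 3.5 : 1
tumour-to-normal ratio.

## Surrogate dosimetry

Neutron/photon transport is replaced by a separable model. The lateral
fluence surrogate is ½·erfc((r − R)/(√2 σ)): ≈1 on axis, 0.5 at the
field edge, →0 outside, with per-component penumbra widths (defaults:
thermal 3 mm; gamma 6 mm; neutron 8 mm — scattered components spread
further). Boron-capture components are proportional to local boron times
the thermal profile, with the alpha : ⁷Li dose ratio fixed at the
emission-energy ratio 1.77/1.01; gamma and residual-neutron components
are boron-independent with on-axis magnitudes 2 and 1 Gy. These
magnitudes are arbitrary surrogates: the prescription calibration
removes the overall scale, and only the *relative* spatial shapes
influence the survival patterns. Monte Carlo scoring statistics are
emulated by independent per-cell multiplicative noise (1 + ε),
ε ~ N(0, σ_rel), σ_rel = 2 % by default, clipped so doses stay
non-negative. An ensemble (default 4 runs, ≥ 2 required) derives run
seeds from one base seed via `numpy.random.SeedSequence.spawn`.

EBRT: per-fraction dose = 2 Gy × the same erfc profile (σ = 3 mm), 30
fractions to the PTV; the 10 Gy GTV boost is delivered as 5 additional
2 Gy fractions (the boost fractionation is a model choice, configurable)
so boosted cells accumulate 35 LQ fraction terms.

## Radiobiology

Biological dose d = w_B(D_α + D_Li) + w_γ D_γ + w_n D_n. The weights
are configuration inputs with surrogate defaults w_γ = 1.0, w_n = 3.2,
w_B = 1.35 (literature-typical normal-tissue-type values; clinical
protocols use compound- and tissue-specific factors). Fast and thermal
neutron doses share one weight and are carried combined. The field is
then scaled by s = 73.4 / max over tumour cells (MEP > 0) of the
*ensemble-mean* dose; the same s is applied to every run so per-run
noise cannot shift the prescription between runs. Calibration is
idempotent by construction.

Radiosensitivity heterogeneity: per-cell i.i.d. (α, β) from Gaussians
truncated by rejection resampling at α > 0, β ≥ 0. β is sampled
independently of α. The defaults α = 0.25 ± 0.10 Gy⁻¹,
β = 0.025 ± 0.010 Gy⁻² (α/β = 10 Gy) are surrogate glioma-typical
values; the in-vitro cell-line distribution they stand in for is not
published numerically, so any quantitative use should set these from
data. Zero SDs give the homogeneous-tumour scenario.

OER: applied as a dose divisor (classic definition). BNCT mode is 1
everywhere (high-LET products). EBRT mode is a monotone Gaussian
profile 1 + (OER_max − 1)·exp(−(r/r_c)²) with OER_max = 3 and
r_c = 1 mm — a hypoxic core concentric with the (deliberately small)
GTV, approaching 1 in the periphery.

Survival: SP = MEP·exp(−(αd + βd²)) for single-fraction BNCT;
SP = MEP·exp(−n(α d_eff + β d_eff²)) for EBRT with per-cell fraction
count n and d_eff = fraction dose / OER. SP ≤ MEP everywhere, and
SP = MEP at zero dose.

## Survival-fraction analytics

Survivors in a region are ΣSP over its cells; the initial burden is
ΣMEP (expected counts, not thresholded). Regional SFs use the
grid-global denominator by default, which makes in-beam + penumbra +
out-of-field SFs exactly additive to the total; a per-region mode
exists for periphery-relative questions. Differential SFs use per-shell
denominators; shells with zero initial burden are reported as
undefined (NaN/null), never zero. Run statistics are mean ± sample SD
(ddof = 1) over ensemble runs.

SFchange = 100·(SF₂.₀ − SF₂.₅)/SF₂.₀ per matched run pair (the two
margin scenarios share dose-noise seeds, pairing the runs). Its
expectation and SD come from 10 uniform draws over [min, max] of the
per-run values — with identical per-run values the result is exactly
(value, 0). Modality comparison is a two-sided Welch t-test on those
draws; two degenerate zero-variance sample sets compare as p = 1 when
their means coincide.

## Orchestration and reproducibility

A scenario config (modality, infiltration model, CTV margin → beam
radius mapping {2.0 cm → 25 mm, 2.5 cm → 30 mm}, all stage parameters)
plus one master seed determines every output byte: stage seeds for the
infiltration phases, radiosensitivity sampling, the dose ensemble and
the SFchange draw are spawned deterministically from the master seed,
and reports are written as sorted-key JSON. Fields round-trip through
dense CSV with a one-line `# key=value;…` metadata header; masks use
integer coding (0 out, 1 beam, 2 penumbra).

## What the synthetic generator does and does not show

The generator reproduces the *structure* of transport-scored dosimetry:
four component matrices, boron-dose locality, in-beam plateau, lateral
penumbra falloff, and run-to-run statistical noise. It does not model
scatter physics, spectral thermalisation with depth, phantom-edge
effects, or realistic component magnitude ratios. Passing tests
therefore demonstrate the correctness of the geometry, biodistribution,
calibration, survival and analytics machinery, and the *direction* of
the modality contrasts (BNCT survival rising with radius inside the
beam as boron falls; EBRT survival peaking in the hypoxic boosted core;
positive SFchange from margin extension) — not absolute survival
levels, which depend on the surrogate dose shapes.

Qualitative pattern assertions run with noise-free dosimetry and
homogeneous radiosensitivity: per-shell strict monotonicity is a
property of the underlying dose gradient, and at reduced grid
resolution per-cell sampling noise in sparse shells would otherwise
dominate the shell means. Heterogeneous, noisy defaults are exercised
by the conservation, bound and margin-monotonicity tests.

## Numerical choices and degenerate inputs

- Distances and masks are exact functions of the cell-centre radial
  field; no area weighting, no tolerance fudging at region boundaries.
- The erfc profile is evaluated in double precision; no cutoffs.
- Noise clipping at −1 (factor 0) preserves non-negativity at large
  σ_rel at the cost of a slight positive bias there; at the 2 % default
  the bias is negligible (< 10⁻¹⁵ relative).
- Zero initial burden → explicit undefined-SF errors (regional) or NaN
  (shells); zero maximum tumour dose → calibration error; ensembles of
  fewer than two runs are rejected wherever spread is needed.
- A beam + penumbra larger than the grid warns (empty out-of-field is
  legitimate) rather than failing.

## Problem sizes

Defaults run the 450 × 450 grid (200 μm cells, 0.2 M cells) in well
under a second per scenario; the full 4500 × 4500 resolution (20 M
cells) is supported and linear in cell count. The test and example
suites use 90–181-cell grids with identical physical extent, chosen so
the complete margin-study matrix (3 infiltration models × 2 margins ×
2 modalities × 4 runs) stays essentially instantaneous.

## Known limitations

2-D slice scoring (underestimates survival relative to a 3-D tumour);
LQ validity at the large single BNCT fraction; no repopulation, repair
kinetics, immune or microenvironment effects; single boron RBE weight
(no compound-specific CBE, no tissue dependence); static boron
biodistribution (no pharmacokinetics); surrogate dose magnitudes as
discussed above.
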