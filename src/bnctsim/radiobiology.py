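"""RBE weighting, prescription calibration, radiosensitivity and cell survival.

Physical dose components become a single biological dose by weighting
each with its relative biological effectiveness (RBE):

    d = w_B·(D_alpha + D_Li) + w_γ·D_γ + w_n·D_n        (RBE-Gy)

The field is then calibrated so the maximum dose over tumour cells
equals the single-fraction BNCT prescription of 73.4 RBE-Gy.

Cell kill follows the linear-quadratic (LQ) model with per-cell
radiosensitivity (α, β) drawn from truncated Gaussians, representing the
genetic heterogeneity of glioma cell lines.  For the single-fraction
BNCT scheme,

    SP_ij = MEP_ij · exp(-(α_ij d_ij + β_ij d_ij²)),

so a cell's survival probability is bounded by its probability of being
a tumour cell at all.  The fractionated X-ray EBRT analogue repeats the
LQ exponent once per fraction with the per-fraction dose divided by the
local oxygen enhancement ratio (OER); for the high-LET BNCT products the
OER is 1 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .grid import ConfigurationError, GridSpec, radial_distance_field
from .dosimetry import DoseComponents, EBRTDoseField
from .mep import MEPField

__all__ = [
    "DEFAULT_PRESCRIPTION_RBE_GY",
    "RBEWeights",
    "BioDoseField",
    "RadiosensitivityField",
    "OERField",
    "SurvivalMap",
    "weight_components",
    "calibrate_prescription",
    "sample_radiosensitivity",
    "build_oer_field",
    "survival_bnct",
    "survival_ebrt",
]

#: single-fraction maximum tumour dose prescription (RBE-Gy)
DEFAULT_PRESCRIPTION_RBE_GY = 73.4


@dataclass(frozen=True)
class RBEWeights:
    """RBE factors per physical component.

    Defaults are literature-typical surrogates for normal-tissue-type
    weighting (the clinical protocol values are compound- and
    tissue-specific and must be configured for any quantitative use).
    Fast and thermal neutron doses share ``w_neutron``.
    """

    w_boron: float = 1.35
    w_gamma: float = 1.0
    w_neutron: float = 3.2

    def __post_init__(self) -> None:
        if min(self.w_boron, self.w_gamma, self.w_neutron) <= 0:
            raise ConfigurationError("all RBE weights must be positive")


@dataclass(frozen=True)
class BioDoseField:
    """Per-cell RBE-weighted dose (RBE-Gy)."""

    values: np.ndarray


@dataclass(frozen=True)
class RadiosensitivityField:
    """Per-cell LQ parameters α (Gy⁻¹) and β (Gy⁻²)."""

    alpha: np.ndarray
    beta: np.ndarray
    seed: Any = None
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    beta_mean: float = 0.0
    beta_sd: float = 0.0


@dataclass(frozen=True)
class OERField:
    """Per-cell oxygen enhancement ratio, ≥ 1 everywhere."""

    values: np.ndarray
    mode: str = "bnct"


@dataclass(frozen=True)
class SurvivalMap:
    """Per-cell survival probability, 0 ≤ SP_ij ≤ MEP_ij."""

    values: np.ndarray


def weight_components(components: DoseComponents, weights: RBEWeights | None = None,
                      grid: GridSpec | None = None) -> BioDoseField:
    """Combine physical components into RBE-weighted biological dose."""
    weights = weights or RBEWeights()
    shapes = {components.alpha.shape, components.li7.shape,
              components.gamma.shape, components.neutron_residual.shape}
    if len(shapes) != 1:
        raise ConfigurationError("dose component matrices are not on one grid")
    if grid is not None and components.alpha.shape != grid.shape:
        raise ConfigurationError("dose components do not match the grid")
    d = (
        weights.w_boron * (components.alpha + components.li7)
        + weights.w_gamma * components.gamma
        + weights.w_neutron * components.neutron_residual
    )
    return BioDoseField(values=d)


def calibrate_prescription(
    bio: BioDoseField,
    tumour_mask: np.ndarray,
    prescription_rbe_gy: float = DEFAULT_PRESCRIPTION_RBE_GY,
) -> tuple[float, BioDoseField]:
    """Scale the dose field so the maximum tumour dose equals the prescription.

    Returns ``(s, scaled_field)`` with ``s = prescription / max_tumour(d)``.
    For a run ensemble, calibrate on the ensemble-mean field and apply the
    same ``s`` to every run, so per-run noise does not shift the
    prescription scale between runs.
    """
    if not np.any(tumour_mask):
        raise ConfigurationError("tumour mask is empty")
    dmax = float(bio.values[tumour_mask].max())
    if dmax <= 0:
        raise ConfigurationError("maximum tumour dose is zero; cannot calibrate")
    s = prescription_rbe_gy / dmax
    return s, BioDoseField(values=bio.values * s)


def sample_radiosensitivity(
    grid: GridSpec,
    alpha_mean: float = 0.25,
    alpha_sd: float = 0.10,
    beta_mean: float = 0.025,
    beta_sd: float = 0.010,
    seed=None,
) -> RadiosensitivityField:
    """Draw per-cell (α, β) from truncated Gaussians.

    Truncation by rejection resampling enforces α > 0 and β ≥ 0.  Zero
    standard deviations reduce to the homogeneous-radiosensitivity model.
    The defaults are surrogate glioma-typical values (α/β = 10 Gy); they
    are configuration inputs, not measured cell-line parameters.
    """
    if alpha_mean <= 0 or beta_mean <= 0:
        raise ConfigurationError("alpha_mean and beta_mean must be positive")
    if alpha_sd < 0 or beta_sd < 0:
        raise ConfigurationError("standard deviations must be non-negative")

    rng = np.random.default_rng(seed)

    def _truncated(mean: float, sd: float, lower_open: bool) -> np.ndarray:
        if sd == 0.0:
            return np.full(grid.shape, mean)
        draws = rng.normal(mean, sd, size=grid.shape)
        bad = (draws <= 0.0) if lower_open else (draws < 0.0)
        while np.any(bad):
            draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = (draws <= 0.0) if lower_open else (draws < 0.0)
        return draws

    alpha = _truncated(alpha_mean, alpha_sd, lower_open=True)
    beta = _truncated(beta_mean, beta_sd, lower_open=False)
    return RadiosensitivityField(
        alpha=alpha, beta=beta, seed=seed,
        alpha_mean=alpha_mean, alpha_sd=alpha_sd,
        beta_mean=beta_mean, beta_sd=beta_sd,
    )


def build_oer_field(
    grid: GridSpec,
    mode: str = "bnct",
    oer_max: float = 3.0,
    core_radius_mm: float = 1.0,
) -> OERField:
    """Oxygen-enhancement-ratio field.

    BNCT mode returns 1 everywhere (high-LET products are insensitive to
    oxygen status).  EBRT mode models a hypoxic tumour core: a Gaussian
    radial profile with ``oer_max`` at the centre decaying monotonically
    towards 1 at the infiltration periphery, with ``core_radius_mm`` the
    e-folding length scale of the hypoxic core.
    """
    if oer_max < 1.0:
        raise ConfigurationError("oer_max must be >= 1")
    if mode == "bnct":
        return OERField(values=np.ones(grid.shape), mode="bnct")
    if mode != "ebrt":
        raise ConfigurationError(f"unknown OER mode {mode!r}")
    if core_radius_mm <= 0:
        raise ConfigurationError("core_radius_mm must be positive")
    r = radial_distance_field(grid)
    values = 1.0 + (oer_max - 1.0) * np.exp(-((r / core_radius_mm) ** 2))
    return OERField(values=values, mode="ebrt")


def _check_same_grid(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ConfigurationError("fields are not on one grid")


def survival_bnct(
    mep: MEPField, bio: BioDoseField, rs: RadiosensitivityField
) -> SurvivalMap:
    """Single-fraction LQ survival, SP = MEP · exp(-(α d + β d²))."""
    _check_same_grid(mep.values, bio.values, rs.alpha, rs.beta)
    d = bio.values
    if np.any(d < 0):
        raise ConfigurationError("negative dose encountered")
    sp = mep.values * np.exp(-(rs.alpha * d + rs.beta * d * d))
    return SurvivalMap(values=sp)


def survival_ebrt(
    mep: MEPField,
    ebrt: EBRTDoseField,
    rs: RadiosensitivityField,
    oer: OERField,
) -> SurvivalMap:
    """Fractionated LQ survival with oxygen modification.

    The effective per-fraction dose is the physical fraction dose divided
    by the local OER; the LQ exponent accumulates over the per-cell
    fraction count (PTV fractions everywhere plus boost fractions inside
    the GTV): SP = MEP · exp(-n·(α d_eff + β d_eff²)).
    """
    _check_same_grid(mep.values, ebrt.fraction_dose, rs.alpha, rs.beta, oer.values)
    if np.any(ebrt.fraction_dose < 0):
        raise ConfigurationError("negative dose encountered")
    d_eff = ebrt.fraction_dose / oer.values
    exponent = ebrt.n_fractions * (rs.alpha * d_eff + rs.beta * d_eff * d_eff)
    sp = mep.values * np.exp(-exponent)
    return SurvivalMap(values=sp)
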