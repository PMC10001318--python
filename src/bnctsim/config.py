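"""Scenario configuration: dataclasses, YAML round-trip and seed derivation.

A :class:`ScenarioConfig` fully determines one treatment simulation:
modality (BNCT or X-ray EBRT), infiltration model, CTV margin (which
fixes the beam radius: 2.0 cm margin → 2.5 cm beam, 2.5 cm → 3.0 cm),
the grid resolution and all model parameters.  Every stochastic stage
(infiltration phases, radiosensitivity sampling, dose noise, SFchange
resampling) derives its seed deterministically from ``master_seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .grid import ConfigurationError
from .mep import DEFAULT_BORON_INTERCEPT, DEFAULT_BORON_SLOPE, DEFAULT_DECAY_PER_MM
from .radiobiology import DEFAULT_PRESCRIPTION_RBE_GY

__all__ = [
    "CTV_MARGIN_TO_BEAM_RADIUS_MM",
    "GridConfig",
    "GeometryConfig",
    "MEPConfig",
    "BoronConfig",
    "BNCTDoseConfig",
    "EBRTConfig",
    "RBEConfig",
    "RadiosensitivityConfig",
    "OERConfig",
    "ScenarioConfig",
    "load_config",
    "save_config",
]

#: fixed mapping from CTV margin (cm) to conical beam radius (mm)
CTV_MARGIN_TO_BEAM_RADIUS_MM: dict[float, float] = {2.0: 25.0, 2.5: 30.0}


@dataclass(frozen=True)
class GridConfig:
    # default: reduced-resolution grid with the full 9 cm x 9 cm extent
    n_x: int = 450
    n_y: int = 450
    cell_size_um: float = 200.0
    slice_depth_cm: float = 2.0


@dataclass(frozen=True)
class GeometryConfig:
    gtv_radius_mm: float = 0.5
    me_extent_mm: float = 41.0
    penumbra_width_mm: float = 5.0


@dataclass(frozen=True)
class MEPConfig:
    model: str = "circular"  # circular | elliptical | irregular
    decay: float = DEFAULT_DECAY_PER_MM
    axis_ratio: float = 2.0
    orientation_deg: float = 0.0
    n_lobes: int = 4
    amplitude: float = 0.3


@dataclass(frozen=True)
class BoronConfig:
    slope: float = DEFAULT_BORON_SLOPE
    intercept: float = DEFAULT_BORON_INTERCEPT


@dataclass(frozen=True)
class BNCTDoseConfig:
    k_alpha_gy_per_ugg: float = 0.1
    gamma_dose_gy: float = 2.0
    neutron_dose_gy: float = 1.0
    thermal_sigma_mm: float = 3.0
    gamma_sigma_mm: float = 6.0
    neutron_sigma_mm: float = 8.0
    noise_rel: float = 0.02
    n_runs: int = 4


@dataclass(frozen=True)
class EBRTConfig:
    fraction_dose_gy: float = 2.0
    n_fractions: int = 30
    boost_gy: float = 10.0
    boost_fraction_gy: float = 2.0
    penumbra_sigma_mm: float = 3.0
    noise_rel: float = 0.02
    n_runs: int = 4


@dataclass(frozen=True)
class RBEConfig:
    w_boron: float = 1.35
    w_gamma: float = 1.0
    w_neutron: float = 3.2


@dataclass(frozen=True)
class RadiosensitivityConfig:
    alpha_mean: float = 0.25
    alpha_sd: float = 0.10
    beta_mean: float = 0.025
    beta_sd: float = 0.010


@dataclass(frozen=True)
class OERConfig:
    oer_max: float = 3.0
    core_radius_mm: float = 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete, reproducible description of one treatment scenario."""

    modality: str = "bnct"  # bnct | ebrt
    ctv_margin_cm: float = 2.0
    master_seed: int = 0
    shell_width_mm: float = 0.5
    prescription_rbe_gy: float = DEFAULT_PRESCRIPTION_RBE_GY
    grid: GridConfig = field(default_factory=GridConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    mep: MEPConfig = field(default_factory=MEPConfig)
    boron: BoronConfig = field(default_factory=BoronConfig)
    bnct_dose: BNCTDoseConfig = field(default_factory=BNCTDoseConfig)
    ebrt: EBRTConfig = field(default_factory=EBRTConfig)
    rbe: RBEConfig = field(default_factory=RBEConfig)
    radiosensitivity: RadiosensitivityConfig = field(default_factory=RadiosensitivityConfig)
    oer: OERConfig = field(default_factory=OERConfig)

    def __post_init__(self) -> None:
        if self.modality not in ("bnct", "ebrt"):
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if self.ctv_margin_cm not in CTV_MARGIN_TO_BEAM_RADIUS_MM:
            raise ConfigurationError(
                f"ctv_margin_cm must be one of {sorted(CTV_MARGIN_TO_BEAM_RADIUS_MM)}, "
                f"got {self.ctv_margin_cm}"
            )
        if self.mep.model not in ("circular", "elliptical", "irregular"):
            raise ConfigurationError(f"unknown MEP model {self.mep.model!r}")

    @property
    def beam_radius_mm(self) -> float:
        return CTV_MARGIN_TO_BEAM_RADIUS_MM[self.ctv_margin_cm]

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed.

        The dose-ensemble seed is shared between CTV margins of one
        margin study (the configs differ only in margin), pairing the
        per-run noise realisations across margins.
        """
        children = np.random.SeedSequence(self.master_seed).spawn(4)
        names = ("mep", "radiosensitivity", "dose_ensemble", "sfchange_mc")
        return {
            name: int(child.generate_state(1, dtype=np.uint32)[0])
            for name, child in zip(names, children)
        }

    def with_margin(self, ctv_margin_cm: float) -> "ScenarioConfig":
        return replace(self, ctv_margin_cm=ctv_margin_cm)

    def to_dict(self) -> dict:
        return asdict(self)


def _from_dict(data: dict) -> ScenarioConfig:
    kwargs = dict(data)
    for key, cls in (
        ("grid", GridConfig),
        ("geometry", GeometryConfig),
        ("mep", MEPConfig),
        ("boron", BoronConfig),
        ("bnct_dose", BNCTDoseConfig),
        ("ebrt", EBRTConfig),
        ("rbe", RBEConfig),
        ("radiosensitivity", RadiosensitivityConfig),
        ("oer", OERConfig),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    return ScenarioConfig(**kwargs)


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a scenario configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(data)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario configuration to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
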