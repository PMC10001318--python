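"""Cellular lattice, distance fields and region-of-interest masks.

The dose-scoring geometry is a two-dimensional slice of square cells
(default 20 μm, matching the slice thickness) centred on the tumour.
The gross tumour volume (GTV), the microscopic-extension (ME) region,
the irradiated field, the penumbra and concentric radial shells are all
realised as boolean / integer masks on this lattice.  All distances are
held in millimetres internally; cell sizes are configured in micrometres.

A cell belongs to a circular region iff its *centre* does — this
cell-centre membership rule avoids partial-area ambiguity and makes every
mask an exact function of the radial distance field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfigurationError",
    "GridSpec",
    "RegionMasks",
    "ShellDecomposition",
    "build_grid",
    "radial_distance_field",
    "make_roi_masks",
    "shell_decomposition",
]

UM_PER_MM = 1000.0


class ConfigurationError(ValueError):
    """Invalid geometry or model configuration."""


@dataclass(frozen=True)
class GridSpec:
    """A 2-D lattice of square cells with the tumour centre at its middle.

    Parameters
    ----------
    n_x, n_y:
        Number of cells along each axis (≥ 1).
    cell_size_um:
        Cell side length in micrometres (> 0).
    slice_depth_cm:
        Depth of the scoring slice below the phantom surface.  Metadata
        only — the model is two-dimensional and sits at the depth of dose
        maximum, so no depth-dose curve is applied.
    """

    n_x: int
    n_y: int
    cell_size_um: float
    slice_depth_cm: float = 2.0

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ConfigurationError(
                f"grid dimensions must be >= 1, got {self.n_x} x {self.n_y}"
            )
        if self.cell_size_um <= 0:
            raise ConfigurationError(
                f"cell size must be positive, got {self.cell_size_um} um"
            )

    @property
    def cell_size_mm(self) -> float:
        return self.cell_size_um / UM_PER_MM

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape (rows, columns) = (n_y, n_x)."""
        return (self.n_y, self.n_x)

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical extent (x, y) of the slice in mm."""
        return (self.n_x * self.cell_size_mm, self.n_y * self.cell_size_mm)

    def cell_centres_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinates ``(x, y)`` in mm relative to the tumour centre.

        The tumour centre sits at the geometric centre of the slice, so for
        an even cell count no cell centre lies exactly at the origin.
        """
        cs = self.cell_size_mm
        x = (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * cs
        y = (np.arange(self.n_y) - (self.n_y - 1) / 2.0) * cs
        return np.meshgrid(x, y)


def build_grid(
    n_x: int, n_y: int, cell_size_um: float, slice_depth_cm: float = 2.0
) -> GridSpec:
    """Create a :class:`GridSpec` with the tumour centre at the grid centre."""
    return GridSpec(n_x=n_x, n_y=n_y, cell_size_um=cell_size_um,
                    slice_depth_cm=slice_depth_cm)


def radial_distance_field(grid: GridSpec) -> np.ndarray:
    """Euclidean distance (mm) from the tumour centre to every cell centre."""
    x, y = grid.cell_centres_mm()
    return np.hypot(x, y)


@dataclass(frozen=True)
class RegionMasks:
    """Boolean region-of-interest masks on one grid.

    ``in_beam``, ``penumbra`` and ``out_of_field`` are pairwise disjoint and
    together cover the grid.  ``gtv`` is the gross-tumour disc and
    ``me_region`` the surrounding microscopic-extension annulus.
    """

    gtv: np.ndarray
    me_region: np.ndarray
    in_beam: np.ndarray
    penumbra: np.ndarray
    out_of_field: np.ndarray
    gtv_radius_mm: float
    me_extent_mm: float
    beam_radius_mm: float
    penumbra_width_mm: float


def make_roi_masks(
    grid: GridSpec,
    gtv_radius_mm: float = 0.5,
    me_extent_mm: float = 41.0,
    beam_radius_mm: float = 25.0,
    penumbra_width_mm: float = 5.0,
) -> RegionMasks:
    """Build GTV / ME / beam / penumbra / out-of-field masks.

    ``in_beam`` is the disc r ≤ beam radius (the PTV footprint on the
    slice), ``penumbra`` the annulus of the configured width just outside
    it, ``out_of_field`` the remainder.  The ME region is the annulus
    extending ``me_extent_mm`` beyond the GTV surface.
    """
    if gtv_radius_mm <= 0:
        raise ConfigurationError("gtv_radius_mm must be positive")
    if me_extent_mm <= gtv_radius_mm:
        raise ConfigurationError("me_extent_mm must exceed gtv_radius_mm")
    if beam_radius_mm <= 0 or penumbra_width_mm <= 0:
        raise ConfigurationError("beam radius and penumbra width must be positive")

    r = radial_distance_field(grid)
    half_extent = min(grid.extent_mm) / 2.0
    if beam_radius_mm + penumbra_width_mm > half_extent:
        warnings.warn(
            "beam + penumbra extends beyond the grid; out-of-field region "
            "may be empty",
            stacklevel=2,
        )

    in_beam = r <= beam_radius_mm
    penumbra = (r > beam_radius_mm) & (r <= beam_radius_mm + penumbra_width_mm)
    out_of_field = ~(in_beam | penumbra)
    gtv = r <= gtv_radius_mm
    me_region = (r > gtv_radius_mm) & (r <= gtv_radius_mm + me_extent_mm)
    return RegionMasks(
        gtv=gtv,
        me_region=me_region,
        in_beam=in_beam,
        penumbra=penumbra,
        out_of_field=out_of_field,
        gtv_radius_mm=gtv_radius_mm,
        me_extent_mm=me_extent_mm,
        beam_radius_mm=beam_radius_mm,
        penumbra_width_mm=penumbra_width_mm,
    )


@dataclass(frozen=True)
class ShellDecomposition:
    """Concentric annular shells about the tumour centre.

    ``shell_index`` labels every cell with floor(r / shell_width); labels
    are contiguous from 0 and every cell belongs to exactly one shell.
    """

    shell_width_mm: float
    shell_index: np.ndarray
    shell_radii_mm: np.ndarray  # outer radius of each shell

    @property
    def n_shells(self) -> int:
        return len(self.shell_radii_mm)

    def shell_centres_mm(self) -> np.ndarray:
        return self.shell_radii_mm - self.shell_width_mm / 2.0


def shell_decomposition(grid: GridSpec, shell_width_mm: float = 0.5) -> ShellDecomposition:
    """Decompose the grid into concentric annuli of the given width."""
    if shell_width_mm <= 0:
        raise ConfigurationError("shell_width_mm must be positive")
    r = radial_distance_field(grid)
    index = np.floor(r / shell_width_mm).astype(np.int64)
    n_shells = int(index.max()) + 1
    outer = (np.arange(n_shells) + 1) * shell_width_mm
    return ShellDecomposition(
        shell_width_mm=shell_width_mm, shell_index=index, shell_radii_mm=outer
    )
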