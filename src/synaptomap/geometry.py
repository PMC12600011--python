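"""Physical voxel geometry of an aligned serial-section volume.

Serial-section single-molecule localization stacks are strongly anisotropic:
the lateral voxel pitch is set by the rendering of localization data
(15.5 nm by default) while the axial pitch is the physical section thickness
(70 nm by default).  Every distance, radius and Gaussian sigma in this
package is specified in nanometres and converted per axis, so the same
configuration applies to any voxel pitch.

Internally all arrays are indexed ``(z, y, x)`` and all internal coordinate
arrays are ``(z, y, x)`` in nanometres; the user-facing ``shape`` argument
keeps the conventional ``(nx, ny, nz)`` order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImagingGeometry"]


@dataclass(frozen=True)
class ImagingGeometry:
    """Voxel geometry of an aligned multi-channel volume.

    Parameters
    ----------
    voxel_xy : float
        Lateral voxel pitch in nm (> 0).
    voxel_z : float
        Section thickness in nm (> 0).
    shape : tuple of int
        Voxel counts ``(nx, ny, nz)``; every entry >= 1.
    bit_depth : int
        Intensity quantization; 8 for the rendered stacks used here.
    """

    voxel_xy: float = 15.5
    voxel_z: float = 70.0
    shape: tuple[int, int, int] = (256, 256, 32)
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError("shape must be three entries, all >= 1")
        if self.bit_depth < 1 or self.bit_depth > 16:
            raise ValueError("bit_depth out of range")

    # ---- derived quantities -------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Array shape ``(nz, ny, nx)``."""
        nx, ny, nz = self.shape
        return (int(nz), int(ny), int(nx))

    @property
    def spacing_nm(self) -> tuple[float, float, float]:
        """Per-axis voxel pitch ``(z, y, x)`` in nm."""
        return (self.voxel_z, self.voxel_xy, self.voxel_xy)

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in cubic micrometres."""
        return self.voxel_xy * self.voxel_xy * self.voxel_z * 1e-9

    @property
    def physical_size_nm(self) -> tuple[float, float, float]:
        """Extent ``(z, y, x)`` of the volume in nm."""
        nz, ny, nx = self.grid_shape
        return (nz * self.voxel_z, ny * self.voxel_xy, nx * self.voxel_xy)

    @property
    def volume_um3(self) -> float:
        """Total physical volume in cubic micrometres."""
        nz, ny, nx = self.grid_shape
        return nz * ny * nx * self.voxel_volume_um3

    @property
    def intensity_max(self) -> int:
        return (1 << self.bit_depth) - 1

    # ---- coordinate transforms ---------------------------------------------

    def voxel_to_nm(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices ``(..., 3)`` (z, y, x) to voxel-centre nm coords."""
        idx = np.asarray(idx, dtype=float)
        return (idx + 0.5) * np.asarray(self.spacing_nm)

    def nm_to_voxel(self, pos_nm: np.ndarray) -> np.ndarray:
        """Map nm coordinates (z, y, x) to (floating) voxel indices."""
        pos_nm = np.asarray(pos_nm, dtype=float)
        return pos_nm / np.asarray(self.spacing_nm) - 0.5

    def sigma_to_voxels(self, sigma_nm: float) -> tuple[float, float, float]:
        """Convert an isotropic physical sigma to per-axis voxel sigmas."""
        return (
            sigma_nm / self.voxel_z,
            sigma_nm / self.voxel_xy,
            sigma_nm / self.voxel_xy,
        )
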