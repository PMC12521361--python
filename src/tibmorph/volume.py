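"""Core in-memory container for micro-CT image volumes.

The axis convention used throughout the package is ``(z, y, x)`` with the
z index increasing from proximal (index 0) to distal, ``y`` running
anterior→posterior and ``x`` medial→lateral.  The physical z position of
slice ``i`` is ``i * voxel_size_mm`` (isotropic voxels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageVolume:
    """A 3D grayscale volume with isotropic voxel size.

    Parameters
    ----------
    intensities
        ``(nz, ny, nx)`` array of raw intensities (no rescaling applied).
    voxel_size_mm
        Isotropic voxel edge length in millimetres (must be > 0).
    """

    intensities: np.ndarray
    voxel_size_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"expected a 3D array, got shape {self.intensities.shape}"
            )
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be > 0")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def z_mm(self, index: int | np.ndarray) -> float | np.ndarray:
        """Physical z position (mm) of a slice index; z=0 is the proximal end."""
        return np.asarray(index) * self.voxel_size_mm

    @property
    def z_extent_mm(self) -> float:
        """Total length of the volume along z in mm."""
        return self.n_slices * self.voxel_size_mm
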