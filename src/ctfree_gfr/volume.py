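"""Core in-memory containers for 3D volumetric images.

All arrays are ordered ``(z, y, x)`` = (axial, anterior-posterior, left-right)
with patient-left at +x; anterior is the low-``y`` face.  Voxel spacing is
carried in millimetres.  NIfTI orientation handling lives in :mod:`ctfree_gfr.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume3D", "LabelMap", "BACKGROUND", "RIGHT_KIDNEY", "LEFT_KIDNEY"]

#: Integer class encoding used throughout: 0 background, 1 right kidney, 2 left kidney.
BACKGROUND = 0
RIGHT_KIDNEY = 1
LEFT_KIDNEY = 2


@dataclass
class Volume3D:
    """A 3D scalar field with isotropic-or-not voxel spacing in mm.

    Parameters
    ----------
    data:
        3D array ordered (z, y, x).
    spacing_mm:
        Per-axis voxel edge length in mm, same axis order as ``data``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (3.45, 3.45, 3.45)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D array, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing_mm
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def require_isotropic(self) -> float:
        """Return the isotropic spacing in mm, or raise for anisotropic volumes."""
        if not self.is_isotropic:
            raise ValueError(
                f"operation requires isotropic voxels, got spacing {self.spacing_mm} mm"
            )
        return self.spacing_mm[0]

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume sharing this volume's spacing."""
        return type(self)(data=data, spacing_mm=self.spacing_mm)

    def copy(self) -> "Volume3D":
        return type(self)(data=self.data.copy(), spacing_mm=self.spacing_mm)

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm, atol=atol
        )


@dataclass
class LabelMap(Volume3D):
    """Integer class map: 0 background, 1 right kidney, 2 left kidney."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("LabelMap requires integer class values")
            self.data = rounded.astype(np.int16)

    def class_mask(self, class_id: int) -> np.ndarray:
        return self.data == class_id

    def class_count(self, class_id: int) -> int:
        return int(np.count_nonzero(self.data == class_id))

    def class_volume_ml(self, class_id: int) -> float:
        return self.class_count(class_id) * self.voxel_volume_ml

    def present_classes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.data))
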