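"""Basic volumetric containers.

A :class:`ScalarVolume` is a 3D intensity grid ``I(y)`` over the voxel domain
together with its physical metadata (voxel spacing and origin in mm).  All
level-set machinery works in voxel units; spacing is only consumed by the
surface-distance metrics and by the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScalarVolume:
    """3D scalar image with physical metadata.

    Parameters
    ----------
    data:
        3D array of intensities (HU-like units for CT).
    spacing:
        Voxel spacing in mm per axis, all positive.
    origin:
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.spacing, self.origin)


def as_volume(obj, spacing=(1.0, 1.0, 1.0)) -> ScalarVolume:
    """Coerce a bare array into a :class:`ScalarVolume` (identity on volumes)."""
    if isinstance(obj, ScalarVolume):
        return obj
    return ScalarVolume(np.asarray(obj, dtype=np.float64), spacing)
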