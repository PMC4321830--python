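"""Core voxel-grid containers shared across the pipeline.

All volumes live on a regular 3-D lattice with physical voxel dimensions in
millimetres.  Distances are always measured between voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_CSF",
    "LABEL_NAWM",
    "LABEL_WMH",
    "LABEL_STROKE",
    "TISSUE_LABELS",
    "VolumeGrid",
    "LabelVolume",
    "GridMismatchError",
    "as_binary_mask",
]

LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_NAWM = 2
LABEL_WMH = 3
LABEL_STROKE = 4

#: label value -> canonical tissue name
TISSUE_LABELS = {
    LABEL_BACKGROUND: "background",
    LABEL_CSF: "csf",
    LABEL_NAWM: "nawm",
    LABEL_WMH: "wmh",
    LABEL_STROKE: "stroke",
}


class GridMismatchError(ValueError):
    """Two volumes do not share shape and voxel dimensions."""


@dataclass
class VolumeGrid:
    """A scalar volume on a regular lattice.

    Parameters
    ----------
    data:
        3-D array of finite scalars.
    voxel_dims:
        Physical voxel edge lengths ``(dx, dy, dz)`` in mm, all positive.
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.data.shape}")
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be three positive lengths, got {self.voxel_dims}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_dims, other.voxel_dims)

    def require_same_grid(self, other: "VolumeGrid") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}@{self.voxel_dims} vs {other.shape}@{other.voxel_dims}"
            )


@dataclass
class LabelVolume(VolumeGrid):
    """Ground-truth tissue labels: 0 background, 1 CSF, 2 NAWM, 3 WMH, 4 stroke."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must be integer typed")
        super().__post_init__()
        present = set(np.unique(self.data).tolist())
        if not present <= set(TISSUE_LABELS):
            raise ValueError(f"unknown labels present: {sorted(present - set(TISSUE_LABELS))}")

    def mask(self, label: int) -> np.ndarray:
        """Binary mask of one tissue class."""
        return self.data == label

    @property
    def brain_mask(self) -> np.ndarray:
        return self.data != LABEL_BACKGROUND


def as_binary_mask(arr: np.ndarray, name: str = "mask") -> np.ndarray:
    """Validate that an array contains only {0, 1} and return it as bool."""
    arr = np.asarray(arr)
    if arr.dtype == bool:
        return arr
    values = np.unique(arr)
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError(f"{name} is not binary; found values {values[:10]}")
    return arr.astype(bool)
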