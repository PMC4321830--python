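"""Distance-shell analysis of the white matter surrounding lesions.

Shells are built by thresholding an anisotropy-aware Euclidean distance
transform of the lesion mask (distances between voxel centres), so nominal
2 mm increments are approximate on a coarse lattice, and each shell is the
set difference of two consecutive dilations intersected with the
normal-appearing white matter mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import GridMismatchError

__all__ = ["EmptyLesionError", "ShellSet", "dilate_to_distance", "build_shells",
           "sample_fixed_rois"]

_EPS = 1e-9


class EmptyLesionError(ValueError):
    """The lesion mask is empty; the subject has no shells."""


@dataclass
class ShellSet:
    """Ordered disjoint NAWM shells around the lesion mask plus the remainder.

    ``shells`` maps nominal outer distance in mm (e.g. 2.0, 4.0, ...) to a
    binary mask; ``remaining_nawm`` is the NAWM beyond the outermost shell.
    """

    shells: dict[float, np.ndarray]
    remaining_nawm: np.ndarray
    voxel_dims: tuple[float, float, float]
    step_mm: float = 2.0

    @property
    def distances(self) -> list[float]:
        return sorted(self.shells)

    def labelled_masks(self):
        """Yield (label, mask) pairs in increasing distance order."""
        for d in self.distances:
            yield f"shell_{d:g}mm", self.shells[d]
        yield "remaining_nawm", self.remaining_nawm


def _lesion_distance(mask: np.ndarray, voxel_dims) -> np.ndarray:
    """Centre-to-nearest-mask-voxel-centre Euclidean distance in mm."""
    return ndimage.distance_transform_edt(~mask, sampling=voxel_dims)


def dilate_to_distance(
    mask: np.ndarray, distance_mm: float, voxel_dims: tuple[float, float, float]
) -> np.ndarray:
    """All voxels within ``distance_mm`` of the mask (by centre distance), plus the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyLesionError("cannot dilate an empty mask")
    if distance_mm <= 0:
        raise ValueError(f"distance must be positive, got {distance_mm}")
    dist = _lesion_distance(mask, voxel_dims)
    return dist <= distance_mm + _EPS


def build_shells(
    wmh: np.ndarray,
    nawm: np.ndarray,
    voxel_dims: tuple[float, float, float],
    max_mm: float = 10.0,
    step_mm: float = 2.0,
) -> ShellSet:
    """Disjoint NAWM shells at nominal ``step_mm`` increments out to ``max_mm``.

    shell_k = (dilate(wmh, k) - dilate(wmh, k - step)) ∩ nawm, and
    remaining_nawm = nawm - dilate(wmh, max_mm).  Together with the shells it
    partitions the NAWM mask exactly.
    """
    wmh = np.asarray(wmh, dtype=bool)
    nawm = np.asarray(nawm, dtype=bool)
    if wmh.shape != nawm.shape:
        raise GridMismatchError("wmh and nawm masks differ in shape")
    if not wmh.any():
        raise EmptyLesionError("subject has no lesion voxels; skip shell analysis")
    if step_mm <= 0 or max_mm < step_mm:
        raise ValueError("need 0 < step_mm <= max_mm")

    dist = _lesion_distance(wmh, voxel_dims)
    nawm_only = nawm & ~wmh
    shells: dict[float, np.ndarray] = {}
    edges = np.arange(step_mm, max_mm + _EPS, step_mm)
    prev = 0.0
    for outer in edges:
        shells[float(outer)] = nawm_only & (dist > prev + _EPS) & (dist <= outer + _EPS)
        prev = float(outer)
    remaining = nawm_only & (dist > prev + _EPS)
    return ShellSet(shells=shells, remaining_nawm=remaining,
                    voxel_dims=tuple(voxel_dims), step_mm=float(step_mm))


def sample_fixed_rois(
    volume,
    centers: list[tuple[int, int, int]],
    radius_mm: float,
    valid_mask: np.ndarray | None = None,
) -> list[float]:
    """Mean map value inside a sphere of ``radius_mm`` around each voxel centre.

    A radius smaller than every voxel dimension reduces to the centre voxel.
    If ``valid_mask`` is given and a sphere misses it entirely, that ROI is
    reported as NaN (missing).
    """
    data = volume.data
    dims = np.asarray(volume.voxel_dims, dtype=float)
    shape = np.asarray(data.shape)
    means: list[float] = []
    for center in centers:
        center = np.asarray(center, dtype=int)
        if np.any(center < 0) or np.any(center >= shape):
            raise ValueError(f"centre {tuple(center)} outside grid {tuple(shape)}")
        reach = np.maximum(np.floor(radius_mm / dims).astype(int), 0)
        lo = np.maximum(center - reach, 0)
        hi = np.minimum(center + reach + 1, shape)
        sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        offs = [
            (np.arange(lo[i], hi[i]) - center[i]) * dims[i] for i in range(3)
        ]
        dx, dy, dz = np.meshgrid(*offs, indexing="ij")
        inside = dx**2 + dy**2 + dz**2 <= radius_mm**2 + _EPS
        if valid_mask is not None:
            inside &= valid_mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if not inside.any():
            means.append(float("nan"))
        else:
            means.append(float(sub[inside].mean()))
    return means
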