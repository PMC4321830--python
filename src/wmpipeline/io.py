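"""NIfTI and table I/O with grid-compatibility enforcement.

The loader never resamples or registers: volumes whose shapes or voxel
dimensions disagree are rejected.  Voxel dimensions are taken from the NIfTI
affine column norms (no oblique handling — phantoms are axis-aligned).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import GridMismatchError, LabelVolume, VolumeGrid, as_binary_mask
from .phantom import SubjectRecord

__all__ = [
    "SubjectBundle",
    "read_volume",
    "write_volume",
    "load_bundle",
    "save_results",
    "load_results",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
]


def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal affine from voxel_dims."""
    path = Path(path)
    affine = np.diag([*grid.voxel_dims, 1.0])
    img = nib.Nifti1Image(np.asarray(grid.data), affine)
    img.header.set_zooms(grid.voxel_dims)
    nib.save(img, path)
    return path


def read_volume(path: str | Path, labels: bool = False) -> VolumeGrid:
    """Read a NIfTI-1 volume; voxel_dims come from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if labels:
        return LabelVolume(np.round(data).astype(np.int16), zooms)
    return VolumeGrid(data.astype(np.float64), zooms)


@dataclass
class SubjectBundle:
    """All co-registered volumes and metadata for one subject."""

    structural: dict[str, VolumeGrid] = field(default_factory=dict)
    parametric: dict[str, VolumeGrid] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    record: SubjectRecord | None = None
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        ref: VolumeGrid | None = None
        for name, vol in [*self.structural.items(), *self.parametric.items()]:
            if ref is None:
                ref = vol
                self.voxel_dims = vol.voxel_dims
            else:
                try:
                    ref.require_same_grid(vol)
                except GridMismatchError as exc:
                    raise GridMismatchError(f"volume {name!r}: {exc}") from exc
        ref_shape = ref.shape if ref is not None else None
        for name, mask in self.masks.items():
            mask = as_binary_mask(mask, name=name)
            if ref_shape is None:
                ref_shape = mask.shape
            elif mask.shape != ref_shape:
                raise GridMismatchError(
                    f"mask {name!r} shape {mask.shape} != bundle shape {ref_shape}"
                )
            self.masks[name] = mask


def load_bundle(
    structural_paths: dict[str, str | Path] | None = None,
    parametric_paths: dict[str, str | Path] | None = None,
    mask_paths: dict[str, str | Path] | None = None,
    record: SubjectRecord | None = None,
) -> SubjectBundle:
    """Load and validate one subject's files into a bundle.

    Raises ``GridMismatchError`` if any volume disagrees on shape or voxel
    dimensions, and ``ValueError`` if a mask is non-binary.
    """
    structural = {k: read_volume(p) for k, p in (structural_paths or {}).items()}
    parametric = {k: read_volume(p) for k, p in (parametric_paths or {}).items()}
    masks = {}
    for k, p in (mask_paths or {}).items():
        vol = read_volume(p)
        masks[k] = as_binary_mask(vol.data.astype(np.int16), name=k)
    return SubjectBundle(structural=structural, parametric=parametric, masks=masks, record=record)


def save_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write result tables as CSV (one file per table); NaN -> empty field.

    Round-trips losslessly up to float64 representation via ``load_results``.
    """
    if not tables:
        raise ValueError("no tables to save")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, frame in tables.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, na_rep="")
        written[name] = path
    return written


def load_results(out_dir: str | Path, names: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Read back tables written by :func:`save_results`."""
    out_dir = Path(out_dir)
    paths = sorted(out_dir.glob("*.csv")) if names is None else [out_dir / f"{n}.csv" for n in names]
    return {p.stem: pd.read_csv(p) for p in paths}


_COHORT_COLUMNS = ["id", "age_days", "gender", "fazekas_pv", "fazekas_deep", "fazekas_total"]


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records (one row each, VRF flags as 0/1 columns)."""
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "age_days": rec.age_days,
            "gender": rec.gender,
            "fazekas_pv": rec.fazekas_pv,
            "fazekas_deep": rec.fazekas_deep,
            "fazekas_total": rec.fazekas_total,
        }
        for factor, flag in rec.vrf.items():
            row[factor] = int(flag)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: list[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(records).to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    frame = pd.read_csv(path)
    records = []
    vrf_cols = [c for c in frame.columns if c not in _COHORT_COLUMNS]
    for _, row in frame.iterrows():
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                age_days=int(row["age_days"]),
                gender=str(row["gender"]),
                fazekas_pv=int(row["fazekas_pv"]),
                fazekas_deep=int(row["fazekas_deep"]),
                vrf={c: bool(row[c]) for c in vrf_cols},
            )
        )
    return records
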