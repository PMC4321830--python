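"""Synthetic subject generator.

Produces ground-truth tissue label geometry (ventricular CSF, a thick white
matter compartment, periventricular and deep lesions), structural contrasts,
parametric biomarker maps with an optional distance-decaying lesion penumbra,
and cohort-level paired biomarker draws calibrated to the default population
tables.

Every generator is a pure function of its arguments and an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import defaults
from .grids import (
    LABEL_BACKGROUND,
    LABEL_CSF,
    LABEL_NAWM,
    LABEL_STROKE,
    LABEL_WMH,
    TISSUE_LABELS,
    LabelVolume,
    VolumeGrid,
)

__all__ = [
    "PhantomSizingError",
    "ConfigurationError",
    "PenumbraConfig",
    "BiomarkerTable",
    "SubjectRecord",
    "make_label_phantom",
    "synthesize_structural",
    "synthesize_parametric",
    "make_cohort",
    "assign_vrf",
    "score_split",
    "draw_paired_biomarker",
]


class PhantomSizingError(ValueError):
    """Requested grid cannot contain the phantom geometry."""


class ConfigurationError(ValueError):
    """A required (tissue, modality) or (tissue, biomarker) entry is missing."""


@dataclass(frozen=True)
class PenumbraConfig:
    """Distance-decaying shift of NAWM biomarker expectations toward lesion values.

    A NAWM voxel at Euclidean distance ``d`` mm from the nearest lesion voxel
    has its expected value shifted by ``amplitude * exp(-d / decay_mm)`` times
    the (lesion mean - NAWM mean) difference, per biomarker.
    """

    amplitude: float = defaults.PENUMBRA_AMPLITUDE
    decay_mm: float = defaults.PENUMBRA_DECAY_MM

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"amplitude must be in [0, 1], got {self.amplitude}")
        if self.decay_mm <= 0:
            raise ValueError(f"decay_mm must be > 0, got {self.decay_mm}")


@dataclass
class BiomarkerTable:
    """Population (mean, SD) per biomarker per tissue, plus the paired correlation."""

    values: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {b: dict(t) for b, t in defaults.BIOMARKER_TABLE.items()}
    )
    rho: float = defaults.DEFAULT_RHO

    def __post_init__(self) -> None:
        for biomarker, tissues in self.values.items():
            for tissue, (_, sd) in tissues.items():
                if sd < 0:
                    raise ValueError(f"negative SD for ({tissue}, {biomarker})")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")

    @property
    def biomarkers(self) -> tuple[str, ...]:
        return tuple(self.values)

    def mean_sd(self, biomarker: str, tissue: str) -> tuple[float, float]:
        try:
            return self.values[biomarker][tissue]
        except KeyError as exc:
            raise ConfigurationError(f"missing biomarker entry ({tissue}, {biomarker})") from exc


@dataclass
class SubjectRecord:
    """Demographics, ground-truth Fazekas scores and risk-factor flags."""

    id: str
    age_days: int
    gender: str
    fazekas_pv: int
    fazekas_deep: int
    vrf: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        if not (0 <= self.fazekas_pv <= 3 and 0 <= self.fazekas_deep <= 3):
            raise ValueError("Fazekas sub-scores must lie in 0..3")
        smoker_flags = self.vrf.get("current_smoker", False), self.vrf.get("ex_smoker", False)
        if all(smoker_flags):
            raise ValueError("current and ex smoker flags are mutually exclusive")

    @property
    def fazekas_total(self) -> int:
        return self.fazekas_pv + self.fazekas_deep


def score_split(total_score: int) -> tuple[int, int]:
    """Split a total score 0..6 into (periventricular, deep) sub-scores."""
    if not 0 <= total_score <= 6:
        raise ValueError(f"total score must be in 0..6, got {total_score}")
    pv = math.ceil(total_score / 2)
    return pv, total_score - pv


# geometry fractions of the field of view (per axis)
_BRAIN_FRAC = 0.45
_VENT_OFFSET_FRAC = 0.11  # lateral offset of each ventricle along x
_VENT_SEMI_FRAC = (0.06, 0.20, 0.09)
_NAWM_MARGIN_MM = 12.0  # so 10 mm shells fit inside NAWM
_DEEP_RADIUS_MM = 5.0
_PV_THICKNESS_PER_SCORE_MM = 2.0  # ring thickness = (pv + 1) * this, pv >= 1
_MAX_DEEP_LESIONS = 3


def _coordinate_mm(shape, voxel_dims):
    """Voxel-centre coordinates in mm relative to the grid centre, per axis."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * d for n, d in zip(shape, voxel_dims)
    ]


def make_label_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 2.0),
    target_score: int = 2,
    seed: int | np.random.Generator = 0,
    with_stroke: bool = False,
) -> LabelVolume:
    """Generate ground-truth tissue labels for one synthetic subject.

    The phantom contains an ellipsoidal brain of white matter, two
    ellipsoidal lateral-ventricle CSF compartments, periventricular lesion
    caps adjacent to the CSF and isolated deep lesion spheres.  Total lesion
    volume increases strictly with ``target_score`` at fixed seed;
    ``target_score=0`` produces no lesion voxels.
    """
    pv, deep = score_split(target_score)
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    voxel_dims = tuple(float(d) for d in voxel_dims)

    extent = np.array([n * d for n, d in zip(shape, voxel_dims)])
    # margin between ventricle extremes and the brain surface, per axis
    vent_extent_frac = np.array([_VENT_OFFSET_FRAC + _VENT_SEMI_FRAC[0],
                                 _VENT_SEMI_FRAC[1], _VENT_SEMI_FRAC[2]])
    margins = (_BRAIN_FRAC - vent_extent_frac) * extent
    if np.any(margins < _NAWM_MARGIN_MM):
        needed = _NAWM_MARGIN_MM / (_BRAIN_FRAC - vent_extent_frac)
        raise PhantomSizingError(
            f"field of view {extent} mm too small for a {_NAWM_MARGIN_MM} mm NAWM "
            f"margin; need at least {np.ceil(needed)} mm per axis"
        )

    xs, ys, zs = _coordinate_mm(shape, voxel_dims)
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")

    a = _BRAIN_FRAC * extent
    brain = (x / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2 <= 1.0

    v = np.array(_VENT_SEMI_FRAC) * extent
    off = _VENT_OFFSET_FRAC * extent[0]
    vent = np.zeros(shape, dtype=bool)
    for sign in (-1.0, 1.0):
        vent |= ((x - sign * off) / v[0]) ** 2 + (y / v[1]) ** 2 + (z / v[2]) ** 2 <= 1.0
    vent &= brain

    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = LABEL_NAWM
    labels[vent] = LABEL_CSF

    # distances from CSF and from outside-brain, between voxel centres
    dist_csf = ndimage.distance_transform_edt(~vent, sampling=voxel_dims)
    dist_bg = ndimage.distance_transform_edt(brain, sampling=voxel_dims)

    nawm = labels == LABEL_NAWM

    # deep-lesion candidate centres: clear of ventricles, caps and surface.
    # Centres are always drawn (same rng consumption for every score) so the
    # lesion sets are nested across scores at a fixed seed.
    max_cap_mm = _PV_THICKNESS_PER_SCORE_MM * 4  # thickest cap (pv=3)
    candidates = np.flatnonzero(
        nawm.ravel()
        & (dist_csf.ravel() >= max_cap_mm + _DEEP_RADIUS_MM + 2.0)
        & (dist_bg.ravel() >= _DEEP_RADIUS_MM + 2.0)
    )
    order = rng.permutation(candidates)
    centres: list[np.ndarray] = []
    coord_of = lambda flat: np.array(np.unravel_index(flat, shape)) * voxel_dims  # noqa: E731
    n_wanted = _MAX_DEEP_LESIONS + (1 if with_stroke else 0)
    for flat in order:
        c = coord_of(flat)
        if all(np.linalg.norm(c - p) >= 2 * _DEEP_RADIUS_MM + 2.0 for p in centres):
            centres.append(c)
        if len(centres) == n_wanted:
            break
    if len(centres) < n_wanted:
        raise PhantomSizingError(
            f"could not place {n_wanted} deep lesion centres; grid too small"
        )

    wmh = np.zeros(shape, dtype=bool)
    if pv >= 1:
        cap = _PV_THICKNESS_PER_SCORE_MM * (pv + 1)
        wmh |= nawm & (dist_csf > 0) & (dist_csf <= cap)
    for c in centres[:deep]:
        # centres are in absolute mm from voxel (0,0,0); convert grid coords
        cx = c - (np.array(extent) - np.array(voxel_dims)) / 2.0
        r2 = (x - cx[0]) ** 2 + (y - cx[1]) ** 2 + (z - cx[2]) ** 2
        wmh |= nawm & (r2 <= _DEEP_RADIUS_MM**2)
    labels[wmh & nawm] = LABEL_WMH

    if with_stroke:
        c = centres[_MAX_DEEP_LESIONS]
        cx = c - (np.array(extent) - np.array(voxel_dims)) / 2.0
        r2 = (x - cx[0]) ** 2 + (y - cx[1]) ** 2 + (z - cx[2]) ** 2
        stroke = (labels == LABEL_NAWM) & (r2 <= (_DEEP_RADIUS_MM - 1.0) ** 2)
        labels[stroke] = LABEL_STROKE

    return LabelVolume(labels, voxel_dims)


def _tissue_maps(labels: LabelVolume, lookup, missing_ok=()) -> tuple[np.ndarray, np.ndarray]:
    """Build per-voxel (mean, SD) arrays from a tissue -> (mean, sd) lookup."""
    mean = np.zeros(labels.shape, dtype=float)
    sd = np.zeros(labels.shape, dtype=float)
    for value, tissue in TISSUE_LABELS.items():
        mask = labels.data == value
        if not mask.any() or value == LABEL_BACKGROUND:
            continue
        if tissue not in lookup:
            if tissue in missing_ok:
                continue
            raise ConfigurationError(f"missing contrast entry for tissue {tissue!r}")
        m, s = lookup[tissue]
        mean[mask] = m
        sd[mask] = s
    return mean, sd


def synthesize_structural(
    labels: LabelVolume,
    contrasts: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int | np.random.Generator = 0,
    noise_scale: float = 1.0,
) -> dict[str, VolumeGrid]:
    """Simulate co-registered structural volumes (T1W, T2W, FLAIR, T2*W).

    Each voxel draws tissue mean + Gaussian noise at the tissue SD; all
    modalities share the label grid exactly.
    """
    contrasts = defaults.CONTRAST_TABLE if contrasts is None else contrasts
    rng = np.random.default_rng(seed)
    out = {}
    for modality in defaults.STRUCTURAL_MODALITIES:
        if modality not in contrasts:
            raise ConfigurationError(f"missing modality {modality!r} in contrast table")
        mean, sd = _tissue_maps(labels, contrasts[modality])
        noise = rng.standard_normal(labels.shape)
        out[modality] = VolumeGrid(mean + noise_scale * sd * noise, labels.voxel_dims)
    return out


def synthesize_parametric(
    labels: LabelVolume,
    table: BiomarkerTable | None = None,
    penumbra: PenumbraConfig | None = None,
    seed: int | np.random.Generator = 0,
    noise_scale: float = 1.0,
) -> dict[str, VolumeGrid]:
    """Simulate parametric biomarker maps (FA, MD, MTR, T1).

    Lesion and NAWM voxels draw Gaussian values around their population
    means; CSF voxels are fixed at fluid values; stroke voxels reuse the
    lesion distribution.  With a penumbra, NAWM expectations are pulled
    toward the lesion mean with an exponential decay in distance from the
    nearest lesion voxel.
    """
    table = BiomarkerTable() if table is None else table
    rng = np.random.default_rng(seed)

    wmh_mask = labels.mask(LABEL_WMH)
    dist = None
    if penumbra is not None and penumbra.amplitude > 0 and wmh_mask.any():
        dist = ndimage.distance_transform_edt(~wmh_mask, sampling=labels.voxel_dims)

    out = {}
    for biomarker in table.biomarkers:
        mu_n, sd_n = table.mean_sd(biomarker, "nawm")
        mu_w, sd_w = table.mean_sd(biomarker, "wmh")
        lookup = {
            "nawm": (mu_n, sd_n),
            "wmh": (mu_w, sd_w),
            "stroke": (mu_w, sd_w),
            "csf": (defaults.CSF_PARAMETRIC.get(biomarker, 0.0), 0.0),
        }
        mean, sd = _tissue_maps(labels, lookup)
        if dist is not None:
            nawm = labels.mask(LABEL_NAWM)
            shift = penumbra.amplitude * np.exp(-dist[nawm] / penumbra.decay_mm)
            mean[nawm] += shift * (mu_w - mu_n)
        noise = rng.standard_normal(labels.shape)
        out[biomarker] = VolumeGrid(mean + noise_scale * sd * noise, labels.voxel_dims)
    return out


def _paired_draws(rng, n, nawm_ms, wmh_ms, rho):
    """Bivariate-Gaussian paired (NAWM, WMH) draws with correlation rho."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    nawm = nawm_ms[0] + nawm_ms[1] * z1
    wmh = wmh_ms[0] + wmh_ms[1] * (rho * z1 + math.sqrt(1.0 - rho**2) * z2)
    return nawm, wmh


def draw_paired_biomarker(
    biomarker: str,
    n: int,
    seed: int | np.random.Generator,
    table: BiomarkerTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (NAWM, lesion) subject-mean draws from the pooled population rows."""
    table = BiomarkerTable() if table is None else table
    rng = np.random.default_rng(seed)
    return _paired_draws(rng, n, table.mean_sd(biomarker, "nawm"),
                         table.mean_sd(biomarker, "wmh"), table.rho)


def make_cohort(
    group_sizes: dict[int, int] | None = None,
    table: BiomarkerTable | None = None,
    per_score_nawm: dict[int, dict[str, tuple[float, float]]] | None = None,
    seed: int | np.random.Generator = 0,
):
    """Simulate a cohort of subject records with paired per-tissue biomarker means.

    Returns ``(records, summaries)`` where ``summaries`` is a pandas
    DataFrame with one row per subject and columns ``nawm_<b>`` /
    ``wmh_<b>`` per biomarker.  The NAWM marginal comes from the subject's
    Fazekas-group row; the lesion marginal is the pooled population row;
    the paired draws are bivariate Gaussian with correlation ``table.rho``.
    """
    import pandas as pd

    group_sizes = defaults.GROUP_SIZES if group_sizes is None else group_sizes
    table = BiomarkerTable() if table is None else table
    per_score_nawm = defaults.PER_SCORE_NAWM if per_score_nawm is None else per_score_nawm
    if any(n < 0 for n in group_sizes.values()):
        raise ValueError("group sizes must be non-negative")
    rng = np.random.default_rng(seed)

    lo, hi = defaults.AGE_RANGE_YEARS
    records: list[SubjectRecord] = []
    rows = []
    idx = 0
    for score in sorted(group_sizes):
        n = int(group_sizes[score])
        if n == 0:
            continue
        male_frac = defaults.MALE_COUNTS.get(score, 0) / max(defaults.GROUP_SIZES.get(score, 1), 1)
        pv, deep = score_split(score)
        genders = np.where(rng.random(n) < male_frac, "M", "F")
        ages = rng.uniform(lo, hi, n) * defaults.DAYS_PER_YEAR
        draws = {}
        for biomarker in table.biomarkers:
            nawm_ms = per_score_nawm[score][biomarker]
            wmh_ms = table.mean_sd(biomarker, "wmh")
            draws[biomarker] = _paired_draws(rng, n, nawm_ms, wmh_ms, table.rho)
        for i in range(n):
            rec = SubjectRecord(
                id=f"S{idx:04d}",
                age_days=int(round(ages[i])),
                gender=str(genders[i]),
                fazekas_pv=pv,
                fazekas_deep=deep,
            )
            records.append(rec)
            row = {"id": rec.id, "fazekas_total": score,
                   "age_days": rec.age_days, "gender": rec.gender}
            for biomarker in table.biomarkers:
                nawm_v, wmh_v = draws[biomarker]
                row[f"nawm_{biomarker}"] = nawm_v[i]
                row[f"wmh_{biomarker}"] = wmh_v[i]
            rows.append(row)
            idx += 1
    return records, pd.DataFrame(rows)


def assign_vrf(
    records: list[SubjectRecord],
    incidence: dict[str, tuple[float, float]] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SubjectRecord]:
    """Assign vascular-risk-factor flags by gender-specific incidence (percent).

    Smoking status (current / ex / never) is one categorical draw; the other
    factors are independent Bernoulli draws.  Returns new records.
    """
    incidence = defaults.VRF_INCIDENCE if incidence is None else incidence
    for factor, rates in incidence.items():
        if len(rates) != 2 or any(not 0.0 <= r <= 100.0 for r in rates):
            raise ValueError(f"malformed incidence for {factor!r}: {rates}")
    cur = incidence.get("current_smoker", (0.0, 0.0))
    ex = incidence.get("ex_smoker", (0.0, 0.0))
    if cur[0] + ex[0] > 100.0 or cur[1] + ex[1] > 100.0:
        raise ValueError("smoking incidences exceed 100% combined")

    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        g = 0 if rec.gender == "M" else 1
        flags: dict[str, bool] = {}
        u = rng.random()
        flags["current_smoker"] = u < cur[g] / 100.0
        flags["ex_smoker"] = cur[g] / 100.0 <= u < (cur[g] + ex[g]) / 100.0
        for factor, rates in incidence.items():
            if factor in ("current_smoker", "ex_smoker"):
                continue
            flags[factor] = rng.random() < rates[g] / 100.0
        out.append(
            SubjectRecord(
                id=rec.id,
                age_days=rec.age_days,
                gender=rec.gender,
                fazekas_pv=rec.fazekas_pv,
                fazekas_deep=rec.fazekas_deep,
                vrf=flags,
            )
        )
    return out
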