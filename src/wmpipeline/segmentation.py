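"""Semiautomatic tissue segmentation via two-channel colour fusion.

Two structural contrasts are normalised, stacked into a red-green colour
volume, reduced to a small palette by a greedy minimum-variance quantizer
(recursive binary splits of axis-aligned colour boxes, each split chosen to
maximally reduce the total within-box SSE),
and tissue masks are selected from the palette centroids by contrast rules.

Refinement dilates the CSF mask by one voxel (26-neighbourhood) and removes
it from the tissue masks to suppress partial-volume contamination at fluid
boundaries; stroke voxels are removed by set difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridMismatchError, VolumeGrid

__all__ = [
    "FusedColorVolume",
    "ColorCluster",
    "EmptySelectionWarning",
    "normalize_channel",
    "fuse_red_green",
    "minimum_variance_quantize",
    "select_tissue_clusters",
    "refine_masks",
    "exclude_stroke",
    "dice",
]


class EmptySelectionWarning(UserWarning):
    """No cluster satisfied the tissue-selection rule; returning an empty mask."""


@dataclass
class FusedColorVolume:
    """Per-voxel (red, green) colour pair on the source grid, channels in [0, 255]."""

    red: np.ndarray
    green: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.red.shape != self.green.shape:
            raise GridMismatchError("red and green channels differ in shape")
        for name, chan in (("red", self.red), ("green", self.green)):
            if chan.min() < 0 or chan.max() > 255:
                raise ValueError(f"{name} channel outside [0, 255]")

    @property
    def shape(self):
        return self.red.shape


@dataclass
class ColorCluster:
    """One palette entry: centroid colour, member voxels, within-cluster SSE."""

    cluster_id: int
    centroid: tuple[float, float]
    members: np.ndarray  # flat voxel indices into the source grid
    sse: float

    @property
    def size(self) -> int:
        return int(self.members.size)


def normalize_channel(volume: VolumeGrid, brain_mask: np.ndarray) -> VolumeGrid:
    """Clip to the in-mask [1st, 99th] percentile range and map to [0, 255].

    A constant volume maps to all zeros (documented degenerate case).
    Voxels outside the mask are scaled with the same affine map and clipped.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    values = volume.data[brain_mask]
    lo, hi = np.percentile(values, [1.0, 99.0])
    out = np.zeros_like(volume.data, dtype=float)
    if hi > lo:
        out = np.clip(volume.data, lo, hi)
        out = np.clip((out - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    return VolumeGrid(out, volume.voxel_dims)


def fuse_red_green(vol_red: VolumeGrid, vol_green: VolumeGrid) -> FusedColorVolume:
    """Stack two normalised volumes into a red-green colour volume."""
    vol_red.require_same_grid(vol_green)
    return FusedColorVolume(vol_red.data.astype(float), vol_green.data.astype(float),
                            vol_red.voxel_dims)


_LOOKAHEAD_ROWS = 64  # lookahead only for small boxes (exact for <= 3 levels)


class _Box:
    """An axis-aligned colour box over a subset of in-mask voxels."""

    __slots__ = ("colors", "indices", "sse", "best_gain", "best_split", "_lookahead")

    def __init__(self, colors: np.ndarray, indices: np.ndarray):
        self.colors = colors  # (n, 2) float
        self.indices = indices  # flat voxel indices, same length
        centroid = colors.mean(axis=0)
        self.sse = float(((colors - centroid) ** 2).sum())
        self._lookahead = None
        self._find_best_split()

    def _find_best_split(self) -> None:
        """Best (channel, threshold) minimising the post-split total SSE."""
        self.best_gain = 0.0
        self.best_split = None
        n = self.colors.shape[0]
        if n < 2:
            return
        for channel in (0, 1):
            order = np.argsort(self.colors[:, channel], kind="stable")
            c = self.colors[order]
            # prefix sums for O(1) SSE of every left/right part
            s = np.cumsum(c, axis=0)
            s2 = np.cumsum(c**2, axis=0)
            total_s, total_s2 = s[-1], s2[-1]
            k = np.arange(1, n)  # left part sizes
            # only cut between distinct values along this channel
            distinct = c[1:, channel] > c[:-1, channel]
            if not distinct.any():
                continue
            left_sse = (s2[:-1] - s[:-1] ** 2 / k[:, None]).sum(axis=1)
            right_n = n - k
            rs = total_s - s[:-1]
            rs2 = total_s2 - s2[:-1]
            right_sse = (rs2 - rs**2 / right_n[:, None]).sum(axis=1)
            split_sse = np.where(distinct, left_sse + right_sse, np.inf)
            best = int(np.argmin(split_sse))
            gain = self.sse - float(split_sse[best])
            if self.best_split is None or gain > self.best_gain + 1e-12:
                threshold = 0.5 * (c[best, channel] + c[best + 1, channel])
                self.best_gain = gain
                self.best_split = (channel, threshold)

    def lookahead(self) -> tuple[float, tuple[int, float]] | None:
        """Best (gain over two splits, first split) for small boxes.

        Evaluates every candidate first split followed by the best immediate
        child split, which makes 3-level quantization exactly optimal; large
        boxes fall back to the plain greedy split.
        """
        if self.best_split is None or self.colors.shape[0] > _LOOKAHEAD_ROWS:
            return None
        if self._lookahead is not None:
            return self._lookahead
        best_gain, best_split = -np.inf, None
        for channel in (0, 1):
            cuts = np.unique(self.colors[:, channel])
            for i in range(cuts.size - 1):
                threshold = 0.5 * (cuts[i] + cuts[i + 1])
                left = self.colors[:, channel] <= threshold
                lbox = _Box(self.colors[left], self.indices[left])
                rbox = _Box(self.colors[~left], self.indices[~left])
                gain = self.sse - lbox.sse - rbox.sse + max(lbox.best_gain, rbox.best_gain)
                if gain > best_gain + 1e-12:
                    best_gain, best_split = gain, (channel, threshold)
        self._lookahead = (best_gain, best_split)
        return self._lookahead

    def split(self, at: tuple[int, float] | None = None) -> tuple["_Box", "_Box"]:
        channel, threshold = at if at is not None else self.best_split
        left = self.colors[:, channel] <= threshold
        return (_Box(self.colors[left], self.indices[left]),
                _Box(self.colors[~left], self.indices[~left]))


def minimum_variance_quantize(
    fused: FusedColorVolume,
    brain_mask: np.ndarray,
    n_levels: int = 16,
) -> list[ColorCluster]:
    """Reduce the in-mask colours to ``n_levels`` palette clusters.

    Greedy minimum-variance quantization: starting from one box holding all
    in-mask colours, repeatedly split a box at the channel/threshold pair that
    maximally reduces the total SSE, until ``n_levels`` boxes exist or no box
    contains more than one distinct colour.  Deterministic for fixed input.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    indices = np.flatnonzero(brain_mask.ravel())
    colors = np.column_stack([fused.red.ravel()[indices], fused.green.ravel()[indices]])

    boxes = [_Box(colors, indices)]
    while len(boxes) < n_levels:
        splittable = [b for b in boxes if b.best_split is not None]
        if not splittable:
            break
        budget = n_levels - len(boxes)  # splits still available, this one included

        def _score(b: _Box) -> float:
            if budget >= 2 and (la := b.lookahead()) is not None:
                return la[0]
            return b.best_gain

        # split the box (and cut) that reduces the total SSE the most,
        # looking one split ahead where that is affordable
        box = max(splittable, key=_score)
        at = None
        if budget >= 2 and (la := box.lookahead()) is not None:
            at = la[1]
        boxes.remove(box)
        boxes.extend(box.split(at))

    clusters = []
    for i, box in enumerate(sorted(boxes, key=lambda b: tuple(b.colors.mean(axis=0)))):
        centroid = box.colors.mean(axis=0)
        clusters.append(ColorCluster(i, (float(centroid[0]), float(centroid[1])),
                                     box.indices, box.sse))
    return clusters


def _members_to_mask(clusters, selected, shape) -> np.ndarray:
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    for cluster in selected:
        mask[cluster.members] = True
    return mask.reshape(shape)


def select_tissue_clusters(
    clusters: list[ColorCluster],
    target: str,
    fusion_kind: str,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Assign palette clusters to a tissue class and return the binary mask.

    For the T1W(red)+T2W(green) fusion, centroids are scored by red-green: a
    three-class Otsu partition of the scores puts white matter in the top
    class and CSF in the bottom class.  For the T2*W(red)+FLAIR(green)
    fusion, lesions are the clusters whose green centroid lies above an Otsu
    cut (FLAIR hyperintensity).  Returns an empty mask with a warning if no
    cluster qualifies.
    """
    if not clusters:
        raise ValueError("no clusters given")
    if fusion_kind not in ("T1W+T2W", "T2SW+FLAIR"):
        raise ValueError(f"unknown fusion kind {fusion_kind!r}")
    cents = np.array([c.centroid for c in clusters])

    if fusion_kind == "T1W+T2W":
        if target not in ("nawm", "csf"):
            raise ValueError(f"fusion {fusion_kind} selects 'nawm' or 'csf', not {target!r}")
        score = cents[:, 0] - cents[:, 1]
        if target == "csf":
            score = -score
        selected = _top_class(score)
    else:
        if target != "wmh":
            raise ValueError(f"fusion {fusion_kind} selects 'wmh', not {target!r}")
        green = cents[:, 1]
        if np.unique(green).size < 2:
            warnings.warn("all centroids share one green value; no lesion cluster",
                          EmptySelectionWarning)
            selected = np.zeros(len(clusters), dtype=bool)
        else:
            cut = _otsu_threshold(green)
            selected = green > cut
    if not selected.any():
        warnings.warn(f"no cluster selected for target {target!r}", EmptySelectionWarning)
    chosen = [c for c, s in zip(clusters, selected) if s]
    return _members_to_mask(clusters, chosen, shape)


def _otsu_threshold(values: np.ndarray) -> float:
    """Exact (exhaustive) Otsu cut over a small set of values.

    Minimises the total within-class sum of squares over every split between
    consecutive sorted unique values; the returned threshold is the midpoint
    at the best split, so comparisons against it are unambiguous (unlike a
    histogram-based cut on a handful of points).
    """
    v = np.asarray(values, dtype=float)
    uniq = np.sort(np.unique(v))
    if uniq.size < 2:
        raise ValueError("need at least two distinct values")
    best_within, best_cut = np.inf, None
    for i in range(uniq.size - 1):
        lower = v[v <= uniq[i]]
        upper = v[v > uniq[i]]
        within = lower.var() * lower.size + upper.var() * upper.size
        if within < best_within - 1e-12:
            best_within = within
            best_cut = 0.5 * (uniq[i] + uniq[i + 1])
    return float(best_cut)


def _top_class(score: np.ndarray) -> np.ndarray:
    """Top class of an exact 3-class minimum-within-variance partition of scores."""
    uniq = np.sort(np.unique(score))
    if uniq.size == 1:
        return score >= uniq[0]  # single colour: everything is the target
    if uniq.size == 2:
        return score > uniq[0]
    best_within, best_cut = np.inf, uniq[-2]
    for i in range(uniq.size - 2):
        low = score[score <= uniq[i]]
        rest = score[score > uniq[i]]
        for j in range(i + 1, uniq.size - 1):
            mid = rest[rest <= uniq[j]]
            top = rest[rest > uniq[j]]
            within = (low.var() * low.size + mid.var() * mid.size
                      + top.var() * top.size)
            if within < best_within - 1e-12:
                best_within = within
                best_cut = 0.5 * (uniq[j] + uniq[j + 1])
    return score > best_cut


_BOX_3 = np.ones((3, 3, 3), dtype=bool)


def refine_masks(
    nawm: np.ndarray, wmh: np.ndarray, csf: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove a one-voxel CSF dilation (26-neighbourhood box) from both masks."""
    nawm = np.asarray(nawm, dtype=bool)
    wmh = np.asarray(wmh, dtype=bool)
    csf = np.asarray(csf, dtype=bool)
    if nawm.shape != wmh.shape or nawm.shape != csf.shape:
        raise GridMismatchError("masks differ in shape")
    if not csf.any():
        return nawm.copy(), wmh.copy()
    dilated = ndimage.binary_dilation(csf, structure=_BOX_3)
    return nawm & ~dilated, wmh & ~dilated


def exclude_stroke(mask: np.ndarray, stroke: np.ndarray) -> np.ndarray:
    """Set difference: remove stroke voxels from a tissue mask."""
    mask = np.asarray(mask, dtype=bool)
    stroke = np.asarray(stroke, dtype=bool)
    if mask.shape != stroke.shape:
        raise GridMismatchError("masks differ in shape")
    return mask & ~stroke


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / float(denom)
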