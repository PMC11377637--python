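"""Lesion labelling, volume filtering and perilesional ring delineation.

Lesions are connected components of a binary mask; each lesion is
surrounded by two exclusive rings of normal-appearing tissue obtained by
thresholding the Euclidean distance (in physical mm, honouring
anisotropic voxels) to the nearest lesion voxel: the first ring covers
0 < d < 2 mm, the second 2 <= d < 3.5 mm. Voxels lying within the outer
cutoff of two or more distinct lesions are discarded from all rings so
that perilesional measurements stay specific to a single lesion.
Analyses are restricted to lesions fully inside the white-matter and
subcortical region, at least one voxel away from its boundary, and with
volumes between 3 and 150 uL.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclasses.dataclass
class LesionLabelMap:
    """Integer-labelled lesion components (0 = background)."""

    labels: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D volume")
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def voxel_volume_ul(self) -> float:
        return float(np.prod(self.voxel_dims))


@dataclasses.dataclass
class RingMasks:
    """Per-lesion exclusive perilesional ring voxel sets.

    ``ring1`` / ``ring2`` map lesion id to a boolean volume. Rings of
    different lesions never share a voxel and never contain lesion
    voxels of any lesion.
    """

    ring1: dict[int, np.ndarray]
    ring2: dict[int, np.ndarray]
    cutoffs: tuple[float, float]


def label_lesions(mask: np.ndarray, voxel_dims, connectivity: int = 26) -> LesionLabelMap:
    """Label connected components of a binary lesion mask.

    Labels are consecutive positive integers ordered by each component's
    first voxel in scan (C-raster) order, so the labelling is
    deterministic and independent of library internals.
    """
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("lesion mask must be binary (0/1)")
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    raw, n = ndimage.label(mask.astype(bool), structure=structure)
    if n > 0:
        # relabel by first-voxel scan order
        flat = raw.ravel()
        nz = np.flatnonzero(flat)
        # first occurrence per label (nz is ascending)
        lab = flat[nz]
        _, first_idx = np.unique(lab, return_index=True)
        order = np.argsort(nz[first_idx])
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[np.unique(lab)[order]] = np.arange(1, n + 1)
        raw = remap[raw]
    return LesionLabelMap(raw.astype(np.int32), voxel_dims)


def lesion_volumes(lm: LesionLabelMap) -> dict[int, float]:
    """Per-lesion volume in uL (voxel count x voxel volume; 1 uL = 1 mm^3)."""
    ids, counts = np.unique(lm.labels[lm.labels > 0], return_counts=True)
    return {int(i): float(c) * lm.voxel_volume_ul for i, c in zip(ids, counts)}


def filter_by_volume(
    volumes: dict[int, float], vmin: float = 3.0, vmax: float = 150.0
) -> list[int]:
    """Keep lesion ids with vmin <= volume <= vmax (bounds inclusive)."""
    return [i for i, v in volumes.items() if vmin <= v <= vmax]


def distance_to_lesions(
    lm: LesionLabelMap, outer_cutoff: float = 3.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euclidean distance (mm) of every voxel to the nearest lesion.

    Computes one anisotropic distance transform per lesion and reduces
    them voxelwise. Returns (distance, nearest lesion id, number of
    lesions closer than ``outer_cutoff``). Distance is 0 inside lesions;
    ties in the nearest lesion go to the lower label id.
    """
    ids = lm.ids
    if ids.size == 0:
        raise ValueError("distance map undefined: label map contains no lesions")
    best = np.full(lm.labels.shape, np.inf)
    nearest = np.zeros(lm.labels.shape, dtype=np.int32)
    n_close = np.zeros(lm.labels.shape, dtype=np.int16)
    for lid in ids:
        d = ndimage.distance_transform_edt(lm.labels != lid, sampling=lm.voxel_dims)
        closer = d < best - 1e-12  # strict: ties keep the lower (earlier) id
        nearest[closer] = lid
        best = np.minimum(best, d)
        n_close += d < outer_cutoff
    return best, nearest, n_close


def make_rings(
    lm: LesionLabelMap,
    distances: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    cutoffs: tuple[float, float] = (2.0, 3.5),
) -> RingMasks:
    """Delineate the two exclusive perilesional rings of each lesion.

    ring1 = {0 < d < cutoffs[0]}, ring2 = {cutoffs[0] <= d < cutoffs[1]}
    around the nearest lesion; any voxel within the outer cutoff of two
    or more distinct lesions is removed from all rings, and lesion
    voxels (of any lesion) are never ring members.
    """
    if cutoffs[0] > cutoffs[1]:
        raise ValueError("inner cutoff must not exceed outer cutoff")
    if distances is None:
        distances = distance_to_lesions(lm, outer_cutoff=cutoffs[1])
    dist, nearest, n_close = distances
    exclusive = n_close < 2
    outside = lm.labels == 0
    r1_all = (dist > 0) & (dist < cutoffs[0]) & outside & exclusive
    r2_all = (dist >= cutoffs[0]) & (dist < cutoffs[1]) & outside & exclusive
    ring1 = {int(i): r1_all & (nearest == i) for i in lm.ids}
    ring2 = {int(i): r2_all & (nearest == i) for i in lm.ids}
    return RingMasks(ring1, ring2, tuple(cutoffs))


def restrict_to_wm(
    lm: LesionLabelMap, tissue_mask: np.ndarray, wm_label: int = 2, connectivity: int = 26
) -> list[int]:
    """Keep lesions fully inside the eroded white-matter/subcortical region.

    The WM+subcortical region is eroded by one voxel (26-connectivity by
    default) so that kept lesions are more than one voxel away from the
    tissue boundary.
    """
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    wm = np.asarray(tissue_mask) == wm_label
    eroded = ndimage.binary_erosion(wm, structure=structure, border_value=0)
    kept = []
    for lid in lm.ids:
        if np.all(eroded[lm.labels == lid]):
            kept.append(int(lid))
    return kept
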