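"""Refine cell-candidate masks and segment the nucleolus.

Region growing extends each Frangi-detected seed to the full soma
morphology: 26-neighbours are added while their intensity stays within
``max_intensity_distance`` of the *initial* seed mean (the reference is
fixed at the start — updating it lets the region drift and may destroy
the fixpoint), and growth is capped at a Euclidean distance of
``growth_cap_vox`` from the seed so that low-contrast boundaries in
noisy data cannot leak.

The nucleolus is located at the intensity maximum inside the refined
cell (maximal phase shift) and segmented by Otsu thresholding of the
in-cell intensity histogram; its mask is the 26-connected
above-threshold component containing that maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import STRUCT_26, SegmentedObject
from .volumes import Volume

__all__ = [
    "RefinementParams",
    "CellRecord",
    "region_grow",
    "segment_nucleolus",
    "refine_cells",
    "cells_to_table",
]


@dataclass(frozen=True)
class RefinementParams:
    max_intensity_distance: float = 0.0385  # on the normalised [0, 1] scale
    growth_cap_vox: int = 5
    otsu_bins: int = 256

    def __post_init__(self) -> None:
        if self.max_intensity_distance < 0:
            raise ValueError("intensity tolerance must be >= 0")
        if self.growth_cap_vox < 0:
            raise ValueError("growth cap must be >= 0")
        if self.otsu_bins < 2:
            raise ValueError("need at least 2 histogram bins")


@dataclass
class CellRecord:
    """One refined Purkinje cell."""

    label: int
    coords: tuple[np.ndarray, np.ndarray, np.ndarray]
    centroid: tuple[float, float, float]
    volume_um3: float
    nucleolus_pos: tuple[int, int, int] | None = None
    nucleolus_coords: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    nucleolus_volume_um3: float | None = None

    @property
    def size_vox(self) -> int:
        return int(self.coords[0].size)


def region_grow(v: Volume, seed: SegmentedObject, p: RefinementParams = RefinementParams(),
                reference_mean: float | None = None) -> np.ndarray:
    """Grow the seed mask to an intensity-homogeneous region.

    Returns a boolean mask over the full volume; the result always
    contains the seed.  Voxels join if they 26-neighbour the current
    region, lie within ``growth_cap_vox`` (Euclidean) of the seed mask,
    and their intensity differs from the initial seed mean by at most
    ``max_intensity_distance``; iteration runs to the fixpoint.

    ``reference_mean`` overrides the seed-mean reference (used e.g. to
    re-grow a previously grown region under its original reference).
    """
    if seed.size_vox == 0:
        raise ValueError("empty seed")
    shape = v.shape
    cap = p.growth_cap_vox
    box = seed.bounding_box(margin=cap + 1, shape=shape)
    local_seed = np.zeros(tuple(s.stop - s.start for s in box), dtype=bool)
    local_seed[tuple(seed.coords[ax] - box[ax].start for ax in range(3))] = True
    data = np.asarray(v.data)[box]
    seed_mean = (float(data[local_seed].mean())
                 if reference_mean is None else float(reference_mean))
    within_tol = np.abs(data - seed_mean) <= p.max_intensity_distance
    # Euclidean distance to the seed caps the reachable set
    dist = ndimage.distance_transform_edt(~local_seed)
    allowed = within_tol & (dist <= cap)
    grown = local_seed.copy()
    while True:
        frontier = ndimage.binary_dilation(grown, structure=STRUCT_26) & allowed & ~grown
        if not frontier.any():
            break
        grown |= frontier
    mask = np.zeros(shape, dtype=bool)
    mask[box] = grown
    return mask


def segment_nucleolus(v: Volume, cell_mask: np.ndarray,
                      p: RefinementParams = RefinementParams()
                      ) -> tuple[tuple[int, int, int], np.ndarray]:
    """Locate and segment the nucleolus inside a refined cell mask.

    The seed is the in-mask intensity maximum (ties resolved by
    lexicographic (z, y, x) order); the mask is the 26-connected
    component of in-cell voxels above the in-cell Otsu threshold that
    contains the seed.  Raises on a degenerate (constant) histogram.
    """
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    data = np.asarray(v.data)
    values = data[cell_mask]
    if np.ptp(values) == 0:
        raise ValueError("degenerate intensity histogram inside the cell mask")
    # first flat index of the masked maximum == lexicographic (z,y,x) tie-break
    flat = np.flatnonzero(cell_mask.ravel())
    seed_flat = flat[int(np.argmax(data.ravel()[flat]))]
    seed = np.unravel_index(seed_flat, data.shape)
    from skimage.filters import threshold_otsu
    thr = threshold_otsu(values, nbins=p.otsu_bins)
    above = cell_mask & (data > thr)
    above[seed] = True  # the maximum itself always qualifies
    labels, _ = ndimage.label(above, structure=STRUCT_26)
    nuc = labels == labels[seed]
    return tuple(int(i) for i in seed), nuc  # type: ignore[return-value]


def refine_cells(v: Volume, candidates: list[SegmentedObject],
                 p: RefinementParams = RefinementParams()) -> list[CellRecord]:
    """Region-grow every cell candidate and segment its nucleolus.

    Cells whose interior is degenerate (constant intensity) keep an
    empty nucleolus entry instead of failing the whole run.
    """
    voxvol = v.voxel_volume_um3
    out: list[CellRecord] = []
    for obj in candidates:
        mask = region_grow(v, obj, p)
        zz, yy, xx = np.nonzero(mask)
        centroid = (float(zz.mean()), float(yy.mean()), float(xx.mean()))
        rec = CellRecord(obj.label, (zz, yy, xx), centroid,
                         volume_um3=float(zz.size) * voxvol)
        try:
            pos, nuc = segment_nucleolus(v, mask, p)
        except ValueError:
            pos, nuc = None, None
        if pos is not None:
            nz_, ny_, nx_ = np.nonzero(nuc)
            rec.nucleolus_pos = pos
            rec.nucleolus_coords = (nz_, ny_, nx_)
            rec.nucleolus_volume_um3 = float(nz_.size) * voxvol
        out.append(rec)
    return out


def cells_to_table(cells: list[CellRecord]):
    """Refined-cell table (CSV-ready DataFrame)."""
    import pandas as pd

    rows = []
    for c in cells:
        pos = c.nucleolus_pos or (np.nan, np.nan, np.nan)
        rows.append({
            "label": c.label,
            "z": c.centroid[0], "y": c.centroid[1], "x": c.centroid[2],
            "volume_um3": c.volume_um3,
            "nucleolus_z": pos[0], "nucleolus_y": pos[1], "nucleolus_x": pos[2],
            "nucleolus_volume_um3": (c.nucleolus_volume_um3
                                     if c.nucleolus_volume_um3 is not None else np.nan),
        })
    return pd.DataFrame(rows, columns=["label", "z", "y", "x", "volume_um3",
                                       "nucleolus_z", "nucleolus_y", "nucleolus_x",
                                       "nucleolus_volume_um3"])
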