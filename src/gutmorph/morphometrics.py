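"""Per-object geometry from 3D label grids ("label analysis").

Computes, for every labelled object, its voxel count, physical volume
under the anisotropic spacing, voxel-centre centroid in world nm, and
equivalent spherical diameter ``(6 V / pi)^(1/3)``; assigns vesicles to
cells by maximal voxel overlap; and splits vesicles into the small
secretory (~300 nm) and large dense (~1 µm) size classes at a 600 nm
equivalent-diameter cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import VoxelGrid

__all__ = [
    "ObjectRecord",
    "VesicleAssignment",
    "object_census",
    "census_table",
    "assign_vesicles",
    "assignment_table",
    "classify_size",
    "measure_vesicles",
    "SIZE_CUTOFF_NM",
]

SIZE_CUTOFF_NM = 600.0


@dataclass
class ObjectRecord:
    """Geometry of one labelled object."""

    label: int
    voxel_count: int
    volume_nm3: float
    centroid_nm: tuple[float, float, float]  # (z, y, x) world, voxel centres
    eq_diam_nm: float
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open


@dataclass
class VesicleAssignment:
    """Ownership of one vesicle: the cell with maximal voxel overlap."""

    vesicle_label: int
    owner_cell: int | None  # None when the vesicle overlaps no cell
    size_class: str
    overlap_fraction: float


def equivalent_diameter_nm(volume_nm3: float) -> float:
    return (6.0 * volume_nm3 / math.pi) ** (1.0 / 3.0)


def object_census(labels: VoxelGrid) -> list[ObjectRecord]:
    """One :class:`ObjectRecord` per distinct positive label, sorted by label.

    Background (0) is excluded.  Negative labels are an error.
    """
    values = labels.values
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError("object_census expects an integer label grid")
    if values.size and np.issubdtype(values.dtype, np.signedinteger):
        if values.min() < 0:
            raise ValueError("label grid contains negative labels")

    max_label = int(values.max()) if values.size else 0
    if max_label == 0:
        return []
    flat = values.ravel()
    nz = np.flatnonzero(flat)
    labs = flat[nz].astype(np.int64)
    counts = np.bincount(labs, minlength=max_label + 1)
    present = np.nonzero(counts[1:])[0] + 1

    # Per-label index sums over the occupied voxels only -> centroids.
    coords = np.unravel_index(nz, values.shape)
    sums = [
        np.bincount(labs, weights=coords[axis], minlength=max_label + 1)
        for axis in range(3)
    ]

    slices = ndimage.find_objects(values)
    voxvol = labels.voxel_volume_nm3
    spacing = labels.spacing_nm
    records = []
    for label in present:
        n = int(counts[label])
        centroid_idx = np.array([s[label] / n for s in sums])
        centroid = tuple((centroid_idx + 0.5) * np.asarray(spacing))
        volume = n * voxvol
        sl = slices[label - 1]
        bbox = tuple((s.start, s.stop) for s in sl)
        records.append(
            ObjectRecord(
                label=int(label),
                voxel_count=n,
                volume_nm3=volume,
                centroid_nm=tuple(float(c) for c in centroid),
                eq_diam_nm=equivalent_diameter_nm(volume),
                bbox=bbox,
            )
        )
    return records


def census_table(records: list[ObjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "object_id": [r.label for r in records],
            "voxels": [r.voxel_count for r in records],
            "volume_nm3": [r.volume_nm3 for r in records],
            "centroid_z_nm": [r.centroid_nm[0] for r in records],
            "centroid_y_nm": [r.centroid_nm[1] for r in records],
            "centroid_x_nm": [r.centroid_nm[2] for r in records],
            "eq_diam_nm": [r.eq_diam_nm for r in records],
        }
    )


def classify_size(record: ObjectRecord, cutoff_nm: float = SIZE_CUTOFF_NM) -> str:
    """``secretory`` below the cutoff, ``large`` at or above it."""
    return "secretory" if record.eq_diam_nm < cutoff_nm else "large"


def assign_vesicles(
    vesicle_labels: VoxelGrid,
    cell_labels: VoxelGrid,
    records: list[ObjectRecord] | None = None,
    cutoff_nm: float = SIZE_CUTOFF_NM,
    rule: str = "overlap",
) -> list[VesicleAssignment]:
    """Assign each vesicle to the cell with which it shares the most voxels.

    Ties go to the smaller cell id.  Vesicles overlapping no cell are
    returned with ``owner_cell=None`` (reported, excluded from per-cell
    statistics).  ``rule='centroid'`` instead assigns by the cell label at
    the vesicle's centroid voxel.
    """
    if vesicle_labels.shape != cell_labels.shape:
        raise ValueError(
            f"shape mismatch: vesicles {vesicle_labels.shape} vs cells "
            f"{cell_labels.shape}"
        )
    if rule not in ("overlap", "centroid"):
        raise ValueError(f"unknown ownership rule {rule!r}")
    if records is None:
        records = object_census(vesicle_labels)
    ves = vesicle_labels.values
    cells = cell_labels.values

    assignments = []
    if rule == "centroid":
        for rec in records:
            idx = vesicle_labels.world_to_index(rec.centroid_nm)
            owner = int(cells[tuple(idx)])
            overlap = float(np.count_nonzero(
                (ves[_bbox_slices(rec)] == rec.label)
                & (cells[_bbox_slices(rec)] == owner)
            )) / rec.voxel_count if owner else 0.0
            assignments.append(
                VesicleAssignment(
                    vesicle_label=rec.label,
                    owner_cell=owner if owner > 0 else None,
                    size_class=classify_size(rec, cutoff_nm),
                    overlap_fraction=overlap,
                )
            )
        return assignments

    inside = ves > 0
    v = ves[inside].astype(np.int64)
    c = cells[inside].astype(np.int64)
    n_cell_bins = int(c.max()) + 1 if c.size else 1
    max_ves = int(v.max()) if v.size else 0
    key = v * n_cell_bins + c
    pair_counts = np.bincount(key, minlength=(max_ves + 1) * n_cell_bins)
    for rec in records:
        start = rec.label * n_cell_bins
        cell_overlaps = pair_counts[start + 1 : start + n_cell_bins]  # drop bg
        if cell_overlaps.size and cell_overlaps.max() > 0:
            owner = int(np.argmax(cell_overlaps)) + 1  # argmax = smallest id on ties
            frac = float(cell_overlaps[owner - 1]) / rec.voxel_count
        else:
            owner, frac = None, 0.0
        assignments.append(
            VesicleAssignment(
                vesicle_label=rec.label,
                owner_cell=owner,
                size_class=classify_size(rec, cutoff_nm),
                overlap_fraction=frac,
            )
        )
    return assignments


def _bbox_slices(rec: ObjectRecord):
    return tuple(slice(lo, hi) for lo, hi in rec.bbox)


def assignment_table(assignments: list[VesicleAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "object_id": [a.vesicle_label for a in assignments],
            "owner_cell": [
                a.owner_cell if a.owner_cell is not None else pd.NA
                for a in assignments
            ],
            "size_class": [a.size_class for a in assignments],
            "overlap_fraction": [a.overlap_fraction for a in assignments],
        }
    )


def measure_vesicles(
    vesicle_labels: VoxelGrid,
    cell_labels: VoxelGrid,
    cutoff_nm: float = SIZE_CUTOFF_NM,
    rule: str = "overlap",
) -> pd.DataFrame:
    """The full vesicle table: census + ownership + size class.

    Columns: object_id, owner_cell, size_class, voxels, volume_nm3,
    centroid_z_nm, centroid_y_nm, centroid_x_nm, eq_diam_nm,
    overlap_fraction.
    """
    records = object_census(vesicle_labels)
    assignments = assign_vesicles(
        vesicle_labels, cell_labels, records=records, cutoff_nm=cutoff_nm, rule=rule
    )
    census = census_table(records)
    assign = assignment_table(assignments)
    table = census.merge(assign, on="object_id", validate="one_to_one")
    cols = [
        "object_id",
        "owner_cell",
        "size_class",
        "voxels",
        "volume_nm3",
        "centroid_z_nm",
        "centroid_y_nm",
        "centroid_x_nm",
        "eq_diam_nm",
        "overlap_fraction",
    ]
    return table[cols]
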