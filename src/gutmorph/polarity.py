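"""Apico-basal axis estimation and the apical-vesicle rule.

Epithelial midgut cells are polarized: the apical surface faces the gut
lumen, the basal surface the blastocoel.  The polarization statistic
computed here is the *apical fraction*: the fraction of a cell's
secretory vesicles lying between the base of the nucleus and the apical
membrane, i.e. above the nucleus's apical-most extent along the cell's
apico-basal axis.

Axis estimation: the apical anchor is the centroid of the cell voxels
6-adjacent to the lumen mask; the basal anchor the centroid of the cell
voxels 6-adjacent to background on the side away from the lumen.  When a
cell has no lumen contact a configured global axis may be used instead.

"Base of the nucleus" is interpreted as the nucleus's apical-most extent
along the axis, so the apical compartment is the supranuclear cytoplasm.
A percentile parameter softens this extreme against segmentation noise
(100 = apical-most voxel, 0 = basal-most, 50 = median); alternative
readings of the rule are therefore selectable rather than hard-coded.
Vesicle position is its centroid; a centroid exactly at the nucleus-base
coordinate counts as basal (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .morphometrics import ObjectRecord
from .volio import VoxelGrid

__all__ = [
    "CellAxis",
    "PolarityResult",
    "AxisEstimationError",
    "estimate_axis",
    "nucleus_base",
    "apical_fraction",
    "polarity_table",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class AxisEstimationError(RuntimeError):
    """Raised when a cell's apico-basal axis cannot be estimated."""


@dataclass
class CellAxis:
    """Apico-basal axis of one cell in world coordinates (nm).

    ``axis_coordinate(p)`` measures position along the basal->apical unit
    direction, zero at the basal anchor.
    """

    cell_id: int
    apical_anchor: np.ndarray
    basal_anchor: np.ndarray
    unit_axis: np.ndarray

    def axis_coordinate(self, points_nm) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points_nm, dtype=float))
        coords = (points - self.basal_anchor) @ self.unit_axis
        return coords if coords.size > 1 else coords.reshape(-1)


@dataclass
class PolarityResult:
    """Apical-vesicle statistics of one cell."""

    cell_id: int
    nucleus_base_coord: float
    n_secretory: int
    n_apical: int

    @property
    def apical_fraction(self) -> float:
        """Apical share of secretory vesicles; NaN when the cell has none."""
        if self.n_secretory == 0:
            return float("nan")
        return self.n_apical / self.n_secretory


def _surface_centroid(mask_box, against_box, offset, spacing) -> np.ndarray | None:
    """Centroid (world nm) of mask voxels 6-adjacent to ``against`` voxels."""
    touching = mask_box & ndimage.binary_dilation(against_box, structure=_STRUCT6)
    idx = np.argwhere(touching)
    if idx.size == 0:
        return None
    centroid_idx = idx.mean(axis=0) + np.asarray(offset)
    return (centroid_idx + 0.5) * np.asarray(spacing)


def _mask_centroid_world(idx, offset, spacing) -> np.ndarray:
    return (idx.mean(axis=0) + np.asarray(offset) + 0.5) * np.asarray(spacing)


def estimate_axis(
    cell_mask: VoxelGrid,
    lumen_mask: VoxelGrid,
    background_mask: VoxelGrid | None = None,
    cell_id: int = 0,
    global_axis=None,
    origin=(0, 0, 0),
) -> CellAxis:
    """Estimate one cell's apico-basal axis from its lumen/background contacts.

    ``cell_mask`` and ``lumen_mask`` are boolean (or 0/1) grids; the
    background mask defaults to voxels belonging to neither cells nor
    lumen wherever the caller has that information — here, anything that
    is neither this cell nor lumen is *not* assumed background, so pass
    an explicit ``background_mask`` for multi-cell scenes.

    Falls back to ``global_axis`` (a length-3 vector, axis order z,y,x)
    when the cell does not touch the lumen; with no fallback configured
    this is an error naming the cell.

    ``origin`` is the index offset of the supplied (possibly cropped)
    grids within the full volume, so world coordinates stay consistent
    when callers pass bounding-box crops.
    """
    spacing = cell_mask.spacing_nm
    cell = cell_mask.values.astype(bool)
    idx_all = np.argwhere(cell)
    if idx_all.size == 0:
        raise AxisEstimationError(f"cell {cell_id}: empty mask")

    # Work inside a padded bounding box; dilations there see all contacts.
    lo = np.maximum(idx_all.min(axis=0) - 1, 0)
    hi = np.minimum(idx_all.max(axis=0) + 2, cell_mask.shape)
    lo_world = lo + np.asarray(origin)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    cell_box = cell[box]
    lumen_box = lumen_mask.values[box].astype(bool)
    centroid = _mask_centroid_world(np.argwhere(cell_box), lo_world, spacing)

    apical = _surface_centroid(cell_box, lumen_box, lo_world, spacing)
    if apical is None:
        if global_axis is None:
            raise AxisEstimationError(
                f"cell {cell_id}: no lumen contact and no global axis configured"
            )
        unit = np.asarray(global_axis, dtype=float)
        unit = unit / np.linalg.norm(unit)
        world = (np.argwhere(cell_box) + lo_world + 0.5) * np.asarray(spacing)
        proj = world @ unit
        half_voxel = np.linalg.norm(np.asarray(spacing)) / 2.0
        apical = world[proj >= proj.max() - half_voxel].mean(axis=0)
        basal = world[proj <= proj.min() + half_voxel].mean(axis=0)
        return CellAxis(cell_id, apical, basal, unit)

    # Basal surface: background-adjacent voxels on the side away from the
    # lumen (within 60 degrees of the apical->centroid direction, so that
    # lateral background contacts of edge cells do not skew the anchor).
    basal = None
    if background_mask is not None:
        bg_box = background_mask.values[box].astype(bool)
        touching = cell_box & ndimage.binary_dilation(bg_box, structure=_STRUCT6)
        idx = np.argwhere(touching)
        if idx.size:
            world = (idx + lo_world + 0.5) * np.asarray(spacing)
            d = centroid - apical
            d = d / np.linalg.norm(d)
            rel = world - centroid
            norms = np.linalg.norm(rel, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (rel @ d) / np.where(norms > 0, norms, np.inf)
            keep = cosang > 0.5
            if keep.any():
                basal = world[keep].mean(axis=0)
    if basal is None:
        # No usable background contact: take the cell's extreme voxels
        # along the apical-anchor -> centroid direction.
        d = centroid - apical
        d = d / np.linalg.norm(d)
        world = (np.argwhere(cell_box) + lo_world + 0.5) * np.asarray(spacing)
        proj = (world - apical) @ d
        half_voxel = np.linalg.norm(np.asarray(spacing)) / 2.0
        basal = world[proj >= proj.max() - half_voxel].mean(axis=0)

    diff = apical - basal
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise AxisEstimationError(f"cell {cell_id}: degenerate axis (zero length)")
    return CellAxis(cell_id, apical, basal, diff / norm)


def nucleus_base(
    nucleus_mask: VoxelGrid,
    axis: CellAxis,
    percentile: float = 100.0,
    origin=(0, 0, 0),
) -> float:
    """Axis coordinate of the nucleus's apical-most extent.

    The given percentile of the axis coordinates of nucleus voxel centres;
    the default (100) is the apical-most voxel, marking the boundary of the
    supranuclear (apical) compartment.
    """
    idx = np.argwhere(nucleus_mask.values.astype(bool))
    if idx.size == 0:
        raise ValueError(f"cell {axis.cell_id}: empty nucleus mask")
    world = (idx + np.asarray(origin) + 0.5) * np.asarray(nucleus_mask.spacing_nm)
    coords = (world - axis.basal_anchor) @ axis.unit_axis
    return float(np.percentile(coords, percentile))


def apical_fraction(
    vesicles: list[ObjectRecord] | np.ndarray,
    axis: CellAxis,
    base_coord: float,
) -> PolarityResult:
    """Count apical secretory vesicles of one cell.

    A vesicle is apical iff the axis coordinate of its centroid strictly
    exceeds ``base_coord``.  With no vesicles the fraction is NaN (never a
    division error).
    """
    if len(vesicles) and isinstance(vesicles[0], ObjectRecord):
        centroids = np.array([r.centroid_nm for r in vesicles], dtype=float)
    else:
        centroids = np.asarray(vesicles, dtype=float).reshape(-1, 3)
    n = len(centroids)
    if n == 0:
        return PolarityResult(axis.cell_id, base_coord, 0, 0)
    coords = (centroids - axis.basal_anchor) @ axis.unit_axis
    n_apical = int(np.count_nonzero(coords > base_coord))
    return PolarityResult(axis.cell_id, base_coord, n, n_apical)


def polarity_table(
    cells: VoxelGrid,
    nuclei: VoxelGrid,
    lumen: VoxelGrid,
    vesicle_table: pd.DataFrame,
    percentile: float = 100.0,
    global_axis=None,
    include_large: bool = False,
) -> pd.DataFrame:
    """Per-cell polarity statistics for a whole scene.

    ``vesicle_table`` is the measurement table from
    :func:`gutmorph.morphometrics.measure_vesicles`.  Large (~1 µm)
    vesicles are excluded from the apical statistic unless
    ``include_large`` is set.  Returns columns: cell_id, axis_z, axis_y,
    axis_x, nucleus_base_nm, n_secretory, n_apical, apical_fraction.
    """
    cell_values = cells.values
    spacing = cells.spacing_nm
    background = ((cell_values == 0) & (lumen.values == 0)).astype(np.uint8)
    table = vesicle_table
    if not include_large:
        table = table[table["size_class"] == "secretory"]
    table = table[table["owner_cell"].notna()]

    cell_boxes = ndimage.find_objects(cell_values)
    nuc_boxes = ndimage.find_objects(nuclei.values)
    rows = []
    for cell_id in np.unique(cell_values[cell_values > 0]):
        cell_id = int(cell_id)
        sl = cell_boxes[cell_id - 1]
        # Pad by one voxel so adjacency to lumen/background stays visible.
        padded = tuple(
            slice(max(0, s.start - 1), min(dim, s.stop + 1))
            for s, dim in zip(sl, cell_values.shape)
        )
        origin = tuple(s.start for s in padded)
        cell_mask = VoxelGrid(
            (cell_values[padded] == cell_id).astype(np.uint8), spacing
        )
        axis = estimate_axis(
            cell_mask,
            VoxelGrid(lumen.values[padded], spacing),
            VoxelGrid(background[padded], spacing),
            cell_id=cell_id,
            global_axis=global_axis,
            origin=origin,
        )
        nsl = nuc_boxes[cell_id - 1] if cell_id - 1 < len(nuc_boxes) else None
        if nsl is None:
            raise ValueError(f"cell {cell_id}: no nucleus label in the scene")
        nuc_mask = VoxelGrid(
            (nuclei.values[nsl] == cell_id).astype(np.uint8), spacing
        )
        base = nucleus_base(
            nuc_mask, axis, percentile=percentile, origin=tuple(s.start for s in nsl)
        )
        own = table[table["owner_cell"] == cell_id]
        centroids = own[["centroid_z_nm", "centroid_y_nm", "centroid_x_nm"]].to_numpy()
        result = apical_fraction(centroids, axis, base)
        rows.append(
            {
                "cell_id": cell_id,
                "axis_z": axis.unit_axis[0],
                "axis_y": axis.unit_axis[1],
                "axis_x": axis.unit_axis[2],
                "nucleus_base_nm": base,
                "n_secretory": result.n_secretory,
                "n_apical": result.n_apical,
                "apical_fraction": result.apical_fraction,
            }
        )
    return pd.DataFrame(rows)
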