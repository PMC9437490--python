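"""Threshold + seeded region growing segmentation of grayscale volumes.

The computational analog of interactive "thresholding and magic wand"
segmentation: a band threshold grouped into connected components with a
minimum-size filter, and a wand that grows a connected region from a seed
voxel within an absolute intensity tolerance of the *seed's* value (not a
running mean — the result is therefore order-independent and
deterministic).

Connectivity is defined in index space and ignores voxel anisotropy, the
usual convention of voxel-grid tooling; 6 = faces only, 26 = faces, edges
and corners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import flood

from .volio import VoxelGrid

__all__ = [
    "SegmentationParams",
    "threshold_components",
    "magic_wand",
    "match_to_truth",
]

_CONNECTIVITY_RANK = {6: 1, 26: 3}


@dataclass
class SegmentationParams:
    """Band threshold, connectivity and size filter for segmentation.

    ``wand_tolerance`` is the maximum absolute intensity difference from
    the seed voxel's value for :func:`magic_wand`.
    """

    low: int = 200
    high: int = 255
    connectivity: int = 6
    min_size_voxels: int = 8
    wand_tolerance: int = 30
    wand_connectivity: int = 26

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"low ({self.low}) must be <= high ({self.high})")
        for conn in (self.connectivity, self.wand_connectivity):
            if conn not in _CONNECTIVITY_RANK:
                raise ValueError(f"connectivity must be 6 or 26, got {conn}")
        if self.min_size_voxels < 1:
            raise ValueError("min_size_voxels must be >= 1")
        if self.wand_tolerance < 0:
            raise ValueError("wand_tolerance must be >= 0")


def _check_intensity(grid: VoxelGrid) -> np.ndarray:
    values = grid.values
    if values.dtype != np.uint8:
        raise ValueError(
            f"expected an 8-bit intensity grid, got dtype {values.dtype}"
        )
    return values


def threshold_components(
    intensity: VoxelGrid,
    params: SegmentationParams,
    mask: VoxelGrid | None = None,
) -> VoxelGrid:
    """Band-threshold the volume and label connected components.

    Voxels with ``low <= value <= high`` (restricted to ``mask`` if given)
    are grouped under ``params.connectivity``; components smaller than
    ``min_size_voxels`` are dropped.  Survivors are labelled 1..K in
    descending size order, ties broken by the smaller first voxel in
    (slice, row, column) scan order, so the labelling is deterministic and
    idempotent.  An empty result is not an error.
    """
    values = _check_intensity(intensity)
    binary = (values >= params.low) & (values <= params.high)
    if mask is not None:
        if mask.shape != intensity.shape:
            raise ValueError("mask shape does not match the intensity grid")
        binary &= mask.values > 0

    structure = ndimage.generate_binary_structure(
        3, _CONNECTIVITY_RANK[params.connectivity]
    )
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return VoxelGrid(labels.astype(np.int32), intensity.spacing_nm)

    counts = np.bincount(labels.ravel())
    keep = np.nonzero(counts[1:] >= params.min_size_voxels)[0] + 1
    if keep.size == 0:
        return VoxelGrid(
            np.zeros_like(labels, dtype=np.int32), intensity.spacing_nm
        )

    # First C-order occurrence of each label = its lexicographic anchor.
    flat = labels.ravel()
    order_ids, first_idx = np.unique(flat, return_index=True)
    anchor = np.zeros(n + 1, dtype=np.int64)
    anchor[order_ids] = first_idx
    rank = sorted(keep.tolist(), key=lambda l: (-int(counts[l]), int(anchor[l])))

    mapping = np.zeros(n + 1, dtype=np.int32)
    for new_id, old_id in enumerate(rank, start=1):
        mapping[old_id] = new_id
    return VoxelGrid(mapping[labels], intensity.spacing_nm)


def magic_wand(
    intensity: VoxelGrid,
    seed_voxel: tuple[int, int, int],
    params: SegmentationParams,
) -> np.ndarray:
    """Seeded region growing: the connected set of voxels within
    ``wand_tolerance`` of the seed voxel's value.

    Returns a boolean mask; the seed is always included.  The seed must be
    in bounds.
    """
    values = _check_intensity(intensity)
    seed = tuple(int(i) for i in seed_voxel)
    if len(seed) != 3 or any(
        not 0 <= i < s for i, s in zip(seed, intensity.shape)
    ):
        raise IndexError(
            f"seed voxel {seed_voxel} out of bounds for shape {intensity.shape}"
        )
    return flood(
        values,
        seed,
        tolerance=params.wand_tolerance,
        connectivity=_CONNECTIVITY_RANK[params.wand_connectivity],
    )


def match_to_truth(
    pred_labels: VoxelGrid,
    true_labels: VoxelGrid,
    iou_threshold: float = 0.5,
):
    """Greedy one-to-one matching of predicted to true objects by IoU.

    Candidate (true, pred) pairs with positive voxel overlap are matched
    greedily in descending IoU order (ties: smaller true id, then smaller
    pred id).  A true object counts as detected when its match reaches
    ``iou_threshold``.

    Returns ``(pairs, summary)``: a DataFrame with columns true_id,
    pred_id, intersection, iou, detected; and a dict with n_true, n_pred,
    n_detected, n_missed, n_spurious.
    """
    if pred_labels.shape != true_labels.shape:
        raise ValueError(
            f"shape mismatch: pred {pred_labels.shape} vs truth {true_labels.shape}"
        )
    pred = pred_labels.values.astype(np.int64)
    true = true_labels.values.astype(np.int64)
    true_ids, true_counts = np.unique(true[true > 0], return_counts=True)
    pred_ids, pred_counts = np.unique(pred[pred > 0], return_counts=True)
    true_size = dict(zip(true_ids.tolist(), true_counts.tolist()))
    pred_size = dict(zip(pred_ids.tolist(), pred_counts.tolist()))

    either = (pred > 0) & (true > 0)
    n_pred_bins = int(pred.max()) + 1 if pred_ids.size else 1
    key = true[either] * n_pred_bins + pred[either]
    pair_key, inter = np.unique(key, return_counts=True)
    candidates = []
    for k, i in zip(pair_key.tolist(), inter.tolist()):
        t, p = divmod(k, n_pred_bins)
        union = true_size[t] + pred_size[p] - i
        candidates.append((i / union, t, p, i))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    matched_true: set[int] = set()
    matched_pred: set[int] = set()
    rows = []
    for iou, t, p, i in candidates:
        if t in matched_true or p in matched_pred:
            continue
        matched_true.add(t)
        matched_pred.add(p)
        rows.append(
            {
                "true_id": t,
                "pred_id": p,
                "intersection": i,
                "iou": iou,
                "detected": iou >= iou_threshold,
            }
        )
    pairs = pd.DataFrame(
        rows, columns=["true_id", "pred_id", "intersection", "iou", "detected"]
    )
    n_detected = int(pairs["detected"].sum()) if len(pairs) else 0
    summary = {
        "n_true": int(true_ids.size),
        "n_pred": int(pred_ids.size),
        "n_detected": n_detected,
        "n_missed": int(true_ids.size) - n_detected,
        "n_spurious": int(pred_ids.size) - n_detected,
    }
    return pairs, summary
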