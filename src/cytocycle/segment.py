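"""Label-free segmentation of the cell in a brightfield tile.

The flow medium gives enough contrast that the cell boundary can be found
without any stain: edges are enhanced with a Sobel gradient magnitude, the
enhanced image is thresholded (Otsu, floored at background mean + 2 s.d.
so featureless tiles do not segment their own noise), and the mask is
cleaned by morphological closing, hole filling and largest-component
selection. The darkfield channel is deliberately never segmented — its
speckle does not depict the cell's physical outline and is analysed
whole-frame downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .montage import estimate_background

__all__ = ["SegmentationParams", "SegmentationResult", "segment_brightfield", "qc_filter"]

QC_FLAGS = ("no_object", "touches_border_heavily", "multiple_objects", "too_small", "missing_values")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the brightfield segmentation.

    min_area: components below this (px^2) are debris. closing_radius:
    disk radius for the morphological closing that bridges the rim.
    floor_nsd: the threshold never drops below background mean +
    ``floor_nsd`` background s.d. of the enhanced image's border frame.
    """

    min_area: int = 50
    closing_radius: int = 2
    floor_nsd: float = 2.0
    border_occupancy_flag: float = 0.15


@dataclass
class SegmentationResult:
    mask: np.ndarray
    object_found: bool
    qc_flags: Set[str] = field(default_factory=set)


def segment_brightfield(
    tile: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> SegmentationResult:
    """Segment the single cell in a brightfield tile.

    Pipeline: Sobel gradient magnitude -> global threshold (Otsu with a
    background-statistics floor) -> closing -> hole filling -> keep the
    largest connected component (doublets are flagged, not split).
    Non-finite pixels yield a ``missing_values`` flag, never an exception.
    """
    tile = np.asarray(tile, dtype=float)
    flags: Set[str] = set()
    if not np.all(np.isfinite(tile)):
        flags.add("missing_values")
        return SegmentationResult(np.zeros(tile.shape, bool), False, flags)

    edges = filters.sobel(tile)
    bg = estimate_background(edges)
    floor = bg.mean + params.floor_nsd * bg.std
    if np.ptp(edges) > 0:
        thresh = max(float(filters.threshold_otsu(edges)), floor)
    else:
        thresh = floor
    binary = edges > thresh
    binary = morphology.closing(binary, morphology.disk(params.closing_radius))
    binary = ndi.binary_fill_holes(binary)
    # the gradient band straddles the true boundary by ~1 px outward;
    # peel one pixel so mask areas track the physical outline
    binary = morphology.erosion(binary, morphology.disk(1))

    labels, n = ndi.label(binary)
    if n == 0:
        flags.add("no_object")
        return SegmentationResult(np.zeros(tile.shape, bool), False, flags)
    areas = np.bincount(labels.ravel())[1:]
    order = np.argsort(areas)[::-1]
    largest = order[0] + 1
    if areas[order[0]] < params.min_area:
        flags.add("too_small")
        return SegmentationResult(np.zeros(tile.shape, bool), False, flags)
    if np.sum(areas >= params.min_area) > 1:
        flags.add("multiple_objects")
    mask = labels == largest

    border = np.concatenate([mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]])
    if border.mean() > params.border_occupancy_flag:
        flags.add("touches_border_heavily")
    return SegmentationResult(mask, True, flags)


def qc_filter(
    results: Sequence[Tuple[str, SegmentationResult]],
    discard_flags: Sequence[str] = ("no_object", "too_small", "missing_values"),
) -> Tuple[List[str], List[Tuple[str, str]]]:
    """Partition cells into kept and discarded by their QC flags.

    ``results`` is a sequence of (cell_id, SegmentationResult). The default
    policy discards cells with no usable object or missing values;
    ``multiple_objects`` is *retained* by default because telophase cells
    legitimately present as doublets (pass an extended ``discard_flags``
    to drop them too).

    Returns (kept ids, [(discarded id, reason), ...]); the reason is the
    first offending flag in ``discard_flags`` order.
    """
    kept: List[str] = []
    discarded: List[Tuple[str, str]] = []
    for cell_id, res in results:
        reason = next((f for f in discard_flags if f in res.qc_flags), None)
        if reason is None and not res.object_found:
            reason = "no_object"
        if reason is None:
            kept.append(cell_id)
        else:
            discarded.append((cell_id, reason))
    return kept, discarded
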