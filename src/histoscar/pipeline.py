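"""End-to-end characterization of one ROI: segmentation → density → orientation → DV."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fibers import (
    AiryKernel,
    OrientationField,
    VarianceMap,
    airy_kernel,
    collagen_density,
    directional_variance,
    estimate_orientation,
)
from .segmentation import SegmentationResult, segment_tissue
from .stats import RoiMetrics, summarize_roi

__all__ = ["CharacterizationResult", "characterize"]


@dataclass
class CharacterizationResult:
    """Everything the collagen characterization pipeline computes for one ROI."""

    segmentation: SegmentationResult
    density: np.ndarray
    orientation: OrientationField
    variance: VarianceMap
    kernel: AiryKernel
    metrics: RoiMetrics


def characterize(
    image: np.ndarray,
    roi_mask: np.ndarray | None = None,
    kernel_radius: int = 16,
    window_radius: int = 8,
    n_angles: int = 18,
    seed: int = 0,
    restarts: int = 10,
    roi_id: str = "",
    group: str = "",
) -> CharacterizationResult:
    """Run the full collagen characterization on one RGB ROI.

    An optional binary ``roi_mask`` restricts the analysis: pixels outside it
    are forced to background before the density and orientation stages (the
    clustering itself still sees the whole frame, which stabilizes the
    centroids).
    """
    seg = segment_tissue(image, seed=seed, restarts=restarts)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        seg = SegmentationResult(
            cas=seg.cas & roi_mask,
            fs=seg.fs & roi_mask,
            bs=seg.bs | ~roi_mask,
            role_map=seg.role_map,
        )
    kernel = airy_kernel(kernel_radius)
    density = collagen_density(seg.cas, kernel)
    orientation = estimate_orientation(seg.cas, window_radius=window_radius, n_angles=n_angles)
    variance = directional_variance(orientation, kernel, density=density)
    metrics = summarize_roi(seg, density, variance, roi_id=roi_id, group=group)
    return CharacterizationResult(
        segmentation=seg,
        density=density,
        orientation=orientation,
        variance=variance,
        kernel=kernel,
        metrics=metrics,
    )
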