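"""Airway-bifurcation detection by counting dark lumen regions.

Looking down the bronchoscope axis, the non-illuminated airway lumen appears
as a large dark area; at a branching point two or more daughter lumina are
visible at once.  Frames are therefore classified by thresholding the dark
(complemented-luminance) pixels, cleaning the mask morphologically, labelling
connected components, and keeping only regions above a size threshold: two or
more surviving regions identify a branching view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, opening

from .frame_io import Frame

__all__ = [
    "DarkRegion",
    "BranchDetectorParams",
    "segment_dark_regions",
    "is_branching",
]


@dataclass(frozen=True)
class DarkRegion:
    """A connected dark (non-illuminated) area surviving the size filter."""

    label_id: int
    area: int
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (top, left, bottom, right), half-open


@dataclass(frozen=True)
class BranchDetectorParams:
    """Tunables of the dark-region segmentation.

    dark_threshold
        Luminance at or below which a pixel counts as dark (lumen interiors
        in endoscopy are near-black).
    se_radius
        Disk radius of the structuring element used for the morphological
        opening (dilation of the erosion) then closing (erosion of the
        dilation) that clean the mask.
    min_area_fraction
        Minimum region area as a fraction of the frame's pixel count; encodes
        "relatively large".
    """

    dark_threshold: int = 40
    se_radius: int = 5
    min_area_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.dark_threshold < 255:
            raise ValueError("dark_threshold must lie in (0, 255)")
        if self.se_radius < 1:
            raise ValueError("se_radius must be at least 1")
        if not 0.0 < self.min_area_fraction < 1.0:
            raise ValueError("min_area_fraction must lie in (0, 1)")


def segment_dark_regions(
    frame: Frame, params: BranchDetectorParams | None = None
) -> list[DarkRegion]:
    """Find large dark regions in a frame, sorted by area descending.

    The binary mask is the complement of the luminance thresholded at
    ``255 - dark_threshold`` (equivalently, luminance <= dark_threshold),
    cleaned by opening then closing with a disk of ``se_radius``; 8-connected
    components are labelled and regions with area >= ``min_area_fraction`` of
    the frame's pixels are returned.
    """
    params = params or BranchDetectorParams()
    mask = (255.0 - frame.pixels) >= (255.0 - params.dark_threshold)
    se = disk(params.se_radius)
    mask = opening(mask, se)
    mask = closing(mask, se)
    labelled = label(mask, connectivity=2)  # 8-connected
    min_area = params.min_area_fraction * frame.height * frame.width
    regions = [
        DarkRegion(
            label_id=r.label,
            area=int(r.area),
            centroid=(float(r.centroid[0]), float(r.centroid[1])),
            bbox=tuple(int(v) for v in r.bbox),
        )
        for r in regionprops(labelled)
        if r.area >= min_area
    ]
    regions.sort(key=lambda r: (-r.area, r.label_id))
    return regions


def is_branching(regions: list[DarkRegion]) -> bool:
    """True iff two or more large dark areas are present (a branching view)."""
    return len(regions) >= 2
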