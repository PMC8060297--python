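"""Whole-section and compartment masks, areas and DAPI-based cellularity.

The section footprint is reconstructed from the marker and DAPI channels by
lighten-merging them, thresholding at the lowest grey value, closing small
boundary gaps morphologically and filling enclosed holes. Compartments
(epithelial band vs stromal interior) are split by mask arithmetic, and
areas are reported in pixels, mm^2 and percentages.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk

from .image_ops import (
    BinaryMask,
    GreyImage,
    binarize,
    blend_darken,
    blend_lighten,
    invert_mask,
)

__all__ = [
    "SectionGeometry",
    "AreaReport",
    "build_section_mask",
    "split_compartments",
    "measure_areas",
    "cellularity",
    "write_area_reports_csv",
]

DEFAULT_CLOSE_RADIUS_PX = 15


@dataclass
class SectionGeometry:
    """Section mask plus its exact epithelial/stromal partition."""

    section_mask: BinaryMask
    epithelial_mask: BinaryMask
    stromal_mask: BinaryMask
    resolution_um_per_px: float

    def __post_init__(self) -> None:
        shapes = {
            self.section_mask.pixels.shape,
            self.epithelial_mask.pixels.shape,
            self.stromal_mask.pixels.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"mask dimensions differ: {shapes}")
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution_um_per_px must be positive")
        epi = self.epithelial_mask.as_bool
        stro = self.stromal_mask.as_bool
        sect = self.section_mask.as_bool
        if (epi & stro).any():
            raise ValueError("epithelial and stromal masks overlap")
        if ((epi | stro) != sect).any():
            raise ValueError("epithelial + stromal masks do not partition the section mask")


@dataclass
class AreaReport:
    """Histomorphometry of one section."""

    whole_section_px: int
    whole_section_mm2: float
    epithelial_fraction_pct: float
    stromal_fraction_pct: float
    cellularity_pct: float | None = None
    sample_id: str = ""
    section_index: int = 0


def build_section_mask(
    marker: GreyImage,
    dapi: GreyImage,
    close_radius_px: int = DEFAULT_CLOSE_RADIUS_PX,
) -> BinaryMask:
    """Reconstruct the whole-section footprint from two channels.

    Lighten-merge marker and DAPI, binarize at grey value 1 (so every stained
    pixel turns white), close boundary gaps with a disk of the given radius
    (the automated stand-in for manual brush tracing) and fill enclosed
    holes, yielding a solid white section on black background.
    """
    if close_radius_px < 0:
        raise ValueError(f"close_radius_px must be >= 0, got {close_radius_px}")
    merged = blend_lighten(marker, dapi)
    mask = binarize(merged, 1, role="section")
    grid = mask.as_bool
    if not grid.any():
        warnings.warn("both channels are all-zero; returning an empty section mask")
        return BinaryMask.from_bool(grid, role="section")
    if close_radius_px > 0:
        grid = closing(grid, disk(close_radius_px)).astype(bool)
    grid = ndimage.binary_fill_holes(grid)
    return BinaryMask.from_bool(grid, role="section")


def split_compartments(
    section: BinaryMask,
    epithelial_mask: BinaryMask,
    resolution_um_per_px: float = 1.0,
) -> SectionGeometry:
    """Partition the section into epithelial and stromal compartments.

    The stromal mask is the section darken-blended with the inverted
    epithelial mask, so epithelial | stromal == section exactly. Epithelial
    pixels outside the section are cleared with a warning.
    """
    if section.pixels.shape != epithelial_mask.pixels.shape:
        raise ValueError(
            f"section {section.pixels.shape} and epithelial "
            f"{epithelial_mask.pixels.shape} dimensions differ"
        )
    epi = epithelial_mask.as_bool
    sect = section.as_bool
    outside = epi & ~sect
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} epithelial px lie outside the section mask; clearing them"
        )
        epi = epi & sect
    epi_mask = BinaryMask.from_bool(epi, role="epithelial")
    section_img = GreyImage(section.pixels)
    inverted = invert_mask(epi_mask)
    stromal_px = blend_darken(section_img, GreyImage(inverted.pixels)).pixels
    return SectionGeometry(
        section_mask=BinaryMask(section.pixels.copy(), role="section"),
        epithelial_mask=epi_mask,
        stromal_mask=BinaryMask(stromal_px, role="stromal"),
        resolution_um_per_px=resolution_um_per_px,
    )


def measure_areas(
    geometry: SectionGeometry,
    sample_id: str = "",
    section_index: int = 0,
    cellularity_pct: float | None = None,
) -> AreaReport:
    """Pixel counts, mm^2 and compartment fractions for one section.

    mm^2 = px count x (um/px / 1000)^2. Fractions are percentages of the
    whole-section area and sum to 100 exactly (the partition is enforced
    before any rounding).
    """
    whole = geometry.section_mask.white_px
    if whole == 0:
        raise ValueError("section mask is empty; areas undefined")
    mm_per_px = geometry.resolution_um_per_px / 1000.0
    epi = geometry.epithelial_mask.white_px
    stro = geometry.stromal_mask.white_px
    return AreaReport(
        whole_section_px=whole,
        whole_section_mm2=whole * mm_per_px**2,
        epithelial_fraction_pct=epi / whole * 100.0,
        stromal_fraction_pct=stro / whole * 100.0,
        cellularity_pct=cellularity_pct,
        sample_id=sample_id,
        section_index=section_index,
    )


def cellularity(dapi: GreyImage, mask: BinaryMask, t: int = 10) -> float:
    """Percent of in-mask area covered by DAPI signal at or above ``t``.

    This expression-domain measure of the nuclear counterstain is the
    cell-content proxy; no cells are counted.
    """
    if dapi.pixels.shape != mask.pixels.shape:
        raise ValueError(
            f"image {dapi.pixels.shape} and mask {mask.pixels.shape} dimensions differ"
        )
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {t}")
    sel = mask.as_bool
    total = int(np.count_nonzero(sel))
    if total == 0:
        raise ValueError("mask is empty; cellularity undefined")
    supra = int(np.count_nonzero(dapi.pixels[sel] >= t))
    return supra / total * 100.0


def write_area_reports_csv(reports: Iterable[AreaReport], path) -> None:
    """Emit one CSV row per section."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "sample_id",
                "section_index",
                "whole_px",
                "whole_mm2",
                "epi_pct",
                "stroma_pct",
                "cellularity_pct",
            ]
        )
        for r in reports:
            writer.writerow(
                [
                    r.sample_id,
                    r.section_index,
                    r.whole_section_px,
                    f"{r.whole_section_mm2:.7g}",
                    f"{r.epithelial_fraction_pct:.4f}",
                    f"{r.stromal_fraction_pct:.4f}",
                    "" if r.cellularity_pct is None else f"{r.cellularity_pct:.4f}",
                ]
            )
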