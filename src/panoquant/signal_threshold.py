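"""Signal-threshold determination: separating true fluorescence from the
low-grey-value autofluorescence floor.

The procedure has three stages. First, the background floor is found by
scanning binary thresholds upward until (almost) no background pixel
survives. Second, candidate thresholds in the weak-signal range are scored:
each candidate's binary threshold image is reduced to a top-down profile and
regressed against the profile of the original region; the candidate whose
binary footprint best co-varies spatially with the actual signal (highest
R^2) wins. Third, the chosen threshold is applied by zeroing sub-threshold
pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .image_ops import BinaryMask, GreyImage, binarize, blend_darken
from .quantify import td_profile

__all__ = [
    "ThresholdScan",
    "DEFAULT_CANDIDATES",
    "background_floor",
    "threshold_scan",
    "apply_threshold",
    "select_weak_signal_roi",
]

DEFAULT_CANDIDATES: tuple[int, ...] = (10, 20, 30, 40, 50)


@dataclass
class ThresholdScan:
    """Result of scoring candidate signal thresholds.

    The selected threshold is the candidate with the highest coefficient of
    determination; ties resolve to the lowest grey value (retaining more
    signal).
    """

    candidates: list[int]
    r2_per_candidate: list[float]
    p_per_candidate: list[float]
    selected_threshold: int
    excluded: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.selected_threshold not in self.candidates:
            raise ValueError("selected_threshold must be one of the scored candidates")
        for r2 in self.r2_per_candidate:
            if not 0.0 <= r2 <= 1.0 + 1e-12:
                raise ValueError(f"R^2 out of [0, 1]: {r2}")


def background_floor(
    img: GreyImage,
    background_mask: BinaryMask,
    tolerance_fraction: float = 0.0,
) -> int:
    """Smallest threshold that clears the background.

    Returns the smallest t in 1..255 such that at most ``tolerance_fraction``
    of background-mask pixels survive ``binarize(img, t)``. At tolerance 0
    this is ``max(background GV) + 1``.
    """
    if not 0.0 <= tolerance_fraction < 1.0:
        raise ValueError(f"tolerance_fraction must lie in [0, 1), got {tolerance_fraction}")
    sel = background_mask.as_bool
    if img.pixels.shape != background_mask.pixels.shape:
        raise ValueError(
            f"image {img.pixels.shape} and mask {background_mask.pixels.shape} "
            "dimensions differ"
        )
    n_bg = int(np.count_nonzero(sel))
    if n_bg == 0:
        raise ValueError("background mask is empty")
    counts = np.bincount(img.pixels[sel].ravel(), minlength=256)
    # survivors(t) = number of background px with GV >= t
    survivors = counts[::-1].cumsum()[::-1]
    for t in range(1, 256):
        if survivors[t] <= tolerance_fraction * n_bg:
            return t
    raise ValueError(
        "background contains grey value 255 beyond tolerance; no clearing threshold exists"
    )


def threshold_scan(
    roi: GreyImage,
    candidates: tuple[int, ...] | list[int] = DEFAULT_CANDIDATES,
) -> ThresholdScan:
    """Score candidate thresholds by spatial correlation with the signal.

    For each candidate t the region is binarized at t and both the binary
    image and the original are reduced to top-down profiles over the full
    frame. The original profile (dependent) is regressed on the binary
    profile (independent); R^2 and p are recorded. Candidates whose binary
    profile is constant are excluded with a warning. The candidate with the
    maximal R^2 is selected, ties going to the lowest grey value.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    candidates = sorted(int(c) for c in candidates)
    for c in candidates:
        if not 0 <= c <= 255:
            raise ValueError(f"candidate threshold {c} out of [0, 255]")
    if roi.height < 2:
        raise ValueError("ROI must span at least 2 rows")
    full = BinaryMask.from_bool(np.ones(roi.shape, dtype=bool), role="section")
    orig = td_profile(roi, full).row_means
    if np.var(orig) == 0:
        raise ValueError("ROI profile has zero variance; cannot regress")

    kept: list[int] = []
    r2s: list[float] = []
    ps: list[float] = []
    excluded: list[int] = []
    for t in candidates:
        bimg = GreyImage(
            binarize(roi, t).pixels, resolution_um_per_px=roi.resolution_um_per_px
        )
        bprof = td_profile(bimg, full).row_means
        if np.var(bprof) == 0:
            warnings.warn(f"candidate {t}: constant binary profile; excluded from scan")
            excluded.append(t)
            continue
        fit = stats.linregress(bprof, orig)
        kept.append(t)
        r2s.append(float(fit.rvalue**2))
        ps.append(float(fit.pvalue))
    if not kept:
        raise ValueError("all candidate thresholds gave degenerate regressions")
    best = int(np.argmax(r2s))  # argmax returns the first (lowest GV) on ties
    return ThresholdScan(
        candidates=kept,
        r2_per_candidate=r2s,
        p_per_candidate=ps,
        selected_threshold=kept[best],
        excluded=excluded,
    )


def apply_threshold(img: GreyImage, t: int) -> GreyImage:
    """Zero every pixel below ``t``; supra-threshold pixels are unchanged.

    Equivalent to darken-blending the image with its own binary threshold
    mask, the compositing route used interactively.
    """
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {t}")
    keep = binarize(img, t)
    return blend_darken(img, GreyImage(keep.pixels, resolution_um_per_px=img.resolution_um_per_px))


def select_weak_signal_roi(
    img: GreyImage,
    section_mask: BinaryMask,
    floor: int,
    upper: int = 50,
    window: tuple[int, int] = (128, 128),
    stride: int = 16,
) -> tuple[int, int, int, int]:
    """Pick the in-section window richest in weak signal.

    Scans windows of the given (height, width) on a stride grid and scores
    each by (weak - strong) / in-section pixels, where weak pixels have grey
    values in [floor, upper] and strong pixels lie above ``upper``: a good
    weak-signal region both contains weak staining and avoids strong
    staining. This automates the interactive selection of such a region.
    """
    h, w = window
    if h > img.height or w > img.width:
        raise ValueError(f"window {window} exceeds image {img.shape}")
    sect = section_mask.as_bool
    weak = ((img.pixels >= floor) & (img.pixels <= upper) & sect).astype(np.float64)
    strong = ((img.pixels > upper) & sect).astype(np.float64)
    weak_sum = _box_sum(weak, h, w)
    strong_sum = _box_sum(strong, h, w)
    sect_sum = _box_sum(sect.astype(np.float64), h, w)
    rows = np.arange(0, img.height - h + 1, stride)
    cols = np.arange(0, img.width - w + 1, stride)
    sub_weak = weak_sum[np.ix_(rows, cols)]
    sub_strong = strong_sum[np.ix_(rows, cols)]
    sub_sect = sect_sum[np.ix_(rows, cols)]
    # require the window to be mostly inside the section
    valid = sub_sect >= 0.5 * h * w
    if not valid.any():
        raise ValueError("no window lies at least half inside the section")
    score = np.where(valid, (sub_weak - sub_strong) / np.maximum(sub_sect, 1.0), -np.inf)
    i, j = np.unravel_index(np.argmax(score), score.shape)
    return int(rows[i]), int(cols[j]), h, w


def _box_sum(arr: np.ndarray, h: int, w: int) -> np.ndarray:
    """Sum of every h x w window (valid positions only)."""
    c = arr.cumsum(axis=0).cumsum(axis=1)
    c = np.pad(c, ((1, 0), (1, 0)))
    return c[h:, w:] - c[:-h, w:] - c[h:, :-w] + c[:-h, :-w]
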