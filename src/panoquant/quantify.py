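"""Grey-value histograms, expression domains, top-down plot profiles and
group-level hypothesis tests.

A histogram always reports 256 values regardless of image size, so relative
(fractional) pixel counts are directly comparable between samples. A top-down
(T-D) profile lists the mean in-section grey value of every pixel row from
image top to bottom; its length equals the image height and its x-axis is
calibrated to micrometres via the pixel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .image_ops import BinaryMask, GreyImage

__all__ = [
    "GVHistogram",
    "TDProfile",
    "GroupTestResult",
    "gv_histogram",
    "truncate_histogram",
    "expression_domain",
    "td_profile",
    "compare_groups",
]


@dataclass
class GVHistogram:
    """Absolute and relative pixel counts per grey value 0..255.

    ``rel_counts_pct`` expresses each bin as a percentage of
    ``reference_area_px`` (the masked reference area), which makes histograms
    from sections of different sizes comparable. When a signal threshold is
    set, only bins at or above it are reported (``reported_*`` views); the
    underlying 256 bins are retained.
    """

    abs_counts: np.ndarray  # (256,) int64
    reference_area_px: int
    threshold: int | None = None

    def __post_init__(self) -> None:
        self.abs_counts = np.asarray(self.abs_counts, dtype=np.int64)
        if self.abs_counts.shape != (256,):
            raise ValueError(f"abs_counts must have 256 bins, got {self.abs_counts.shape}")
        if self.reference_area_px <= 0:
            raise ValueError("reference_area_px must be positive")
        if self.threshold is not None and not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must lie in [0, 255], got {self.threshold}")

    @property
    def rel_counts_pct(self) -> np.ndarray:
        return self.abs_counts / self.reference_area_px * 100.0

    @property
    def n_reported(self) -> int:
        """Number of reported bins: 256 with no threshold, 256 - t with one."""
        t = self.threshold or 0
        return 256 - t

    @property
    def reported_gvs(self) -> np.ndarray:
        return np.arange(self.threshold or 0, 256)

    @property
    def reported_abs(self) -> np.ndarray:
        return self.abs_counts[self.threshold or 0 :]

    @property
    def reported_rel_pct(self) -> np.ndarray:
        return self.rel_counts_pct[self.threshold or 0 :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gv": self.reported_gvs, "abs": self.reported_abs, "rel_pct": self.reported_rel_pct}
        )


@dataclass
class TDProfile:
    """Top-down plot profile: one mean grey value per pixel row."""

    row_means: np.ndarray  # (H,) float64, background-excluded row means
    in_section_counts: np.ndarray  # (H,) int64 in-mask pixels per row
    resolution_um_per_px: float
    marker_name: str = ""
    sample_id: str = ""
    section_index: int = 0

    def __post_init__(self) -> None:
        self.row_means = np.asarray(self.row_means, dtype=np.float64)
        self.in_section_counts = np.asarray(self.in_section_counts, dtype=np.int64)
        if self.row_means.ndim != 1 or self.row_means.shape != self.in_section_counts.shape:
            raise ValueError("row_means and in_section_counts must be equal-length 1-D arrays")
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution_um_per_px must be positive")

    def __len__(self) -> int:
        return self.row_means.size

    @property
    def rel_pct(self) -> np.ndarray:
        """Row means as a percentage of the maximal row mean (0 if all-zero)."""
        top = self.row_means.max() if self.row_means.size else 0.0
        if top <= 0:
            return np.zeros_like(self.row_means)
        return self.row_means / top * 100.0

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(len(self)) * self.resolution_um_per_px

    @property
    def total_distance_um(self) -> float:
        """Calibrated scanning distance from the first to the last row."""
        return (len(self) - 1) * self.resolution_um_per_px

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": np.arange(len(self)),
                "mean_gv": self.row_means,
                "n_px": self.in_section_counts,
                "rel_pct": self.rel_pct,
                "um": self.positions_um,
            }
        )


@dataclass
class GroupTestResult:
    test: Literal["t_test", "anova"]
    statistic: float
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def gv_histogram(img: GreyImage, mask: BinaryMask) -> GVHistogram:
    """Tally in-mask pixels per grey value; always 256 bins.

    The mask area is the reference for relative counts, so the relative
    histogram sums to 100%.
    """
    if img.pixels.shape != mask.pixels.shape:
        raise ValueError(
            f"image {img.pixels.shape} and mask {mask.pixels.shape} dimensions differ"
        )
    sel = mask.as_bool
    area = int(np.count_nonzero(sel))
    if area == 0:
        raise ValueError("mask is empty; histogram reference area would be zero")
    counts = np.bincount(img.pixels[sel].ravel(), minlength=256)
    return GVHistogram(abs_counts=counts, reference_area_px=area)


def truncate_histogram(hist: GVHistogram, t: int) -> GVHistogram:
    """Apply a signal-threshold cut-off: bins below ``t`` leave the report.

    The remaining report has exactly ``256 - t`` values (246 at the usual
    threshold of 10).
    """
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {t}")
    return GVHistogram(
        abs_counts=hist.abs_counts.copy(),
        reference_area_px=hist.reference_area_px,
        threshold=t,
    )


def expression_domain(hist: GVHistogram, t: int | None = None) -> float:
    """Percentage of the reference area covered by supra-threshold signal.

    Sums the relative counts over grey values ``t..255``. With ``t`` omitted,
    the histogram's own threshold (or 0) is used.
    """
    if t is None:
        t = hist.threshold or 0
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {t}")
    return float(hist.rel_counts_pct[t:].sum())


def td_profile(img: GreyImage, section_mask: BinaryMask) -> TDProfile:
    """Mean grey value of every pixel row, background excluded.

    The binary whole-section mask is the reference: for each row the mean is
    taken over in-mask pixels only, so pixels outside the section never
    influence the profile. Rows with no in-mask pixels get mean 0.
    """
    if img.pixels.shape != section_mask.pixels.shape:
        raise ValueError(
            f"image {img.pixels.shape} and mask {section_mask.pixels.shape} dimensions differ"
        )
    sel = section_mask.as_bool
    counts = sel.sum(axis=1).astype(np.int64)
    if counts.sum() == 0:
        raise ValueError("section mask is empty")
    sums = np.where(sel, img.pixels, 0).sum(axis=1, dtype=np.float64)
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return TDProfile(
        row_means=means,
        in_section_counts=counts,
        resolution_um_per_px=img.resolution_um_per_px,
        marker_name=img.marker_name,
        sample_id=img.sample_id,
        section_index=img.section_index,
    )


def _pool_group(obs) -> np.ndarray:
    """Flatten a group given as scalars, vectors, or histograms."""
    parts = []
    for o in np.atleast_1d(np.asarray(obs, dtype=object)).ravel():
        if isinstance(o, GVHistogram):
            parts.append(o.reported_rel_pct)
        else:
            parts.append(np.atleast_1d(np.asarray(o, dtype=np.float64)))
    return np.concatenate(parts)


def compare_groups(
    groups: Sequence,
    test: Literal["t_test", "anova"] = "t_test",
    alpha: float | None = None,
    equal_var: bool = True,
) -> GroupTestResult:
    """Compare >= 2 groups of observations.

    ``t_test`` (two groups of scalars, e.g. morphometry parameters; default
    alpha 0.1) uses the pooled-variance Student test by default so that for
    two groups ``F == t**2`` against the one-way ANOVA. ``anova`` (default
    alpha 0.01) pools each group's observations — scalars, vectors, or
    truncated histograms (their reported relative counts) — into a single
    observation vector per group and runs one-way ANOVA.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = [_pool_group(g) for g in groups]
    for i, g in enumerate(pooled):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    if test == "t_test":
        if len(pooled) != 2:
            raise ValueError("t_test requires exactly two groups")
        if alpha is None:
            alpha = 0.1
        res = stats.ttest_ind(pooled[0], pooled[1], equal_var=equal_var)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # identical constant groups -> zero difference
            stat, p = 0.0, 1.0
    elif test == "anova":
        if alpha is None:
            alpha = 0.01
        res = stats.f_oneway(*pooled)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):
            stat, p = 0.0, 1.0
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupTestResult(test=test, statistic=stat, p_value=p, alpha=alpha)
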