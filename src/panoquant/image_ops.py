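"""Pixel-level primitives for 8-bit panoramic images.

Everything downstream (masking, thresholding, histograms, profiles) is built
from the handful of operations defined here: per-pixel min/max blending,
binarization, mask inversion, desaturation of colour images, dynamic-range
heatmap classification, and a reference colour step-tablet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "GreyImage",
    "BinaryMask",
    "ColorImage",
    "blend_darken",
    "blend_lighten",
    "binarize",
    "invert_mask",
    "desaturate",
    "heatmap_classify",
    "HeatmapResult",
    "HEATMAP_CLASSES",
    "HEATMAP_COLORS",
    "make_step_tablet",
    "step_tablet_layout",
    "read_grey",
    "write_grey",
    "read_mask",
    "write_mask",
    "write_color",
    "PIXEL_COUNT_WARN_LIMIT",
]

Channel = Literal["dapi", "marker"]
MaskRole = Literal["section", "epithelial", "stromal", "threshold", "background"]

#: Pixel-count ceiling above which some desktop tools refuse to load an image.
#: We only warn and process anyway.
PIXEL_COUNT_WARN_LIMIT = 120_000_000


def _as_u8_grid(pixels, what: str) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{what} must be a 2-D grid, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"{what} must hold integer grey values, got dtype {arr.dtype}")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError(
                f"{what} grey values must lie in [0, 255], got range "
                f"[{arr.min()}, {arr.max()}]"
            )
        arr = arr.astype(np.uint8)
    return arr


@dataclass
class GreyImage:
    """A 2-D grid of 8-bit grey values plus acquisition metadata.

    Parameters
    ----------
    pixels
        ``(H, W)`` integer array with values in ``[0, 255]``.
    resolution_um_per_px
        Physical pixel size in micrometres per pixel; must be positive.
    channel
        ``"dapi"`` for the nuclear counterstain, ``"marker"`` for an
        antibody channel.
    """

    pixels: np.ndarray
    resolution_um_per_px: float = 1.0
    channel: Channel = "marker"
    marker_name: str = ""
    sample_id: str = ""
    section_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = _as_u8_grid(self.pixels, "GreyImage.pixels")
        if not self.resolution_um_per_px > 0:
            raise ValueError(
                f"resolution_um_per_px must be positive, got {self.resolution_um_per_px}"
            )
        if self.channel not in ("dapi", "marker"):
            raise ValueError(f"channel must be 'dapi' or 'marker', got {self.channel!r}")
        if self.section_index < 0:
            raise ValueError(f"section_index must be >= 0, got {self.section_index}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A grey image restricted to the two values 0 and 255."""

    pixels: np.ndarray
    role: MaskRole = "section"

    def __post_init__(self) -> None:
        self.pixels = _as_u8_grid(self.pixels, "BinaryMask.pixels")
        bad = np.setdiff1d(np.unique(self.pixels), [0, 255])
        if bad.size:
            raise ValueError(
                f"BinaryMask may only contain 0 and 255, found values {bad.tolist()}"
            )
        if self.role not in ("section", "epithelial", "stromal", "threshold", "background"):
            raise ValueError(f"unknown mask role {self.role!r}")

    @classmethod
    def from_bool(cls, grid: np.ndarray, role: MaskRole = "section") -> "BinaryMask":
        return cls(np.where(np.asarray(grid, dtype=bool), 255, 0).astype(np.uint8), role=role)

    @property
    def as_bool(self) -> np.ndarray:
        return self.pixels == 255

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def white_px(self) -> int:
        return int(np.count_nonzero(self.pixels))


@dataclass
class ColorImage:
    """An RGB image with 8-bit channels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"ColorImage.pixels must have shape (H, W, 3), got {arr.shape}")
        if arr.dtype != np.uint8:
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"RGB values must be integers, got dtype {arr.dtype}")
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("RGB values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _require_same_shape(a, b, op: str) -> None:
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(
            f"{op} requires equal dimensions, got {a.pixels.shape} and {b.pixels.shape}"
        )


def blend_darken(foreground: GreyImage, background: GreyImage) -> GreyImage:
    """Per-pixel minimum of two grey images ("Darken" compositing).

    R = min{F, B}; commutative in pixel values. Metadata is carried over from
    the foreground image.
    """
    _require_same_shape(foreground, background, "blend_darken")
    return replace(foreground, pixels=np.minimum(foreground.pixels, background.pixels))


def blend_lighten(a: GreyImage, b: GreyImage) -> GreyImage:
    """Per-pixel maximum of two grey images ("Lighten" compositing)."""
    _require_same_shape(a, b, "blend_lighten")
    return replace(a, pixels=np.maximum(a.pixels, b.pixels))


def binarize(img: GreyImage, t: int, role: MaskRole = "threshold") -> BinaryMask:
    """Threshold a grey image: pixels with GV >= ``t`` become 255, others 0.

    The threshold is inclusive, so ``t = 1`` whitens every nonzero pixel.
    """
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {t}")
    return BinaryMask.from_bool(img.pixels >= t, role=role)


def invert_mask(mask: BinaryMask) -> BinaryMask:
    """Swap 0 and 255. Involution: ``invert(invert(m)) == m``."""
    return BinaryMask((255 - mask.pixels.astype(np.int16)).astype(np.uint8), role=mask.role)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round is round-half-to-even; grey values are non-negative so
    # floor(x + 0.5) is round-half-away-from-zero.
    return np.floor(x + 0.5)


def desaturate(img: ColorImage, mode: str = "luminosity") -> GreyImage:
    """Convert an RGB image to grey values.

    ``average`` mode uses ``(R + G + B) / 3``; ``luminosity`` mode uses the
    Rec.601 weights ``0.299 R + 0.587 G + 0.114 B``. Both round half away
    from zero so outputs are bit-reproducible. Different desktop tools pick
    different formulas, which is why both are exposed.
    """
    rgb = img.pixels.astype(np.float64)
    if mode == "average":
        grey = rgb.sum(axis=2) / 3.0
    elif mode == "luminosity":
        grey = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    else:
        raise ValueError(f"unknown desaturation mode {mode!r}; use 'average' or 'luminosity'")
    out = np.clip(_round_half_away(grey), 0, 255).astype(np.uint8)
    return GreyImage(out)


#: Inclusive grey-value ranges of the dynamic-range heatmap classes.
HEATMAP_CLASSES: tuple[tuple[int, int, str], ...] = (
    (0, 9, "black"),
    (10, 49, "blue"),
    (50, 149, "green"),
    (150, 254, "red"),
    (255, 255, "yellow"),
)

HEATMAP_COLORS: dict[str, tuple[int, int, int]] = {
    "black": (0, 0, 0),
    "blue": (0, 0, 255),
    "green": (0, 255, 0),
    "red": (255, 0, 0),
    "yellow": (255, 255, 0),
}


@dataclass
class HeatmapResult:
    """Output of :func:`heatmap_classify`."""

    labels: np.ndarray  # (H, W) uint8, class index 0..4
    counts: dict[str, int]
    rgb: ColorImage


def heatmap_classify(img: GreyImage) -> HeatmapResult:
    """Assign each pixel to one of five intensity classes.

    Classes partition [0, 255]: black 0-9, blue 10-49, green 50-149,
    red 150-254, yellow 255. Also renders the classification as an RGB
    image in the fixed class colours.
    """
    gv = img.pixels
    labels = np.zeros(gv.shape, dtype=np.uint8)
    counts: dict[str, int] = {}
    palette = np.zeros((len(HEATMAP_CLASSES), 3), dtype=np.uint8)
    for idx, (lo, hi, name) in enumerate(HEATMAP_CLASSES):
        sel = (gv >= lo) & (gv <= hi)
        labels[sel] = idx
        counts[name] = int(np.count_nonzero(sel))
        palette[idx] = HEATMAP_COLORS[name]
    rgb = ColorImage(palette[labels])
    return HeatmapResult(labels=labels, counts=counts, rgb=rgb)


_STEP_TABLET_PANELS: tuple[tuple[str, tuple[int, int, int]], ...] = (
    ("white", (255, 255, 255)),
    ("green", (0, 255, 0)),
    ("red", (255, 0, 0)),
    ("blue", (0, 0, 255)),
    ("yellow", (255, 255, 0)),
    ("cyan", (0, 255, 255)),
    ("magenta", (255, 0, 255)),
)

_PANEL_W = 50
_TABLET_H = 150
_TABLET_W = 750


def step_tablet_layout() -> dict[str, slice]:
    """Column slices of the seven colour panels within the step tablet.

    Panels are 50 columns wide and alternate with 50-column black gaps:
    gap, panel, gap, panel, ..., gap (8 gaps + 7 panels = 750 columns).
    """
    layout = {}
    col = _PANEL_W  # leading black gap
    for name, _ in _STEP_TABLET_PANELS:
        layout[name] = slice(col, col + _PANEL_W)
        col += 2 * _PANEL_W  # panel + trailing gap
    return layout


def make_step_tablet() -> ColorImage:
    """Generate the 750x150 reference colour step-tablet.

    Seven 50-column panels (white, green, red, blue, yellow, cyan, magenta),
    each 150 px tall, separated by 50-column black spaces. Desaturating the
    tablet and profiling it left-to-right exercises the full grey scale.
    """
    pixels = np.zeros((_TABLET_H, _TABLET_W, 3), dtype=np.uint8)
    layout = step_tablet_layout()
    for name, rgb in _STEP_TABLET_PANELS:
        pixels[:, layout[name], :] = rgb
    return ColorImage(pixels)


# ---------------------------------------------------------------------------
# File I/O: 8-bit greyscale / RGB TIFF and PNG
# ---------------------------------------------------------------------------

def _warn_if_huge(arr: np.ndarray, path) -> None:
    n = arr.shape[0] * arr.shape[1]
    if n > PIXEL_COUNT_WARN_LIMIT:
        warnings.warn(
            f"{path}: {n} px exceeds the ~{PIXEL_COUNT_WARN_LIMIT} px limit of some "
            "desktop tools; processing anyway",
            stacklevel=3,
        )


def _read_array(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path))


def read_grey(path, resolution_um_per_px: float = 1.0, **meta) -> GreyImage:
    """Read an 8-bit greyscale TIFF/PNG as a :class:`GreyImage`."""
    arr = _read_array(Path(path))
    if arr.ndim == 3:  # tolerate grey stored as RGB
        same = (arr[..., 0] == arr[..., 1]).all() and (arr[..., 1] == arr[..., 2]).all()
        if not same:
            raise ValueError(f"{path} is a colour image; desaturate it explicitly")
        arr = arr[..., 0]
    _warn_if_huge(arr, path)
    return GreyImage(arr, resolution_um_per_px=resolution_um_per_px, **meta)


def read_mask(path, role: MaskRole = "section") -> BinaryMask:
    """Read a binary {0, 255} mask from TIFF/PNG."""
    arr = _read_array(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    _warn_if_huge(arr, path)
    return BinaryMask(arr, role=role)


def _write_array(arr: np.ndarray, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def write_grey(img: GreyImage, path) -> None:
    _warn_if_huge(img.pixels, path)
    _write_array(img.pixels, Path(path))


def write_mask(mask: BinaryMask, path) -> None:
    _write_array(mask.pixels, Path(path))


def write_color(img: ColorImage, path) -> None:
    _write_array(img.pixels, Path(path))
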