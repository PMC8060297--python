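"""Seeded generator of gingiva-like panoramic test images.

Produces a blob-shaped tissue section on a dark background with an
epithelial band along the boundary and a stromal interior, a DAPI nuclei
speckle, and marker channels composed of a sub-floor autofluorescence
texture plus compartment-biased smooth signal fields with an optional
shared hotspot (an inflammatory-infiltrate stand-in). Every truth quantity
used by the measurement modules — section geometry, per-marker expression
domain, autofluorescence floor, latent field correlations — is recorded so
round-trip tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_ops import BinaryMask, GreyImage
from .morphometry import SectionGeometry

__all__ = [
    "MarkerConfig",
    "SectionParams",
    "SectionTruth",
    "SyntheticSample",
    "generate_section",
    "generate_serial_stack",
    "generate_weak_signal_roi",
]

DEFAULT_RESOLUTION_UM_PER_PX = 0.53937


@dataclass(frozen=True)
class MarkerConfig:
    """Recipe for one marker channel."""

    name: str
    domain_pct: float = 30.0  # % of section area covered by supra-floor signal
    floor_gv: int = 10  # first grey value accepted as signal
    epithelial_bias: float = 0.0  # latent-field offset inside the epithelial band (sd units)
    hotspot_center: tuple[float, float] | None = None  # relative (row, col) in [0, 1]
    hotspot_width: float = 0.15  # gaussian sigma relative to min(height, width)
    hotspot_strength: float = 2.0  # latent-field amplitude (sd units)
    smooth_sigma_px: float = 40.0
    noise_sd: float = 0.3  # white-noise amplitude added to the latent field
    weak_patch: bool = False  # embed a weak-signal region (for threshold scans)
    weak_patch_size: tuple[int, int] = (128, 96)


@dataclass(frozen=True)
class SectionParams:
    """Canvas and tissue parameters for one synthetic section.

    The default canvas is a desk-scale stand-in for multi-thousand-pixel
    panoramas; pass a larger height/width for full-size generation.
    """

    height: int = 512
    width: int = 352
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    epithelial_fraction: float = 0.25  # of section area, as a band along the boundary
    nuclei_density: float = 0.004  # nuclei per in-section px
    nucleus_radius_px: int = 3
    markers: tuple[MarkerConfig, ...] = (MarkerConfig("marker"),)
    boundary_amplitude: float = 0.08  # relative radial perturbation of the blob outline
    blob_fill: float = 0.62  # blob radii relative to half the canvas
    background_salt_pct: float = 2.0  # % of background px carrying sub-floor autofluorescence
    dapi_floor_gv: int = 10


@dataclass
class SectionTruth:
    """Ground truth recorded at generation time."""

    geometry: SectionGeometry
    domain_pct: dict[str, float]
    floor_gv: dict[str, int]
    epithelial_fraction_pct: float
    field_correlations: dict[tuple[str, str], float]


@dataclass
class SyntheticSample:
    dapi: GreyImage
    markers: dict[str, GreyImage]
    truth: SectionTruth
    seed: int
    params: SectionParams


def _validate(params: SectionParams) -> None:
    if params.height < 32 or params.width < 32:
        raise ValueError(f"canvas {params.height}x{params.width} too small")
    if not 0.0 < params.epithelial_fraction < 1.0:
        raise ValueError(
            f"epithelial_fraction must lie in (0, 1); {params.epithelial_fraction} would make "
            "the band wider than the blob"
        )
    if not params.nuclei_density >= 0:
        raise ValueError("nuclei_density must be >= 0")
    if not 0.0 < params.blob_fill <= 1.0:
        raise ValueError("blob_fill must lie in (0, 1]")
    if not 0.0 <= params.background_salt_pct <= 100.0:
        raise ValueError("background_salt_pct must lie in [0, 100]")
    if not 2 <= params.dapi_floor_gv <= 254:
        raise ValueError(f"dapi_floor_gv must lie in [2, 254], got {params.dapi_floor_gv}")
    names = [m.name for m in params.markers]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate marker names {names}")
    for m in params.markers:
        if not 0.0 < m.domain_pct <= 100.0:
            raise ValueError(f"{m.name}: domain_pct must lie in (0, 100], got {m.domain_pct}")
        if not 2 <= m.floor_gv <= 254:
            raise ValueError(f"{m.name}: floor_gv must lie in [2, 254], got {m.floor_gv}")


def _section_blob(params: SectionParams, rng: np.random.Generator) -> np.ndarray:
    """Blob-shaped footprint: an ellipse with a low-order radial perturbation."""
    h, w = params.height, params.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = params.blob_fill * h / 2.0, params.blob_fill * w / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    u = (yy - cy) / ry
    v = (xx - cx) / rx
    rho = np.hypot(u, v)
    theta = np.arctan2(u, v)
    scale = np.ones_like(rho)
    for k in range(2, 7):
        amp = rng.normal(0.0, params.boundary_amplitude / k)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        scale += amp * np.cos(k * theta + phase)
    mask = rho <= scale
    return ndimage.binary_fill_holes(mask)


def _split_band(section: np.ndarray, fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Epithelial band of the requested area fraction along the boundary."""
    dist = ndimage.distance_transform_edt(section)
    inside = dist[section]
    cutoff = np.quantile(inside, fraction)
    epi = section & (dist <= cutoff)
    return epi, section & ~epi


def _latent_field(cfg: MarkerConfig, params: SectionParams, epi: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    h, w = params.height, params.width
    base = ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.smooth_sigma_px)
    sd = base.std()
    if sd > 0:
        base = base / sd
    if cfg.epithelial_bias:
        base = base + cfg.epithelial_bias * epi
    if cfg.hotspot_center is not None:
        cy = cfg.hotspot_center[0] * (h - 1)
        cx = cfg.hotspot_center[1] * (w - 1)
        sigma = cfg.hotspot_width * min(h, w)
        yy, xx = np.mgrid[0:h, 0:w]
        base = base + cfg.hotspot_strength * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
        )
    if cfg.noise_sd:
        base = base + cfg.noise_sd * rng.standard_normal((h, w))
    return base


def weak_signal_field(
    shape: tuple[int, int],
    rng: np.random.Generator,
    floor: int = 10,
) -> np.ndarray:
    """Weak-signal texture whose best-fitting binary threshold is ``floor``.

    Five speckle classes with grey values spread over the weak range
    (floor+4 ... floor+44). The dimmest class is dense and carries the
    dominant smooth row-density variance; brighter classes are sparse, with
    geometrically decaying variance and decaying coupling to the dim
    class's density field. Binarizing at the floor captures the dominant
    spatial structure; every higher candidate threshold erases the then
    most informative class, so the profile-regression R^2 of successive
    thresholds decreases.
    """
    h, w = shape
    img = rng.integers(0, floor, (h, w)).astype(np.int64)
    taken = np.zeros((h, w), dtype=bool)

    def smooth(sigma=5.0):
        z = ndimage.gaussian_filter1d(rng.standard_normal(h), sigma)
        return z / z.std()

    z_dim = smooth()
    # (gv offset, mean density, lognormal sd, coupling to the dim field)
    classes = [
        (14, 0.05, 0.50, 0.50),
        (24, 0.04, 0.42, 0.35),
        (34, 0.03, 0.34, 0.20),
        (44, 0.02, 0.26, 0.08),
        (4, 0.30, 0.70, 1.0),  # dim class placed last so it is never blocked
    ]
    for off, m, s, rho in classes:
        z = rho * z_dim + np.sqrt(1.0 - rho**2) * smooth()
        dens = np.clip(m * np.exp(s * z - s * s / 2.0), 0.0, 0.8)
        sel = (rng.random((h, w)) < dens[:, None]) & ~taken
        img[sel] = floor + off + rng.integers(0, 4, int(sel.sum()))
        taken |= sel
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_weak_signal_roi(
    seed: int = 0,
    height: int = 160,
    width: int = 200,
    floor: int = 10,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
) -> GreyImage:
    """A stand-alone weak-signal region with a constructed floor grey value."""
    rng = np.random.default_rng(seed)
    return GreyImage(
        weak_signal_field((height, width), rng, floor=floor),
        resolution_um_per_px=resolution_um_per_px,
    )


def _patch_rect(section: np.ndarray, size: tuple[int, int]) -> tuple[slice, slice]:
    """Patch rectangle centred on the section's centre of mass."""
    cy, cx = ndimage.center_of_mass(section)
    h, w = section.shape
    ph, pw = size
    r0 = int(np.clip(round(cy - ph / 2), 0, h - ph))
    c0 = int(np.clip(round(cx - pw / 2), 0, w - pw))
    return slice(r0, r0 + ph), slice(c0, c0 + pw)


def _render_marker(latent: np.ndarray, section: np.ndarray, cfg: MarkerConfig,
                   params: SectionParams, rng: np.random.Generator) -> np.ndarray:
    """Quantile-map the latent field: top ``domain_pct`` of in-section pixels
    become supra-floor signal; the rest become sub-floor autofluorescence.

    With ``weak_patch`` set, a weak-signal region is stamped at the section
    centre first and the smooth-field quantile is adjusted so the total
    expression domain still matches ``domain_pct``.
    """
    img = np.zeros(latent.shape, dtype=np.float64)
    section_px = int(section.sum())
    target_signal = cfg.domain_pct / 100.0 * section_px

    free = section.copy()
    if cfg.weak_patch:
        rows, cols = _patch_rect(section, cfg.weak_patch_size)
        patch = weak_signal_field(
            (rows.stop - rows.start, cols.stop - cols.start), rng, floor=cfg.floor_gv
        )
        region = np.zeros_like(section)
        region[rows, cols] = True
        region &= section
        # stamp patch values where the rectangle overlaps the section
        sub = img[rows, cols]
        inside = section[rows, cols]
        sub[inside] = patch[inside]
        img[rows, cols] = sub
        free &= ~region
        patch_signal = int(np.count_nonzero(img[region] >= cfg.floor_gv))
        target_signal -= patch_signal
        if target_signal < 0:
            raise ValueError(
                f"{cfg.name}: weak patch alone exceeds the configured domain "
                f"({cfg.domain_pct}%)"
            )

    free_vals = latent[free]
    frac = target_signal / max(int(free.sum()), 1)
    frac = min(max(frac, 0.0), 1.0)
    if frac >= 1.0:
        cut = free_vals.min() - 1.0
        signal = free.copy()
    elif frac <= 0.0:
        cut = free_vals.max()
        signal = np.zeros_like(free)
    else:
        cut = np.quantile(free_vals, 1.0 - frac)
        signal = free & (latent > cut)
    top = free_vals.max()
    if top > cut:
        img[signal] = cfg.floor_gv + (latent[signal] - cut) / (top - cut) * (255 - cfg.floor_gv)
    else:
        img[signal] = cfg.floor_gv
    auto = free & ~signal
    lo = free_vals.min()
    if cut > lo:
        img[auto] = (latent[auto] - lo) / (cut - lo) * (cfg.floor_gv - 1)
    _salt_background(img, section, cfg.floor_gv, params.background_salt_pct, rng)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _salt_background(img: np.ndarray, section: np.ndarray, floor: int,
                     salt_pct: float, rng: np.random.Generator) -> None:
    """Scatter sub-floor autofluorescence over the dark background, making
    sure the maximal background grey value is exactly ``floor - 1`` so the
    floor is a recoverable truth quantity."""
    if salt_pct <= 0 or floor < 2:
        return
    bg_idx = np.flatnonzero(~section.ravel())
    if bg_idx.size == 0:
        return
    n = max(1, int(round(salt_pct / 100.0 * bg_idx.size)))
    chosen = rng.choice(bg_idx, size=min(n, bg_idx.size), replace=False)
    values = rng.integers(1, floor, size=chosen.size)
    values[0] = floor - 1
    img.ravel()[chosen] = values


def _render_dapi(section: np.ndarray, params: SectionParams,
                 rng: np.random.Generator) -> np.ndarray:
    h, w = params.height, params.width
    img = np.zeros((h, w), dtype=np.float64)
    in_idx = np.flatnonzero(section.ravel())
    n_nuclei = int(round(params.nuclei_density * in_idx.size))
    if n_nuclei > 0:
        centers = rng.choice(in_idx, size=min(n_nuclei, in_idx.size), replace=False)
        amps = rng.integers(150, 256, size=centers.size)
        seeds = np.zeros(h * w, dtype=np.float64)
        seeds[centers] = amps
        seeds = seeds.reshape(h, w)
        r = params.nucleus_radius_px
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        footprint = (yy**2 + xx**2) <= r**2
        img = ndimage.maximum_filter(seeds, footprint=footprint)
        img[~section] = 0.0
    floor = params.dapi_floor_gv
    auto = section & (img == 0)
    img[auto] = rng.integers(1, floor, size=int(auto.sum()))
    _salt_background(img, section, floor, params.background_salt_pct, rng)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_section(params: SectionParams = SectionParams(), seed: int = 0) -> SyntheticSample:
    """Generate one synthetic section; bit-identical for identical seeds."""
    _validate(params)
    rng = np.random.default_rng(seed)
    section = _section_blob(params, rng)
    epi, stro = _split_band(section, params.epithelial_fraction)
    geometry = SectionGeometry(
        section_mask=BinaryMask.from_bool(section, role="section"),
        epithelial_mask=BinaryMask.from_bool(epi, role="epithelial"),
        stromal_mask=BinaryMask.from_bool(stro, role="stromal"),
        resolution_um_per_px=params.resolution_um_per_px,
    )
    dapi = GreyImage(
        _render_dapi(section, params, rng),
        resolution_um_per_px=params.resolution_um_per_px,
        channel="dapi",
        marker_name="DAPI",
    )
    latents: dict[str, np.ndarray] = {}
    markers: dict[str, GreyImage] = {}
    for cfg in params.markers:
        latent = _latent_field(cfg, params, epi, rng)
        latents[cfg.name] = latent
        markers[cfg.name] = GreyImage(
            _render_marker(latent, section, cfg, params, rng),
            resolution_um_per_px=params.resolution_um_per_px,
            channel="marker",
            marker_name=cfg.name,
        )
    correlations: dict[tuple[str, str], float] = {}
    names = list(latents)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            c = np.corrcoef(latents[a][section], latents[b][section])[0, 1]
            correlations[(a, b)] = float(c)
    truth = SectionTruth(
        geometry=geometry,
        domain_pct={m.name: m.domain_pct for m in params.markers},
        floor_gv={m.name: m.floor_gv for m in params.markers},
        epithelial_fraction_pct=params.epithelial_fraction * 100.0,
        field_correlations=correlations,
    )
    return SyntheticSample(dapi=dapi, markers=markers, truth=truth, seed=seed, params=params)


def _shift_down(arr: np.ndarray, dy: int) -> np.ndarray:
    """Integer vertical shift with zero fill."""
    if dy == 0:
        return arr.copy()
    out = np.zeros_like(arr)
    if dy > 0:
        out[dy:] = arr[:-dy]
    else:
        out[:dy] = arr[-dy:]
    return out


def _shift_sample(parent: SyntheticSample, dy: int, section_index: int,
                  marker_subset: Sequence[str]) -> SyntheticSample:
    def g(img: GreyImage) -> GreyImage:
        return replace(img, pixels=_shift_down(img.pixels, dy), section_index=section_index)

    def m(mask: BinaryMask) -> BinaryMask:
        return BinaryMask(_shift_down(mask.pixels, dy), role=mask.role)

    geo = parent.truth.geometry
    truth = SectionTruth(
        geometry=SectionGeometry(
            section_mask=m(geo.section_mask),
            epithelial_mask=m(geo.epithelial_mask),
            stromal_mask=m(geo.stromal_mask),
            resolution_um_per_px=geo.resolution_um_per_px,
        ),
        domain_pct={k: v for k, v in parent.truth.domain_pct.items() if k in marker_subset},
        floor_gv={k: v for k, v in parent.truth.floor_gv.items() if k in marker_subset},
        epithelial_fraction_pct=parent.truth.epithelial_fraction_pct,
        field_correlations=dict(parent.truth.field_correlations),
    )
    return SyntheticSample(
        dapi=g(parent.dapi),
        markers={k: g(v) for k, v in parent.markers.items() if k in marker_subset},
        truth=truth,
        seed=parent.seed,
        params=parent.params,
    )


def generate_serial_stack(
    params: SectionParams = SectionParams(),
    n_sections: int = 6,
    jitter: float = 0.0,
    seed: int = 0,
    one_marker_per_section: bool = True,
) -> list[SyntheticSample]:
    """Generate ``n_sections`` serial sections sharing one parent shape.

    Section k is the parent translated down by ``round(k * jitter)`` px, so
    shape agreement with the reference decays monotonically along the stack
    and ``jitter = 0`` gives identical sections. With
    ``one_marker_per_section`` each section keeps DAPI plus a single marker,
    cycling through the configured marker recipes — the serial-section
    staining scheme where every section carries a different antibody.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    parent = generate_section(params, seed)
    names = list(parent.markers)
    stack = []
    for k in range(n_sections):
        dy = int(round(k * jitter))
        dy = min(dy, params.height - 1)
        subset = [names[k % len(names)]] if (one_marker_per_section and names) else names
        stack.append(_shift_sample(parent, dy, k, subset))
    return stack
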