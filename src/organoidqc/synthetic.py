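"""Seeded generators for section images, growth series, and score batches.

The section generator renders the phenotypes the measurements are built for:
a disk-shaped organoid with a raggedness-perturbed boundary; a DAPI channel of
filled nuclear disks whose union coverage hits a target area-based density
(coverage = density x 80 um^2); cell-less holes carved from all channels; a
GFAP channel painted to a requested coverage fraction; and a gamma-H2AX
channel with well-separated foci of known size.  Every image ships with a
ground-truth record computed from the actual rendered masks, so round-trip
tests compare measurements against what was truly drawn, not just what was
requested.

Intensity model (8-bit): background 10, intra-tissue baseline 60, stained
structures 140-255 with a mild radial falloff inside each nucleus.  Any fixed
threshold in (75, 135) recovers a stained-structure footprint exactly; (25,
55) recovers the tissue footprint.  Defaults of 100 (structures) and 40
(tissue) are used throughout.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .growth import GrowthSeries
from .image_quant import NUCLEUS_AREA_UM2, SectionImage

__all__ = [
    "SyntheticSectionSpec",
    "SyntheticBatchSpec",
    "make_section",
    "make_growth",
    "make_batch",
    "STRUCTURE_THRESHOLD",
    "TISSUE_THRESHOLD",
]

#: Fixed thresholds that exactly recover the generated masks.
STRUCTURE_THRESHOLD = 100.0
TISSUE_THRESHOLD = 40.0

_BACKGROUND = 10.0
_TISSUE_BASE = 60.0
_NUCLEUS_PEAK = 255.0
_NUCLEUS_RIM = 140.0


@dataclass(frozen=True)
class SyntheticSectionSpec:
    """Ground-truth parameters for one generated section image."""

    canvas_px: int = 512
    pixel_size: float = 2.0  # um / px
    radius_um: float = 400.0
    raggedness: float = 0.05  # 0 (smooth circle) .. 1 (very ragged)
    density: float = 10_000.0  # target cells / mm^2 (area-based)
    nucleus_radius_um: float = 5.0
    nucleus_radius_sd_um: float = 1.0
    hole_radii_um: tuple[float, ...] = ()
    gfap_fraction: float = 0.0  # fraction of section surface, 0..1
    puncta_count: int = 0
    puncta_radius_um: float = 3.0
    seed: int = 0
    organoid_id: str = "synthetic"
    slice_id: str = "s1"

    def __post_init__(self) -> None:
        if not 0 <= self.raggedness <= 1:
            raise ValueError("raggedness must be in [0, 1]")
        if not 0 <= self.gfap_fraction <= 1:
            raise ValueError("gfap_fraction must be in [0, 1]")
        max_density = 1.0e6 / NUCLEUS_AREA_UM2
        if not 0 <= self.density <= max_density:
            raise ValueError(
                f"density {self.density:g} unachievable: the area-based model "
                f"caps at {max_density:g} cells/mm^2"
            )
        if self.radius_um * 1.05 > self.canvas_px * self.pixel_size / 2:
            raise ValueError("organoid radius does not fit on the canvas")


@dataclass(frozen=True)
class SyntheticBatchSpec:
    """Parameters for a batch of raw initial-QC score rows."""

    n_organoids: int = 58
    quality_levels: tuple[str, ...] = ("high",)  # cycled over organoids
    seed: int = 0

    def __post_init__(self) -> None:
        known = {"high", "medium", "low", "destroyed"}
        bad = set(self.quality_levels) - known
        if bad:
            raise ValueError(f"unknown quality levels {sorted(bad)}")


def _rng_for(seed: int, *ids: object) -> np.random.Generator:
    """One independent stream per image, stable under reordering."""
    entropy = [seed & 0x7FFFFFFF] + [zlib.crc32(str(i).encode()) for i in ids]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _organoid_mask(spec: SyntheticSectionSpec, rng: np.random.Generator) -> np.ndarray:
    """Disk with a smoothly perturbed (ragged) boundary."""
    n = spec.canvas_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = (yy - c) * spec.pixel_size, (xx - c) * spec.pixel_size
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    # Low-order Fourier perturbation of the radius: smooth lobes, amplitude
    # proportional to raggedness.
    radius = np.full_like(r, spec.radius_um)
    for k in range(2, 7):
        amp = spec.raggedness * spec.radius_um * rng.uniform(0.0, 0.08)
        phase = rng.uniform(0, 2 * np.pi)
        radius += amp * np.cos(k * theta + phase)
    return r <= radius


def _paint_disks_to_coverage(
    allowed: np.ndarray,
    target_px: int,
    radius_px_sampler,
    rng: np.random.Generator,
    max_iter: int = 2_000_000,
) -> np.ndarray:
    """Union of random disks inside ``allowed`` until coverage >= target_px."""
    n = allowed.shape[0]
    mask = np.zeros_like(allowed)
    coverage = 0
    ys, xs = np.nonzero(allowed)
    if ys.size == 0 or target_px == 0:
        return mask
    it = 0
    while coverage < target_px and it < max_iter:
        it += 1
        j = rng.integers(ys.size)
        cy, cx = int(ys[j]), int(xs[j])
        rad = max(1, int(round(radius_px_sampler())))
        y0, y1 = max(0, cy - rad), min(n, cy + rad + 1)
        x0, x1 = max(0, cx - rad), min(n, cx + rad + 1)
        yy, xx = np.ogrid[y0:y1, x0:x1]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        patch = disk & allowed[y0:y1, x0:x1] & ~mask[y0:y1, x0:x1]
        coverage += int(patch.sum())
        mask[y0:y1, x0:x1] |= disk & allowed[y0:y1, x0:x1]
    return mask


def make_section(spec: SyntheticSectionSpec) -> tuple[SectionImage, dict]:
    """Render a section image and its ground-truth record.

    Returns ``(image, truth)`` where ``truth`` holds the rendered (not merely
    requested) values: section area, DAPI area, area-based density, hole
    fraction, GFAP coverage relative to both section and DAPI areas, and the
    puncta count.
    """
    rng = _rng_for(spec.seed, spec.organoid_id, spec.slice_id)
    px = spec.pixel_size
    px_area = px**2
    organoid = _organoid_mask(spec, rng)
    section_px = int(organoid.sum())

    # Holes: disks carved at random interior positions.  A tissue margin is
    # kept between each hole and the border, so holes stay enclosed cavities
    # rather than boundary indentations.
    holes = np.zeros_like(organoid)
    ys, xs = np.nonzero(organoid)
    margin = 3  # px
    for radius_um in spec.hole_radii_um:
        rad = int(round(radius_um / px))
        for _ in range(10_000):
            j = rng.integers(ys.size)
            cy, cx = int(ys[j]), int(xs[j])
            yy, xx = np.ogrid[: organoid.shape[0], : organoid.shape[1]]
            r2 = (yy - cy) ** 2 + (xx - cx) ** 2
            if (( r2 <= (rad + margin) ** 2) <= organoid).all():
                holes |= r2 <= rad**2
                break
    tissue = organoid & ~holes

    # DAPI: nucleus disks to the union coverage implied by the target density.
    # Coverage target is defined over the full section surface (holes filled),
    # matching the density normalization.
    target_frac = spec.density * NUCLEUS_AREA_UM2 / 1.0e6
    target_px = int(round(target_frac * section_px))
    nucleus_sampler = lambda: rng.normal(spec.nucleus_radius_um, spec.nucleus_radius_sd_um) / px
    dapi_mask = _paint_disks_to_coverage(tissue, target_px, nucleus_sampler, rng)

    # GFAP: blobby patches up to the requested fraction of the section surface.
    gfap_target_px = int(round(spec.gfap_fraction * section_px))
    gfap_sampler = lambda: rng.uniform(3.0, 10.0) / px
    gfap_mask = _paint_disks_to_coverage(tissue, gfap_target_px, gfap_sampler, rng)

    # gamma-H2AX: well-separated foci inside the tissue.
    puncta_mask = np.zeros_like(organoid)
    centers: list[tuple[int, int]] = []
    rad = max(1, int(round(spec.puncta_radius_um / px)))
    min_sep = 4 * rad + 4
    tys, txs = np.nonzero(tissue)
    attempts = 0
    while len(centers) < spec.puncta_count and attempts < 100_000:
        attempts += 1
        j = rng.integers(tys.size)
        cy, cx = int(tys[j]), int(txs[j])
        if any((cy - y) ** 2 + (cx - x) ** 2 < min_sep**2 for y, x in centers):
            continue
        yy, xx = np.ogrid[: organoid.shape[0], : organoid.shape[1]]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        if (disk <= tissue).all():
            puncta_mask |= disk
            centers.append((cy, cx))
    if len(centers) < spec.puncta_count:
        raise ValueError("could not place the requested puncta without overlap")

    def render(structure: np.ndarray, falloff: bool = False) -> np.ndarray:
        img = np.full(organoid.shape, _BACKGROUND, dtype=float)
        img[tissue] = _TISSUE_BASE
        if falloff:
            # Radial falloff inside each nucleus: peak at the center, rim
            # still well above the structure threshold.
            dist = _distance_to_edge(structure)
            level = np.where(
                structure,
                _NUCLEUS_RIM + (_NUCLEUS_PEAK - _NUCLEUS_RIM) * dist,
                img,
            )
            img = level
        else:
            img[structure] = 200.0
        img += rng.normal(0.0, 3.0, size=img.shape)
        return np.clip(img, 0, 255)

    channels = {"dapi": render(dapi_mask, falloff=True)}
    if spec.gfap_fraction > 0:
        channels["gfap"] = render(gfap_mask)
    if spec.puncta_count > 0:
        channels["gh2ax"] = render(puncta_mask)

    image = SectionImage(channels, px, spec.organoid_id, spec.slice_id)
    dapi_px = int(dapi_mask.sum())
    truth = {
        "organoid_id": spec.organoid_id,
        "slice_id": spec.slice_id,
        "pixel_size": px,
        "section_area_um2": section_px * px_area,
        "dapi_area_um2": dapi_px * px_area,
        "density_per_mm2": (dapi_px * px_area / NUCLEUS_AREA_UM2)
        / (section_px * px_area / 1.0e6),
        "cellless_pct": 100.0 * holes.sum() / section_px,
        "gfap_pct_of_section": 100.0 * gfap_mask.sum() / section_px,
        "gfap_pct_of_dapi": (100.0 * gfap_mask.sum() / dapi_px) if dapi_px else 0.0,
        "puncta_count": len(centers),
        "seed": spec.seed,
    }
    return image, truth


def _distance_to_edge(mask: np.ndarray) -> np.ndarray:
    """Normalized interior distance (0 at the rim, ~1 at object centers)."""
    from scipy import ndimage as ndi

    if not mask.any():
        return np.zeros(mask.shape)
    dist = ndi.distance_transform_edt(mask)
    m = dist.max()
    return dist / m if m > 0 else dist


def make_growth(
    slope: float,
    noise_sd: float,
    days: Sequence[int],
    intercept: float = 100_000.0,
    seed: int = 0,
    organoid_id: str = "synthetic",
) -> GrowthSeries:
    """Linear growth with additive Gaussian noise, clipped at zero area.

    area(day) = intercept + slope * day + N(0, noise_sd), in um^2.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng_for(seed, organoid_id, "growth")
    days = tuple(int(d) for d in days)
    areas = intercept + slope * np.asarray(days, dtype=float)
    areas = areas + rng.normal(0.0, noise_sd, size=len(days))
    areas = np.clip(areas, 0.0, None)
    return GrowthSeries(organoid_id, days, tuple(float(a) for a in areas))


# Per-level raw-score generators for initial-QC batches (indices A1-A3, B1-B2).
# "low" rows always total below the 16/25 initial threshold; "destroyed" rows
# always fail the first morphology index.
_INITIAL_INDICES = ("A1", "A2", "A3", "B1", "B2")


def _draw_row(level: str, rng: np.random.Generator) -> dict[str, int]:
    if level == "high":
        return {ix: int(rng.choice([4, 5], p=[0.3, 0.7])) for ix in _INITIAL_INDICES}
    if level == "medium":
        # Comfortably above every per-index minimum, totals 20-23.
        return {ix: int(rng.choice([4, 5])) for ix in ("A1", "A3", "B1", "B2")} | {
            "A2": int(rng.choice([3, 4]))
        }
    if level == "low":
        # Near the per-index minima: totals 13-15, always below 16.
        return {
            "A1": 3,
            "A2": int(rng.choice([2, 3])),
            "A3": 3,
            "B1": 3,
            "B2": int(rng.choice([2, 3])),
        }
    # destroyed: first morphology index below its minimum of 3.
    return {
        "A1": int(rng.choice([0, 1, 2])),
        "A2": int(rng.choice([0, 1])),
        "A3": int(rng.choice([0, 1])),
        "B1": int(rng.choice([0, 1, 2])),
        "B2": int(rng.choice([0, 1])),
    }


def make_batch(spec: SyntheticBatchSpec) -> list[dict[str, object]]:
    """Raw initial-QC score rows for a batch with known quality composition.

    Quality levels cycle over organoids; each row carries ``organoid_id``,
    ``condition`` (the level) and the five A/B index scores, ready for
    :func:`organoidqc.scheme_engine.evaluate` in initial mode.
    """
    rows = []
    for i in range(spec.n_organoids):
        level = spec.quality_levels[i % len(spec.quality_levels)]
        rng = _rng_for(spec.seed, "batch", i)
        row: dict[str, object] = {"organoid_id": str(i + 1), "condition": level}
        row.update(_draw_row(level, rng))
        rows.append(row)
    return rows
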