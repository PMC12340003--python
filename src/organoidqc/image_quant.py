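"""Image-based measurements on calibrated organoid section images.

All operators work on 2-D intensity rasters with an isotropic pixel size in
µm/px and report physical units (µm², mm⁻², %).  The measurement model is
area-based throughout: cellular density is DAPI-positive surface divided by a
mean nucleus area (80 µm²) and normalized to the section surface; cell-less
regions are holes inside the filled section outline; astrocytic reactivity is
GFAP-positive coverage; DNA-damage foci are connected components passing a
physical size and circularity filter, as in ImageJ's Analyze Particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "SectionImage",
    "BinaryMask",
    "Punctum",
    "PunctaSet",
    "QuantResult",
    "threshold_mask",
    "positive_surface",
    "section_mask",
    "cell_density",
    "cellless_fraction",
    "gfap_fraction",
    "count_puncta",
    "puncta_density",
    "positive_control_ratio",
    "quantify_section",
]

#: Mean nucleus cross-section used to convert DAPI-positive area to a cell
#: count, in µm².
NUCLEUS_AREA_UM2 = 80.0

UM2_PER_MM2 = 1.0e6


@dataclass
class SectionImage:
    """Calibrated multi-channel section raster.

    ``channels`` maps lower-case channel names (dapi, sox2, tubb3, gfap,
    gh2ax, brightfield -- any subset) to 2-D arrays sharing one shape;
    ``pixel_size`` is isotropic, in µm per pixel.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    organoid_id: str = ""
    slice_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class BinaryMask:
    """A thresholded channel with its calibration and provenance."""

    data: np.ndarray
    pixel_size: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size**2


@dataclass(frozen=True)
class Punctum:
    area_um2: float
    circularity: float
    centroid: tuple[float, float]


@dataclass
class PunctaSet:
    """Connected objects retained by the size/circularity particle filter."""

    puncta: list[Punctum]
    min_area_um2: float
    circ_range: tuple[float, float]
    labels: np.ndarray | None = None

    @property
    def count(self) -> int:
        return len(self.puncta)


@dataclass(frozen=True)
class QuantResult:
    """One tidy measurement row."""

    organoid_id: str
    slice_id: str
    metric: str
    value: float
    units: str
    provenance: str = ""


def threshold_mask(
    channel: np.ndarray,
    pixel_size: float,
    method: str | float = "otsu",
) -> BinaryMask:
    """Binarize a channel at a global threshold.

    ``method`` is either ``"otsu"`` (histogram-based automatic threshold) or a
    fixed numeric value emulating a manually adjusted threshold.  Pixels with
    intensity >= threshold are in the mask; the threshold used is recorded in
    the mask's provenance.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty channel")
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown threshold method {method!r}")
        if np.ptp(channel) == 0:
            raise ValueError(
                "constant-intensity image: automatic thresholding is undefined, "
                "pass a fixed threshold value instead"
            )
        thr = float(threshold_otsu(channel))
        prov = f"otsu={thr:g}"
    else:
        thr = float(method)
        prov = f"fixed={thr:g}"
    return BinaryMask(channel >= thr, pixel_size, provenance=prov)


def positive_surface(mask: BinaryMask) -> tuple[float, float]:
    """Positive area in µm² and as a fraction of the whole raster."""
    area = mask.area_um2
    fraction = mask.n_pixels / mask.data.size
    return area, fraction


def section_mask(
    channel: np.ndarray,
    pixel_size: float,
    method: str | float = "otsu",
) -> BinaryMask:
    """Tissue mask from an elevated threshold, suitable for hole analysis.

    The returned mask covers the tissue but not cell-less holes; the filled
    outline of this mask defines the section surface area.
    """
    mask = threshold_mask(channel, pixel_size, method)
    mask.provenance = "section:" + mask.provenance
    return mask


def _filled_outline(mask: BinaryMask) -> np.ndarray:
    return ndi.binary_fill_holes(mask.data)


def cell_density(
    dapi_area_um2: float,
    section_area_mm2: float,
    nucleus_area_um2: float = NUCLEUS_AREA_UM2,
) -> tuple[float, float]:
    """Area-based cellular density.

    Estimated cell count = DAPI-positive area / mean nucleus area (80 µm²);
    density = count / section area.  Returns ``(density per mm², cell count)``.
    """
    if section_area_mm2 <= 0:
        raise ValueError("section_area_mm2 must be > 0")
    if nucleus_area_um2 <= 0:
        raise ValueError("nucleus_area_um2 must be > 0")
    if dapi_area_um2 < 0:
        raise ValueError("dapi_area_um2 must be >= 0")
    if dapi_area_um2 > section_area_mm2 * UM2_PER_MM2 * (1 + 1e-9):
        raise ValueError(
            f"DAPI-positive area ({dapi_area_um2:g} um^2) exceeds the section "
            f"area ({section_area_mm2:g} mm^2): check masks and calibration"
        )
    count = dapi_area_um2 / nucleus_area_um2
    density = count / section_area_mm2
    return density, count


def cellless_fraction(tissue_mask: BinaryMask) -> float:
    """Percent of the section surface occupied by cell-less holes.

    The section surface is the filled outline of the elevated-threshold
    tissue mask; holes are pixels inside that outline but outside the mask.
    """
    if tissue_mask.n_pixels == 0:
        raise ValueError("empty tissue mask: no section to analyze")
    filled = _filled_outline(tissue_mask)
    holes = filled & ~tissue_mask.data
    return 100.0 * holes.sum() / filled.sum()


def gfap_fraction(gfap_mask: BinaryMask, reference: BinaryMask) -> float:
    """GFAP-positive coverage as a percentage of a reference area.

    The reference is either the DAPI-positive mask (the default normalization
    for astrocytic reactivity) or the filled section mask; which one was used
    should be recorded by the caller via the masks' provenance.
    """
    if gfap_mask.pixel_size != reference.pixel_size:
        raise ValueError("masks have different calibrations")
    ref_px = int(_filled_outline(reference).sum()) if reference.provenance.startswith(
        "section:"
    ) else reference.n_pixels
    if ref_px == 0:
        raise ValueError("zero reference area")
    return 100.0 * gfap_mask.n_pixels / ref_px


def _circularity(area_px: float, perimeter_px: float) -> float:
    """ImageJ convention 4*pi*area/perimeter^2, clamped to 1."""
    if perimeter_px <= 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area_px / perimeter_px**2)


def count_puncta(
    channel: np.ndarray,
    pixel_size: float | None,
    min_area_um2: float = 15.0,
    circ_range: tuple[float, float] = (0.0, 1.0),
    threshold: str | float = "otsu",
    connectivity: int = 2,
) -> PunctaSet:
    """Count foci (e.g. γH2AX puncta) with a physical particle filter.

    Binarizes the channel, labels connected components (8-connectivity by
    default), and keeps objects with area >= ``min_area_um2`` (physical µm²)
    and circularity 4π·A/P² within ``circ_range`` (Crofton perimeter).
    """
    if pixel_size is None:
        raise ValueError("pixel_size is required: the area filter is physical (um^2)")
    mask = threshold_mask(channel, pixel_size, threshold)
    labels = label(mask.data, connectivity=connectivity)
    lo, hi = circ_range
    kept: list[Punctum] = []
    kept_labels = np.zeros_like(labels)
    for region in regionprops(labels):
        area = region.area * pixel_size**2
        circ = _circularity(region.area, region.perimeter_crofton)
        if area >= min_area_um2 and lo <= circ <= hi:
            kept.append(Punctum(area, circ, region.centroid))
            kept_labels[labels == region.label] = len(kept)
    return PunctaSet(kept, min_area_um2, circ_range, labels=kept_labels)


def puncta_density(puncta: PunctaSet | int, dapi_area_um2: float) -> tuple[float, float]:
    """Foci count normalized to DAPI-positive surface.

    Returns ``(count per µm², count per mm²)``.
    """
    if dapi_area_um2 <= 0:
        raise ValueError("dapi_area_um2 must be > 0")
    count = puncta.count if isinstance(puncta, PunctaSet) else int(puncta)
    per_um2 = count / dapi_area_um2
    return per_um2, per_um2 * UM2_PER_MM2


def positive_control_ratio(value: float, pos_values: Sequence[float]) -> float:
    """Distance of a measurement below the positive-control mean, in control SDs.

    ratio = (mean(controls) − value) / sd(controls), with the sample standard
    deviation.  Large positive ratios mean the sample is far below the
    maximal-damage controls (low cytotoxicity); negative ratios mean damage at
    or above control level.
    """
    pos = np.asarray(pos_values, dtype=float)
    if pos.size < 2:
        raise ValueError("need at least 2 positive-control values")
    sd = float(pos.std(ddof=1))
    if sd == 0:
        raise ValueError("positive controls have zero standard deviation")
    return (float(pos.mean()) - float(value)) / sd


def quantify_section(
    image: SectionImage,
    dapi_threshold: str | float = "otsu",
    tissue_threshold: str | float = "otsu",
    gfap_threshold: str | float = "otsu",
    puncta_threshold: str | float = "otsu",
    gfap_reference: str = "dapi",
    min_puncta_area_um2: float = 15.0,
    nucleus_area_um2: float = NUCLEUS_AREA_UM2,
) -> list[QuantResult]:
    """Run every applicable measurement on one section image.

    Emits tidy rows: section/DAPI areas, cellular density and count, cell-less
    fraction (needs dapi), GFAP coverage (needs gfap), puncta count and
    density (needs gh2ax).  ``gfap_reference`` is ``"dapi"`` or ``"section"``.
    """
    px = image.pixel_size
    out: list[QuantResult] = []

    def emit(metric: str, value: float, units: str, provenance: str = "") -> None:
        out.append(
            QuantResult(image.organoid_id, image.slice_id, metric, value, units, provenance)
        )

    if "dapi" not in image.channels:
        return out

    dapi = threshold_mask(image.channels["dapi"], px, dapi_threshold)
    tissue = section_mask(image.channels["dapi"], px, tissue_threshold)
    filled = _filled_outline(tissue)
    section_area_um2 = float(filled.sum()) * px**2
    section_area_mm2 = section_area_um2 / UM2_PER_MM2
    dapi_area, _ = positive_surface(dapi)
    emit("section_area", section_area_um2, "um^2", tissue.provenance)
    emit("dapi_area", dapi_area, "um^2", dapi.provenance)

    density, count = cell_density(dapi_area, section_area_mm2, nucleus_area_um2)
    emit("cell_density", density, "mm^-2", f"nucleus_area={nucleus_area_um2:g}um^2")
    emit("cell_count", count, "count")
    emit("cellless_fraction", cellless_fraction(tissue), "%", tissue.provenance)

    if "gfap" in image.channels:
        gmask = threshold_mask(image.channels["gfap"], px, gfap_threshold)
        ref = dapi if gfap_reference == "dapi" else tissue
        emit(
            "gfap_fraction",
            gfap_fraction(gmask, ref),
            "%",
            f"{gmask.provenance};ref={gfap_reference}",
        )

    if "gh2ax" in image.channels:
        puncta = count_puncta(
            image.channels["gh2ax"], px, min_puncta_area_um2, threshold=puncta_threshold
        )
        emit("puncta_count", puncta.count, "count", f"min_area={min_puncta_area_um2:g}um^2")
        if dapi_area > 0:
            _, per_mm2 = puncta_density(puncta, dapi_area)
            emit("puncta_density", per_mm2, "mm^-2", "ref=dapi_area")

    return out
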