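"""Per-slice cross-section segmentation and trait extraction.

The measurement chain for one calibrated 8-bit CT slice is:

1. threshold the image into foreground/background (:func:`binarize`),
2. morphological closing with a disc structuring element to reconnect
   regions fragmented by noise (:func:`morphological_close`),
3. hole filling and connected-component extraction with a minimum-area
   filter proportional to the image size (:func:`extract_regions`),
4. an eccentricity filter to drop non-stem regions
   (:func:`filter_by_eccentricity`),
5. per region: an exterior circle fitted to the boundary pixels, the mean
   intensity relative to the 8-bit maximum, an inner circle fitted to the
   sub-threshold (non-rind) pixels, the dark-pixel "pithy" fraction of the
   inner disc, and the rind area outside the inner circle.

Circle fitting uses the Kasa algebraic least-squares formulation, which is
closed-form and exact on noise-free circle points.  Radii fitted to pixel
*centres* systematically underestimate the continuous outline by about half
a pixel, so fitted boundary circles are expanded by a configurable
half-pixel correction before any area or diameter is derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "CalibratedSlice",
    "SliceRegion",
    "FittedCircle",
    "CrossSectionTraits",
    "SegmentationConfig",
    "CircleFitError",
    "binarize",
    "morphological_close",
    "extract_regions",
    "filter_by_eccentricity",
    "fit_circle",
    "boundary_pixels",
    "measure_intensity",
    "fit_inner_circle",
    "measure_pithy_fraction",
    "measure_rind_area",
    "analyze_slice",
]

MAX_INTENSITY = 255


class CircleFitError(ValueError):
    """Raised when a circle cannot be fitted (too few or collinear points)."""


@dataclass
class CalibratedSlice:
    """One 2-D 8-bit CT image with its spatial calibration."""

    pixels: np.ndarray  # (H, W) uint8
    pixel_spacing: float  # mm per pixel
    slice_thickness: float  # mm
    z_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be a 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > MAX_INTENSITY:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_spacing and slice_thickness must be positive")
        if self.z_index < 0:
            raise ValueError("z_index must be >= 0")


@dataclass
class SliceRegion:
    """A connected foreground component with shape descriptors."""

    coords: np.ndarray  # (N, 2) array of (row, col) pixel members
    centroid: tuple[float, float]
    eccentricity: float

    @property
    def area_px(self) -> int:
        return int(self.coords.shape[0])

    def mask(self) -> tuple[np.ndarray, tuple[int, int]]:
        """Boolean mask cropped to the region's bounding box and its
        (row, col) offset."""
        r0, c0 = self.coords.min(axis=0)
        r1, c1 = self.coords.max(axis=0)
        m = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
        m[self.coords[:, 0] - r0, self.coords[:, 1] - c0] = True
        return m, (int(r0), int(c0))


@dataclass
class FittedCircle:
    center: tuple[float, float]  # (row, col), px
    radius_px: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.center)) or not np.isfinite(self.radius_px):
            raise CircleFitError("degenerate circle fit (non-finite parameters)")
        if self.radius_px <= 0:
            raise CircleFitError("fitted radius must be positive")


@dataclass
class CrossSectionTraits:
    """Per-region measurements for one slice."""

    z_index: int
    exterior: FittedCircle
    inner: FittedCircle | None
    diameter_px: float
    diameter_mm: float
    rind_area_px: float
    intensity: float  # mean / 255, in [0, 1]
    pithy_fraction: float | None  # None when no inner circle exists
    area_px: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def center(self) -> tuple[float, float]:
        return self.exterior.center


@dataclass
class SegmentationConfig:
    """Tunables of the per-slice pipeline (8-bit intensity scale).

    ``eccentricity_mode`` selects how the eccentricity cutoff is applied:
    ``"exclude_below"`` drops regions whose eccentricity falls below the
    cutoff, ``"exclude_above"`` drops regions above it (keeping the
    near-circular ones).  The second mode is what a stem pipeline normally
    wants, with a permissive cutoff such as 0.9.
    """

    binarize_threshold: int = 40
    closing_radius_px: int = 3
    area_factor: float = 0.00005
    eccentricity_cutoff: float = 0.08
    eccentricity_mode: str = "exclude_below"
    high_intensity_threshold: int = 175
    dark_threshold: int = 20
    radius_correction_px: float = 0.5
    pithy_denominator: str = "component"  # or "circle_count" / "continuous"
    fill_holes: bool = True

    def __post_init__(self) -> None:
        for name in ("binarize_threshold", "high_intensity_threshold", "dark_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= MAX_INTENSITY:
                raise ValueError(f"{name}={v} outside [0, {MAX_INTENSITY}]")
        if self.area_factor <= 0:
            raise ValueError("area_factor must be > 0")
        if self.closing_radius_px < 0:
            raise ValueError("closing_radius_px must be >= 0")
        if self.eccentricity_mode not in ("exclude_below", "exclude_above"):
            raise ValueError("eccentricity_mode must be exclude_below or exclude_above")
        if self.pithy_denominator not in ("component", "circle_count", "continuous"):
            raise ValueError(
                "pithy_denominator must be component, circle_count or continuous"
            )


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------


def binarize(slc: CalibratedSlice, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Foreground mask: pixels at or above the binarization threshold."""
    cfg = cfg or SegmentationConfig()
    return slc.pixels >= cfg.binarize_threshold


def morphological_close(mask: np.ndarray, radius_px: int = 3) -> np.ndarray:
    """Binary closing (dilation then erosion) with a disc structuring element."""
    if radius_px == 0:
        return mask.copy()
    return morphology.closing(mask, footprint=morphology.disk(radius_px)).astype(bool)


def extract_regions(
    mask: np.ndarray,
    area_factor: float = 0.00005,
    fill_holes: bool = True,
) -> list[SliceRegion]:
    """Connected components (8-connectivity) above the minimum-area cutoff.

    The cutoff is ``height * width * area_factor`` pixels; smaller specks
    (noise, debris not on the platform) are discarded.  Because pithy tissue
    is nearly transparent to X-rays, a stem's interior can fall below the
    binarization threshold; interior holes are therefore filled before
    labelling so that a region covers the full cross-section.
    """
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    h, w = mask.shape
    min_area = h * w * area_factor
    labels = measure.label(mask, connectivity=2)
    regions = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area:
            continue
        regions.append(
            SliceRegion(
                coords=rp.coords.copy(),
                centroid=tuple(rp.centroid),
                eccentricity=float(rp.eccentricity),
            )
        )
    return regions


def filter_by_eccentricity(
    regions: Iterable[SliceRegion],
    cutoff: float = 0.08,
    mode: str = "exclude_below",
) -> list[SliceRegion]:
    """Drop regions on the wrong side of the eccentricity cutoff.

    ``exclude_below`` removes regions with eccentricity < cutoff;
    ``exclude_above`` removes regions with eccentricity > cutoff.
    """
    if mode == "exclude_below":
        return [r for r in regions if not r.eccentricity < cutoff]
    if mode == "exclude_above":
        return [r for r in regions if not r.eccentricity > cutoff]
    raise ValueError(f"unknown eccentricity mode {mode!r}")


def fit_circle(points: Sequence[tuple[float, float]] | np.ndarray) -> FittedCircle:
    """Kasa algebraic least-squares circle through (row, col) points.

    Minimises sum((x^2 + y^2 + a x + b y + c)^2), a linear problem that is
    exact for points lying on a true circle.  Raises :class:`CircleFitError`
    for fewer than three points or collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise CircleFitError("circle fit needs at least 3 points")
    y, x = pts[:, 0], pts[:, 1]
    # centre coordinates to keep the normal equations well conditioned
    my, mx = y.mean(), x.mean()
    yc, xc = y - my, x - mx
    A = np.column_stack([xc, yc, np.ones_like(xc)])
    b = xc**2 + yc**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise CircleFitError("points are collinear; no unique circle")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        raise CircleFitError("degenerate circle fit")
    return FittedCircle(center=(cy + my, cx + mx), radius_px=float(np.sqrt(r2)))


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of mask pixels with >= 1 background 4-neighbour."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(mask & ~eroded)


def _fit_boundary_circle(mask: np.ndarray, offset: tuple[int, int], correction: float) -> FittedCircle:
    pts = boundary_pixels(mask).astype(float)
    pts[:, 0] += offset[0]
    pts[:, 1] += offset[1]
    c = fit_circle(pts)
    return FittedCircle(center=c.center, radius_px=c.radius_px + correction)


def measure_intensity(region: SliceRegion, slc: CalibratedSlice) -> float:
    """Mean pixel intensity of the region divided by the 8-bit maximum."""
    if region.area_px == 0:
        raise ValueError("cannot measure intensity of an empty region")
    vals = slc.pixels[region.coords[:, 0], region.coords[:, 1]]
    return float(vals.mean()) / MAX_INTENSITY


def _inner_component(
    region: SliceRegion,
    slc: CalibratedSlice,
    high_intensity_threshold: int = 175,
) -> tuple[np.ndarray, tuple[int, int]] | None:
    """Largest connected component of the region's non-rind pixels.

    Pixels brighter than ``high_intensity_threshold`` (lignified rind) are
    excluded; the dominant remaining component is the pith disc.  Returns a
    (mask, offset) pair or ``None`` when fewer than three pixels qualify.
    """
    vals = slc.pixels[region.coords[:, 0], region.coords[:, 1]]
    keep = vals <= high_intensity_threshold
    if int(keep.sum()) < 3:
        return None
    mask, offset = region.mask()
    qual = np.zeros_like(mask)
    kc = region.coords[keep]
    qual[kc[:, 0] - offset[0], kc[:, 1] - offset[1]] = True
    # keep only the dominant interior component (noise can leave stray
    # sub-threshold pixels inside the rind annulus)
    labels = measure.label(qual, connectivity=2)
    if labels.max() > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        qual = labels == int(np.argmax(counts))
        if int(qual.sum()) < 3:
            return None
    return qual, offset


def fit_inner_circle(
    region: SliceRegion,
    slc: CalibratedSlice,
    high_intensity_threshold: int = 175,
    radius_correction_px: float = 0.5,
    exterior: FittedCircle | None = None,
) -> FittedCircle | None:
    """Circle fitted to the non-rind interior of a cross-section.

    The circle is fitted to the boundary of the largest connected component
    of pixels at or below ``high_intensity_threshold``.  Returns ``None``
    for a fully lignified, solid section (fewer than three qualifying
    pixels).  When an exterior circle is supplied the inner radius is
    clamped to it.
    """
    comp = _inner_component(region, slc, high_intensity_threshold)
    if comp is None:
        return None
    qual, offset = comp
    try:
        inner = _fit_boundary_circle(qual, offset, radius_correction_px)
    except CircleFitError:
        return None
    if exterior is not None and inner.radius_px > exterior.radius_px:
        inner = FittedCircle(center=inner.center, radius_px=exterior.radius_px)
    return inner


def _inside_inner(region: SliceRegion, inner: FittedCircle) -> np.ndarray:
    d = np.hypot(
        region.coords[:, 0] - inner.center[0], region.coords[:, 1] - inner.center[1]
    )
    return d <= inner.radius_px


def measure_pithy_fraction(
    region: SliceRegion,
    slc: CalibratedSlice,
    inner: FittedCircle | None,
    dark_threshold: int = 20,
    denominator: str = "component",
    high_intensity_threshold: int = 175,
) -> float | None:
    """Fraction of the inner disc occupied by dark (air-filled) pixels.

    Numerator: inner-disc pixels with intensity below ``dark_threshold``.
    The inner-disc area in the denominator follows one of three documented
    conventions: ``"component"`` (default) counts the pixels of the
    segmented inner component, which is exact with respect to the rasterised
    pith disc; ``"circle_count"`` counts region pixels inside the fitted
    inner circle; ``"continuous"`` uses pi * r^2 of the fitted circle.
    Returns ``None`` when the section has no inner circle; the fraction is
    clipped to [0, 1].
    """
    if inner is None:
        return None
    vals = slc.pixels[region.coords[:, 0], region.coords[:, 1]]
    if denominator == "component":
        comp = _inner_component(region, slc, high_intensity_threshold)
        if comp is None:
            return None
        qual, offset = comp
        in_comp = qual[region.coords[:, 0] - offset[0], region.coords[:, 1] - offset[1]]
        n_dark = int(np.count_nonzero(in_comp & (vals < dark_threshold)))
        denom: float = int(np.count_nonzero(in_comp))
    else:
        inside = _inside_inner(region, inner)
        n_dark = int(np.count_nonzero(inside & (vals < dark_threshold)))
        if denominator == "continuous":
            denom = np.pi * inner.radius_px**2
        else:
            denom = int(np.count_nonzero(inside))
    if denom <= 0:
        return 0.0
    return float(np.clip(n_dark / denom, 0.0, 1.0))


def measure_rind_area(
    region: SliceRegion,
    exterior: FittedCircle,
    inner: FittedCircle | None,
    slc: CalibratedSlice | None = None,
    high_intensity_threshold: int = 175,
) -> float:
    """Rind area as the annulus pixel count outside the inner disc.

    When the slice is available the rind is counted directly as the region
    pixels not belonging to the segmented inner component (the bright
    annulus); otherwise it falls back to the region pixels outside the
    fitted inner circle.  With no inner circle the whole region is rind.
    """
    if inner is None:
        return float(region.area_px)
    if slc is not None:
        comp = _inner_component(region, slc, high_intensity_threshold)
        if comp is not None:
            qual, offset = comp
            in_comp = qual[
                region.coords[:, 0] - offset[0], region.coords[:, 1] - offset[1]
            ]
            return float(region.area_px - int(np.count_nonzero(in_comp)))
    return float(np.count_nonzero(~_inside_inner(region, inner)))


def analyze_slice(
    slc: CalibratedSlice, cfg: SegmentationConfig | None = None
) -> list[CrossSectionTraits]:
    """Run the full per-slice chain and return one trait record per region."""
    cfg = cfg or SegmentationConfig()
    mask = binarize(slc, cfg)
    mask = morphological_close(mask, cfg.closing_radius_px)
    regions = extract_regions(mask, cfg.area_factor, fill_holes=cfg.fill_holes)
    regions = filter_by_eccentricity(
        regions, cfg.eccentricity_cutoff, cfg.eccentricity_mode
    )
    out: list[CrossSectionTraits] = []
    for region in regions:
        mask_r, offset = region.mask()
        try:
            exterior = _fit_boundary_circle(mask_r, offset, cfg.radius_correction_px)
        except CircleFitError:
            continue
        comp = _inner_component(region, slc, cfg.high_intensity_threshold)
        inner: FittedCircle | None = None
        pithy: float | None = None
        rind_area = float(region.area_px)
        if comp is not None:
            qual, qoff = comp
            try:
                inner = _fit_boundary_circle(qual, qoff, cfg.radius_correction_px)
                if inner.radius_px > exterior.radius_px:
                    inner = FittedCircle(
                        center=inner.center, radius_px=exterior.radius_px
                    )
            except CircleFitError:
                inner = None
        if inner is not None:
            vals = slc.pixels[region.coords[:, 0], region.coords[:, 1]]
            qual, qoff = comp
            in_comp = qual[
                region.coords[:, 0] - qoff[0], region.coords[:, 1] - qoff[1]
            ]
            n_inner = int(np.count_nonzero(in_comp))
            rind_area = float(region.area_px - n_inner)
            if cfg.pithy_denominator == "component":
                n_dark = int(np.count_nonzero(in_comp & (vals < cfg.dark_threshold)))
                denom: float = n_inner
            else:
                inside = _inside_inner(region, inner)
                n_dark = int(np.count_nonzero(inside & (vals < cfg.dark_threshold)))
                denom = (
                    np.pi * inner.radius_px**2
                    if cfg.pithy_denominator == "continuous"
                    else int(np.count_nonzero(inside))
                )
            pithy = float(np.clip(n_dark / denom, 0.0, 1.0)) if denom > 0 else 0.0
        flags = [f"eccentricity_mode={cfg.eccentricity_mode}"]
        if inner is None:
            flags.append("solid_section")
        out.append(
            CrossSectionTraits(
                z_index=slc.z_index,
                exterior=exterior,
                inner=inner,
                diameter_px=2.0 * exterior.radius_px,
                diameter_mm=2.0 * exterior.radius_px * slc.pixel_spacing,
                rind_area_px=rind_area,
                intensity=measure_intensity(region, slc),
                pithy_fraction=pithy,
                area_px=region.area_px,
                flags=flags,
            )
        )
    return out
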