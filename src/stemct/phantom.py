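"""Synthetic CT phantoms with known ground truth.

Two generators live here:

* :func:`generate_stack` renders a stack of 8-bit cross-section images that
  emulate what a medical CT produces for grass stems standing on a 5 x 6
  platform: a bright, lignified rind annulus around a mid-intensity pith
  disc, an adjustable fraction of near-zero "pithy" (air-filled) pixels
  inside the pith, solid bright node slices, per-slice taper, and additive
  Gaussian noise.  Every rendered quantity (centres, radii, areas, pithy
  fraction, mean intensity) is recorded in a truth table so the segmentation
  pipeline can be validated pixel-for-pixel.

* :func:`generate_trait_dataset` simulates internode-level trait records
  under the nested linear model y_ijk = mu + g_i + i(g)_ij + e_ijk used for
  repeatability estimation, with known variance components.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import CalibratedSlice

__all__ = [
    "PhantomStemSpec",
    "PhantomSpec",
    "TraitSimSpec",
    "PhantomValidationError",
    "grid_cell_centers",
    "generate_stack",
    "generate_trait_dataset",
    "phantom_spec_from_dict",
    "sample_platform_spec",
]

#: platform layout: 5 rows x 6 columns of stems per scan
GRID_ROWS = 5
GRID_COLS = 6

#: number of consecutive slices a rendered node occupies
NODE_SPAN = 2

#: intensity written into "pithy" (air-filled parenchyma) pixels; must sit
#: below the dark-pixel threshold (20) used downstream
DARK_PIXEL_VALUE = 0


class PhantomValidationError(ValueError):
    """A phantom specification violates its geometric invariants."""


@dataclass
class PhantomStemSpec:
    """One synthetic stem on the platform.

    ``outer_radius_mm`` may be a scalar (constant cross-section) or a
    sequence of per-slice radii; a two-element sequence is interpreted as a
    linear taper from the basal slice to the top of the stem's extent.
    """

    grid_cell: tuple[int, int]
    outer_radius_mm: float | Sequence[float]
    rind_thickness_mm: float
    pith_intensity: int = 120
    rind_intensity: int = 200
    pithy_fraction_true: float = 0.0
    node_slices: list[int] = field(default_factory=list)
    present_in_slices: tuple[int, int] | None = None  # inclusive z-range

    def radius_mm_at(self, z: int, z0: int, z1: int) -> float:
        r = self.outer_radius_mm
        if np.isscalar(r):
            return float(r)
        r = np.asarray(r, dtype=float)
        if r.size == 1:
            return float(r[0])
        # piecewise-linear taper over the stem's extent
        t = 0.0 if z1 == z0 else (z - z0) / (z1 - z0)
        xp = np.linspace(0.0, 1.0, r.size)
        return float(np.interp(t, xp, r))

    def min_radius_mm(self) -> float:
        r = self.outer_radius_mm
        return float(np.min(r)) if not np.isscalar(r) else float(r)

    def max_radius_mm(self) -> float:
        r = self.outer_radius_mm
        return float(np.max(r)) if not np.isscalar(r) else float(r)

    def validate(self, high_intensity_threshold: int = 175) -> None:
        row, col = self.grid_cell
        if not (0 <= row < GRID_ROWS and 0 <= col < GRID_COLS):
            raise PhantomValidationError(
                f"grid_cell {self.grid_cell} outside the {GRID_ROWS}x{GRID_COLS} platform"
            )
        if self.rind_thickness_mm <= 0:
            raise PhantomValidationError("rind_thickness_mm must be positive")
        if self.rind_thickness_mm >= self.min_radius_mm():
            raise PhantomValidationError(
                f"rind_thickness_mm {self.rind_thickness_mm} must be smaller than the "
                f"outer radius {self.min_radius_mm()}"
            )
        if not 0 <= self.pithy_fraction_true <= 1:
            raise PhantomValidationError("pithy_fraction_true must lie in [0, 1]")
        if not 0 <= self.pith_intensity <= 255 or not 0 <= self.rind_intensity <= 255:
            raise PhantomValidationError("tissue intensities must lie in [0, 255]")
        if self.pith_intensity >= high_intensity_threshold:
            raise PhantomValidationError(
                f"pith_intensity {self.pith_intensity} must sit below the "
                f"high-intensity (rind) threshold {high_intensity_threshold}"
            )
        if self.rind_intensity <= self.pith_intensity:
            raise PhantomValidationError("rind_intensity must exceed pith_intensity")


@dataclass
class PhantomSpec:
    """A full platform scan: stems, geometry calibration, noise and seed."""

    stems: list[PhantomStemSpec]
    n_slices: int
    image_shape: tuple[int, int] = (512, 512)
    pixel_spacing: float = 1.0 / 1.024  # mm per pixel
    slice_thickness_mm: float = 0.6
    noise_sd: float = 0.0
    background_intensity: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_slices < 1:
            raise PhantomValidationError("n_slices must be >= 1")
        if self.pixel_spacing <= 0 or self.slice_thickness_mm <= 0:
            raise PhantomValidationError("calibration values must be positive")
        if self.noise_sd < 0:
            raise PhantomValidationError("noise_sd must be >= 0")
        centers = grid_cell_centers(self.image_shape)
        h, w = self.image_shape
        max_r_px = [s.max_radius_mm() / self.pixel_spacing for s in self.stems]
        for i, stem in enumerate(self.stems):
            stem.validate()
            cy, cx = centers[stem.grid_cell]
            r = max_r_px[i]
            if cy - r < 0 or cy + r > h - 1 or cx - r < 0 or cx + r > w - 1:
                raise PhantomValidationError(
                    f"stem {i} (cell {stem.grid_cell}) extends outside the image"
                )
        # overlap / duplicate-cell check at maximal radii
        bad: list[tuple[int, int]] = []
        for i in range(len(self.stems)):
            for j in range(i + 1, len(self.stems)):
                ci = centers[self.stems[i].grid_cell]
                cj = centers[self.stems[j].grid_cell]
                d = float(np.hypot(ci[0] - cj[0], ci[1] - cj[1]))
                if d <= max_r_px[i] + max_r_px[j]:
                    bad.append((i, j))
        if bad:
            raise PhantomValidationError(f"overlapping stem discs: {bad}")


def grid_cell_centers(
    image_shape: tuple[int, int],
    n_rows: int = GRID_ROWS,
    n_cols: int = GRID_COLS,
) -> dict[tuple[int, int], tuple[float, float]]:
    """Centre (row, col) pixel coordinates of each platform cell."""
    h, w = image_shape
    out = {}
    for r in range(n_rows):
        for c in range(n_cols):
            out[(r, c)] = ((r + 0.5) * h / n_rows, (c + 0.5) * w / n_cols)
    return out


def _stem_extent(stem: PhantomStemSpec, n_slices: int) -> tuple[int, int]:
    if stem.present_in_slices is None:
        return 0, n_slices - 1
    z0, z1 = stem.present_in_slices
    return max(0, z0), min(n_slices - 1, z1)


def generate_stack(spec: PhantomSpec) -> tuple[list[CalibratedSlice], pd.DataFrame]:
    """Render the phantom stack and its per-stem, per-slice truth table.

    Returns the ordered list of :class:`CalibratedSlice` and a DataFrame
    with one row per stem per slice in which the stem is present.  Truth
    columns record, by construction: disc centre (px), outer radius (px),
    rind annulus pixel count, inner (pith) disc pixel count, realised pithy
    fraction, diameter in px, and mean disc intensity / 255 (all measured on
    the noise-free rendering).  Node slices are rendered as solid bright
    discs and flagged ``is_node``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers = grid_cell_centers(spec.image_shape)
    h, w = spec.image_shape
    yy, xx = np.mgrid[0:h, 0:w]

    slices: list[CalibratedSlice] = []
    rows: list[dict] = []

    # Pre-compute, per stem, the set of z-indices occupied by nodes.
    node_z: list[set[int]] = []
    for stem in spec.stems:
        zs: set[int] = set()
        for nz in stem.node_slices:
            zs.update(range(nz, nz + NODE_SPAN))
        node_z.append(zs)

    for z in range(spec.n_slices):
        img = np.full((h, w), spec.background_intensity, dtype=float)
        for i, stem in enumerate(spec.stems):
            z0, z1 = _stem_extent(stem, spec.n_slices)
            if not z0 <= z <= z1:
                continue
            cy, cx = centers[stem.grid_cell]
            r_out_px = stem.radius_mm_at(z, z0, z1) / spec.pixel_spacing
            r_pith_px = max(
                0.0,
                (stem.radius_mm_at(z, z0, z1) - stem.rind_thickness_mm)
                / spec.pixel_spacing,
            )
            dist = np.hypot(yy - cy, xx - cx)
            disc = dist <= r_out_px
            is_node = z in node_z[i]
            if is_node:
                # nodes are solid lignified tissue: uniformly bright
                img[disc] = stem.rind_intensity
                rows.append(
                    {
                        "stem_index": i,
                        "grid_row": stem.grid_cell[0],
                        "grid_col": stem.grid_cell[1],
                        "z_index": z,
                        "center_row": cy,
                        "center_col": cx,
                        "outer_radius_px": r_out_px,
                        "diameter_px": 2 * r_out_px,
                        "rind_area_px": int(disc.sum()),
                        "inner_area_px": 0,
                        "pithy_fraction": np.nan,
                        "mean_intensity": stem.rind_intensity / 255.0,
                        "is_node": True,
                    }
                )
                continue
            pith = dist <= r_pith_px
            rind = disc & ~pith
            img[rind] = stem.rind_intensity
            img[pith] = stem.pith_intensity
            n_pith = int(pith.sum())
            n_dark = int(round(stem.pithy_fraction_true * n_pith))
            if n_dark > 0:
                pith_idx = np.flatnonzero(pith.ravel())
                dark_idx = rng.choice(pith_idx, size=n_dark, replace=False)
                img.ravel()[dark_idx] = DARK_PIXEL_VALUE
            mean_int = float(img[disc].mean()) / 255.0 if disc.any() else np.nan
            rows.append(
                {
                    "stem_index": i,
                    "grid_row": stem.grid_cell[0],
                    "grid_col": stem.grid_cell[1],
                    "z_index": z,
                    "center_row": cy,
                    "center_col": cx,
                    "outer_radius_px": r_out_px,
                    "diameter_px": 2 * r_out_px,
                    "rind_area_px": int(rind.sum()),
                    "inner_area_px": n_pith,
                    "pithy_fraction": (n_dark / n_pith) if n_pith else np.nan,
                    "mean_intensity": mean_int,
                    "is_node": False,
                }
            )
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        slices.append(
            CalibratedSlice(
                pixels=img,
                pixel_spacing=spec.pixel_spacing,
                slice_thickness=spec.slice_thickness_mm,
                z_index=z,
            )
        )

    truth = pd.DataFrame(rows)
    return slices, truth


def sample_platform_spec(
    seed: int,
    n_stems: int | None = None,
    n_slices: int = 1,
    noise_sd: float = 0.0,
    radius_px_range: tuple[float, float] = (5.0, 40.0),
    rind_fraction_range: tuple[float, float] = (0.12, 0.30),
    pithy_range: tuple[float, float] = (0.0, 0.8),
) -> PhantomSpec:
    """Draw a random but valid platform scan for benchmarking.

    The defaults span the morphology the platform is built for: 1-30 stems
    per scan, outer radii of 5-40 px (roughly 5-40 mm at the default
    calibration), a rind occupying 12-30% of the radius — typical for
    sorghum, whose lignified rind is a few millimetres thick — and pithy
    fractions from fully juicy (0) to heavily pithy (0.8).  Stems sit at
    their grid-cell centres, so discs never overlap; the field of view is
    slightly wider than the default image so that even maximal-radius
    neighbours stay separated by more than twice the closing radius and are
    never morphologically bridged.
    """
    rng = np.random.default_rng(seed)
    cells = [(r, c) for r in range(GRID_ROWS) for c in range(GRID_COLS)]
    rng.shuffle(cells)
    if n_stems is None:
        n_stems = int(rng.integers(1, GRID_ROWS * GRID_COLS + 1))
    spec = PhantomSpec(stems=[], n_slices=n_slices, noise_sd=noise_sd,
                       image_shape=(540, 640),
                       seed=int(rng.integers(1 << 30)))
    for cell in cells[:n_stems]:
        radius_px = float(rng.uniform(*radius_px_range))
        radius_mm = radius_px * spec.pixel_spacing
        rind_mm = float(rng.uniform(*rind_fraction_range)) * radius_mm
        spec.stems.append(
            PhantomStemSpec(
                grid_cell=cell,
                outer_radius_mm=radius_mm,
                rind_thickness_mm=rind_mm,
                pithy_fraction_true=float(rng.uniform(*pithy_range)),
            )
        )
    spec.validate()
    return spec


def phantom_spec_from_dict(data: dict) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a plain mapping (YAML/JSON config).

    Stem entries use the :class:`PhantomStemSpec` field names; ``grid_cell``
    and ``present_in_slices`` may be two-element lists.
    """
    data = dict(data)
    stems = []
    for i, entry in enumerate(data.pop("stems", [])):
        entry = dict(entry)
        try:
            entry["grid_cell"] = tuple(entry["grid_cell"])
            if entry.get("present_in_slices") is not None:
                entry["present_in_slices"] = tuple(entry["present_in_slices"])
            stems.append(PhantomStemSpec(**entry))
        except (KeyError, TypeError) as exc:
            raise PhantomValidationError(f"stem entry {i}: {exc}") from exc
    if "image_shape" in data:
        data["image_shape"] = tuple(data["image_shape"])
    try:
        spec = PhantomSpec(stems=stems, **data)
    except TypeError as exc:
        raise PhantomValidationError(str(exc)) from exc
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Trait-table simulation for the repeatability / LS-means layer
# ---------------------------------------------------------------------------


@dataclass
class TraitSimSpec:
    """Generative spec for nested trait records.

    ``y_ijk = mu + g_i + i(g)_ij + e_ijk`` with independent zero-mean normal
    draws: genotype effects g_i ~ N(0, genotype_sd^2), internode-within-
    genotype effects ~ N(0, internode_sd^2), residuals ~ N(0, residual_sd^2).
    The defaults mirror a field trial of 19 genotypes, six plants each, with
    seven measured internodes per plant.
    """

    n_genotypes: int = 19
    plants_per_genotype: int = 6
    internodes_per_plant: int = 7
    grand_mean: float = 10.0
    genotype_sd: float = 1.0
    internode_sd: float = 1.0
    residual_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genotypes, self.plants_per_genotype, self.internodes_per_plant) < 1:
            raise ValueError("all counts must be >= 1")
        if min(self.genotype_sd, self.internode_sd, self.residual_sd) < 0:
            raise ValueError("all standard deviations must be >= 0")

    @property
    def h2_true(self) -> float:
        """Repeatability implied by the generative variances,
        sigma_G^2 / (sigma_G^2 + sigma_E^2)."""
        vg, ve = self.genotype_sd**2, self.residual_sd**2
        return vg / (vg + ve) if (vg + ve) > 0 else np.nan


def generate_trait_dataset(spec: TraitSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-format trait table plus its generative truth.

    Returns ``(table, truth)`` where the table has columns genotype,
    plant_id, internode, value and truth records the variance components and
    the implied repeatability.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = rng.normal(0.0, spec.genotype_sd, size=spec.n_genotypes)
    ig = rng.normal(
        0.0, spec.internode_sd, size=(spec.n_genotypes, spec.internodes_per_plant)
    )
    rows = []
    for i in range(spec.n_genotypes):
        for j in range(spec.internodes_per_plant):
            eps = rng.normal(0.0, spec.residual_sd, size=spec.plants_per_genotype)
            for k in range(spec.plants_per_genotype):
                rows.append(
                    {
                        "genotype": f"G{i:03d}",
                        "plant_id": f"G{i:03d}_P{k}",
                        "internode": j + 1,
                        "value": spec.grand_mean + g[i] + ig[i, j] + eps[k],
                    }
                )
    truth = {
        "sigma_g2": spec.genotype_sd**2,
        "sigma_ig2": spec.internode_sd**2,
        "sigma_e2": spec.residual_sd**2,
        "h2": spec.h2_true,
    }
    return pd.DataFrame(rows), truth
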