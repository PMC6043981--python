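"""Stem tracking across slices, profile cleaning, internode aggregation.

Regions found slice-by-slice are assigned to fixed platform positions
(nearest 5 x 6 grid-cell centre), giving one :class:`StemProfile` per
occupied cell.  Node slices — annotated manually, since nodes are not
algorithmically separable from internode tissue — are removed together with
a configurable guard band, the remaining series is cleaned (missing slices,
diameter outliers by a median ± k*MAD rule), and traits are averaged per
internode.  Internode 1 is the basal-most segment, i.e. the run of slices
between the bottom of the stack and the first node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import CrossSectionTraits
from .phantom import GRID_COLS, GRID_ROWS, grid_cell_centers

__all__ = [
    "GridSpec",
    "StemProfile",
    "InternodeRecord",
    "track_stems",
    "internode_length_mm",
    "node_window",
    "clean_profile",
    "internode_segments",
    "aggregate_internodes",
    "profiles_to_frame",
    "internodes_to_frame",
]


@dataclass
class GridSpec:
    """Expected platform layout within the image.

    ``image_shape`` may be left ``None``, in which case the tracker uses the
    shape of the slices being processed (or the 512 x 512 default).
    """

    image_shape: tuple[int, int] | None = None
    n_rows: int = GRID_ROWS
    n_cols: int = GRID_COLS
    max_jump_px: float = 15.0

    def centers(
        self, fallback_shape: tuple[int, int] | None = None
    ) -> dict[tuple[int, int], tuple[float, float]]:
        shape = self.image_shape or fallback_shape or (512, 512)
        return grid_cell_centers(shape, self.n_rows, self.n_cols)


@dataclass
class StemProfile:
    """One stem's ordered per-slice trait series."""

    stem_id: str
    grid_cell: tuple[int, int]
    traits: list[CrossSectionTraits]
    node_z_indices: list[int] = field(default_factory=list)
    z_start: int = 0
    z_end: int = 0  # inclusive
    missing_z: list[int] = field(default_factory=list)
    conflict_z: list[int] = field(default_factory=list)
    outlier_z: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        zs = [t.z_index for t in self.traits]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("trait z-indices must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return self.z_end - self.z_start + 1

    def with_nodes(self, node_z: list[int]) -> "StemProfile":
        bad = [z for z in node_z if not self.z_start <= z <= self.z_end]
        if bad:
            raise ValueError(f"node indices {bad} outside stack range for {self.stem_id}")
        self.node_z_indices = sorted(node_z)
        return self


@dataclass
class InternodeRecord:
    """Per-internode aggregate feeding biomechanics and statistics."""

    genotype: str
    plant_id: str
    internode_number: int  # 1 = basal
    length_cm: float
    diameter_mm: float
    rind_area_px: float
    intensity: float
    pithy_fraction: float | None
    n_slices: int
    n_retained_slices: int
    fresh_mass_g: float | None = None
    dry_mass_g: float | None = None

    @property
    def volume_cm3(self) -> float:
        """v = pi r^2 h with r from the mean diameter."""
        r_cm = self.diameter_mm / 20.0
        return math.pi * r_cm**2 * self.length_cm

    @property
    def density_g_cm3(self) -> float | None:
        """rho = m / v from the fresh mass, when supplied."""
        if self.fresh_mass_g is None:
            return None
        return self.fresh_mass_g / self.volume_cm3

    @property
    def dry_density_g_cm3(self) -> float | None:
        if self.dry_mass_g is None:
            return None
        return self.dry_mass_g / self.volume_cm3


def track_stems(
    slice_traits: list[list[CrossSectionTraits]],
    grid: GridSpec | None = None,
    image_shape: tuple[int, int] | None = None,
) -> list[StemProfile]:
    """Assign per-slice regions to platform cells and build stem profiles.

    Each region goes to the nearest grid-cell centre.  When two regions in
    one slice map to the same cell, the nearer is kept and the slice is
    recorded as a conflict.  A centroid jump larger than ``max_jump_px``
    between consecutive accepted slices flags the slice as missing for that
    stem (the cross-section drifted out of its measurement area).
    """
    grid = grid or GridSpec()
    if not slice_traits:
        return []
    centers = grid.centers(fallback_shape=image_shape)
    cells = list(centers)
    cmat = np.array([centers[c] for c in cells])

    assigned: dict[tuple[int, int], list[CrossSectionTraits]] = {}
    conflicts: dict[tuple[int, int], list[int]] = {}
    for traits in slice_traits:
        best_for_cell: dict[tuple[int, int], tuple[float, CrossSectionTraits]] = {}
        for t in traits:
            d = np.hypot(cmat[:, 0] - t.center[0], cmat[:, 1] - t.center[1])
            cell = cells[int(np.argmin(d))]
            dist = float(d.min())
            if cell in best_for_cell:
                z = t.z_index
                conflicts.setdefault(cell, []).append(z)
                if dist >= best_for_cell[cell][0]:
                    continue
            best_for_cell[cell] = (dist, t)
        for cell, (_, t) in best_for_cell.items():
            assigned.setdefault(cell, []).append(t)

    z_lo = min(s[0].z_index for s in slice_traits if s) if any(slice_traits) else 0
    z_hi = (
        max(t.z_index for s in slice_traits for t in s) if any(slice_traits) else 0
    )
    profiles = []
    for cell in sorted(assigned):
        series = sorted(assigned[cell], key=lambda t: t.z_index)
        kept: list[CrossSectionTraits] = []
        missing: list[int] = []
        prev = None
        for t in series:
            if prev is not None:
                jump = math.hypot(
                    t.center[0] - prev.center[0], t.center[1] - prev.center[1]
                )
                if jump > grid.max_jump_px:
                    missing.append(t.z_index)
                    continue
            kept.append(t)
            prev = t
        seen = {t.z_index for t in kept}
        missing += [z for z in range(z_lo, z_hi + 1) if z not in seen and z not in missing]
        profiles.append(
            StemProfile(
                stem_id=f"r{cell[0]}c{cell[1]}",
                grid_cell=cell,
                traits=kept,
                z_start=z_lo,
                z_end=z_hi,
                missing_z=sorted(missing),
                conflict_z=sorted(conflicts.get(cell, [])),
            )
        )
    return profiles


def internode_length_mm(n_slices: int, slice_thickness: float) -> float:
    """Internode length: slice count times slice thickness (mm)."""
    if n_slices < 1:
        raise ValueError("an internode must span at least one slice")
    if slice_thickness <= 0:
        raise ValueError("slice thickness must be positive")
    return n_slices * slice_thickness


def node_window(node_z: list[int], half_width: int = 1) -> set[int]:
    """Slice indices removed around annotated nodes (guard band included)."""
    out: set[int] = set()
    for z in node_z:
        out.update(range(z - half_width, z + half_width + 1))
    return out


def clean_profile(
    profile: StemProfile,
    node_half_width: int = 1,
    outlier_k: float = 3.5,
) -> StemProfile:
    """Remove node slices and diameter outliers from a profile.

    Node slices (annotated index ± ``node_half_width``) are dropped; within
    each internode segment, slices whose diameter deviates from the segment
    median by more than ``outlier_k`` times the median absolute deviation
    are removed and logged in ``outlier_z``.
    """
    nodes = node_window(profile.node_z_indices, node_half_width)
    kept = [t for t in profile.traits if t.z_index not in nodes]
    segments = internode_segments(
        profile.z_start, profile.z_end, profile.node_z_indices, node_half_width
    )
    outliers: list[int] = []
    final: list[CrossSectionTraits] = []
    for seg in segments:
        seg_traits = [t for t in kept if t.z_index in seg]
        if not seg_traits:
            continue
        d = np.array([t.diameter_px for t in seg_traits])
        med = float(np.median(d))
        mad = float(np.median(np.abs(d - med)))
        for t, dv in zip(seg_traits, d):
            if mad > 0 and abs(dv - med) > outlier_k * mad:
                outliers.append(t.z_index)
            elif mad == 0 and dv != med:
                outliers.append(t.z_index)
            else:
                final.append(t)
    final.sort(key=lambda t: t.z_index)
    return StemProfile(
        stem_id=profile.stem_id,
        grid_cell=profile.grid_cell,
        traits=final,
        node_z_indices=list(profile.node_z_indices),
        z_start=profile.z_start,
        z_end=profile.z_end,
        missing_z=list(profile.missing_z),
        conflict_z=list(profile.conflict_z),
        outlier_z=sorted(outliers),
    )


def internode_segments(
    z_start: int,
    z_end: int,
    node_z: list[int],
    node_half_width: int = 1,
) -> list[set[int]]:
    """Maximal runs of non-node slice indices, base (low z) first."""
    nodes = node_window(node_z, node_half_width)
    segments: list[set[int]] = []
    current: set[int] = set()
    for z in range(z_start, z_end + 1):
        if z in nodes:
            if current:
                segments.append(current)
                current = set()
        else:
            current.add(z)
    if current:
        segments.append(current)
    return segments


def aggregate_internodes(
    profile: StemProfile,
    slice_thickness_mm: float,
    genotype: str = "NA",
    plant_id: str = "NA",
    node_half_width: int = 1,
    fresh_mass_g: dict[int, float] | None = None,
    dry_mass_g: dict[int, float] | None = None,
) -> list[InternodeRecord]:
    """Average a cleaned profile into per-internode records.

    Length comes from the full slice span of each segment (slice count x
    slice thickness); diameter, intensity, pithy fraction and rind area are
    means over the retained slices only.  A segment with no retained slices
    yields no record (reported missing, never fabricated).  Optional mass
    dictionaries are keyed by internode number.
    """
    if not profile.traits:
        return []
    segments = internode_segments(
        profile.z_start, profile.z_end, profile.node_z_indices, node_half_width
    )
    by_z = {t.z_index: t for t in profile.traits}
    records: list[InternodeRecord] = []
    for num, seg in enumerate(segments, start=1):
        seg_traits = [by_z[z] for z in sorted(seg) if z in by_z]
        if not seg_traits:
            continue
        length_mm = internode_length_mm(len(seg), slice_thickness_mm)
        pithy_vals = [
            t.pithy_fraction for t in seg_traits if t.pithy_fraction is not None
        ]
        records.append(
            InternodeRecord(
                genotype=genotype,
                plant_id=plant_id,
                internode_number=num,
                length_cm=length_mm / 10.0,
                diameter_mm=float(np.mean([t.diameter_mm for t in seg_traits])),
                rind_area_px=float(np.mean([t.rind_area_px for t in seg_traits])),
                intensity=float(np.mean([t.intensity for t in seg_traits])),
                pithy_fraction=float(np.mean(pithy_vals)) if pithy_vals else None,
                n_slices=len(seg),
                n_retained_slices=len(seg_traits),
                fresh_mass_g=(fresh_mass_g or {}).get(num),
                dry_mass_g=(dry_mass_g or {}).get(num),
            )
        )
    return records


def profiles_to_frame(profiles: list[StemProfile]) -> pd.DataFrame:
    """Flatten stem profiles to a tidy per-slice DataFrame."""
    rows = []
    for p in profiles:
        for t in p.traits:
            rows.append(
                {
                    "stem_id": p.stem_id,
                    "grid_row": p.grid_cell[0],
                    "grid_col": p.grid_cell[1],
                    "z_index": t.z_index,
                    "center_row": t.center[0],
                    "center_col": t.center[1],
                    "diameter_px": t.diameter_px,
                    "diameter_mm": t.diameter_mm,
                    "rind_area_px": t.rind_area_px,
                    "intensity": t.intensity,
                    "pithy_fraction": (
                        np.nan if t.pithy_fraction is None else t.pithy_fraction
                    ),
                    "flags": ";".join(t.flags),
                }
            )
    return pd.DataFrame(rows)


def internodes_to_frame(records: list[InternodeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "genotype": r.genotype,
                "plant_id": r.plant_id,
                "internode_number": r.internode_number,
                "length_cm": r.length_cm,
                "diameter_mm": r.diameter_mm,
                "rind_area_px": r.rind_area_px,
                "intensity": r.intensity,
                "pithy_fraction": (
                    np.nan if r.pithy_fraction is None else r.pithy_fraction
                ),
                "volume_cm3": r.volume_cm3,
                "fresh_mass_g": np.nan if r.fresh_mass_g is None else r.fresh_mass_g,
                "dry_mass_g": np.nan if r.dry_mass_g is None else r.dry_mass_g,
                "density_g_cm3": (
                    np.nan if r.density_g_cm3 is None else r.density_g_cm3
                ),
                "n_slices": r.n_slices,
                "n_retained_slices": r.n_retained_slices,
            }
        )
    return pd.DataFrame(rows)
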