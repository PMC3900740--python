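"""Difference maps, half-split noise controls, contour counting, displacements.

The workflow mirrors standard 2D-crystal difference mapping: condition maps
are placed on a common cell and subtracted; random half-split controls of
same-condition data calibrate the noise floor; contour levels are drawn at a
fixed absolute step of 1.5 × σ of the control map, so a ±2-level background
corresponds to ~3σ; peak-to-trough contour counts in declared elliptical
regions quantify the conformational signal; and helix displacements are read
from intensity-weighted peak centroids of the two state maps.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .geometry import GeometryError, UnitCell2D, fractional_grid, mean_cell
from .mapsynth import ProjectionMap, synthesize_map
from .merging import merge_lattices, scale_amplitudes
from .simulate import LatticeDataset


class ControlError(ValueError):
    """Not enough data for a half-split control."""


class RegionError(ValueError):
    """Empty or invalid peak region."""


class DetectionError(ValueError):
    """No density peak above threshold."""


@dataclass(frozen=True)
class DifferenceMap:
    """Signed difference density with its absolute contouring calibration."""

    grid: np.ndarray
    cell: UnitCell2D
    contour_step: float            # absolute density units, 1.5·σ of the control
    background_levels: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        if self.contour_step <= 0:
            raise ValueError("contour_step must be positive")
        if self.background_levels < 0:
            raise ValueError("background_levels must be non-negative")

    @property
    def sigma(self) -> float:
        return float(self.grid.std())

    def negated(self) -> "DifferenceMap":
        return replace(self, grid=-self.grid)


@dataclass(frozen=True)
class PeakRegion:
    """Elliptical region of interest in the cell frame (angstroms)."""

    id: str
    center: np.ndarray             # (2,) Å
    semi_axes: np.ndarray          # (2,) Å
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(2))
        axes = np.asarray(self.semi_axes, float).reshape(2)
        if np.any(axes <= 0):
            raise RegionError(f"region {self.id}: semi-axes must be positive")
        object.__setattr__(self, "semi_axes", axes)

    def mask(self, cell: UnitCell2D, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of grid points inside the ellipse (minimum-image)."""
        xf, yf = fractional_grid(shape)
        cf = cell.cart_to_frac(self.center)
        dxf = (xf - cf[0] + 0.5) % 1.0 - 0.5
        dyf = (yf - cf[1] + 0.5) % 1.0 - 0.5
        M = cell.matrix
        dx = M[0, 0] * dxf + M[0, 1] * dyf
        dy = M[1, 0] * dxf + M[1, 1] * dyf
        r = np.deg2rad(self.rotation_deg)
        u = np.cos(r) * dx + np.sin(r) * dy
        v = -np.sin(r) * dx + np.cos(r) * dy
        return (u / self.semi_axes[0]) ** 2 + (v / self.semi_axes[1]) ** 2 <= 1.0

    def overlaps(self, other: "PeakRegion", cell: UnitCell2D, shape=(256, 320)) -> bool:
        return bool(np.any(self.mask(cell, shape) & other.mask(cell, shape)))


@dataclass(frozen=True)
class ContourCount:
    """Contour levels reached by the extreme densities inside one region."""

    region_id: str
    positive_levels: int
    negative_levels: int

    def __post_init__(self) -> None:
        if self.positive_levels < 0 or self.negative_levels < 0:
            raise ValueError("contour counts must be non-negative")

    @property
    def peak_to_trough(self) -> int:
        return self.positive_levels + self.negative_levels


# ---------------------------------------------------------------------------
def resample_common_cell(
    pmap: ProjectionMap, target: UnitCell2D, grid: tuple[int, int]
) -> ProjectionMap:
    """Re-grid one unit cell of density onto a target cell.

    Periodic bilinear interpolation in fractional coordinates — the numerical
    analogue of excising a map and placing it into a common cell.  Requires
    the cells to agree within 10% per axis.
    """
    if not pmap.cell.is_compatible(target, tol=0.10):
        raise GeometryError("source and target cells differ by more than 10%")
    nx, ny = int(grid[0]), int(grid[1])
    if (nx, ny) == pmap.shape:
        return ProjectionMap(grid=pmap.grid.copy(), cell=target)
    xf, yf = fractional_grid((nx, ny))
    sx, sy = pmap.shape
    coords = np.stack([xf * sx, yf * sy])
    out = ndimage.map_coordinates(pmap.grid, coords, order=1, mode="grid-wrap")
    return ProjectionMap(grid=out, cell=target)


def subtract_maps(
    a: ProjectionMap, b: ProjectionMap, contour_step: float, background_levels: int = 0
) -> DifferenceMap:
    """Pointwise a − b on a shared grid; ``b`` must already be scaled to ``a``.

    The contour step is the absolute value fixed by the half-split control of
    the analysis, never re-derived from this map's own σ.
    """
    if a.shape != b.shape:
        raise GeometryError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not a.cell.is_compatible(b.cell, tol=1e-6):
        raise GeometryError("maps must be on the same target cell")
    return DifferenceMap(
        grid=a.grid - b.grid,
        cell=a.cell,
        contour_step=contour_step,
        background_levels=background_levels,
    )


def half_split_control(
    lattices: list[LatticeDataset],
    seed: int,
    grid: tuple[int, int] = (128, 160),
    min_step: float = 1e-12,
    step_per_sigma: float = 1.5,
    reference=None,
) -> tuple[DifferenceMap, int]:
    """Noise-floor calibration from a random half-split of one condition.

    The lattices are randomly partitioned into two near-equal sets; each half
    is merged against a common reference and synthesized; the halves are
    amplitude-scaled and subtracted.  The contour step is 1.5 × σ of this
    control difference map (floored at ``min_step``), and the background
    level is the largest contour count found anywhere on the map.

    ``reference`` fixes the phase origin of both halves (e.g. the registered
    merge of the full condition); by default the first lattice serves.
    """
    if len(lattices) < 2:
        raise ControlError("half-split control needs at least 2 lattices")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(lattices))
    half = len(lattices) // 2
    sfs = [lat.sf for lat in lattices]
    ref = reference if reference is not None else sfs[0]
    merged_a, _ = merge_lattices([sfs[idx] for idx in perm[:half]], reference=ref)
    merged_b, _ = merge_lattices([sfs[idx] for idx in perm[half:]], reference=ref)
    kscale = scale_amplitudes(merged_b, merged_a)
    merged_b = merged_b.with_values(kscale * merged_b.values)
    cell = mean_cell([merged_a.cell, merged_b.cell])
    map_a = synthesize_map(merged_a, grid)
    map_b = synthesize_map(merged_b, grid)
    map_a = resample_common_cell(map_a, cell, grid)
    map_b = resample_common_cell(map_b, cell, grid)
    diff = map_a.grid - map_b.grid
    # degenerate (noise-free) data: residuals at the numerical-precision level
    # of the origin refinement constitute an empty control, not a noise floor
    empty = float(diff.std()) < 1e-4 * max(map_a.sigma, map_b.sigma, 1e-300)
    if empty:
        step, background = min_step, 0
    else:
        step = max(step_per_sigma * float(diff.std()), min_step)
        background = int(np.floor(np.max(np.abs(diff)) / step))
    control = DifferenceMap(
        grid=diff, cell=cell, contour_step=step, background_levels=background
    )
    return control, background


def count_contours(diff: DifferenceMap, region: PeakRegion) -> ContourCount:
    """Count contour lines reached by the extremes of ``diff`` inside ``region``.

    A contour line at level n exists only if the density reaches n·step, so
    counts are floors of the extreme values in units of the absolute step.
    """
    mask = region.mask(diff.cell, diff.grid.shape)
    if not np.any(mask):
        raise RegionError(f"region {region.id} covers no grid points")
    vals = diff.grid[mask]
    pos = int(max(0, np.floor(vals.max() / diff.contour_step)))
    neg = int(max(0, np.floor(-vals.min() / diff.contour_step)))
    return ContourCount(region_id=region.id, positive_levels=pos, negative_levels=neg)


def estimate_displacement(
    state_a: ProjectionMap,
    state_b: ProjectionMap,
    region: PeakRegion,
    threshold_sigmas: float = 1.0,
) -> float:
    """Distance (Å) between the dominant density peak of two state maps.

    Within the region, grid points above mean + ``threshold_sigmas``·σ (map
    statistics) mark the peak; its centroid is taken over the dominant
    connected component, weighting only density above half the in-region
    maximum so the estimate is insensitive to truncation by the region
    boundary.  Centroid positions are compared in fractional coordinates and
    the distance expressed in the mean-cell frame, so a uniform lattice-drift
    difference between the two maps' cells does not register as a helix
    movement.
    """
    frac_centroids = []
    for pmap in (state_a, state_b):
        mask = region.mask(pmap.cell, pmap.shape)
        if not np.any(mask):
            raise RegionError(f"region {region.id} covers no grid points")
        thresh = pmap.mean + threshold_sigmas * pmap.sigma
        above = mask & (pmap.grid > thresh)
        if not np.any(above):
            raise DetectionError(
                f"no peak above {threshold_sigmas}σ in region {region.id}"
            )
        labels, nlab = ndimage.label(above)
        strengths = ndimage.sum_labels(
            pmap.grid - thresh, labels, index=np.arange(1, nlab + 1)
        )
        sel = labels == (int(np.argmax(strengths)) + 1)
        floor = max(thresh, 0.5 * float(pmap.grid[sel].max()))
        weights = np.where(sel, np.clip(pmap.grid - floor, 0.0, None), 0.0)
        w = weights[sel]
        if w.sum() == 0:
            raise DetectionError(f"degenerate peak in region {region.id}")
        xf, yf = fractional_grid(pmap.shape)
        # unwrap around the region center so periodic boundaries cannot split
        cf = pmap.cell.cart_to_frac(region.center)
        fx = (xf[sel] - cf[0] + 0.5) % 1.0 - 0.5 + cf[0]
        fy = (yf[sel] - cf[1] + 0.5) % 1.0 - 0.5 + cf[1]
        frac_centroids.append(np.array([np.sum(w * fx), np.sum(w * fy)]) / np.sum(w))
    frame = mean_cell([state_a.cell, state_b.cell])
    return float(np.linalg.norm(frame.frac_to_cart(frac_centroids[1] - frac_centroids[0])))
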