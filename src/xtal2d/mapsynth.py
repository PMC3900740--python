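"""Fourier synthesis of projection maps from structure factors.

Maps follow the crystallographic convention

    ρ(x, y) = (1/A) Σ_{hk} F(h,k) · exp(+2πi (h·x + k·y)),

summed over the full reciprocal set (Friedel mates completed), with A the
cell area, so map values are densities per Å².  The F(0,0) term is excluded
throughout, giving maps of (near-)zero mean; σ-scaling is applied only when
contouring, never baked into the stored grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, UnitCell2D
from .reflections import StructureFactorSet


class SamplingError(GeometryError):
    """Grid too coarse for the requested resolution."""


@dataclass(frozen=True)
class ProjectionMap:
    """Real-space projection density on one unit cell."""

    grid: np.ndarray
    cell: UnitCell2D

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2 or g.shape[0] < 2 or g.shape[1] < 2:
            raise GeometryError("map grid must be 2D with at least 2 points per axis")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def mean(self) -> float:
        return float(self.grid.mean())

    @property
    def sigma(self) -> float:
        return float(self.grid.std())


def _check_nyquist(sf: StructureFactorSet, grid: tuple[int, int]) -> None:
    nx, ny = grid
    hmax = int(np.max(np.abs(sf.h), initial=0))
    kmax = int(np.max(np.abs(sf.k), initial=0))
    if nx < 2 * hmax + 1 or ny < 2 * kmax + 1:
        raise SamplingError(
            f"grid {grid} undersamples reflections up to ({hmax}, {kmax}); "
            f"need at least ({2 * hmax + 1}, {2 * kmax + 1})"
        )


def synthesize_map(sf: StructureFactorSet, grid: tuple[int, int]) -> ProjectionMap:
    """Inverse Fourier synthesis of a half-plane structure-factor set.

    Friedel mates are completed so the result is real to machine precision.
    """
    nx, ny = int(grid[0]), int(grid[1])
    _check_nyquist(sf, (nx, ny))
    F = np.zeros((nx, ny), dtype=complex)
    vals = sf.values
    F[sf.h % nx, sf.k % ny] += vals
    F[(-sf.h) % nx, (-sf.k) % ny] += np.conj(vals)
    rho = np.fft.ifft2(F).real * (nx * ny) / sf.cell.area
    return ProjectionMap(grid=rho, cell=sf.cell)


def map_to_structure_factors(pmap: ProjectionMap, d_min: float) -> StructureFactorSet:
    """Forward FFT of a gridded map back to a half-plane reflection list.

    Inverse of :func:`synthesize_map` up to sampling error; also serves as the
    numerical oracle for the analytic Gaussian transform.
    """
    nx, ny = pmap.shape
    h, k = pmap.cell.reflections_to(d_min)
    if np.max(h) * 2 + 1 > nx or np.max(np.abs(k)) * 2 + 1 > ny:
        raise SamplingError("map grid too coarse for the requested d_min")
    F = np.fft.fft2(pmap.grid) * pmap.cell.area / (nx * ny)
    vals = F[h % nx, k % ny]
    return StructureFactorSet(
        cell=pmap.cell,
        d_min=d_min,
        h=h,
        k=k,
        amplitude=np.abs(vals),
        phase_deg=np.rad2deg(np.angle(vals)) % 360.0,
    )
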