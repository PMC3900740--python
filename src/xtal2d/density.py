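"""Periodic Gaussian mixture densities and their analytic Fourier transforms.

The projected density of one unit cell is a sum of 2D Gaussians
ρ(r) = Σ_j w_j · N(r; c_j, Σ_j) repeated on the lattice.  Its structure
factors are available in closed form:

    F(h,k) = Σ_j w_j · exp(−2π² qᵀ Σ_j q) · exp(−2πi (h x_j + k y_j)),

with q = h a* + k b* the Cartesian scattering vector and (x_j, y_j) the
fractional center.  This is the forward model for the synthetic crystals and
the oracle against which FFT-based synthesis is checked.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import UnitCell2D, fractional_grid
from .reflections import StructureFactorSet
from .rods import ConformationModel, ModelError


@dataclass(frozen=True)
class GaussianDensity:
    """Weighted Gaussian components on a 2D lattice (fractional centers)."""

    cell: UnitCell2D
    frac: np.ndarray      # (n, 2) fractional centers
    cov: np.ndarray       # (n, 2, 2) Cartesian covariances, Å²
    weight: np.ndarray    # (n,) integrated masses

    def __post_init__(self) -> None:
        object.__setattr__(self, "frac", np.asarray(self.frac, float).reshape(-1, 2) % 1.0)
        object.__setattr__(self, "cov", np.asarray(self.cov, float).reshape(-1, 2, 2))
        object.__setattr__(self, "weight", np.asarray(self.weight, float).ravel())

    @classmethod
    def from_model(cls, model: ConformationModel) -> "GaussianDensity":
        frac, cov, w = model.components()
        return cls(cell=model.cell, frac=frac, cov=cov, weight=w)

    @classmethod
    def mixture(
        cls,
        apo: ConformationModel,
        bound: ConformationModel,
        theta: float,
    ) -> "GaussianDensity":
        """Population mixture (1−θ)·apo + θ·bound on the θ-interpolated cell.

        Component positions are carried over in fractional coordinates, which
        mirrors the practice of excising each map and placing it into a common
        cell before subtraction.
        """
        if not (0.0 <= theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")
        if apo.rod_ids != bound.rod_ids:
            raise ModelError("apo and bound models must share rod ids")
        cell = apo.cell.interpolate(bound.cell, theta)
        fa, ca, wa = apo.components()
        fb, cb, wb = bound.components()
        return cls(
            cell=cell,
            frac=np.concatenate([fa, fb]),
            cov=np.concatenate([ca, cb]),
            weight=np.concatenate([(1.0 - theta) * wa, theta * wb]),
        )

    @property
    def total_mass(self) -> float:
        return float(self.weight.sum())

    # ---- real space -------------------------------------------------------
    def rasterize(self, grid: tuple[int, int]) -> np.ndarray:
        """Sample the periodic density on an (nx, ny) fractional grid (Å⁻² units)."""
        xf, yf = fractional_grid(grid)
        M = self.cell.matrix
        rho = np.zeros(grid, dtype=float)
        images = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
        for c_frac, cov, w in zip(self.frac, self.cov, self.weight):
            if w == 0.0:
                continue
            prec = np.linalg.inv(cov)
            norm = w / (2.0 * np.pi * np.sqrt(np.linalg.det(cov)))
            for di, dj in images:
                dx = xf - (c_frac[0] + di)
                dy = yf - (c_frac[1] + dj)
                cx = M[0, 0] * dx + M[0, 1] * dy
                cy = M[1, 0] * dx + M[1, 1] * dy
                expo = prec[0, 0] * cx * cx + 2 * prec[0, 1] * cx * cy + prec[1, 1] * cy * cy
                rho += norm * np.exp(-0.5 * expo)
        return rho

    # ---- reciprocal space ---------------------------------------------------
    def structure_factors(self, d_min: float) -> StructureFactorSet:
        """Analytic structure factors of the mixture to resolution ``d_min``."""
        h, k = self.cell.reflections_to(d_min)
        q = self.cell.scattering_vectors(h, k)          # (m, 2)
        # exponent: −2π² q^T Σ q per component
        qq = np.einsum("mi,nij,mj->nm", q, self.cov, q)  # (n, m)
        decay = np.exp(-2.0 * np.pi**2 * qq)
        phase = np.exp(-2j * np.pi * (np.outer(self.frac[:, 0], h) + np.outer(self.frac[:, 1], k)))
        F = (self.weight[:, None] * decay * phase).sum(axis=0)
        return StructureFactorSet(
            cell=self.cell,
            d_min=d_min,
            h=h,
            k=k,
            amplitude=np.abs(F),
            phase_deg=np.rad2deg(np.angle(F)) % 360.0,
        )
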