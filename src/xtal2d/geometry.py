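"""2D crystal geometry: unit cells, reciprocal vectors, resolution limits.

The cell convention places the **a** axis along Cartesian x; **b** makes an
angle gamma (degrees) with **a**.  Fractional coordinates (x, y) map to
Cartesian angstroms through the cell matrix ``M = [a | b]`` (columns).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Incompatible cells or grids."""


@dataclass(frozen=True)
class UnitCell2D:
    """Two-dimensional crystal unit cell.

    Parameters
    ----------
    a, b : float
        Cell edge lengths in angstroms; must be positive.
    gamma : float, optional
        Included angle in degrees, ``0 < gamma < 180``.  Defaults to 90.
    """

    a: float
    b: float
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"cell edges must be positive, got a={self.a}, b={self.b}")
        if not (0.0 < self.gamma < 180.0):
            raise ValueError(f"gamma must lie in (0, 180) degrees, got {self.gamma}")

    # ---- real-space frame -------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """Cell matrix with lattice vectors as columns (Å)."""
        g = np.deg2rad(self.gamma)
        return np.array([[self.a, self.b * np.cos(g)], [0.0, self.b * np.sin(g)]])

    @property
    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @property
    def area(self) -> float:
        """Unit-cell area in Å²."""
        g = np.deg2rad(self.gamma)
        return self.a * self.b * np.sin(g)

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        """Fractional (..., 2) -> Cartesian Å (..., 2)."""
        return np.asarray(frac, dtype=float) @ self.matrix.T

    def cart_to_frac(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.inverse_matrix.T

    # ---- reciprocal space -------------------------------------------------
    @property
    def reciprocal(self) -> np.ndarray:
        """Rows are the reciprocal vectors a*, b* in Å⁻¹ (no 2π factor)."""
        return self.inverse_matrix

    def scattering_vectors(self, h: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Cartesian scattering vectors q = h a* + k b*, shape (..., 2), Å⁻¹."""
        hk = np.stack([np.asarray(h, float), np.asarray(k, float)], axis=-1)
        return hk @ self.reciprocal

    def d_spacing(self, h, k) -> np.ndarray:
        """Resolution d = 1/|q| of reflection (h, k) in Å (inf for (0,0))."""
        q = self.scattering_vectors(h, k)
        qn = np.linalg.norm(q, axis=-1)
        with np.errstate(divide="ignore"):
            return np.where(qn > 0, 1.0 / np.where(qn > 0, qn, 1.0), np.inf)

    def reflections_to(self, d_min: float) -> tuple[np.ndarray, np.ndarray]:
        """Unique half-plane Miller indices with d >= d_min.

        Convention: h > 0 for all k, plus h = 0 with k > 0; (0, 0) excluded.
        Returned sorted lexicographically by (h, k).
        """
        if d_min <= 0:
            raise ValueError("d_min must be positive")
        hmax = int(np.ceil(self.a / d_min)) + 1
        kmax = int(np.ceil(self.b / d_min)) + 1
        hs, ks = np.meshgrid(np.arange(0, hmax + 1), np.arange(-kmax, kmax + 1), indexing="ij")
        hs, ks = hs.ravel(), ks.ravel()
        half = (hs > 0) | ((hs == 0) & (ks > 0))
        keep = half & (self.d_spacing(hs, ks) >= d_min * (1 - 1e-12))
        hs, ks = hs[keep], ks[keep]
        order = np.lexsort((ks, hs))
        return hs[order].astype(int), ks[order].astype(int)

    # ---- comparisons ------------------------------------------------------
    def is_compatible(self, other: "UnitCell2D", tol: float = 0.10) -> bool:
        """True when edges agree to a relative tolerance and angles to 2°·(tol/0.1)."""
        return (
            abs(self.a - other.a) / self.a <= tol
            and abs(self.b - other.b) / self.b <= tol
            and abs(self.gamma - other.gamma) <= 20.0 * tol
        )

    def interpolate(self, other: "UnitCell2D", t: float) -> "UnitCell2D":
        """Linear interpolation between two cells (t = 0 -> self, t = 1 -> other)."""
        return UnitCell2D(
            a=(1 - t) * self.a + t * other.a,
            b=(1 - t) * self.b + t * other.b,
            gamma=(1 - t) * self.gamma + t * other.gamma,
        )


def mean_cell(cells: list[UnitCell2D]) -> UnitCell2D:
    return UnitCell2D(
        a=float(np.mean([c.a for c in cells])),
        b=float(np.mean([c.b for c in cells])),
        gamma=float(np.mean([c.gamma for c in cells])),
    )


def fractional_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Fractional sampling coordinates of an (nx, ny) map grid (pixel origins)."""
    nx, ny = shape
    xf = np.arange(nx) / nx
    yf = np.arange(ny) / ny
    return np.meshgrid(xf, yf, indexing="ij")
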