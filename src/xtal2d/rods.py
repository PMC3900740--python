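"""Gaussian-rod protomer models.

A transmembrane helix viewed down the membrane normal projects to a roughly
Gaussian density peak; a tilted helix projects to an elongated (anisotropic)
peak.  A conformational state of the protomer is a list of such rods plus a
rigid in-plane symmetry operation generating the second protomer of the dimer.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import UnitCell2D


class ModelError(ValueError):
    """Inconsistent conformation models."""


def _rotation(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class HelixRod:
    """One projected helix density peak.

    Attributes
    ----------
    id : str
        Helix label, e.g. ``"5c"``, ``"12e"``, ``"6"``, ``"13"``.
    center : ndarray, shape (2,)
        Peak position in angstroms, cell frame.
    covariance : ndarray, shape (2, 2)
        Symmetric positive-definite projected-width matrix (Å²); anisotropy
        encodes helix tilt elongation.
    mass : float
        Scattering weight (integral of the peak), arbitrary density units.
    order : float
        Fraction in [0, 1] scaling the amplitude; models positional disorder.
    """

    id: str
    center: np.ndarray
    covariance: np.ndarray
    mass: float = 1.0
    order: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(2))
        cov = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        object.__setattr__(self, "covariance", cov)
        if not np.allclose(cov, cov.T):
            raise ModelError(f"rod {self.id}: covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ModelError(f"rod {self.id}: covariance must be positive definite")
        if not (0.0 <= self.order <= 1.0):
            raise ModelError(f"rod {self.id}: order must lie in [0, 1]")
        if self.mass < 0:
            raise ModelError(f"rod {self.id}: mass must be non-negative")

    @classmethod
    def make(
        cls,
        id: str,
        x: float,
        y: float,
        sigma_long: float = 3.0,
        sigma_short: float | None = None,
        angle_deg: float = 0.0,
        mass: float = 1.0,
        order: float = 1.0,
    ) -> "HelixRod":
        """Build a rod from principal widths (Å) and a long-axis angle."""
        if sigma_short is None:
            sigma_short = sigma_long
        rot = _rotation(angle_deg)
        cov = rot @ np.diag([sigma_long**2, sigma_short**2]) @ rot.T
        return cls(id=id, center=np.array([x, y]), covariance=cov, mass=mass, order=order)

    def shifted(self, delta: np.ndarray) -> "HelixRod":
        return replace(self, center=self.center + np.asarray(delta, float))


@dataclass(frozen=True)
class DimerOp:
    """Rigid in-plane operation (fractional frame) generating protomer B.

    ``frac -> rot @ frac + trans`` and must be an involution (applying it
    twice is the identity modulo lattice translations).
    """

    rot: np.ndarray = field(default_factory=lambda: -np.eye(2))
    trans: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rot", np.asarray(self.rot, dtype=float).reshape(2, 2))
        object.__setattr__(self, "trans", np.asarray(self.trans, dtype=float).reshape(2))
        r2 = self.rot @ self.rot
        t2 = self.rot @ self.trans + self.trans
        if not np.allclose(r2, np.eye(2), atol=1e-9) or not np.allclose(t2 % 1.0, 0.0, atol=1e-9):
            raise ModelError("dimer operation must be an involution modulo the lattice")

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return (np.asarray(frac, float) @ self.rot.T + self.trans) % 1.0

    @classmethod
    def twofold(cls, center_frac=(0.5, 0.5)) -> "DimerOp":
        """In-plane twofold about ``center_frac`` (plane group p2)."""
        c = np.asarray(center_frac, float)
        return cls(rot=-np.eye(2), trans=(2.0 * c) % 1.0)


@dataclass(frozen=True)
class ConformationModel:
    """One conformational state of the dimeric transporter on its lattice."""

    state_label: str
    rods: tuple[HelixRod, ...]
    cell: UnitCell2D
    dimer_op: DimerOp | None = field(default_factory=DimerOp.twofold)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rods", tuple(self.rods))
        ids = [r.id for r in self.rods]
        if len(set(ids)) != len(ids):
            raise ModelError("rod ids must be unique within a protomer")

    @property
    def rod_ids(self) -> set[str]:
        return {r.id for r in self.rods}

    def rod(self, rod_id: str) -> HelixRod:
        for r in self.rods:
            if r.id == rod_id:
                return r
        raise KeyError(rod_id)

    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Expand dimer: fractional centers (n,2), covariances (n,2,2), weights (n,).

        Covariances stay in the Cartesian frame; the dimer rotation is applied
        to them through the cell matrix.
        """
        M = self.cell.matrix
        frac = np.array([self.cell.cart_to_frac(r.center) % 1.0 for r in self.rods])
        cov = np.array([r.covariance for r in self.rods])
        w = np.array([r.mass * r.order for r in self.rods])
        if self.dimer_op is None:
            return frac, cov, w
        frac_b = self.dimer_op.apply(frac)
        cart_rot = M @ self.dimer_op.rot @ np.linalg.inv(M)
        cov_b = np.einsum("ij,njk,lk->nil", cart_rot, cov, cart_rot)
        return (
            np.concatenate([frac, frac_b]),
            np.concatenate([cov, cov_b]),
            np.concatenate([w, w]),
        )

    def with_cell(self, cell: UnitCell2D) -> "ConformationModel":
        return replace(self, cell=cell)
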