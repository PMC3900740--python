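"""Na⁺ binding equilibrium with H⁺ competition.

A single shared site binds either Na⁺ or H⁺.  With intrinsic sodium
dissociation constant K_Na (mM) and a proton site of pK ``pk``, the apparent
sodium constant at a given pH is

    K_app = K_Na · (1 + [H⁺]/K_H) = K_Na · (1 + 10**(pk − pH)),

so acidification raises K_app (more Na⁺ is needed to displace protons).  The
bound-state occupancy follows the single-site isotherm θ = c / (c + K_app).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BindingParams:
    """Ground-truth binding parameters for the two-state lattice model.

    Attributes
    ----------
    kd_na : float
        Intrinsic Na⁺ dissociation constant in mM (> 0).
    pk : float
        pK of the competing proton site.
    ph : float
        Solution pH (0 < pH < 14).
    """

    kd_na: float
    pk: float
    ph: float

    def __post_init__(self) -> None:
        if self.kd_na <= 0:
            raise ValueError("kd_na must be positive")
        if not (0.0 < self.ph < 14.0):
            raise ValueError("ph must lie in (0, 14)")

    @property
    def kd_app(self) -> float:
        """Apparent Na⁺ dissociation constant (mM) at this pH."""
        return self.kd_na * (1.0 + 10.0 ** (self.pk - self.ph))

    def at_ph(self, ph: float) -> "BindingParams":
        return BindingParams(kd_na=self.kd_na, pk=self.pk, ph=ph)

    @classmethod
    def from_apparent(
        cls,
        kd_app_base: float,
        ph_base: float,
        kd_app_acid: float,
        ph_acid: float,
        ph: float | None = None,
    ) -> "BindingParams":
        """Solve (kd_na, pk) so the competition model matches two measured
        apparent constants, e.g. 30 mM at pH 8 and 280 mM at pH 4.
        """
        if ph_acid >= ph_base:
            raise ValueError("ph_acid must be more acidic than ph_base")
        if kd_app_acid <= kd_app_base:
            raise ValueError("competition requires the acidic apparent K_D to be larger")
        ta, tb = 10.0 ** (-ph_acid), 10.0 ** (-ph_base)
        ratio = kd_app_acid / kd_app_base
        u = (ratio - 1.0) / (ta - ratio * tb)  # u = 10**pk
        if u <= 0:
            raise ValueError("no positive solution for the proton affinity")
        kd_na = kd_app_base / (1.0 + u * tb)
        return cls(kd_na=kd_na, pk=float(np.log10(u)), ph=ph if ph is not None else ph_base)


def occupancy(na_mM, params: BindingParams):
    """Fraction of protomers in the Na⁺-bound conformation at ``na_mM``.

    θ(c) = c / (c + K_app); strictly increasing, θ(0) = 0, θ → 1 as c → ∞.
    Accepts scalars or arrays; raises on negative concentration.
    """
    c = np.asarray(na_mM, dtype=float)
    if np.any(c < 0):
        raise ValueError("Na+ concentration must be non-negative")
    theta = c / (c + params.kd_app)
    return float(theta) if np.isscalar(na_mM) else theta
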