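"""Structure-factor lists for 2D lattices.

A :class:`StructureFactorSet` holds one reciprocal half-plane of (h, k)
amplitudes and phases together with the cell, resolution limit and Friedel
convention.  The half-plane convention is h > 0 for any k, plus h = 0 with
k > 0; the Friedel mate F(-h,-k) = conj F(h,k) is implied (flag ``"+"``).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import UnitCell2D


class ReflectionError(ValueError):
    """Malformed reflection lists."""


def _canonical_order(h: np.ndarray, k: np.ndarray) -> np.ndarray:
    return np.lexsort((k, h))


@dataclass(frozen=True)
class StructureFactorSet:
    """(h, k) amplitude/phase list with its geometric metadata."""

    cell: UnitCell2D
    d_min: float
    h: np.ndarray
    k: np.ndarray
    amplitude: np.ndarray
    phase_deg: np.ndarray
    friedel: str = "+"

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=int).ravel()
        k = np.asarray(self.k, dtype=int).ravel()
        amp = np.asarray(self.amplitude, dtype=float).ravel()
        ph = np.asarray(self.phase_deg, dtype=float).ravel() % 360.0
        if not (h.size == k.size == amp.size == ph.size):
            raise ReflectionError("h, k, amplitude, phase must have equal lengths")
        if self.d_min <= 0:
            raise ReflectionError("d_min must be positive")
        order = _canonical_order(h, k)
        h, k, amp, ph = h[order], k[order], amp[order], ph[order]
        pairs = np.stack([h, k], axis=1)
        if len(np.unique(pairs, axis=0)) != len(pairs):
            raise ReflectionError("duplicate (h, k) indices")
        if np.any(~((h > 0) | ((h == 0) & (k > 0)))):
            raise ReflectionError("reflections must lie in the half-plane h>0 or (h=0, k>0)")
        if np.any(amp < 0):
            raise ReflectionError("amplitudes must be non-negative")
        d = self.cell.d_spacing(h, k)
        if np.any(d < self.d_min * (1 - 1e-9)):
            raise ReflectionError("reflection beyond the stated resolution limit")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "amplitude", amp)
        object.__setattr__(self, "phase_deg", ph)

    def __len__(self) -> int:
        return self.h.size

    @property
    def values(self) -> np.ndarray:
        """Complex structure factors F = A·exp(i·phase)."""
        return self.amplitude * np.exp(1j * np.deg2rad(self.phase_deg))

    def with_values(self, values: np.ndarray) -> "StructureFactorSet":
        values = np.asarray(values, dtype=complex).ravel()
        return replace(
            self,
            amplitude=np.abs(values),
            phase_deg=np.rad2deg(np.angle(values)) % 360.0,
        )

    def shift_origin(self, offset_frac) -> "StructureFactorSet":
        """Apply a real-space phase-origin shift by ``offset_frac`` (fractional).

        A density shifted by +t has phases reduced by 360·(h·tx + k·ty).
        """
        t = np.asarray(offset_frac, dtype=float).reshape(2)
        shift = -2.0 * np.pi * (self.h * t[0] + self.k * t[1])
        return self.with_values(self.values * np.exp(1j * shift))

    def index_map(self) -> dict[tuple[int, int], int]:
        return {(int(hh), int(kk)): i for i, (hh, kk) in enumerate(zip(self.h, self.k))}

    def common_with(self, other: "StructureFactorSet") -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (into self, into other) of shared (h, k)."""
        omap = other.index_map()
        mine, theirs = [], []
        for i, (hh, kk) in enumerate(zip(self.h, self.k)):
            j = omap.get((int(hh), int(kk)))
            if j is not None:
                mine.append(i)
                theirs.append(j)
        return np.asarray(mine, dtype=int), np.asarray(theirs, dtype=int)
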