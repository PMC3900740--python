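"""Phase-origin alignment, amplitude scaling, and lattice merging.

Individual 2D-crystal datasets carry arbitrary phase origins and overall
scales.  Merging aligns every lattice to a common origin (exhaustive Fourier
search plus local refinement), least-squares scales it to the reference, and
vector-averages the complex structure factors reflection by reflection.  The
quality metric is the amplitude-weighted mean absolute phase residual.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry import mean_cell
from .reflections import StructureFactorSet


class MergeError(ValueError):
    """Insufficient or incompatible data for merging."""


class ScaleError(ValueError):
    """Degenerate amplitude scaling."""


@dataclass(frozen=True)
class MergeReport:
    n_lattices: int
    phase_residual: float          # degrees, amplitude-weighted, vs merged reference
    scale_factors: tuple[float, ...]
    origin_offsets: tuple[tuple[float, float], ...]


def _wrap_deg(x: np.ndarray) -> np.ndarray:
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


def phase_residual(
    lattice: StructureFactorSet, reference: StructureFactorSet
) -> float:
    """Amplitude-weighted mean absolute phase difference in degrees."""
    i, j = lattice.common_with(reference)
    if i.size == 0:
        raise MergeError("no common reflections")
    w = lattice.amplitude[i] * reference.amplitude[j]
    dphi = np.abs(_wrap_deg(lattice.phase_deg[i] - reference.phase_deg[j]))
    if w.sum() == 0:
        return float(dphi.mean())
    return float(np.sum(w * dphi) / np.sum(w))


def align_phase_origin(
    lattice: StructureFactorSet,
    reference: StructureFactorSet,
    search_n: int = 240,
) -> tuple[StructureFactorSet, np.ndarray, float]:
    """Find the fractional origin shift aligning ``lattice`` onto ``reference``.

    Maximizes the amplitude-weighted phase correlation on an exhaustive
    ``search_n`` × ``search_n`` fractional grid (evaluated with a single FFT),
    then polishes with a derivative-free local minimization of the true
    residual.  Ties are broken toward the smallest shift vector.

    Returns (shifted lattice, offset, residual in degrees).
    """
    i, j = lattice.common_with(reference)
    if i.size < 3:
        raise MergeError(f"need at least 3 common reflections, got {i.size}")
    h, k = lattice.h[i], lattice.k[i]
    w = lattice.amplitude[i] * reference.amplitude[j]
    dphi = np.deg2rad(lattice.phase_deg[i] - reference.phase_deg[j])

    # C(t) = Σ w·cos(δ − 2π(h,k)·t) is an inverse-style Fourier sum; putting
    # z = w·exp(iδ) at (h, k) makes fft2(Z)[p, q] = Σ z·exp(−2πi(hp+kq)/N).
    n = search_n
    Z = np.zeros((n, n), dtype=complex)
    np.add.at(Z, (h % n, k % n), w * np.exp(1j * dphi))
    corr = np.fft.fft2(Z).real
    best = corr.max()
    cands = np.argwhere(corr >= best - 1e-9 * max(abs(best), 1.0))
    t_cands = ((cands / n) + 0.5) % 1.0 - 0.5
    t0 = t_cands[np.argmin(np.linalg.norm(t_cands, axis=1))]

    def objective(t):
        resid = np.abs(_wrap_deg(np.rad2deg(dphi - 2 * np.pi * (h * t[0] + k * t[1]))))
        return np.sum(w * resid) / np.sum(w) if w.sum() > 0 else resid.mean()

    res = minimize(objective, t0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10})
    t = ((res.x + 0.5) % 1.0) - 0.5
    # shifting the lattice by t subtracts 360·(h·t) from its phases
    shifted = lattice.shift_origin(t)
    return shifted, t, phase_residual(shifted, reference)


def scale_amplitudes(
    lattice: StructureFactorSet, reference: StructureFactorSet
) -> float:
    """Least-squares scale k minimizing Σ (A_ref − k·A_lat)² over common reflections."""
    i, j = lattice.common_with(reference)
    if i.size == 0:
        raise MergeError("no common reflections")
    a_lat, a_ref = lattice.amplitude[i], reference.amplitude[j]
    denom = float(np.sum(a_lat**2))
    if denom == 0:
        raise ScaleError("all lattice amplitudes are zero")
    return float(np.sum(a_ref * a_lat) / denom)


def merge_lattices(
    lattices: list[StructureFactorSet],
    reference: StructureFactorSet | None = None,
    cell_tol: float = 0.10,
) -> tuple[StructureFactorSet, MergeReport]:
    """Origin-align, scale, and vector-average a set of lattices.

    The first lattice (or ``reference``) defines the common phase origin.
    Cells must agree within ``cell_tol``; the merged set carries the mean cell.
    """
    if len(lattices) < 1:
        raise MergeError("need at least one lattice")
    ref = reference if reference is not None else lattices[0]
    for lat in lattices:
        if not lat.cell.is_compatible(ref.cell, cell_tol):
            raise MergeError("lattice cells are incompatible")

    aligned: list[StructureFactorSet] = []
    offsets: list[tuple[float, float]] = []
    scales: list[float] = []
    for lat in lattices:
        shifted, t, _ = align_phase_origin(lat, ref)
        kscale = scale_amplitudes(shifted, ref)
        aligned.append(shifted.with_values(kscale * shifted.values))
        offsets.append((float(t[0]), float(t[1])))
        scales.append(kscale)

    # vector average over the union of reflection indices
    accum: dict[tuple[int, int], complex] = {}
    counts: dict[tuple[int, int], int] = {}
    for lat in aligned:
        for hh, kk, v in zip(lat.h, lat.k, lat.values):
            key = (int(hh), int(kk))
            accum[key] = accum.get(key, 0.0) + v
            counts[key] = counts.get(key, 0) + 1
    keys = sorted(accum)
    vals = np.array([accum[key] / counts[key] for key in keys])
    h = np.array([key[0] for key in keys])
    k = np.array([key[1] for key in keys])
    merged = StructureFactorSet(
        cell=mean_cell([lat.cell for lat in lattices]),
        d_min=min(lat.d_min for lat in lattices),
        h=h,
        k=k,
        amplitude=np.abs(vals),
        phase_deg=np.rad2deg(np.angle(vals)) % 360.0,
    )
    residuals = [phase_residual(lat, merged) for lat in aligned]
    report = MergeReport(
        n_lattices=len(lattices),
        phase_residual=float(np.mean(residuals)),
        scale_factors=tuple(scales),
        origin_offsets=tuple(offsets),
    )
    return merged, report
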