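"""Synthetic two-state 2D crystal generator.

Emulates titration experiments on a dimeric antiporter lattice: every
molecule is either in the apo or the Na⁺-bound conformation, the bound
fraction follows the competition isotherm, and each imaged lattice yields a
noisy, arbitrarily phase-shifted and scaled reflection list — the statistical
raw material of the merging and difference-map stages.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import BindingParams, occupancy
from .density import GaussianDensity
from .mapsynth import ProjectionMap
from .reflections import StructureFactorSet
from .rods import ConformationModel

#: Ion labels that populate the bound conformation.  Li⁺ is a transported
#: substrate like Na⁺; Mg²⁺ (and K⁺, which is not transported) leave the
#: lattice in the apo state at any concentration.
SUBSTRATE_IONS = frozenset({"Na+", "Li+"})


@dataclass(frozen=True)
class Condition:
    """Buffer condition of one simulated dataset."""

    na_mM: float
    ph: float
    ion: str = "Na+"

    def __post_init__(self) -> None:
        if self.na_mM < 0:
            raise ValueError("ion concentration must be non-negative")


@dataclass(frozen=True)
class LatticeDataset:
    """One imaged crystal lattice: noisy reflections plus provenance."""

    sf: StructureFactorSet
    origin_offset: np.ndarray
    noise_sigma: float
    amp_scale: float
    seed: int
    condition: Condition

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin_offset", np.asarray(self.origin_offset, float).reshape(2))


def mixture_density(
    apo: ConformationModel,
    bound: ConformationModel,
    theta: float,
    grid: tuple[int, int],
) -> ProjectionMap:
    """Real-space (1−θ)·apo + θ·bound density on the θ-interpolated cell."""
    mix = GaussianDensity.mixture(apo, bound, theta)
    return ProjectionMap(grid=mix.rasterize(grid), cell=mix.cell)


def structure_factors(model, d_min: float) -> StructureFactorSet:
    """Analytic structure factors of a conformation model or Gaussian density."""
    if isinstance(model, ConformationModel):
        model = GaussianDensity.from_model(model)
    return model.structure_factors(d_min)


def mixture_structure_factors(
    apo: ConformationModel,
    bound: ConformationModel,
    theta: float,
    d_min: float,
) -> StructureFactorSet:
    return GaussianDensity.mixture(apo, bound, theta).structure_factors(d_min)


def simulate_lattice(
    sf: StructureFactorSet,
    noise_sigma: float,
    origin_offset=(0.0, 0.0),
    amp_scale: float = 1.0,
    seed: int = 0,
    condition: Condition | None = None,
) -> LatticeDataset:
    """Degrade ideal structure factors into one observed lattice.

    Each complex structure factor is scaled by ``amp_scale``, phase-shifted by
    the fractional ``origin_offset``, and perturbed by independent zero-mean
    Gaussian noise of scale ``noise_sigma`` on the real and imaginary parts.
    Bit-reproducible for a fixed seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if amp_scale <= 0:
        raise ValueError("amp_scale must be positive")
    shifted = sf.shift_origin(origin_offset)
    values = amp_scale * shifted.values
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sigma, size=(len(sf), 2))
        values = values + noise[:, 0] + 1j * noise[:, 1]
    return LatticeDataset(
        sf=shifted.with_values(values),
        origin_offset=np.asarray(origin_offset, float),
        noise_sigma=noise_sigma,
        amp_scale=amp_scale,
        seed=seed,
        condition=condition if condition is not None else Condition(na_mM=0.0, ph=7.0),
    )


def simulate_condition(
    apo: ConformationModel,
    bound: ConformationModel,
    params: BindingParams,
    na_mM: float,
    n_lattices: int,
    noise_sigma: float,
    seed: int,
    ion: str = "Na+",
    d_min: float = 6.0,
    amp_scale_spread: float = 0.15,
) -> list[LatticeDataset]:
    """Simulate ``n_lattices`` independent crystals of one buffer condition.

    The bound-state occupancy follows the isotherm for substrate ions and is
    pinned at zero for non-transported control ions; each lattice receives its
    own random phase origin, log-normal amplitude scale, and noise stream.
    """
    if n_lattices < 1:
        raise ValueError("n_lattices must be at least 1")
    theta = occupancy(na_mM, params) if ion in SUBSTRATE_IONS else 0.0
    ideal = mixture_structure_factors(apo, bound, theta, d_min)
    cond = Condition(na_mM=na_mM, ph=params.ph, ion=ion)
    ss = np.random.SeedSequence(seed)
    lattices = []
    for child in ss.spawn(n_lattices):
        rng = np.random.default_rng(child)
        offset = rng.uniform(0.0, 1.0, size=2)
        scale = float(np.exp(rng.normal(0.0, amp_scale_spread)))
        lat_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        lattices.append(
            simulate_lattice(
                ideal,
                noise_sigma=noise_sigma,
                origin_offset=offset,
                amp_scale=scale,
                seed=lat_seed,
                condition=cond,
            )
        )
    return lattices
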