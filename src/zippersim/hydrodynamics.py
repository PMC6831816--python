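"""Translational diffusion of peptide blocks treated as rod-like particles.

Blocks are mapped onto circular cylinders: the rod length ``L`` is the
longest block dimension and the rod diameter ``d`` is that of the circle
with the same cross-sectional area as the block.  The translational
diffusion coefficient uses the cylinder interpolation

    D = k_B T (ln p + nu(p)) / (3 pi eta L),      p = L / d,
    nu(p) = 0.312 + 0.565 / p + 0.100 / p**2,

with the aspect ratio clamped below at 1 for compact, cube-like blocks.
Coupling between particle orientation and direction of motion is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple

from .constants import K_BOLTZMANN, METRE_PER_ANGSTROM
from .lattice_geometry import PolymorphSpec, per_peptide_cell


@dataclass(frozen=True)
class SolventConditions:
    """Temperature (K) and dynamic viscosity (Pa s) of the solvent."""

    temperature: float = 300.0
    viscosity: float = 0.89e-3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")


def _end_effect(p: float) -> float:
    """Cylinder end-effect interpolation nu(p)."""
    return 0.312 + 0.565 / p + 0.100 / (p * p)


def rod_diffusion_coefficient(dims: Tuple[float, float, float],
                              cond: SolventConditions) -> float:
    """Translational diffusion coefficient (m^2/s) of a rectangular block.

    ``dims`` are the block dimensions in Angstrom.  The block is treated as
    a cylinder of length equal to its longest dimension and of diameter
    matching its cross-sectional area; aspect ratios below 1 are clamped.
    """
    if any(d <= 0 for d in dims):
        raise ValueError(f"block dimensions must be positive, got {dims}")
    return _rod_diffusion_cached(tuple(sorted(dims)), cond.temperature,
                                 cond.viscosity)


@lru_cache(maxsize=1 << 18)
def _rod_diffusion_cached(sorted_dims: Tuple[float, float, float],
                          temperature: float, viscosity: float) -> float:
    length = sorted_dims[2] * METRE_PER_ANGSTROM
    cross_area = sorted_dims[0] * sorted_dims[1] * METRE_PER_ANGSTROM ** 2
    diameter = math.sqrt(4.0 * cross_area / math.pi)
    p = max(length / diameter, 1.0)
    numerator = K_BOLTZMANN * temperature * (math.log(p) + _end_effect(p))
    return numerator / (3.0 * math.pi * viscosity * length)


def monomer_tau0(spec: PolymorphSpec, cond: SolventConditions) -> float:
    """Dynamical timescale tau_0 (s): time for a peptide to diffuse its own
    length.

    Uses the three-dimensional mean-squared-displacement convention
    ``tau_0 = l^2 / (6 D)`` with ``l`` the longest per-peptide cell
    dimension and ``D`` the monomer's rod diffusion coefficient.
    """
    cell = per_peptide_cell(spec)
    d_monomer = rod_diffusion_coefficient(cell, cond)
    length = max(cell) * METRE_PER_ANGSTROM
    return length * length / (6.0 * d_monomer)
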