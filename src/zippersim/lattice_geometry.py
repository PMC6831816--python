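"""Lattice geometry of the two competing nanocrystal polymorphs.

A growing aggregate is modelled as a rectangular block of ``n_a x n_b x n_c``
peptides, where the three axes are the backbone (terminus-terminus) axis *a*,
the sidechain-stacking axis *b* and the hydrogen-bonding (fibril) axis *c*.
This module maps integer block shapes onto physical dimensions and face areas
using the unit-cell parameters of each polymorph:

* the antiparallel (AP) polymorph packs on a rectangular plane group (p1),
* the parallel (P) polymorph packs on a herringbone plane group (p2), in
  which translation along *a* is accompanied by a 180 degree rotation, so the
  primitive translational cell length along *a* is twice the effective
  peptide repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal, Tuple

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for typing only
    from .interface_energetics import EnergyTable

Axis = Literal["a", "b", "c"]
Symmetry = Literal["rectangular_p1", "herringbone_p2"]

_VALID_AXES = ("a", "b", "c")


@dataclass(frozen=True)
class LatticeParams:
    """Unit-cell constants and peptide content of one polymorph lattice.

    Lengths are in Angstrom, ``gamma`` in degrees.  ``peptides_per_cell_*``
    give how many peptides the translational cell holds along each axis, so
    that lattice constants can be reduced to per-peptide repeats.
    """

    a: float
    b: float
    c: float
    gamma: float = 90.0
    peptides_per_cell_a: int = 1
    peptides_per_cell_b: int = 1
    peptides_per_cell_c: int = 1

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"lattice constant {name} must be positive, "
                                 f"got {getattr(self, name)}")
        if not (0.0 < self.gamma <= 180.0):
            raise ValueError(f"gamma must lie in (0, 180], got {self.gamma}")
        for name in ("peptides_per_cell_a", "peptides_per_cell_b",
                     "peptides_per_cell_c"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class BlockShape:
    """Integer peptide counts of a rectangular block along the a, b, c axes.

    The sidechain axis count ``n_b`` is restricted to 1 or an even integer:
    blocks with an odd number (> 1) of sheets would expose a broken steric
    zipper while burying the weaker plain *b* interface ("inside-out"
    species) and are excluded from the model as a hard shape constraint.
    """

    n_a: int
    n_b: int
    n_c: int

    def __post_init__(self) -> None:
        for name in ("n_a", "n_b", "n_c"):
            v = getattr(self, name)
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
            if iv != v or iv < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
            object.__setattr__(self, name, iv)
        if self.n_b > 1 and self.n_b % 2 != 0:
            raise ValueError(
                f"n_b must be 1 or even (inside-out exclusion), got {self.n_b}")

    @property
    def n_peptides(self) -> int:
        return self.n_a * self.n_b * self.n_c

    def as_tuple(self) -> Tuple[int, int, int]:
        return (self.n_a, self.n_b, self.n_c)


def valid_n_b(n_b: int) -> bool:
    """Whether a sidechain-axis count is admissible (1 or even)."""
    return n_b == 1 or (n_b >= 2 and n_b % 2 == 0)


@dataclass(frozen=True)
class PolymorphSpec:
    """One polymorph: label, plane-group symmetry, lattice and energy table."""

    label: Literal["AP", "P"]
    symmetry: Symmetry
    lattice: LatticeParams
    energies: "EnergyTable" = field(repr=False)

    def __post_init__(self) -> None:
        expected = {"AP": "rectangular_p1", "P": "herringbone_p2"}
        if self.symmetry != expected[self.label]:
            raise ValueError(
                f"polymorph {self.label} must use symmetry {expected[self.label]}, "
                f"got {self.symmetry}")


def per_peptide_cell(spec: PolymorphSpec) -> Tuple[float, float, float]:
    """Per-peptide repeat lengths (Angstrom) along a, b, c.

    Divides each lattice constant by the number of peptides the cell holds
    along that axis.
    """
    lat = spec.lattice
    return (lat.a / lat.peptides_per_cell_a,
            lat.b / lat.peptides_per_cell_b,
            lat.c / lat.peptides_per_cell_c)


def block_dimensions(shape: BlockShape,
                     spec: PolymorphSpec) -> Tuple[float, float, float]:
    """Physical dimensions (Angstrom) of a block, linear in each shape index."""
    ca, cb, cc = per_peptide_cell(spec)
    return (shape.n_a * ca, shape.n_b * cb, shape.n_c * cc)


def face_area(shape: BlockShape, spec: PolymorphSpec, axis: str) -> float:
    """Area (Angstrom^2) of the block face perpendicular to ``axis``.

    This is the assembly-competent contact area entering the collision
    kernels: the product of the two block dimensions perpendicular to the
    named axis.
    """
    if axis not in _VALID_AXES:
        raise ValueError(f"axis must be one of {_VALID_AXES}, got {axis!r}")
    da, db, dc = block_dimensions(shape, spec)
    if axis == "a":
        return db * dc
    if axis == "b":
        return da * dc
    return da * db


def effective_a_repeat(lattice: LatticeParams, symmetry: Symmetry) -> float:
    """Effective repeat length along *a* once lattice symmetry is applied.

    For the herringbone (p2) packing, translation by half the cell combined
    with a 180 degree rotation maps the lattice onto itself, so the effective
    *a* repeat is half the translational cell length.  For the rectangular
    (p1) packing the translational cell length is already the repeat.
    """
    if symmetry == "herringbone_p2":
        return lattice.a / 2.0
    if symmetry == "rectangular_p1":
        return lattice.a
    raise ValueError(f"unknown symmetry {symmetry!r}")
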