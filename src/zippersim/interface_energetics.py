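"""Interface free energies for block joins and splits in both polymorphs.

The model assigns a standard binding free energy to every buried interface
of a rectangular peptide block.  For the rectangular AP lattice the energy
is strictly linear in the number of buried peptides (e.g. an *a*-plane
interface buries ``n_b * n_c`` peptides).  For the herringbone P lattice the
jagged, overhanging edges make lateral interfaces sub-linear in the early
stages of growth; they are composed from the two per-zipper terms ``eps``
and ``eps_prime``:

* *a*-plane interface: ``(2 n_b - 1) * eps / 2`` per unit of ``n_c - 1/2``,
  chosen so a single-sheet association (n_b = 1) buries half a steric
  zipper, and every subsequent whole zipper adds ``eps``;
* *b*-plane interface: ``(n_a - 1) * eps + n_a * eps_prime`` per unit of
  ``n_c - 1/2``.

The factor ``n_c - 1/2`` (instead of ``n_c``) accounts for the half-cell
step between adjacent sheets along the hydrogen-bond axis of the
herringbone lattice; it applies to all lateral (ab-plane) interfaces,
including the intra-cell steric zipper, but not to the *c* interface.

The module also provides the estimators that recover the four per-plane
standard energies from reference block free energies ``G_ijk`` (averages of
minimised block energies), and their large-aggregate limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Literal, Optional, Tuple

from .lattice_geometry import BlockShape, PolymorphSpec, valid_n_b

PlaneAxis = Literal["a", "b", "zip", "c"]
BSplitKind = Literal["zip", "b", "forbidden"]

_PLANE_AXES = ("a", "b", "zip", "c")


@dataclass(frozen=True)
class EnergyTable:
    """Standard per-peptide interface free energies of one polymorph.

    All energies are in kcal/mol per buried peptide; attractive interfaces
    are negative.  ``eps`` and ``eps_prime`` are the herringbone zipper
    terms and are only set for the P polymorph, in which case the lateral
    *a*/*b* interfaces are composed from them rather than read from
    ``dG_a``/``dG_b``.
    """

    dG_a: float
    dG_b: float
    dG_zip: float
    dG_c: float
    eps: Optional[float] = None
    eps_prime: Optional[float] = None

    @property
    def is_herringbone(self) -> bool:
        return self.eps is not None

    @classmethod
    def rectangular(cls, dG_a: float, dG_b: float, dG_zip: float,
                    dG_c: float) -> "EnergyTable":
        """Table for the rectangular (AP) lattice: four linear terms."""
        return cls(dG_a=dG_a, dG_b=dG_b, dG_zip=dG_zip, dG_c=dG_c)

    @classmethod
    def herringbone(cls, eps: float, eps_prime: float, dG_zip: float,
                    dG_c: float) -> "EnergyTable":
        """Table for the herringbone (P) lattice.

        ``dG_a`` and ``dG_b`` are filled with their large-aggregate limits
        (``eps/2`` and ``eps + eps_prime``) for reporting purposes; the
        interface energies themselves are composed from ``eps`` and
        ``eps_prime`` directly.
        """
        return cls(dG_a=eps / 2.0, dG_b=eps + eps_prime, dG_zip=dG_zip,
                   dG_c=dG_c, eps=eps, eps_prime=eps_prime)


@dataclass(frozen=True)
class BlockEnergyRecord:
    """Reference free energy of one block shape.

    ``G`` is the mean minimised free energy (kcal/mol) over ``n_samples``
    block realisations and ``ese`` its standard error.
    """

    shape: BlockShape
    G: float
    n_samples: int = 1
    ese: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.ese < 0:
            raise ValueError("ese must be >= 0")


@dataclass(frozen=True)
class SplitPlane:
    """A cleavage plane: axis ('a', 'b', 'zip' or 'c') and cut position.

    ``position`` counts peptides on the lower side of the cut, so a valid
    position splits the block into two non-empty sub-blocks.
    """

    axis: PlaneAxis
    position: int

    def __post_init__(self) -> None:
        if self.axis not in _PLANE_AXES:
            raise ValueError(f"axis must be one of {_PLANE_AXES}, "
                             f"got {self.axis!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")


def classify_b_split(n_b_parent: int, n_b_left: int,
                     n_b_right: int) -> BSplitKind:
    """Classify a cut along the sidechain axis as zip, plain-b or forbidden.

    A block with an even sheet count splitting into two odd-count halves
    breaks a steric zipper ('zip'); splitting into two even-count halves
    breaks the weaker inter-cell interface ('b').  Any split that would
    create a block with an odd sheet count greater than one is forbidden
    (the "inside-out" exclusion).
    """
    if n_b_left + n_b_right != n_b_parent:
        raise ValueError(
            f"non-conserving b split: {n_b_left}+{n_b_right} != {n_b_parent}")
    if n_b_left < 1 or n_b_right < 1:
        raise ValueError("both halves of a split must be non-empty")
    if not valid_n_b(n_b_left) or not valid_n_b(n_b_right):
        return "forbidden"
    if n_b_left % 2 == 1 and n_b_right % 2 == 1:
        return "zip"
    if n_b_left % 2 == 0 and n_b_right % 2 == 0:
        return "b"
    # odd(=1) + even parent would itself have odd n_b > 1: unreachable for
    # admissible parents, treat as forbidden for safety.
    return "forbidden"


def interface_free_energy(spec: PolymorphSpec, plane: "SplitPlane | str",
                          shape: BlockShape) -> float:
    """Standard free energy (kcal/mol) of the buried interface on ``plane``.

    ``shape`` is the block whose face geometry defines the interface; only
    the two shape indices perpendicular to the plane's axis enter.  The
    *b*-axis plane must already have been classified as 'zip' or 'b'.
    """
    axis = plane.axis if isinstance(plane, SplitPlane) else plane
    if axis not in _PLANE_AXES:
        raise ValueError(f"unknown interface axis {axis!r}")
    tab = spec.energies
    na, nb, nc = shape.n_a, shape.n_b, shape.n_c
    if not tab.is_herringbone:
        if axis == "a":
            return nb * nc * tab.dG_a
        if axis == "b":
            return na * nc * tab.dG_b
        if axis == "zip":
            return na * nc * tab.dG_zip
        return na * nb * tab.dG_c
    if tab.eps is None or tab.eps_prime is None:
        raise ValueError("herringbone table requires eps and eps_prime")
    lateral = nc - 0.5
    if axis == "a":
        return (2 * nb - 1) * (tab.eps / 2.0) * lateral
    if axis == "b":
        return ((na - 1) * tab.eps + na * tab.eps_prime) * lateral
    if axis == "zip":
        # Intra-cell zipper: one zipper column per peptide along a, with the
        # same half-cell overhang correction as the other lateral planes.
        return na * lateral * tab.dG_zip
    return na * nb * tab.dG_c


_REQUIRED_SHAPES: Tuple[Tuple[int, int, int], ...] = (
    (1, 1, 1), (1, 1, 10), (1, 2, 10), (2, 2, 3), (2, 4, 3), (1, 4, 3),
)


def estimate_interface_energies(records: Iterable[BlockEnergyRecord],
                                polymorph: Literal["AP", "P"]) -> EnergyTable:
    """Recover per-plane standard energies from reference block energies.

    The estimators are finite differences between joined and separated
    blocks, divided by the number of peptides buried in the reference
    interface::

        dG_c   = (G(1,1,10) - 10 G(1,1,1)) / 9
        dG_zip = (G(1,2,10) -  2 G(1,1,10)) / 9.5   (P; /10 for AP)
        dG_b   = (G(2,4,3)  -  2 G(2,2,3)) / 6
        dG_a   = (G(2,4,3)  -  2 G(1,4,3)) / 12

    The zip divisor for the P polymorph is 9.5 rather than 10 because of
    the half-cell overhang along *c* between adjacent herringbone sheets.
    The estimators are exact when the block energies are additive in the
    per-interface terms.
    """
    if polymorph not in ("AP", "P"):
        raise ValueError(f"polymorph must be 'AP' or 'P', got {polymorph!r}")
    by_shape: Dict[Tuple[int, int, int], float] = {}
    for rec in records:
        by_shape[rec.shape.as_tuple()] = rec.G
    missing = [s for s in _REQUIRED_SHAPES if s not in by_shape]
    if missing:
        raise ValueError(
            "missing required block shapes for energy estimation: "
            + ", ".join(str(s) for s in missing))
    G = by_shape
    zip_div = 9.5 if polymorph == "P" else 10.0
    dG_c = (G[(1, 1, 10)] - 10.0 * G[(1, 1, 1)]) / 9.0
    dG_zip = (G[(1, 2, 10)] - 2.0 * G[(1, 1, 10)]) / zip_div
    dG_b = (G[(2, 4, 3)] - 2.0 * G[(2, 2, 3)]) / 6.0
    dG_a = (G[(2, 4, 3)] - 2.0 * G[(1, 4, 3)]) / 12.0
    return EnergyTable(dG_a=dG_a, dG_b=dG_b, dG_zip=dG_zip, dG_c=dG_c)


def large_aggregate_limits(table: EnergyTable) -> Tuple[float, float]:
    """Per-peptide lateral growth energies in the large-aggregate limit.

    For a herringbone table the limits follow from the zipper composition:
    adding an *a* interface costs ``eps/2`` per buried peptide and a *b*
    interface ``eps + eps_prime``.  For a rectangular table the energies
    are already linear, so the limits are the table entries themselves.
    """
    if table.is_herringbone:
        assert table.eps_prime is not None
        return (table.eps / 2.0, table.eps + table.eps_prime)
    return (table.dG_a, table.dG_b)


def split_products(shape: BlockShape, plane: SplitPlane
                   ) -> Tuple[BlockShape, BlockShape]:
    """The two sub-blocks produced by cutting ``shape`` on ``plane``.

    Raises if the position does not split the block into two non-empty
    admissible sub-blocks.
    """
    na, nb, nc = shape.as_tuple()
    p = plane.position
    if plane.axis == "a":
        if not 1 <= p < na:
            raise ValueError(f"a-position {p} invalid for n_a={na}")
        return BlockShape(p, nb, nc), BlockShape(na - p, nb, nc)
    if plane.axis in ("b", "zip"):
        if not 1 <= p < nb:
            raise ValueError(f"b-position {p} invalid for n_b={nb}")
        kind = classify_b_split(nb, p, nb - p)
        if kind == "forbidden":
            raise ValueError(
                f"b split {nb} -> {p}+{nb - p} is forbidden (inside-out)")
        if kind != plane.axis:
            raise ValueError(
                f"b split {nb} -> {p}+{nb - p} is a {kind!r} split, "
                f"not {plane.axis!r}")
        return BlockShape(na, p, nc), BlockShape(na, nb - p, nc)
    if not 1 <= p < nc:
        raise ValueError(f"c-position {p} invalid for n_c={nc}")
    return BlockShape(na, nb, p), BlockShape(na, nb, nc - p)


def allowed_b_positions(n_b: int) -> Tuple[Tuple[int, BSplitKind], ...]:
    """All admissible cut positions along the sidechain axis with their kind."""
    out = []
    for p in range(1, n_b):
        kind = classify_b_split(n_b, p, n_b - p)
        if kind != "forbidden":
            out.append((p, kind))
    return tuple(out)
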