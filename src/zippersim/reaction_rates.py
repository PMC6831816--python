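"""Rate constants for every reaction class of the assembly network.

Three classes of process are constructed between rectangular peptide blocks:

* **join** — diffusion-limited collision of two blocks on geometrically
  matching faces.  The rate constant is
  ``k = 2 e^-3 (D_A + D_B) sqrt(2 * A_contact)`` where ``A_contact`` is the
  contact-face area and the ``e^-3`` barrier accounts for the loss of
  translational and rotational degrees of freedom on binding.
* **split** — Arrhenius fragmentation of one block on an internal lattice
  plane, ``k = (1/tau_0) exp(dG_plane / k_B T)`` with ``dG_plane`` the (non
  positive) free energy of the buried interface and ``tau_0`` the time for
  a monomer to diffuse its own length.
* **join_split** — compound collision of two blocks whose contact faces
  mismatch in one or two dimensions.  The virtual non-rectangular collision
  product is immediately resolved back into rectangular blocks by cleaving
  the overhangs; the compound rate multiplies the join kernel by
  ``tau_0 * k_split`` for each cleavage.  Where two cleavage-plane
  choices exist, both are evaluated and only the fastest is retained.

Any channel whose rate constant falls below the pruning threshold of
1e-50 (in the engine's per-second propensity-prefactor units) is discarded
from the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple

from .constants import arrhenius_thermal_energy
from .hydrodynamics import SolventConditions, rod_diffusion_coefficient
from .interface_energetics import (
    allowed_b_positions,
    classify_b_split,
    interface_free_energy,
    split_products,
    SplitPlane,
)
from .lattice_geometry import (
    BlockShape,
    PolymorphSpec,
    block_dimensions,
    per_peptide_cell,
    valid_n_b,
)

Tag = Literal["MONOMER", "AP", "P"]
ReactionKind = Literal["join", "join_split", "split"]

#: Barrier factor for the loss of translational and rotational freedom on
#: joining two blocks (about 3 k_B T).
BARRIER_FACTOR = math.exp(-3.0)

#: Rate constants below this value (per-second propensity prefactor) are
#: discarded from the reaction network.
PRUNE_THRESHOLD = 1e-50

_M_PER_A = 1.0e-10

#: Perpendicular axes for each contact axis, in (first, second) order.
_PERP = {"a": ("b", "c"), "b": ("a", "c"), "c": ("a", "b")}
_AXIS_INDEX = {"a": 0, "b": 1, "c": 2}


@dataclass(frozen=True)
class Species:
    """A population of identical blocks: polymorph tag plus block shape.

    Uncommitted monomers carry the tag ``MONOMER`` and, conversely, every
    (1,1,1) block is an uncommitted monomer: commitment to a polymorph is
    only defined within an assembly.
    """

    tag: Tag
    shape: BlockShape

    def __post_init__(self) -> None:
        is_monomer_shape = self.shape.as_tuple() == (1, 1, 1)
        if (self.tag == "MONOMER") != is_monomer_shape:
            raise ValueError(
                f"MONOMER tag is reserved for shape (1,1,1): "
                f"got {self.tag} with {self.shape.as_tuple()}")

    @property
    def n_peptides(self) -> int:
        return self.shape.n_peptides

    def signature(self) -> Tuple[str, int, int, int]:
        return (self.tag, *self.shape.as_tuple())


MONOMER = Species("MONOMER", BlockShape(1, 1, 1))

_SPECIES_INTERN: Dict[Tuple[str, int, int, int], Species] = {}


def make_species(tag: str, n_a: int, n_b: int, n_c: int) -> Species:
    """Build a species, mapping any (1,1,1) block back to MONOMER.

    Species are interned so repeated construction during network
    enumeration is a dictionary lookup.
    """
    if (n_a, n_b, n_c) == (1, 1, 1):
        return MONOMER
    key = (tag, n_a, n_b, n_c)
    sp = _SPECIES_INTERN.get(key)
    if sp is None:
        sp = Species(tag, BlockShape(n_a, n_b, n_c))  # type: ignore[arg-type]
        _SPECIES_INTERN[key] = sp
    return sp


@dataclass(frozen=True)
class Reaction:
    """One reaction channel blueprint.

    ``rate_constant`` is in m^3/s for bimolecular kinds and 1/s for splits.
    ``multiplicity`` counts equivalent planes (split channels only); the
    engine multiplies it into the propensity.
    """

    kind: ReactionKind
    reactants: Tuple[Species, ...]
    products: Tuple[Species, ...]
    rate_constant: float
    contact_axis: Optional[str] = None
    plane: Optional[str] = None
    multiplicity: int = 1

    def __post_init__(self) -> None:
        n_in = sum(s.n_peptides for s in self.reactants)
        n_out = sum(s.n_peptides for s in self.products)
        if n_in != n_out:
            raise ValueError(
                f"peptide count not conserved: {n_in} -> {n_out} in {self}")
        if self.rate_constant < 0:
            raise ValueError("rate constant must be non-negative")


def prune(k: float) -> bool:
    """True iff a channel with rate constant ``k`` should be discarded."""
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    return k < PRUNE_THRESHOLD


def collision_rate_constant(sA: Species, sB: Species, contact_axis: str,
                            spec: PolymorphSpec, cond: SolventConditions,
                            contact_area: Optional[float] = None) -> float:
    """Diffusion-limited join rate constant (m^3/s) for a face-to-face
    collision along ``contact_axis``.

    ``contact_area`` (Angstrom^2) overrides the default contact patch,
    which is the overlap of the two faces perpendicular to the contact
    axis.  The kernel is symmetric in its two species arguments.
    """
    dims_a = block_dimensions(sA.shape, spec)
    dims_b = block_dimensions(sB.shape, spec)
    D_a = rod_diffusion_coefficient(dims_a, cond)
    D_b = rod_diffusion_coefficient(dims_b, cond)
    if contact_area is None:
        contact_area = _overlap_area(sA.shape, sB.shape, contact_axis, spec)
    area_m2 = contact_area * _M_PER_A * _M_PER_A
    return 2.0 * BARRIER_FACTOR * (D_a + D_b) * math.sqrt(2.0 * area_m2)


def _overlap_area(shape_a: BlockShape, shape_b: BlockShape, axis: str,
                  spec: PolymorphSpec) -> float:
    """Overlap (Angstrom^2) of the two faces perpendicular to ``axis``."""
    d1, d2 = _PERP[axis]
    cell = per_peptide_cell(spec)
    i1, i2 = _AXIS_INDEX[d1], _AXIS_INDEX[d2]
    ta, tb = shape_a.as_tuple(), shape_b.as_tuple()
    return (min(ta[i1], tb[i1]) * cell[i1]) * (min(ta[i2], tb[i2]) * cell[i2])


def bimolecular_propensity(k: float, nA: int, nB: int, V: float,
                           homo: bool) -> float:
    """Propensity (1/s) of a bimolecular channel from species counts.

    For a homodimerisation channel the pair count ``nA * nB`` is replaced
    by the symmetry-corrected ``nA * (nA - 1) / 2``.
    """
    if nA < 0 or nB < 0:
        raise ValueError("counts must be non-negative")
    if V <= 0:
        raise ValueError("volume must be positive")
    if homo:
        return k * nA * (nA - 1) / (2.0 * V)
    return k * nA * nB / V


def split_rate_constant(shape: BlockShape, plane: "SplitPlane | str",
                        spec: PolymorphSpec, tau0: float,
                        cond: SolventConditions) -> float:
    """Arrhenius rate constant (1/s) to cleave one plane of a block.

    The exponent is the full (buried-peptide-scaled) free energy of the
    interface being broken; the prefactor is the inverse monomer diffusion
    time.  Equivalent-plane multiplicity is applied at the propensity
    level, not here.
    """
    dG = interface_free_energy(spec, plane, shape)
    kBT = arrhenius_thermal_energy(cond.temperature)
    exponent = min(dG / kBT, 700.0)
    return math.exp(exponent) / tau0


def split_channels(species: Species, spec: PolymorphSpec, tau0: float,
                   cond: SolventConditions) -> List[Reaction]:
    """All unimolecular fragmentation channels of one species.

    Channels are grouped by plane type; equivalent positions along an axis
    share one rate constant and are counted through ``multiplicity`` (for
    example the ``n_c - 1`` equivalent hydrogen-bond planes of a fibril).
    Position choice within a group is uniform and is resolved by
    :func:`resolve_split_position` at execution time.  Channels below the
    pruning threshold are dropped.
    """
    if species.tag == "MONOMER":
        return []
    na, nb, nc = species.shape.as_tuple()
    out: List[Reaction] = []

    def _add(plane_kind: str, positions: Sequence[int], axis_for_products: str):
        if not positions:
            return
        k = split_rate_constant(species.shape, plane_kind, spec, tau0, cond)
        if prune(k):
            return
        # Representative products from the first position; execution picks
        # a position uniformly via resolve_split_position.
        left, right = split_products(
            species.shape, SplitPlane(axis_for_products, positions[0]))  # type: ignore[arg-type]
        out.append(Reaction(
            kind="split",
            reactants=(species,),
            products=(make_species(species.tag, *left.as_tuple()),
                      make_species(species.tag, *right.as_tuple())),
            rate_constant=k,
            plane=plane_kind,
            multiplicity=len(positions),
        ))

    _add("a", list(range(1, na)), "a")
    b_pos = allowed_b_positions(nb)
    _add("zip", [p for p, kind in b_pos if kind == "zip"], "zip")
    _add("b", [p for p, kind in b_pos if kind == "b"], "b")
    _add("c", list(range(1, nc)), "c")
    return out


def resolve_split_position(species: Species, plane_kind: str,
                           position_index: int) -> Tuple[Species, Species]:
    """Products of a split at the ``position_index``-th equivalent plane."""
    na, nb, nc = species.shape.as_tuple()
    if plane_kind == "a":
        positions = list(range(1, na))
        axis = "a"
    elif plane_kind in ("zip", "b"):
        positions = [p for p, kind in allowed_b_positions(nb)
                     if kind == plane_kind]
        axis = plane_kind
    else:
        positions = list(range(1, nc))
        axis = "c"
    p = positions[position_index]
    left, right = split_products(species.shape, SplitPlane(axis, p))  # type: ignore[arg-type]
    return (make_species(species.tag, *left.as_tuple()),
            make_species(species.tag, *right.as_tuple()))


def _cleavage_plane_kind(dim: str, n_parent: int, n_keep: int) -> Optional[str]:
    """Plane type for cutting ``dim`` of a block from n_parent to n_keep.

    Returns None when the cut is forbidden (inside-out exclusion along b).
    """
    if dim == "b":
        kind = classify_b_split(n_parent, n_keep, n_parent - n_keep)
        return None if kind == "forbidden" else kind
    return dim


def _cut_block(shape: Tuple[int, int, int], dim: str, n_keep: int
               ) -> Tuple[Tuple[int, int, int], Tuple[int, int, int]]:
    """Cut ``shape`` along ``dim`` keeping ``n_keep``; returns (kept, offcut)."""
    i = _AXIS_INDEX[dim]
    kept = list(shape)
    off = list(shape)
    kept[i] = n_keep
    off[i] = shape[i] - n_keep
    return tuple(kept), tuple(off)  # type: ignore[return-value]


def compound_join_split_rate(sA: Species, sB: Species, contact_axis: str,
                             spec: PolymorphSpec, cond: SolventConditions,
                             tau0: float) -> Optional[Reaction]:
    """Compound collision-with-split channel for one contact axis.

    The two blocks join on ``contact_axis``; every perpendicular dimension
    in which they mismatch produces an overhang that is cleaved off the
    larger block so that only rectangular blocks remain.  The compound rate
    constant multiplies the join kernel (over the overlapping contact
    patch) by ``tau_0 * k_split`` per cleavage.  When both overhangs sit on
    the same block the two cut orders give different products and rates;
    only the fastest is retained.  Returns None when the faces match
    exactly (a simple join), when no admissible cleavage exists, or when
    the channel is pruned.
    """
    if sA.tag == "MONOMER" and sB.tag == "MONOMER":
        raise ValueError("monomer-monomer collisions carry polymorph "
                         "commitment; use monomer_dimerisation_channels")
    ta, tb_ = sA.shape.as_tuple(), sB.shape.as_tuple()
    d1, d2 = _PERP[contact_axis]
    i1, i2 = _AXIS_INDEX[d1], _AXIS_INDEX[d2]
    ix = _AXIS_INDEX[contact_axis]

    if contact_axis == "b":
        nb_total = ta[1] + tb_[1]
        if not valid_n_b(nb_total):
            return None
    mismatched = [d for d, i in ((d1, i1), (d2, i2)) if ta[i] != tb_[i]]
    if not mismatched:
        return None  # matching faces: handled as a simple join

    tag = sA.tag if sA.tag != "MONOMER" else sB.tag

    def _cleave_factor(shape: Tuple[int, int, int], dim: str, n_keep: int
                       ) -> Optional[Tuple[float, Tuple[int, int, int],
                                           Tuple[int, int, int]]]:
        kind = _cleavage_plane_kind(dim, shape[_AXIS_INDEX[dim]], n_keep)
        if kind is None:
            return None
        kept, off = _cut_block(shape, dim, n_keep)
        if not (valid_n_b(kept[1]) and valid_n_b(off[1])):
            return None
        k_split = split_rate_constant(BlockShape(*shape), kind, spec, tau0,
                                      cond)
        return tau0 * k_split, kept, off

    # Enumerate cut sequences.  Each candidate is (factor, blocks) where
    # blocks are the final trimmed A, trimmed B and the offcut pieces.
    candidates: List[Tuple[float, Tuple[int, int, int], Tuple[int, int, int],
                           List[Tuple[int, int, int]]]] = []

    def _apply_cuts(order: Sequence[str]) -> None:
        cur_a, cur_b = ta, tb_
        factor = 1.0
        offcuts: List[Tuple[int, int, int]] = []
        for d in order:
            i = _AXIS_INDEX[d]
            if cur_a[i] == cur_b[i]:
                return
            if cur_a[i] > cur_b[i]:
                res = _cleave_factor(cur_a, d, cur_b[i])
                if res is None:
                    return
                f, cur_a, off = res
            else:
                res = _cleave_factor(cur_b, d, cur_a[i])
                if res is None:
                    return
                f, cur_b, off = res
            factor *= f
            offcuts.append(off)
        candidates.append((factor, cur_a, cur_b, offcuts))

    if len(mismatched) == 1:
        _apply_cuts(mismatched)
    else:
        same_block = ((ta[i1] > tb_[i1]) == (ta[i2] > tb_[i2]))
        _apply_cuts([mismatched[0], mismatched[1]])
        if same_block:
            # Both overhangs on one block: cut order changes the offcut
            # shapes and cross-sections; evaluate both, keep the fastest.
            _apply_cuts([mismatched[1], mismatched[0]])

    if not candidates:
        return None

    best = None
    for factor, fin_a, fin_b, offcuts in candidates:
        core = list(fin_a)
        core[ix] = fin_a[ix] + fin_b[ix]
        if not valid_n_b(core[1]):
            continue
        k_join = collision_rate_constant(sA, sB, contact_axis, spec, cond)
        k = factor * k_join
        if best is None or k > best[0]:
            best = (k, tuple(core), offcuts)
    if best is None:
        return None
    k, core, offcuts = best
    products = [make_species(tag, *core)]
    products += [make_species(tag, *off) for off in offcuts]
    return Reaction(
        kind="join_split",
        reactants=(sA, sB),
        products=tuple(products),
        rate_constant=k,
        contact_axis=contact_axis,
    )


def simple_join_channel(sA: Species, sB: Species, contact_axis: str,
                        spec: PolymorphSpec,
                        cond: SolventConditions) -> Optional[Reaction]:
    """Simple two-to-one join on ``contact_axis`` when faces match exactly."""
    ta, tb_ = sA.shape.as_tuple(), sB.shape.as_tuple()
    d1, d2 = _PERP[contact_axis]
    i1, i2 = _AXIS_INDEX[d1], _AXIS_INDEX[d2]
    if ta[i1] != tb_[i1] or ta[i2] != tb_[i2]:
        return None
    if contact_axis == "b":
        nbA, nbB = ta[1], tb_[1]
        zip_pair = nbA == 1 and nbB == 1
        b_pair = nbA % 2 == 0 and nbB % 2 == 0
        if not (zip_pair or b_pair):
            return None
    merged = list(ta)
    ix = _AXIS_INDEX[contact_axis]
    merged[ix] = ta[ix] + tb_[ix]
    if not valid_n_b(merged[1]):
        return None
    tag = sA.tag if sA.tag != "MONOMER" else sB.tag
    k = collision_rate_constant(sA, sB, contact_axis, spec, cond)
    return Reaction(
        kind="join",
        reactants=(sA, sB),
        products=(make_species(tag, *merged),),
        rate_constant=k,
        contact_axis=contact_axis,
    )


def pair_join_channels(sA: Species, sB: Species,
                       specs: Dict[str, PolymorphSpec],
                       cond: SolventConditions,
                       tau0s: Dict[str, float]) -> List[Reaction]:
    """All bimolecular channels between two species (not both monomers).

    Species of different committed polymorphs never react directly; a
    monomer joining a committed aggregate adopts its polymorph.  For each
    contact axis the channel is a simple join when the faces match and a
    compound collision-with-split otherwise.
    """
    if sA.tag == "MONOMER" and sB.tag == "MONOMER":
        raise ValueError("use monomer_dimerisation_channels for two monomers")
    tags = {sA.tag, sB.tag} - {"MONOMER"}
    if len(tags) != 1:
        return []
    tag = tags.pop()
    spec = specs[tag]
    tau0 = tau0s[tag]
    out: List[Reaction] = []
    for axis in ("a", "b", "c"):
        rxn = simple_join_channel(sA, sB, axis, spec, cond)
        if rxn is None:
            rxn = compound_join_split_rate(sA, sB, axis, spec, cond, tau0)
        if rxn is not None:
            out.append(rxn)
    return out


@dataclass(frozen=True)
class DimerisationChannel:
    """Monomer+monomer collision along one contact axis.

    The kernel averages the two polymorph geometries (which differ only
    marginally in their cell dimensions) so that polymorph commitment can
    be drawn with exactly 50% probability at execution time.
    ``products_by_tag`` maps the committed tag to the dimer produced.
    """

    contact_axis: str
    rate_constant: float
    products_by_tag: Dict[str, Species]


def monomer_dimerisation_channels(specs: Dict[str, PolymorphSpec],
                                  cond: SolventConditions
                                  ) -> List[DimerisationChannel]:
    """The three monomer+monomer collision channels (one per contact axis).

    Two colliding monomers may meet terminus-to-terminus (a), sidechain-to-
    sidechain (b, forming the first steric zipper) or stack along the
    hydrogen-bond axis (c).  Which polymorph the nascent dimer commits to
    is decided by a fair coin at execution time.
    """
    dimer_shape = {"a": (2, 1, 1), "b": (1, 2, 1), "c": (1, 1, 2)}
    out = []
    for axis in ("a", "b", "c"):
        ks = [collision_rate_constant(MONOMER, MONOMER, axis, spec, cond)
              for spec in specs.values()]
        k = sum(ks) / len(ks)
        products = {tag: make_species(tag, *dimer_shape[axis])
                    for tag in specs}
        out.append(DimerisationChannel(axis, k, products))
    return out


# ---------------------------------------------------------------------------
# lean rate-sum path
#
# Building the engine's pair-rate matrix touches every (new species,
# registered species) pair once, which makes channel enumeration the
# dominant cost of a run.  The helpers below compute exactly the same per
# channel rate constants as pair_join_channels but on bare index tuples,
# without constructing Species/Reaction objects; the full channel objects
# are only built (and cached) for pairs that are actually selected to
# react.  test_reaction_rates asserts the two paths agree channel by
# channel.


class PolymorphKernel:
    """Precomputed per-polymorph quantities for the lean rate path."""

    __slots__ = ("cell", "herringbone", "dG_a", "dG_b", "dG_zip", "dG_c",
                 "eps", "eps_prime", "tau0", "kBT", "cond", "_D")

    def __init__(self, spec: PolymorphSpec, cond: SolventConditions,
                 tau0: float):
        from .constants import arrhenius_thermal_energy
        self.cell = per_peptide_cell(spec)
        tab = spec.energies
        self.herringbone = tab.is_herringbone
        self.dG_a, self.dG_b = tab.dG_a, tab.dG_b
        self.dG_zip, self.dG_c = tab.dG_zip, tab.dG_c
        self.eps, self.eps_prime = tab.eps, tab.eps_prime
        self.tau0 = tau0
        self.kBT = arrhenius_thermal_energy(cond.temperature)
        self.cond = cond
        self._D: Dict[Tuple[int, int, int], float] = {}

    def diffusion(self, shape: Tuple[int, int, int]) -> float:
        D = self._D.get(shape)
        if D is None:
            ca, cb, cc = self.cell
            D = rod_diffusion_coefficient(
                (shape[0] * ca, shape[1] * cb, shape[2] * cc), self.cond)
            self._D[shape] = D
        return D

    def plane_energy(self, kind: str, shape: Tuple[int, int, int]) -> float:
        na, nb, nc = shape
        if not self.herringbone:
            if kind == "a":
                return nb * nc * self.dG_a
            if kind == "b":
                return na * nc * self.dG_b
            if kind == "zip":
                return na * nc * self.dG_zip
            return na * nb * self.dG_c
        lat = nc - 0.5
        if kind == "a":
            return (2 * nb - 1) * (self.eps / 2.0) * lat
        if kind == "b":
            return ((na - 1) * self.eps + na * self.eps_prime) * lat
        if kind == "zip":
            return na * lat * self.dG_zip
        return na * nb * self.dG_c

    def cleave_exp(self, kind: str, shape: Tuple[int, int, int]) -> float:
        """tau0 * k_split for one cleavage = exp(dG_plane / kBT)."""
        return math.exp(min(self.plane_energy(kind, shape) / self.kBT,
                            700.0))

    def join_k(self, shape_a: Tuple[int, int, int],
               shape_b: Tuple[int, int, int], axis: str) -> float:
        i1, i2 = _PERP_IDX[axis]
        cell = self.cell
        area = (min(shape_a[i1], shape_b[i1]) * cell[i1]
                * min(shape_a[i2], shape_b[i2]) * cell[i2]) * 1e-20
        return (2.0 * BARRIER_FACTOR
                * (self.diffusion(shape_a) + self.diffusion(shape_b))
                * math.sqrt(2.0 * area))


_PERP_IDX = {"a": (1, 2), "b": (0, 2), "c": (0, 1)}


def _b_cut_kind(n_parent: int, n_keep: int) -> Optional[str]:
    n_off = n_parent - n_keep
    left_ok = n_keep == 1 or n_keep % 2 == 0
    right_ok = n_off == 1 or n_off % 2 == 0
    if not (left_ok and right_ok):
        return None
    if n_keep % 2 == 1 and n_off % 2 == 1:
        return "zip"
    if n_keep % 2 == 0 and n_off % 2 == 0:
        return "b"
    return None


def pair_rate_constants(ta: Tuple[int, int, int], tb: Tuple[int, int, int],
                        tag_a: str, tag_b: str,
                        kernels: Dict[str, PolymorphKernel]
                        ) -> Tuple[float, ...]:
    """Rate constants (m^3/s) of all join / join-split channels of a pair.

    Mirrors :func:`pair_join_channels` channel for channel on bare shape
    tuples; used to assemble the engine's pair-rate matrix cheaply.
    """
    tags = {tag_a, tag_b} - {"MONOMER"}
    if len(tags) != 1:
        return ()
    g = kernels[tags.pop()]
    out = []
    for axis, (i1, i2) in _PERP_IDX.items():
        ix = _AXIS_INDEX[axis]
        if axis == "b":
            nb_total = ta[1] + tb[1]
            if not (nb_total == 1 or nb_total % 2 == 0):
                continue
        m1 = ta[i1] != tb[i1]
        m2 = ta[i2] != tb[i2]
        if not (m1 or m2):
            # simple join on matching faces
            if axis == "b":
                zip_pair = ta[1] == 1 and tb[1] == 1
                b_pair = ta[1] % 2 == 0 and tb[1] % 2 == 0
                if not (zip_pair or b_pair):
                    continue
            merged_nb = ta[1] + tb[1] if axis == "b" else ta[1]
            if not (merged_nb == 1 or merged_nb % 2 == 0):
                continue
            out.append(g.join_k(ta, tb, axis))
            continue
        # compound: cleave every mismatched perpendicular dimension
        dims = [d for d, m in zip((i1, i2), (m1, m2)) if m]

        def cut(shape, i_dim, keep):
            if i_dim == 1:
                kind = _b_cut_kind(shape[1], keep)
                if kind is None:
                    return None
            else:
                kind = "abc"[i_dim]
            factor = g.cleave_exp(kind, shape)
            kept = list(shape)
            kept[i_dim] = keep
            return factor, tuple(kept)

        def run_order(order):
            cur_a, cur_b = ta, tb
            factor = 1.0
            for i_dim in order:
                if cur_a[i_dim] == cur_b[i_dim]:
                    return None
                if cur_a[i_dim] > cur_b[i_dim]:
                    res = cut(cur_a, i_dim, cur_b[i_dim])
                    if res is None:
                        return None
                    f, cur_a = res
                else:
                    res = cut(cur_b, i_dim, cur_a[i_dim])
                    if res is None:
                        return None
                    f, cur_b = res
                factor *= f
            core_nb = (cur_a[1] + cur_b[1]) if axis == "b" else cur_a[1]
            if not (core_nb == 1 or core_nb % 2 == 0):
                return None
            return factor

        factors = []
        if len(dims) == 1:
            f = run_order(dims)
            if f is not None:
                factors.append(f)
        else:
            f = run_order(dims)
            if f is not None:
                factors.append(f)
            same_block = (ta[dims[0]] > tb[dims[0]]) == \
                (ta[dims[1]] > tb[dims[1]])
            if same_block:
                f = run_order(dims[::-1])
                if f is not None:
                    factors.append(f)
        if factors:
            out.append(max(factors) * g.join_k(ta, tb, axis))
    return tuple(out)
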