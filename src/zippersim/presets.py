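"""Published lattice and interface-energy parameters of the IFQINS system.

Two polymorphic nanocrystal structures of the lysozyme-derived hexapeptide
IFQINS compete in solution:

* the antiparallel (AP) designed structure, a rectangular (p1) lattice with
  a = 20.0 A, b = 19.1 A, whose cell holds a two-peptide steric zipper
  across the sidechain axis;
* the parallel (P) crystal structure, a herringbone (p2) lattice with a
  translational cell of a = 43.2 A, b = 19.6 A holding two peptides along
  both lateral axes.

The hydrogen-bond (c) repeat is not resolved by the solution experiments;
the canonical cross-beta strand spacing of 4.8 A is used as the default and
is configurable.  Interface free energies (kcal/mol per buried peptide)
are the standard binding free energy gains of the reference energy table:
AP (dG_a, dG_b, dG_zip, dG_c) = (-9.2, -6.2, -16.4, -29.3) and for P the
herringbone terms eps = -18.84, eps_prime = -5.99 with dG_zip = dG_c =
-25.3.
"""

from __future__ import annotations

from typing import Dict

from .interface_energetics import EnergyTable
from .lattice_geometry import LatticeParams, PolymorphSpec

#: Default hydrogen-bond-axis repeat (A): canonical cross-beta spacing.
DEFAULT_C_SPACING = 4.8

AP_ENERGIES = EnergyTable.rectangular(dG_a=-9.2, dG_b=-6.2, dG_zip=-16.4,
                                      dG_c=-29.3)
P_ENERGIES = EnergyTable.herringbone(eps=-18.84, eps_prime=-5.99,
                                     dG_zip=-25.3, dG_c=-25.3)

AP_LATTICE = LatticeParams(a=20.0, b=19.1, c=DEFAULT_C_SPACING, gamma=83.0,
                           peptides_per_cell_a=1, peptides_per_cell_b=2,
                           peptides_per_cell_c=1)
P_LATTICE = LatticeParams(a=43.2, b=19.6, c=DEFAULT_C_SPACING, gamma=90.0,
                          peptides_per_cell_a=2, peptides_per_cell_b=2,
                          peptides_per_cell_c=1)


def default_polymorph_specs() -> Dict[str, PolymorphSpec]:
    """The two competing polymorphs with their published parameters."""
    return {
        "AP": PolymorphSpec("AP", "rectangular_p1", AP_LATTICE, AP_ENERGIES),
        "P": PolymorphSpec("P", "herringbone_p2", P_LATTICE, P_ENERGIES),
    }
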