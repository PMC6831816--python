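# Methods

`zippersim` simulates the competitive self-assembly of a short
amyloidogenic hexapeptide (IFQINS, a fragment of human lysozyme) into two
nanocrystal polymorphs: an **antiparallel (AP)** beta-sheet structure on a
rectangular (plane group p1) lattice, and a **parallel (P)** beta-sheet
structure on a herringbone (plane group p2) lattice, in which translation
along the backbone axis *a* is accompanied by a 180-degree rotation.  The
two polymorphs never mix within one aggregate and interact only by
competing for the shared monomer pool.

## State space

An aggregate is a rectangular block of `n_a x n_b x n_c` peptides along
the backbone (*a*), sidechain-stacking (*b*) and hydrogen-bonding (*c*,
fibril) axes.  Block shapes are mapped to physical dimensions through the
per-peptide cell of each lattice: AP `20.0 x 9.55 x 4.8 A`, P
`21.6 x 9.8 x 4.8 A`.  The *c* repeat (4.8 A, the canonical cross-beta
strand spacing) is not fixed by the solution experiments and is a
configurable parameter; the in-plane angle gamma is carried but does not
enter the kinetic kernels, which use orthogonal box dimensions.

The sidechain-axis count `n_b` is restricted to 1 or an even integer.  A
block with an odd number (> 1) of sheets would expose a broken steric
zipper while burying the weaker plain *b* interface; these "inside-out"
species are excluded as a hard shape constraint, enforced both on split
positions (an even sheet count may only split into two odd singles -
a zipper fracture - or two even halves - a plain *b* fracture) and on
every join and cleavage product.

## Interface free energies

Every buried interface carries a standard binding free energy (kcal/mol
per buried peptide), supplied as an input table.  For the AP lattice the
energy is linear in the buried-peptide count; the reference values are
`dG_a = -9.2`, `dG_b = -6.2`, `dG_zip = -16.4`, `dG_c = -29.3`.  For the
herringbone P lattice, lateral interfaces are composed from two zipper
terms `eps = -18.84` and `eps_prime = -5.99`:

* *a*-interface: `(2 n_b - 1) (eps / 2) (n_c - 1/2)` - a single-sheet
  association (`n_b = 1`) buries half a steric zipper and every
  subsequent whole zipper adds `eps`;
* *b*-interface: `((n_a - 1) eps + n_a eps_prime) (n_c - 1/2)`;
* intra-cell zipper: `n_a (n_c - 1/2) dG_zip` with `dG_zip = -25.3`;
* *c*-interface: `n_a n_b dG_c` with `dG_c = -25.3`.

The factor `n_c - 1/2` reflects the half-cell step between adjacent
herringbone sheets along *c*; it applies to lateral (ab-plane) interfaces
only.  In the large-aggregate limit the P lateral growth energies
approach `eps / 2 = -9.4` per peptide in *a* and `eps + eps_prime =
-24.8` in *b* (`large_aggregate_limits`).

Interface tables can also be *estimated* from reference block free
energies `G_ijk` (ensemble averages of minimised blocks) by finite
differences between joined and separated blocks
(`estimate_interface_energies`); the zip estimator divides by 9.5 for P
instead of 10 because of the half-cell overhang.  The package generates
synthetic additive block-energy tables (`synthetic_block_energies`) to
exercise these estimators; the estimators invert the additive generator
exactly at zero noise.  What the synthetic tables do not emulate is the
finite-size cooperativity of real block energies, so passing round-trip
tests demonstrates correctness of the linear algebra, not accuracy of the
linear approximation itself.

## Kinetics

Three reaction classes connect the blocks:

* **Joins.**  Two blocks with geometrically matching faces collide at the
  diffusion-limited rate `k = 2 e^-3 (D_A + D_B) sqrt(2 A_contact)`,
  where `A_contact` is the contact-face area and `e^-3` is an entropic
  barrier for the loss of translational and rotational freedom on
  binding.  Translational diffusion coefficients treat blocks as
  cylinders (length = longest dimension, diameter = equal-area circle of
  the cross-section) with the end-effect interpolation
  `nu(p) = 0.312 + 0.565/p + 0.100/p^2` and the aspect ratio clamped at
  1; orientation-translation coupling is ignored.
* **Splits.**  A block cleaves on an internal plane at the Arrhenius rate
  `(1/tau_0) exp(dG_plane / k_B T)` with `tau_0` the time for a monomer
  to diffuse its own length (`l^2 / 6 D`, about 1.8 ns for the AP
  monomer in water at 300 K).  Equivalent planes (for example the
  `n_c - 1` hydrogen-bond planes of a fibril) share one rate constant and
  multiply the propensity; the cut position is uniform among equivalent
  planes.
* **Compound collisions.**  Blocks whose contact faces mismatch in one or
  two dimensions may still collide; the virtual non-rectangular product
  is immediately resolved back into rectangular blocks by cleaving the
  overhangs off the larger block(s).  The rate multiplies the join kernel
  (over the overlap patch) by `tau_0 k_split` per cleavage.  When both
  overhangs sit on one block the two cut orders give different products
  and rates; both are evaluated and only the fastest is retained.  These
  channels have extremely low rates but prevent artificial freezing of
  populations with no matching faces.  No three-to-two reverse process is
  constructed.

Channels whose per-second propensity prefactor (the rate constant itself
for splits, `k / V` for bimolecular channels) falls below `1e-50` are
discarded.

**Polymorph commitment.**  When two monomers collide (on any of the three
contact axes) the nascent dimer commits to P or AP with a fair coin; a
committed peptide returns to the uncommitted pool only by leaving its
assembly.  So that the coin is exactly fair, the monomer-monomer kernel
for each contact axis averages the two polymorph geometries, whose cell
dimensions differ by less than 8%.

### The thermal scale of the fragmentation exponents

The interface tables are thermodynamic standard energies in kcal/mol.
The fragmentation exponents, however, evaluate the tabulated values on a
kJ/mol thermal scale (`R T / 1000`, about 2.494 at 300 K;
`constants.arrhenius_thermal_energy`), a factor 4.184 softer than a
literal kcal/mol reading.  This calibration is deliberate: it places
early single-sheet aggregates in the reversible regime in which their
dissolution competes with collision timescales over the nM-mM range -
P chains dissolve about five times faster than AP chains, P assembly at
low concentration becomes a rare nucleation-limited event, and the
polymorph balance acquires its concentration dependence.  With the
literal kcal reading every dimer hydrogen-bond interface is locked
(fragmentation at ~1e-10 /s against collision rates of 0.3-1e5 /s), the
commitment coin alone fixes the final masses and the final polymorph
balance is nearly concentration independent, which contradicts the
phenomenology the model exists to describe.  The energy scale enters the
rate module in exactly one place and thermodynamic reporting remains in
kcal/mol.

## Stochastic simulation

The network is sampled with the exact event-driven (direct) stochastic
simulation algorithm: waiting times are exponential in the total
propensity and one channel fires per event.  Species are discovered on
the fly; rate constants for a reactant pair are computed once, the first
time the pair is seen, and cached for the rest of the process (the cache
is shared across replicates and concentrations).  Internally the engine
maintains the dense symmetric matrix `K[i, j]` of summed pair rate
constants and the collision-load vector `q = K n`, updated incrementally
after every event, making each step O(species) instead of O(channels);
the matrix row of a newly discovered species is assembled by an
allocation-free rate path that is property-tested against the full
channel enumeration.  Homodimerisation propensities carry the
`n (n - 1) / 2` symmetry factor.  The peptide-count invariant can be
asserted after every event (`validate=True`).

Concentration is controlled through the simulation volume
`V = N / (c N_A)`.  Replicate `r` of a run uses seed `seed + r`, so
trajectories are bit-reproducible.

## Study conditions and problem sizes

The default configuration runs `N = 1e4` peptides, 10 replicates, at
concentrations 5 nM x 10^i (i = 0..7).  The horizon is `max_time = 100 s`
or `max_events = 120 000` per replicate, whichever comes first.  These
sizes were chosen once so that a full sweep completes on one CPU in
about a quarter of an hour: at the millimolar concentrations the total
aggregated fraction plateaus well before the event cap, and the final
AP/P mass split changes by less than about 1% when the cap is raised
threefold (the assembled state is deeply locked; see limitations).
Intensive observables - mass fractions and aspect ratios - are the
reported quantities, so the peptide count enters mainly through the
granularity of rare nucleation events.

## Observables

* `mass_fractions`: peptide-mass fractions per polymorph in aggregates
  of size >= 2 (1D+), with at least two shape indices > 1 (2D), and with
  all three > 1 (3D); mass (peptide-count) weighted, so
  `frac_3D <= frac_2D <= frac_1D+` always.
* `mean_aspect_ratio`: number-weighted mean of `n_a / n_b` per polymorph,
  with free monomers (ratio 1) counted towards both polymorphs.
* `crossover_concentration`: log-linear interpolation of the zero
  crossing of the final (AP - P) aggregated mass across a concentration
  series, scanning up from the AP-dominated low end; one-sided results
  are reported as such.  Callers exclude concentrations where less than
  1% of the mass aggregated, since those carry no polymorph preference.

## Known limitations

* **Deep kinetic locking at desk scale.**  Once either polymorph reaches
  two-dimensional aggregates, every interface of those aggregates is many
  thermal energies deep and the final mass split freezes.  Under the
  default conditions the AP polymorph converts more mass before locking
  at every concentration of the default sweep: the final AP-P mass
  difference falls monotonically from about +0.74 at 0.5 mM to about
  +0.2 at 50 mM but does not change sign within the swept range, so the
  AP/P balance point extrapolates to above 50 mM rather than to the
  low-mM decade.  Late mass transfer between locked aggregates is
  effectively absent on reachable horizons.
* Elastic twist and bend of large-aspect aggregates, and their feedback
  on assembly, are not modelled; the aspect ratio is reported as a proxy.
* Heterogeneous nucleation of P on AP surfaces is not modelled; the
  polymorphs couple only through the monomer pool.
* No detailed balance is imposed between join and split channels: joins
  are diffusion-limited with a fixed entropic barrier, splits are
  Arrhenius in the interface energy.  The model is kinetic, not an
  equilibrium sampler.
* No spatial correlations: the solution is perfectly mixed at all times.
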