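"""Event-driven stochastic simulation of the assembly reaction network.

The simulator samples the chemical master equation of the join /
join-with-split / split network with the exact (direct-method) algorithm:
waiting times are exponential in the total propensity and one channel is
executed per event with probability proportional to its propensity.

Species are discovered on the fly.  Rate constants for a given reactant
pair are computed once, on the first occasion the reactants meet, and
cached for the remainder of the process (the cache is shared between
replicates and concentrations of a sweep).  Internally the engine keeps a
dense symmetric matrix ``K`` of summed pair rate constants and the vector
``q = K n`` of per-species collision loads, which it updates incrementally
after every event, so that sampling is O(number of species) per event
rather than O(number of channels).

Polymorph commitment happens at monomer dimerisation: the nascent dimer
chooses the P or AP geometry with a fair coin, and a committed peptide can
only return to the uncommitted pool by leaving its assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .constants import N_AVOGADRO
from .hydrodynamics import SolventConditions, monomer_tau0
from .lattice_geometry import PolymorphSpec
from .observables import ObservationRecord, observe
from .reaction_rates import (
    MONOMER,
    DimerisationChannel,
    PRUNE_THRESHOLD,
    PolymorphKernel,
    Reaction,
    Species,
    monomer_dimerisation_channels,
    pair_join_channels,
    pair_rate_constants,
    resolve_split_position,
    split_channels,
)

__all__ = [
    "SystemState", "StopCriteria", "RunConfig", "RateModel", "Simulator",
    "commit_polymorph", "enumerate_reactions", "run", "sweep",
    "volume_for_concentration",
]

logger = logging.getLogger("zippersim.engine")


def volume_for_concentration(total_peptides: int, concentration: float) -> float:
    """Simulation volume (m^3) holding ``total_peptides`` at a molar
    concentration."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    number_density = concentration * 1000.0 * N_AVOGADRO  # 1/m^3
    return total_peptides / number_density


def commit_polymorph(rng: np.random.Generator) -> Literal["P", "AP"]:
    """Polymorph commitment of a nascent dimer: fair coin between P and AP."""
    return "P" if rng.random() < 0.5 else "AP"


@dataclass
class SystemState:
    """Snapshot of the simulation: species counts, volume and clock."""

    counts: Dict[Species, int]
    volume: float
    time: float
    total_peptides: int

    def peptide_count(self) -> int:
        return sum(s.n_peptides * c for s, c in self.counts.items())


@dataclass(frozen=True)
class StopCriteria:
    """Simulation horizon: stop at whichever of the two limits is hit first."""

    max_time: float = 100.0
    max_events: int = 120_000


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation (or its replicates)."""

    total_peptides: int
    concentration: float
    specs: Dict[str, PolymorphSpec]
    solvent: SolventConditions = SolventConditions()
    seed: int = 1
    replicates: int = 1
    stop: StopCriteria = StopCriteria()
    report_points: int = 48
    report_t_min: float = 1e-9

    def __post_init__(self) -> None:
        if self.total_peptides < 2:
            raise ValueError("total_peptides must be >= 2")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if set(self.specs) != {"AP", "P"}:
            raise ValueError("specs must contain exactly the polymorphs AP, P")
        if not 0 <= self.seed < 2 ** 31 - self.replicates:
            raise ValueError("seed must be a small non-negative integer")

    def report_grid(self) -> np.ndarray:
        return np.geomspace(self.report_t_min, self.stop.max_time,
                            self.report_points)


class RateModel:
    """Rate-constant calculator with a per-reactant-signature cache.

    One instance is shared across replicates (and concentrations) so that
    each pair of reactant signatures is enumerated exactly once per
    process, as the rate constants are volume independent.
    """

    def __init__(self, specs: Dict[str, PolymorphSpec],
                 cond: SolventConditions):
        self.specs = dict(specs)
        self.cond = cond
        self.tau0s = {tag: monomer_tau0(spec, cond)
                      for tag, spec in specs.items()}
        self.dimer_channels: List[DimerisationChannel] = \
            monomer_dimerisation_channels(specs, cond)
        self.kernels = {tag: PolymorphKernel(spec, cond, self.tau0s[tag])
                        for tag, spec in specs.items()}
        self._pair_cache: Dict[tuple, Tuple[Reaction, ...]] = {}
        self._rate_cache: Dict[tuple, Tuple[float, ...]] = {}
        self._split_cache: Dict[tuple, Tuple[Reaction, ...]] = {}
        # Instrumentation: how often pair channels were requested vs
        # actually recomputed (cache effectiveness is observable in tests).
        self.pair_requests = 0
        self.pair_computations = 0

    def pair_channels(self, sA: Species, sB: Species) -> Tuple[Reaction, ...]:
        """Bimolecular channels for a (non monomer-monomer) species pair."""
        first, second = sorted((sA, sB), key=Species.signature)
        key = (first.signature(), second.signature())
        self.pair_requests += 1
        hit = self._pair_cache.get(key)
        if hit is not None:
            return hit
        self.pair_computations += 1
        channels = tuple(pair_join_channels(first, second, self.specs,
                                            self.cond, self.tau0s))
        self._pair_cache[key] = channels
        return channels

    def pair_rates(self, sA: Species, sB: Species) -> Tuple[float, ...]:
        """Rate constants of all channels between two species (lean path).

        Computed on bare shape tuples without building channel objects;
        channel-by-channel equal to ``pair_channels`` rates.
        """
        sigA, sigB = sA.signature(), sB.signature()
        if sigB < sigA:
            sigA, sigB = sigB, sigA
        key = (sigA, sigB)
        hit = self._rate_cache.get(key)
        if hit is not None:
            return hit
        rates = pair_rate_constants(sigA[1:], sigB[1:], sigA[0], sigB[0],
                                    self.kernels)
        self._rate_cache[key] = rates
        return rates

    def split_channels_for(self, s: Species) -> Tuple[Reaction, ...]:
        key = s.signature()
        hit = self._split_cache.get(key)
        if hit is not None:
            return hit
        if s.tag == "MONOMER":
            channels: Tuple[Reaction, ...] = ()
        else:
            channels = tuple(split_channels(s, self.specs[s.tag],
                                            self.tau0s[s.tag], self.cond))
        self._split_cache[key] = channels
        return channels


@dataclass(frozen=True)
class Event:
    """One executed reaction: what fired, when and after how long."""

    time: float
    waiting_time: float
    kind: str
    reactants: Tuple[Species, ...]
    products: Tuple[Species, ...]


class Simulator:
    """Mutable simulation state plus the incremental propensity machinery.

    The species registry only ever grows; counts may return to zero.  For
    registered species ``i`` and ``j`` the matrix entry ``K[i, j]`` is the
    sum of all (unpruned) bimolecular rate constants between them, and
    ``s[i]`` the total per-molecule fragmentation rate of ``i``.
    Propensities follow from the counts: ``K[i,j] n_i n_j / V`` for hetero
    pairs, ``K[i,i] n_i (n_i - 1) / (2V)`` for homo pairs and
    ``s[i] n_i`` for splits.
    """

    _INITIAL_CAPACITY = 256

    def __init__(self, model: RateModel, volume: float,
                 validate: bool = False):
        if volume <= 0:
            raise ValueError("volume must be positive")
        self.model = model
        self.volume = volume
        self.validate = validate
        self.time = 0.0
        self.events = 0
        self.status = "running"

        cap = self._INITIAL_CAPACITY
        self._species: List[Species] = []
        self._index: Dict[Tuple, int] = {}
        self._n = np.zeros(cap, dtype=np.int64)
        self._nf = np.zeros(cap, dtype=np.float64)
        self._pep = np.zeros(cap, dtype=np.int64)
        self._K = np.zeros((cap, cap), dtype=np.float64)
        self._diag = np.zeros(cap, dtype=np.float64)
        self._q = np.zeros(cap, dtype=np.float64)
        self._s = np.zeros(cap, dtype=np.float64)
        self._split_groups: List[Tuple[Reaction, ...]] = []
        self._events_since_refresh = 0
        self.total_peptides = 0

        self._monomer_idx = self._register(MONOMER)

    # -- registry ----------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self._species)

    def _grow(self) -> None:
        cap = self._n.shape[0] * 2
        for name in ("_n", "_nf", "_pep", "_diag", "_q", "_s"):
            old = getattr(self, name)
            new = np.zeros(cap, dtype=old.dtype)
            new[:old.shape[0]] = old
            setattr(self, name, new)
        newK = np.zeros((cap, cap), dtype=np.float64)
        s = self._K.shape[0]
        newK[:s, :s] = self._K
        self._K = newK

    def _active_pair_rate(self, rates: Iterable[float]) -> float:
        """Summed pair rate constant after per-volume pruning."""
        thr = PRUNE_THRESHOLD * self.volume
        return sum(k for k in rates if k >= thr)

    def _register(self, species: Species) -> int:
        sig = species.signature()
        idx = self._index.get(sig)
        if idx is not None:
            return idx
        idx = len(self._species)
        if idx >= self._n.shape[0]:
            self._grow()
        self._species.append(species)
        self._index[sig] = idx
        self._pep[idx] = species.n_peptides

        S = idx + 1
        if species.tag == "MONOMER":
            self._K[idx, idx] = sum(ch.rate_constant
                                    for ch in self.model.dimer_channels)
            self._diag[idx] = self._K[idx, idx]
        else:
            for j in range(idx):
                other = self._species[j]
                if other.tag == species.tag or other.tag == "MONOMER":
                    k = self._active_pair_rate(
                        self.model.pair_rates(species, other))
                else:
                    k = 0.0
                self._K[idx, j] = self._K[j, idx] = k
            self._K[idx, idx] = self._active_pair_rate(
                self.model.pair_rates(species, species))
            self._diag[idx] = self._K[idx, idx]
        splits = self.model.split_channels_for(species)
        self._split_groups.append(splits)
        self._s[idx] = sum(r.rate_constant * r.multiplicity for r in splits)

        self._q[idx] = float(self._K[idx, :S] @ self._n[:S])
        return idx

    # -- state -------------------------------------------------------------

    def set_counts(self, counts: Dict[Species, int]) -> None:
        """(Re)initialise species counts; resets the clock and counters."""
        S0 = len(self._species)
        self._n[:S0] = 0
        for species, count in counts.items():
            if count < 0:
                raise ValueError("counts must be non-negative")
            idx = self._register(species)
            self._n[idx] = count
        S = len(self._species)
        self._nf[:S] = self._n[:S]
        self._q[:S] = self._K[:S, :S] @ self._nf[:S]
        self.total_peptides = int(self._pep[:S] @ self._n[:S])
        self.time = 0.0
        self.events = 0
        self.status = "running"

    def init_monomers(self, total_peptides: int) -> None:
        self.set_counts({MONOMER: total_peptides})

    def state(self) -> SystemState:
        S = len(self._species)
        counts = {self._species[i]: int(self._n[i])
                  for i in range(S) if self._n[i] > 0}
        return SystemState(counts=counts, volume=self.volume, time=self.time,
                           total_peptides=self.total_peptides)

    def count_of(self, species: Species) -> int:
        idx = self._index.get(species.signature())
        return int(self._n[idx]) if idx is not None else 0

    # -- propensities ------------------------------------------------------

    def _refresh_q(self) -> None:
        S = len(self._species)
        self._q[:S] = self._K[:S, :S] @ self._nf[:S]
        self._events_since_refresh = 0

    def total_propensity(self) -> float:
        S = len(self._species)
        n = self._nf[:S]
        w = n * (self._q[:S] - self._diag[:S])
        r_bi = float(w.sum()) / (2.0 * self.volume)
        r_uni = float((self._s[:S] * n).sum())
        return r_bi + r_uni

    # -- stepping ----------------------------------------------------------

    def step(self, rng: np.random.Generator) -> Optional[Event]:
        """Execute one reaction event; returns None when exhausted."""
        S = len(self._species)
        n = self._nf[:S]
        w = n * (self._q[:S] - self._diag[:S])
        np.maximum(w, 0.0, out=w)  # guard fp residue from incremental updates
        u = self._s[:S] * n
        W = float(w.sum())
        U = float(u.sum())
        R = W / (2.0 * self.volume) + U
        if R <= 0.0:
            self.status = "exhausted"
            return None

        dt = rng.exponential(1.0 / R)
        pick = rng.random() * R
        if pick < U:
            event = self._execute_split(rng, u, pick)
        else:
            event = self._execute_join(rng, w, pick - U)

        self.time += dt
        self.events += 1
        self._events_since_refresh += 1
        if self._events_since_refresh >= 65536:
            self._refresh_q()
        if self.validate:
            S2 = len(self._species)
            pep = int(self._pep[:S2] @ self._n[:S2])
            if pep != self.total_peptides:
                raise AssertionError(
                    f"peptide count drifted: {pep} != {self.total_peptides}")
        return Event(time=self.time, waiting_time=dt, kind=event[0],
                     reactants=event[1], products=event[2])

    def _choose(self, rng: np.random.Generator, weights: np.ndarray,
                target: Optional[float] = None) -> int:
        cum = np.cumsum(weights)
        total = cum[-1]
        if target is None:
            target = rng.random() * total
        idx = int(np.searchsorted(cum, target, side="right"))
        return min(idx, len(weights) - 1)

    def _execute_split(self, rng: np.random.Generator, u: np.ndarray,
                       target: float) -> tuple:
        i = self._choose(rng, u, target)
        species = self._species[i]
        groups = self._split_groups[i]
        weights = np.array([g.rate_constant * g.multiplicity for g in groups])
        g = groups[self._choose(rng, weights)]
        pos = int(rng.integers(g.multiplicity))
        left, right = resolve_split_position(species, g.plane, pos)
        delta: Dict[Species, int] = {species: -1}
        for p in (left, right):
            delta[p] = delta.get(p, 0) + 1
        self._apply(delta)
        return ("split", (species,), (left, right))

    def _execute_join(self, rng: np.random.Generator, w: np.ndarray,
                      target: float) -> tuple:
        S = len(self._species)
        # ``target`` is in propensity units; w is scaled by 2V relative to it.
        i = self._choose(rng, w, target * 2.0 * self.volume)
        # partner weights: K[i, j] n_j for j != i, K[i, i] (n_i - 1) for j == i
        pw = self._K[i, :S] * self._nf[:S]
        pw[i] = self._K[i, i] * max(self._n[i] - 1, 0)
        np.maximum(pw, 0.0, out=pw)
        j = self._choose(rng, pw)
        sA, sB = self._species[i], self._species[j]

        if i == self._monomer_idx and j == self._monomer_idx:
            channels = self.model.dimer_channels
            weights = np.array([c.rate_constant for c in channels])
            ch = channels[self._choose(rng, weights)]
            tag = commit_polymorph(rng)
            product = ch.products_by_tag[tag]
            self._apply({MONOMER: -2, product: +1})
            return ("join", (sA, sB), (product,))

        thr = PRUNE_THRESHOLD * self.volume
        active = [c for c in self.model.pair_channels(sA, sB)
                  if c.rate_constant >= thr]
        weights = np.array([c.rate_constant for c in active])
        rxn = active[self._choose(rng, weights)]
        delta: Dict[Species, int] = {}
        for r in rxn.reactants:
            delta[r] = delta.get(r, 0) - 1
        for p in rxn.products:
            delta[p] = delta.get(p, 0) + 1
        self._apply(delta)
        return (rxn.kind, rxn.reactants, rxn.products)

    def _apply(self, delta: Dict[Species, int]) -> None:
        """Apply count changes, registering new species and updating q."""
        # Register all involved species before touching counts so that new
        # K rows are computed against the pre-event count vector and then
        # corrected by the same incremental updates as existing rows.
        idxs = [(self._register(sp), d) for sp, d in delta.items() if d != 0]
        S = len(self._species)
        for idx, d in idxs:
            new = self._n[idx] + d
            if new < 0:
                raise AssertionError(
                    f"negative count for {self._species[idx]}")
            self._n[idx] = new
            self._nf[idx] = new
            self._q[:S] += self._K[:S, idx] * d

    # -- high-level driving ------------------------------------------------

    def run_until(self, rng: np.random.Generator, stop: StopCriteria,
                  report_times: Optional[Sequence[float]] = None,
                  species_log: Optional[List[tuple]] = None
                  ) -> List[ObservationRecord]:
        """Advance the simulation to the stop criteria, recording at the
        report grid (log-spaced times) and at termination.

        When ``species_log`` is given, rows of
        ``(time, tag, n_a, n_b, n_c, count)`` are appended to it at every
        report point, giving the full species-resolved trajectory.
        """
        records: List[ObservationRecord] = []
        grid = list(report_times) if report_times is not None else []
        next_report = 0

        def _record(snap: SystemState) -> None:
            records.append(observe(snap))
            if species_log is not None:
                for sp, count in sorted(snap.counts.items(),
                                        key=lambda it: it[0].signature()):
                    species_log.append((snap.time, sp.tag,
                                        *sp.shape.as_tuple(), count))

        while (self.time < stop.max_time and self.events < stop.max_events
               and self.status == "running"):
            event = self.step(rng)
            if event is None:
                break
            while (next_report < len(grid)
                   and grid[next_report] <= self.time):
                snap = self.state()
                snap.time = grid[next_report]
                _record(snap)
                next_report += 1
        if self.status == "running":
            self.status = ("time_reached" if self.time >= stop.max_time
                           else "event_limit")
        _record(self.state())
        return records


def enumerate_reactions(state: SystemState, specs: Dict[str, PolymorphSpec],
                        cond: SolventConditions,
                        model: Optional[RateModel] = None) -> List[Reaction]:
    """All reaction channels available in ``state``, as explicit reactions.

    Monomer dimerisation channels are expanded into one reaction per
    (contact axis, committed polymorph) with half the axis kernel each,
    which is the channel-level statement of the fair-coin commitment.
    Deterministic given the state; uses (and fills) the model's
    per-signature rate cache.
    """
    if model is None:
        model = RateModel(specs, cond)
    thr = PRUNE_THRESHOLD * state.volume
    present = [s for s, c in state.counts.items() if c > 0]
    out: List[Reaction] = []
    for s in present:
        out.extend(model.split_channels_for(s))
    for a in range(len(present)):
        for b in range(a, len(present)):
            sA, sB = present[a], present[b]
            if sA is sB and state.counts[sA] < 2:
                continue
            if sA.tag == "MONOMER" and sB.tag == "MONOMER":
                for ch in model.dimer_channels:
                    for tag, product in sorted(ch.products_by_tag.items()):
                        out.append(Reaction(
                            kind="join", reactants=(MONOMER, MONOMER),
                            products=(product,),
                            rate_constant=ch.rate_constant / 2.0,
                            contact_axis=ch.contact_axis))
            else:
                out.extend(c for c in model.pair_channels(sA, sB)
                           if c.rate_constant >= thr)
    return out


def run(config: RunConfig, model: Optional[RateModel] = None,
        validate: bool = False,
        species_logs: Optional[List[List[tuple]]] = None
        ) -> List[List[ObservationRecord]]:
    """Simulate all replicates of one configuration.

    Replicate ``r`` uses seed ``config.seed + r``; identical configurations
    therefore give bit-identical trajectories.  Returns one record list per
    replicate.  When ``species_logs`` is a list, one species-resolved
    trajectory (rows of time, tag, shape, count at each report point) is
    appended to it per replicate.
    """
    if model is None:
        model = RateModel(config.specs, config.solvent)
    volume = volume_for_concentration(config.total_peptides,
                                      config.concentration)
    grid = config.report_grid()
    trajectories = []
    for r in range(config.replicates):
        rng = np.random.default_rng(config.seed + r)
        sim = Simulator(model, volume, validate=validate)
        sim.init_monomers(config.total_peptides)
        log: Optional[List[tuple]] = [] if species_logs is not None else None
        trajectories.append(sim.run_until(rng, config.stop, grid,
                                          species_log=log))
        if species_logs is not None:
            species_logs.append(log)
        logger.info(
            "replicate %d: %d events, t = %.3g s, %d species, status %s",
            r, sim.events, sim.time, sim.n_species, sim.status)
    return trajectories


def sweep(base: RunConfig, concentrations: Sequence[float],
          model: Optional[RateModel] = None,
          ) -> Dict[float, List[List[ObservationRecord]]]:
    """Run the same configuration across a series of concentrations.

    The rate model (and its channel cache) is shared across the whole
    sweep, since rate constants do not depend on the simulation volume.
    """
    if model is None:
        model = RateModel(base.specs, base.solvent)
    results = {}
    for conc in concentrations:
        cfg = RunConfig(
            total_peptides=base.total_peptides, concentration=conc,
            specs=base.specs, solvent=base.solvent, seed=base.seed,
            replicates=base.replicates, stop=base.stop,
            report_points=base.report_points, report_t_min=base.report_t_min)
        results[conc] = run(cfg, model=model)
    return results
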