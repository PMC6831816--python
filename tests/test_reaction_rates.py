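"""Collision kernels, Arrhenius splits, compound channels and pruning."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zippersim.constants import arrhenius_thermal_energy
from zippersim.hydrodynamics import monomer_tau0, rod_diffusion_coefficient
from zippersim.interface_energetics import interface_free_energy
from zippersim.lattice_geometry import BlockShape, block_dimensions
from zippersim.reaction_rates import (
    BARRIER_FACTOR,
    MONOMER,
    bimolecular_propensity,
    collision_rate_constant,
    compound_join_split_rate,
    make_species,
    monomer_dimerisation_channels,
    pair_join_channels,
    prune,
    simple_join_channel,
    split_channels,
    split_rate_constant,
)

nb_values = st.sampled_from([1, 2, 4])
shape_strategy = st.tuples(st.integers(1, 6), nb_values, st.integers(1, 12))


def sp(tag, *shape):
    return make_species(tag, *shape)


class TestCollisionRateConstant:
    def test_hand_evaluation_of_kernel(self, ap_spec, cond):
        """k = 2 e^-3 (D_A + D_B) sqrt(2 A) against independent arithmetic
        for a monomer-monomer a-axis contact (face 9.55 x 4.8 A)."""
        D = rod_diffusion_coefficient(
            block_dimensions(BlockShape(1, 1, 1), ap_spec), cond)
        k = collision_rate_constant(MONOMER, MONOMER, "a", ap_spec, cond)
        area = 9.55 * 4.8 * 1e-20
        assert k == pytest.approx(
            2 * math.exp(-3) * 2 * D * math.sqrt(2 * area), rel=1e-12)
        assert k == pytest.approx(
            2 * 0.049787 * 2 * D * 9.575e-10, rel=1e-3)

    def test_symmetric_in_species(self, ap_spec, cond):
        a = sp("AP", 3, 2, 5)
        b = sp("AP", 1, 2, 5)
        assert collision_rate_constant(a, b, "a", ap_spec, cond) == \
            collision_rate_constant(b, a, "a", ap_spec, cond)

    def test_barrier_factor_is_e_minus_three(self):
        assert BARRIER_FACTOR == pytest.approx(0.049787, rel=1e-4)


class TestBimolecularPropensity:
    def test_homodimer_symmetry_factor(self):
        assert bimolecular_propensity(1.0, 10, 10, 1.0, homo=True) == 45.0

    def test_zero_counts_give_zero(self):
        assert bimolecular_propensity(2.0, 0, 5, 1.0, homo=False) == 0.0
        assert bimolecular_propensity(2.0, 1, 0, 1.0, homo=True) == 0.0

    def test_hetero_mass_action(self):
        assert bimolecular_propensity(1.0, 2, 3, 1.0, homo=False) == 6.0


class TestSplitRateConstant:
    def test_arrhenius_form_against_independent_arithmetic(
            self, ap_spec, cond):
        tau0 = monomer_tau0(ap_spec, cond)
        shape = BlockShape(1, 1, 5)
        k = split_rate_constant(shape, "c", ap_spec, tau0, cond)
        dG = interface_free_energy(ap_spec, "c", shape)  # 1x1 cross-section
        assert dG == pytest.approx(-29.3)
        expected = math.exp(dG / arrhenius_thermal_energy(300.0)) / tau0
        assert k == pytest.approx(expected, rel=1e-12)

    def test_zero_energy_interface_splits_at_inverse_tau0(self, ap_spec,
                                                          cond):
        table = type(ap_spec.energies).rectangular(0.0, 0.0, 0.0, 0.0)
        spec0 = type(ap_spec)(ap_spec.label, ap_spec.symmetry,
                              ap_spec.lattice, table)
        k = split_rate_constant(BlockShape(2, 2, 2), "c", spec0, 1e-9, cond)
        assert k == pytest.approx(1e9)

    def test_equivalent_plane_multiplicity(self, ap_spec, cond, model):
        """A fibril of length w has w - 1 equivalent hydrogen-bond planes."""
        channels = split_channels(sp("AP", 1, 1, 10), ap_spec,
                                  model.tau0s["AP"], cond)
        c_channels = [c for c in channels if c.plane == "c"]
        assert len(c_channels) == 1
        assert c_channels[0].multiplicity == 9

    @given(shape=shape_strategy.filter(lambda s: s != (1, 1, 1)))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_buried_interface(self, ap_spec, cond, shape):
        """Burying more peptides in the cleaved interface strictly slows
        the split."""
        tau0 = 1e-9
        na, nb, nc = shape
        small = split_rate_constant(BlockShape(na, nb, nc), "c",
                                    ap_spec, tau0, cond)
        big = split_rate_constant(BlockShape(na + 1, nb, nc), "c",
                                  ap_spec, tau0, cond)
        assert big < small


class TestSimpleJoin:
    def test_matching_faces_merge(self, specs, cond, model):
        rxn = simple_join_channel(sp("AP", 1, 1, 3), sp("AP", 1, 1, 5), "c",
                                  specs["AP"], cond)
        assert rxn is not None and rxn.kind == "join"
        assert rxn.products[0].signature() == ("AP", 1, 1, 8)

    def test_zip_contact_requires_single_sheets(self, specs, cond):
        ok = simple_join_channel(sp("AP", 2, 1, 3), sp("AP", 2, 1, 3), "b",
                                 specs["AP"], cond)
        assert ok is not None and ok.products[0].shape.n_b == 2
        bad = simple_join_channel(sp("AP", 2, 1, 3), sp("AP", 2, 2, 3), "b",
                                  specs["AP"], cond)
        assert bad is None  # 1 + 2 would create an inside-out block

    def test_mismatched_faces_do_not_simple_join(self, specs, cond):
        assert simple_join_channel(sp("AP", 1, 1, 3), sp("AP", 1, 1, 5), "a",
                                   specs["AP"], cond) is None


class TestCompoundJoinSplit:
    def test_worked_example_rate_and_products(self, specs, cond, model):
        """(3,4,4) + (2,4,6) colliding on a: the c overhang of the second
        block is cleaved with the (2,4) cross-section rate, giving the
        compound rate tau0 * k_c(2,4) * k_join and products (5,4,4) +
        (2,4,2)."""
        spec = specs["AP"]
        tau0 = model.tau0s["AP"]
        sA, sB = sp("AP", 3, 4, 4), sp("AP", 2, 4, 6)
        rxn = compound_join_split_rate(sA, sB, "a", spec, cond, tau0)
        assert rxn is not None and rxn.kind == "join_split"
        k_c = split_rate_constant(BlockShape(2, 4, 6), "c", spec, tau0, cond)
        k_join = collision_rate_constant(sA, sB, "a", spec, cond)
        assert rxn.rate_constant == pytest.approx(tau0 * k_c * k_join,
                                                  rel=1e-12)
        assert {p.signature() for p in rxn.products} == \
            {("AP", 5, 4, 4), ("AP", 2, 4, 2)}

    def test_matching_shapes_reduce_to_simple_join(self, specs, cond, model):
        sA = sp("AP", 2, 2, 4)
        assert compound_join_split_rate(sA, sA, "c", specs["AP"], cond,
                                        model.tau0s["AP"]) is None
        rxn = simple_join_channel(sA, sA, "c", specs["AP"], cond)
        assert rxn is not None and "split" not in rxn.kind

    def test_two_cleavage_choices_keep_only_fastest(self, specs, cond,
                                                    model):
        """When one block overhangs in both contact-plane dimensions the
        two cut orders give different offcuts and rates; the channel must
        carry the faster of the two."""
        spec = specs["AP"]
        tau0 = model.tau0s["AP"]
        sA, sB = sp("AP", 3, 4, 6), sp("AP", 2, 2, 3)
        rxn = compound_join_split_rate(sA, sB, "a", spec, cond, tau0)
        assert rxn is not None
        k_join = collision_rate_constant(sA, sB, "a", spec, cond)

        # order 1: cut b of (3,4,6) to 2, then c of (3,2,6) to 3
        k1 = (tau0 * split_rate_constant(BlockShape(3, 4, 6), "b", spec,
                                         tau0, cond)
              * tau0 * split_rate_constant(BlockShape(3, 2, 6), "c", spec,
                                           tau0, cond)) * k_join
        # order 2: cut c first, then b
        k2 = (tau0 * split_rate_constant(BlockShape(3, 4, 6), "c", spec,
                                         tau0, cond)
              * tau0 * split_rate_constant(BlockShape(3, 4, 3), "b", spec,
                                           tau0, cond)) * k_join
        assert rxn.rate_constant == pytest.approx(max(k1, k2), rel=1e-12)

    def test_symmetric_under_reactant_exchange(self, specs, cond, model):
        spec = specs["AP"]
        tau0 = model.tau0s["AP"]
        r1 = compound_join_split_rate(sp("AP", 3, 4, 4), sp("AP", 2, 4, 6),
                                      "a", spec, cond, tau0)
        r2 = compound_join_split_rate(sp("AP", 2, 4, 6), sp("AP", 3, 4, 4),
                                      "a", spec, cond, tau0)
        assert r1.rate_constant == pytest.approx(r2.rate_constant)
        assert {p.signature() for p in r1.products} == \
            {p.signature() for p in r2.products}

    @given(a=shape_strategy, b=shape_strategy,
           axis=st.sampled_from(["a", "b", "c"]))
    @settings(max_examples=150, deadline=None)
    def test_conservation_and_shape_validity(self, specs, cond, model,
                                             a, b, axis):
        """Every emitted compound reaction conserves peptides and produces
        only admissible block shapes."""
        if a == (1, 1, 1) and b == (1, 1, 1):
            return
        sA, sB = sp("AP", *a), sp("AP", *b)
        rxn = compound_join_split_rate(sA, sB, axis, specs["AP"], cond,
                                       model.tau0s["AP"])
        if rxn is None:
            return
        assert sum(p.n_peptides for p in rxn.products) == \
            sA.n_peptides + sB.n_peptides
        for p in rxn.products:
            nb = p.shape.n_b
            assert nb == 1 or nb % 2 == 0


class TestPairChannels:
    def test_cross_polymorph_pairs_never_react(self, specs, cond, model):
        channels = pair_join_channels(sp("AP", 1, 1, 2), sp("P", 1, 1, 2),
                                      specs, cond, model.tau0s)
        assert channels == []

    def test_monomer_adopts_aggregate_polymorph(self, specs, cond, model):
        channels = pair_join_channels(MONOMER, sp("P", 1, 1, 4), specs,
                                      cond, model.tau0s)
        assert channels
        for rxn in channels:
            for p in rxn.products:
                assert p.tag in ("P", "MONOMER")


class TestDimerisationChannels:
    def test_three_contact_axes(self, specs, cond):
        channels = monomer_dimerisation_channels(specs, cond)
        assert sorted(c.contact_axis for c in channels) == ["a", "b", "c"]

    def test_kernel_is_polymorph_average(self, specs, cond):
        channels = {c.contact_axis: c
                    for c in monomer_dimerisation_channels(specs, cond)}
        for axis in "abc":
            ks = [collision_rate_constant(MONOMER, MONOMER, axis, spec,
                                          cond) for spec in specs.values()]
            assert channels[axis].rate_constant == \
                pytest.approx(sum(ks) / 2)

    def test_products_cover_both_polymorphs(self, specs, cond):
        for ch in monomer_dimerisation_channels(specs, cond):
            assert set(ch.products_by_tag) == {"AP", "P"}
            n = {t: p.n_peptides for t, p in ch.products_by_tag.items()}
            assert n == {"AP": 2, "P": 2}


class TestPrune:
    @pytest.mark.parametrize("k,discard", [
        (1e-51, True), (1e-49, False), (0.0, True), (1e-50, False),
    ])
    def test_threshold(self, k, discard):
        assert prune(k) is discard

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            prune(-1.0)


class TestLeanRatePath:
    """The allocation-free pair-rate path used to assemble the engine's
    rate matrix must agree channel for channel with the full enumeration."""

    @given(a=shape_strategy, b=shape_strategy,
           tags=st.sampled_from([("AP", "AP"), ("P", "P"),
                                 ("MONOMER", "AP"), ("MONOMER", "P"),
                                 ("AP", "P")]))
    @settings(max_examples=300, deadline=None)
    def test_matches_full_enumeration(self, specs, cond, model, a, b, tags):
        from zippersim.reaction_rates import pair_rate_constants
        tag_a, tag_b = tags
        if tag_a == "MONOMER":
            a = (1, 1, 1)
        if a == (1, 1, 1):
            tag_a = "MONOMER"
        if b == (1, 1, 1):
            tag_b = "MONOMER"
        if tag_a == "MONOMER" and tag_b == "MONOMER":
            return
        sA, sB = sp(tag_a, *a), sp(tag_b, *b)
        full = sorted(r.rate_constant for r in
                      pair_join_channels(sA, sB, specs, cond, model.tau0s))
        lean = sorted(pair_rate_constants(a, b, tag_a, tag_b,
                                          model.kernels))
        assert len(full) == len(lean)
        for kf, kl in zip(full, lean):
            assert kl == pytest.approx(kf, rel=1e-12, abs=1e-300)
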