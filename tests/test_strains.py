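"""Strain edits: knockouts, demethylase swaps, pinning, product coupling."""

import pytest

from aromflux import (
    BatchState,
    apply_edits,
    apply_knockout,
    biomass_yield,
    check_mass_balance,
    make_pdc_strain,
    models_equal,
    pin_wildtype_fluxes,
    run_dfba,
    solve_fba,
    swap_demethylase,
)
from aromflux.strains import (
    StrainEdit,
    StrainEditError,
    evaluate_gpr,
    install_product,
    load_edits,
    pdc_strain_edits,
    save_edits,
)
from aromflux.synthetic import ToySpec, make_kinetics_table, make_toy_model

ONLY_VAN = {"EX_glc": (0.0, None), "EX_syr": (0.0, None), "EX_phb": (0.0, None)}


class TestGpr:
    @pytest.mark.parametrize("expr,ko,active", [
        ("desA or ligM", {"desA"}, True),
        ("desA or ligM", {"desA", "ligM"}, False),
        ("vanA and vanB", {"vanB"}, False),
        ("A and (B or C)", {"B"}, True),
        ("A and (B or C)", {"B", "C"}, False),
        ("A and (B or C)", {"A"}, False),
    ])
    def test_boolean_semantics(self, expr, ko, active):
        assert evaluate_gpr(expr, ko) is active

    def test_gene_knockout_disables_dependent_reactions(self, toy_model):
        # desA alone leaves the isozyme route open
        partial = apply_knockout(toy_model, ["desA"])
        assert partial.reactions["DEMETH_van"].upper_bound > 0
        out = apply_knockout(toy_model, ["desA", "ligM"])
        assert out.reactions["DEMETH_van"].upper_bound == 0.0
        assert out.reactions["DEMETH_van"].lower_bound == 0.0

    def test_biomass_gene_knockout_kills_growth(self, toy_model):
        out = apply_knockout(toy_model, ["bio1"])
        sol = solve_fba(out, extra_bounds={"EX_van": (-1.0, None)})
        assert sol.objective_value == pytest.approx(0.0, abs=1e-12)

    def test_unknown_id_rejected(self, toy_model):
        with pytest.raises(KeyError):
            apply_knockout(toy_model, ["not_a_gene"])


class TestDemethylaseSwap:
    def test_swap_reproduces_generated_variant(self, toy_model):
        for variant in ("hypothetical_nonTHF", "VanAB", "native_THF"):
            swapped = swap_demethylase(toy_model, variant)
            generated = make_toy_model(ToySpec(
                substrates=("glucose", "vanillic", "syringic", "p-HBA"),
                demethylase=variant))
            assert models_equal(swapped, generated)

    def test_variants_differ_only_in_demethylation_reactions(self, toy_model):
        from aromflux.synthetic import DEMETHYLATION_SLOTS

        native = toy_model
        vanab = swap_demethylase(native, "VanAB")
        allowed = set(DEMETHYLATION_SLOTS) | {"MTHF_recycle"}
        diff = set()
        for rid in set(native.reactions) | set(vanab.reactions):
            a, b = native.reactions.get(rid), vanab.reactions.get(rid)
            if a is None or b is None or a.stoichiometry != b.stoichiometry:
                diff.add(rid)
        assert diff <= allowed
        assert diff

    @pytest.mark.parametrize("variant", ["native_THF", "hypothetical_nonTHF",
                                         "VanAB"])
    def test_swapped_models_stay_element_balanced(self, toy_model, variant):
        violations, skipped = check_mass_balance(
            swap_demethylase(toy_model, variant))
        assert violations == []
        assert skipped == 0

    def test_unmethoxylated_yields_identical_across_variants(self, toy_model):
        baseline = {ex: biomass_yield(toy_model, ex).yield_mgdw_per_mmol
                    for ex in ("EX_phb", "EX_glc")}
        for variant in ("hypothetical_nonTHF", "VanAB"):
            m = swap_demethylase(toy_model, variant)
            for ex, ref in baseline.items():
                assert biomass_yield(m, ex).yield_mgdw_per_mmol == ref

    def test_methoxylated_yields_drop_without_thf(self, toy_model):
        for variant in ("hypothetical_nonTHF", "VanAB"):
            m = swap_demethylase(toy_model, variant)
            for ex in ("EX_van", "EX_syr"):
                assert (biomass_yield(m, ex).yield_mgdw_per_mmol
                        < biomass_yield(toy_model, ex).yield_mgdw_per_mmol)

    def test_methyl_carbon_leaves_by_variant_route(self, toy_model):
        """Element bookkeeping of the demethylation fate per variant."""
        sol = solve_fba(toy_model, extra_bounds={"EX_van": (-1.0, None),
                                                 **ONLY_VAN})
        # native: methyl carbon burned to CO2 through the carrier recycle
        assert sol.fluxes["MTHF_recycle"] == pytest.approx(1.0, abs=1e-8)
        non = swap_demethylase(toy_model, "hypothetical_nonTHF")
        sol_n = solve_fba(non, extra_bounds={"EX_van": (-1.0, None), **ONLY_VAN})
        assert sol_n.fluxes["DEMETH_van"] == pytest.approx(1.0, abs=1e-8)
        # formate produced 1:1 with demethylation (oxidized or excreted)
        formate_fate = sol_n.fluxes["FOR_DH"] + sol_n.fluxes["EX_formate"]
        assert formate_fate == pytest.approx(1.0, abs=1e-8)
        vanab = swap_demethylase(toy_model, "VanAB")
        sol_v = solve_fba(vanab, extra_bounds={"EX_van": (-1.0, None), **ONLY_VAN})
        fald_fate = sol_v.fluxes["FALD_DH"] + sol_v.fluxes["EX_fald"]
        assert fald_fate == pytest.approx(1.0, abs=1e-8)

    def test_missing_slots_raise_structural_error(self, chain_model):
        with pytest.raises(StrainEditError, match="slots"):
            swap_demethylase(chain_model, "VanAB")


class TestEditReplay:
    def test_serialized_edits_reproduce_strain(self, toy_model, tmp_path):
        edits = pdc_strain_edits(toy_model)
        path = tmp_path / "pdc_edits.json"
        save_edits(edits, path)
        replayed = apply_edits(toy_model, load_edits(path))
        assert models_equal(replayed, make_pdc_strain(toy_model))

    def test_edit_order_matters(self, toy_model):
        # deleting a reaction then removing its ratio constraint fails,
        # because removal already dropped the constraint
        e1 = StrainEdit("reaction_delete", {"reaction_id": "CHMOD_GAL"})
        e2 = StrainEdit("ratio_constraint_remove",
                        {"constraint_id": "chmod_side_ratio"})
        apply_edits(toy_model, [e2, e1])  # fine in this order
        with pytest.raises(KeyError):
            apply_edits(toy_model, [e1, e2])

    def test_unknown_edit_kind_rejected(self):
        with pytest.raises(StrainEditError):
            StrainEdit("mutate_everything", {})


class TestPdcStrain:
    def test_no_growth_but_full_pdc_flux_on_vanillate(self, toy_model):
        strain = make_pdc_strain(toy_model)
        sol = solve_fba(strain, extra_bounds=ONLY_VAN,
                        pinned_fluxes={"EX_van": -1.0},
                        secondary_objective={"EX_pdc": 1.0})
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        # every vanillate ring leaves as PDC: the funnel's stoichiometric max
        assert sol.fluxes["EX_pdc"] == pytest.approx(1.0, abs=1e-8)

    def test_growth_and_pdc_production_coexist_with_glucose(self, toy_model):
        strain = make_pdc_strain(toy_model)
        sol = solve_fba(strain,
                        extra_bounds={"EX_glc": (-1.0, None),
                                      "EX_syr": (0, None), "EX_phb": (0, None)},
                        pinned_fluxes={"EX_van": -1.0})
        assert sol.objective_value > 0.05
        assert sol.fluxes["EX_pdc"] == pytest.approx(1.0, abs=1e-8)


class TestPinning:
    def test_pinning_exchange_to_zero_equals_closing_it(self, toy_model):
        closed = solve_fba(toy_model, extra_bounds={
            "EX_van": (0.0, 0.0), "EX_glc": (-1.0, None),
            "EX_syr": (0, None), "EX_phb": (0, None)})
        pinned = solve_fba(toy_model, extra_bounds={
            "EX_glc": (-1.0, None), "EX_syr": (0, None), "EX_phb": (0, None)},
            pinned_fluxes={"EX_van": 0.0})
        assert pinned.objective_value == pytest.approx(closed.objective_value,
                                                       abs=1e-9)

    def test_wildtype_pins_transfer_to_mutant(self, toy_model):
        strain = make_pdc_strain(toy_model)
        bounds = {"EX_van": (-0.8, None), "EX_glc": (-0.5, None),
                  "EX_syr": (0, None), "EX_phb": (0, None)}
        pinned, pins = pin_wildtype_fluxes(toy_model, strain, ("EX_van",),
                                           extra_bounds=bounds)
        assert pins["EX_van"] == pytest.approx(-0.8, abs=1e-6)
        sol = solve_fba(pinned, extra_bounds=bounds)
        assert sol.optimal
        assert sol.fluxes["EX_van"] == pytest.approx(pins["EX_van"], abs=1e-8)

    def test_infeasible_pin_names_the_culprit(self, toy_model):
        # a mutant with no vanillate demethylation cannot honor a
        # vanillate-uptake pin (nothing downstream can drain it)
        mutant = apply_knockout(toy_model, ["desA", "ligM"])
        mutant.remove_reaction("MTHF_recycle")
        bounds = {"EX_van": (-0.8, None), "EX_glc": (0, None),
                  "EX_syr": (0, None), "EX_phb": (0, None)}
        with pytest.raises(StrainEditError, match="EX_van"):
            pin_wildtype_fluxes(toy_model, mutant, ("EX_van",),
                                extra_bounds=bounds)


class TestProductCoupling:
    def test_zero_coupling_behaves_as_unedited(self, toy_model):
        strain, _ = install_product(toy_model, "pdc", "EX_van", 0.0)
        a = solve_fba(strain, extra_bounds={"EX_van": (-1.0, None), **ONLY_VAN})
        b = solve_fba(toy_model, extra_bounds={"EX_van": (-1.0, None),
                                               **ONLY_VAN})
        assert a.objective_value == pytest.approx(b.objective_value, abs=1e-10)

    def test_stoichiometric_max_coupling_starves_growth(self, toy_model):
        strain, pex = install_product(toy_model, "pdc", "EX_van", 1.0)
        sol = solve_fba(strain, extra_bounds={**ONLY_VAN},
                        pinned_fluxes={"EX_van": -1.0},
                        secondary_objective={pex: 1.0})
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes[pex] == pytest.approx(1.0, abs=1e-8)
        # all substrate carbon leaves as product, CO2 or byproducts
        c_in = 8 * 1.0
        c_out = (7 * sol.fluxes[pex] + sol.fluxes["EX_co2"]
                 + sol.fluxes["EX_meoh"] + sol.fluxes["EX_formate"]
                 + sol.fluxes["EX_fald"])
        assert c_out == pytest.approx(c_in, rel=1e-6)

    def test_overstoichiometric_coupling_is_infeasible(self, toy_model):
        strain, pex = install_product(toy_model, "pdc", "EX_van", 1.2)
        sol = solve_fba(strain, extra_bounds=ONLY_VAN,
                        pinned_fluxes={"EX_van": -1.0})
        assert sol.status == "infeasible"

    @pytest.mark.parametrize("product", ["ccma", "acetate", "glycerol"])
    def test_shipped_recipes_install_and_produce(self, toy_model, product):
        strain, pex = install_product(toy_model, product, "EX_van", 0.2)
        violations, _ = check_mass_balance(strain)
        assert violations == []
        sol = solve_fba(strain, extra_bounds={"EX_van": (-1.0, None),
                                              **ONLY_VAN})
        assert sol.optimal
        assert sol.fluxes[pex] == pytest.approx(0.2, abs=1e-8)
        assert sol.objective_value > 0.0

    def test_unknown_product_rejected(self, toy_model):
        with pytest.raises(KeyError):
            install_product(toy_model, "unobtainium", "EX_van", 0.1)


class TestSweeps:
    def test_coarse_pdc_sweep_rises_then_falls(self):
        from aromflux import yield_sweep
        from aromflux.synthetic import make_media, substrate_classes

        m = make_toy_model(ToySpec(substrates=("vanillic",)))
        media = make_media(m, {"vanillic": 5.0})
        sweep = yield_sweep(m, "pdc", "EX_van", 5.0, grid_step=0.1,
                            media_caps=media.exchange_bounds(),
                            substrate_classes=substrate_classes(m))
        rates = [r for _, r, _ in sweep.grid]
        best_f, best_rate, _ = sweep.best
        assert best_rate == max(rates)
        assert rates[0] < best_rate  # rises from zero coupling
        assert rates[-1] < best_rate  # falls toward full coupling
        assert 0.0 < best_f < 1.0  # interior optimum

    def test_sweep_grid_step_validated(self, toy_model):
        from aromflux import yield_sweep

        with pytest.raises(ValueError):
            yield_sweep(toy_model, "pdc", "EX_van", 5.0, grid_step=0.5)
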