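"""Steady-state FBA: LP correctness against independent oracles."""

import itertools

import numpy as np
import pytest

from aromflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    biomass_yield,
    solve_fba,
)


def vertex_enumeration_optimum(A_eq, c, bounds):
    """Brute-force LP oracle: enumerate basic feasible solutions.

    Maximizes c.v subject to A_eq v = 0, lb <= v <= ub by fixing every
    subset of n - rank(A) variables at one of its bounds, solving the
    square system for the rest, and keeping the best feasible vertex.
    All bounds must be finite.
    """
    A = np.asarray(A_eq, dtype=float)
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    n_fix = n - rank
    best = None
    lbs = np.array([b[0] for b in bounds])
    ubs = np.array([b[1] for b in bounds])
    for fixed_idx in itertools.combinations(range(n), n_fix):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        for corners in itertools.product(*[(lbs[j], ubs[j]) for j in fixed_idx]):
            v = np.zeros(n)
            for j, val in zip(fixed_idx, corners):
                v[j] = val
            rhs = -A[:, list(fixed_idx)] @ np.array(corners)
            sub = A[:, free_idx]
            sol, *_ = np.linalg.lstsq(sub, rhs, rcond=None)
            if np.linalg.norm(sub @ sol - rhs) > 1e-8:
                continue
            v[free_idx] = sol
            if np.any(v < lbs - 1e-9) or np.any(v > ubs + 1e-9):
                continue
            obj = float(c @ v)
            if best is None or obj > best:
                best = obj
    return best


def random_small_model(rng, with_ratio=False):
    """Random <= 8-reaction model with finite bounds straddling zero."""
    n_mets = rng.integers(2, 4)
    n_rxns = rng.integers(max(3, n_mets + 1), 9)
    m = MetabolicModel(id="rand")
    for i in range(n_mets):
        m.add_metabolite(Metabolite(id=f"m{i}_c", compartment="c"))
    for j in range(n_rxns):
        sto = {}
        for i in rng.choice(n_mets, size=rng.integers(1, n_mets + 1),
                            replace=False):
            coeff = float(rng.integers(-2, 3))
            if coeff:
                sto[f"m{i}_c"] = coeff
        if not sto:
            sto[f"m0_c"] = 1.0
        lb = float(-rng.integers(0, 6))
        ub = float(rng.integers(1, 6))
        m.add_reaction(Reaction(id=f"r{j}", stoichiometry=sto,
                                lower_bound=lb, upper_bound=ub))
    m.objective = f"r{rng.integers(0, n_rxns)}"
    if with_ratio and n_rxns >= 2:
        a, b = rng.choice(n_rxns, size=2, replace=False)
        m.add_ratio_constraint(f"r{a}", f"r{b}", 0.15)
    return m


class TestOracleEquivalence:
    @pytest.mark.parametrize("with_ratio", [False, True])
    def test_lp_matches_vertex_enumeration(self, with_ratio):
        rng = np.random.default_rng(20220418 + int(with_ratio))
        checked = 0
        while checked < 20:
            model = random_small_model(rng, with_ratio)
            sol = solve_fba(model)
            if not sol.optimal:
                continue
            S, _, rxn_ids = model.stoichiometric_matrix()
            rows = [S]
            for rc in model.ratio_constraints:
                row = np.zeros((1, len(rxn_ids)))
                row[0, rxn_ids.index(rc.reaction_a)] = 1.0
                row[0, rxn_ids.index(rc.reaction_b)] = -rc.ratio
                rows.append(row)
            A = np.vstack(rows)
            c = np.zeros(len(rxn_ids))
            c[rxn_ids.index(model.objective)] = 1.0
            bounds = [(model.reactions[r].lower_bound,
                       model.reactions[r].upper_bound) for r in rxn_ids]
            brute = vertex_enumeration_optimum(A, c, bounds)
            assert brute is not None
            assert sol.objective_value == pytest.approx(brute, abs=1e-9)
            # steady state and ratio residuals at the reported vertex
            v = np.array([sol.fluxes[r] for r in rxn_ids])
            assert np.max(np.abs(A @ v)) < 1e-9
            checked += 1
        assert checked == 20

    def test_toy_optimum_matches_cobrapy(self, toy_model):
        """Independent solver cross-check on the funneling model.

        cobrapy/GLPK gets the same model without the ratio constraint
        (SBML-FBC cannot carry it), so the comparison removes it from
        both sides.
        """
        import cobra

        from aromflux.model import _to_cobra

        model = toy_model.copy()
        model.ratio_constraints = []
        for rid in ("EX_van", "EX_glc", "EX_syr", "EX_phb"):
            model.reactions[rid].lower_bound = -1.0
        ours = solve_fba(model)
        cm = _to_cobra(model)
        theirs = cm.optimize()
        assert theirs.status == "optimal"
        assert ours.objective_value == pytest.approx(theirs.objective_value,
                                                     rel=1e-6)


class TestBasics:
    def test_linear_chain_hand_value(self, chain_model):
        sol = solve_fba(chain_model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.5, abs=1e-9)

    def test_knocked_out_biomass_gives_zero(self, chain_model):
        chain_model.reactions["GROWTH"].upper_bound = 0.0
        sol = solve_fba(chain_model)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_reported_without_fluxes(self, chain_model):
        # demand flux through the chain while the uptake is closed
        chain_model.reactions["EX_A"].lower_bound = 0.0
        sol = solve_fba(chain_model, pinned_fluxes={"GROWTH": 0.4})
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_unknown_objective_raises(self, chain_model):
        with pytest.raises(KeyError):
            solve_fba(chain_model, objective="nope")

    def test_pin_outside_bounds_rejected(self, chain_model):
        with pytest.raises(ValueError, match="outside"):
            solve_fba(chain_model, pinned_fluxes={"EX_A": -5.0})


class TestRatioConstraints:
    def test_toy_side_branch_operates_at_fifteen_percent(self, toy_model):
        # force S flux through the ring-cleavage branch point by removing
        # the gallate demethylation escape (otherwise the optimum may
        # satisfy the ratio trivially at zero)
        toy_model.remove_reaction("DEMETH_mga")
        sol = solve_fba(toy_model, extra_bounds={
            "EX_syr": (-1.0, None), "EX_glc": (0, None),
            "EX_van": (0, None), "EX_phb": (0, None)})
        assert sol.optimal
        v_gal = sol.fluxes["CHMOD_GAL"]
        v_pdc = sol.fluxes["CHMOD_PDC"]
        assert v_pdc > 0
        assert v_gal == pytest.approx(0.15 * v_pdc, abs=1e-9)

    def test_zero_ratio_forces_zero_flux(self, toy_model):
        m = toy_model.copy()
        m.remove_ratio_constraint("chmod_side_ratio")
        m.add_ratio_constraint("CHMOD_GAL", "CHMOD_PDC", 0.0)
        sol = solve_fba(m, extra_bounds={
            "EX_syr": (-1.0, None), "EX_glc": (0, None),
            "EX_van": (0, None), "EX_phb": (0, None)})
        assert sol.fluxes["CHMOD_GAL"] == 0.0

    def test_unit_ratio_splits_parallel_branches_equally(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite(id="a_e", compartment="e"))
        m.add_metabolite(Metabolite(id="a_c", compartment="c"))
        m.add_metabolite(Metabolite(id="b_c", compartment="c"))
        m.add_reaction(Reaction(id="EX_a", stoichiometry={"a_e": -1.0},
                                lower_bound=-2.0, kind="exchange"))
        m.add_reaction(Reaction(id="T", stoichiometry={"a_e": -1.0, "a_c": 1.0},
                                lower_bound=0.0, kind="transport"))
        m.add_reaction(Reaction(id="P1", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                                lower_bound=0.0))
        m.add_reaction(Reaction(id="P2", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                                lower_bound=0.0))
        m.add_reaction(Reaction(id="SINK", stoichiometry={"b_c": -1.0},
                                lower_bound=0.0, kind="demand"))
        m.objective = "SINK"
        m.add_ratio_constraint("P1", "P2", 1.0)
        sol = solve_fba(m)
        assert sol.objective_value == pytest.approx(2.0, abs=1e-9)
        assert sol.fluxes["P1"] == pytest.approx(sol.fluxes["P2"], abs=1e-9)
        assert sol.fluxes["P1"] == pytest.approx(1.0, abs=1e-9)

    def test_unknown_reaction_in_ratio_rejected(self, toy_model):
        with pytest.raises(KeyError):
            toy_model.add_ratio_constraint("CHMOD_GAL", "nope", 0.5)


class TestProperties:
    def test_raising_uptake_never_decreases_growth(self, toy_model):
        prev = -1.0
        for cap in (0.2, 0.5, 1.0, 2.0):
            sol = solve_fba(toy_model, extra_bounds={
                "EX_van": (-cap, None), "EX_glc": (0, None),
                "EX_syr": (0, None), "EX_phb": (0, None)})
            assert sol.objective_value >= prev - 1e-12
            prev = sol.objective_value

    def test_doubling_uptake_doubles_optimum(self, toy_model):
        def mu(cap):
            return solve_fba(toy_model, extra_bounds={
                "EX_van": (-cap, None), "EX_glc": (0, None),
                "EX_syr": (0, None), "EX_phb": (0, None)}).objective_value

        assert mu(2.0) == pytest.approx(2 * mu(1.0), rel=1e-9)

    def test_internal_metabolites_conserved_at_optimum(self, toy_model):
        sol = solve_fba(toy_model, extra_bounds={"EX_van": (-1.0, None)})
        S, met_ids, rxn_ids = toy_model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in rxn_ids])
        assert np.max(np.abs(S @ v)) < 1e-9


class TestYield:
    def test_chain_yield_in_mg_per_mmol(self, chain_model):
        res = biomass_yield(chain_model, "EX_A", amount=1.0)
        assert res.yield_mgdw_per_mmol == pytest.approx(500.0, abs=1e-6)

    def test_yield_zero_iff_no_growth(self, chain_model):
        chain_model.reactions["GROWTH"].upper_bound = 0.0
        res = biomass_yield(chain_model, "EX_A")
        assert res.yield_mgdw_per_mmol == 0.0

    def test_carbon_bookkeeping_doubles_with_richer_substrate(self):
        # substrate with 4 C vs biomass needing exactly 2 C per unit:
        # one mmol feeds two units of growth
        m = MetabolicModel()
        m.add_metabolite(Metabolite(id="s_e", compartment="e", formula="C4H8O4"))
        m.add_metabolite(Metabolite(id="c2_c", compartment="c", formula="C2H4O2"))
        m.add_reaction(Reaction(id="EX_s", stoichiometry={"s_e": -1.0},
                                lower_bound=-10.0, kind="exchange"))
        m.add_reaction(Reaction(id="SPLIT", stoichiometry={"s_e": -1.0, "c2_c": 2.0},
                                lower_bound=0.0))
        m.add_reaction(Reaction(id="GROW", stoichiometry={"c2_c": -1.0},
                                lower_bound=0.0, kind="biomass"))
        m.objective = "GROW"
        res = biomass_yield(m, "EX_s", amount=1.0)
        assert res.yield_mgdw_per_mmol == pytest.approx(2000.0)

    def test_maintenance_toggle_lowers_yield(self, toy_model_variant):
        from aromflux.synthetic import ToySpec, make_toy_model

        m = make_toy_model(ToySpec(substrates=("vanillic",), ngam=1.0))
        with_m = biomass_yield(m, "EX_van", maintenance=True)
        without = biomass_yield(m, "EX_van", maintenance=False)
        assert without.yield_mgdw_per_mmol > with_m.yield_mgdw_per_mmol
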