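"""Steady-state flux balance analysis on :class:`~aromflux.model.MetabolicModel`.

The LP is ``max c.v  s.t.  S.v = 0,  lb <= v <= ub`` with one extra
zero-right-hand-side row per flux-ratio constraint (``v_a - r*v_b = 0``).
Solving uses scipy's HiGHS interface. In place of exact rational
arithmetic we apply a numerical contract: fluxes with magnitude below
``ZERO_TOL`` are snapped to zero and constraint residuals are verified
after every optimal solve.

Sign convention: exchange flux < 0 is uptake; reported yields use
positive magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

ZERO_TOL = 1e-9


class FbaError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"reaction_id": list(self.fluxes), "flux": list(self.fluxes.values())}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _effective_bounds(model, extra_bounds=None, pinned_fluxes=None):
    bounds = {}
    for rid, rxn in model.reactions.items():
        bounds[rid] = (rxn.lower_bound, rxn.upper_bound)
    if extra_bounds:
        for rid, bd in extra_bounds.items():
            if rid not in bounds:
                raise KeyError(f"unknown reaction {rid} in extra_bounds")
            lo, hi = bounds[rid]
            nlo, nhi = bd
            # extra bounds tighten, never relax, the structural bounds
            bounds[rid] = (max(lo, nlo) if nlo is not None else lo,
                           min(hi, nhi) if nhi is not None else hi)
    if pinned_fluxes:
        for rid, v in pinned_fluxes.items():
            if rid not in bounds:
                raise KeyError(f"unknown reaction {rid} in pinned_fluxes")
            lo, hi = model.reactions[rid].lower_bound, model.reactions[rid].upper_bound
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(
                    f"pinned flux {v} for {rid} outside structural bounds [{lo}, {hi}]"
                )
            bounds[rid] = (v, v)
    return bounds


def _build_lp(model, bounds):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    rows = [S]
    for rc in model.ratio_constraints:
        row = np.zeros((1, len(rxn_ids)))
        row[0, rxn_ids.index(rc.reaction_a)] = 1.0
        row[0, rxn_ids.index(rc.reaction_b)] = -rc.ratio
        rows.append(row)
    A_eq = np.vstack(rows)
    b_eq = np.zeros(A_eq.shape[0])
    lp_bounds = [bounds[rid] for rid in rxn_ids]
    return A_eq, b_eq, lp_bounds, rxn_ids


def solve_fba(
    model: MetabolicModel,
    extra_bounds: dict | None = None,
    pinned_fluxes: dict | None = None,
    objective: str | None = None,
    direction: str | None = None,
    secondary_objective: dict | None = None,
    parsimonious: bool = False,
) -> FluxSolution:
    """Maximize (or minimize) the objective reaction's flux.

    Parameters
    ----------
    extra_bounds
        ``{reaction_id: (lb, ub)}`` tightened onto the structural bounds for
        this solve only (None entries leave that side unchanged).
    pinned_fluxes
        ``{reaction_id: v}`` equality pins; must lie within structural bounds.
    secondary_objective
        ``{reaction_id: weight}``; after the primary optimum is found the
        primary objective is fixed and this linear function is maximized
        (lexicographic two-stage solve). Used e.g. to prefer maximal
        substrate turnover among biomass-equivalent optima.
    parsimonious
        After the optimum, re-solve minimizing total absolute flux at the
        fixed objective value and report that flux vector.
    """
    obj_id = objective or model.objective
    if obj_id is None:
        raise FbaError("model has no objective reaction")
    if obj_id not in model.reactions:
        raise KeyError(f"unknown objective reaction {obj_id}")
    sense = direction or model.objective_direction

    bounds = _effective_bounds(model, extra_bounds, pinned_fluxes)
    A_eq, b_eq, lp_bounds, rxn_ids = _build_lp(model, bounds)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(obj_id)] = -1.0 if sense == "max" else 1.0

    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=lp_bounds, method="highs")
    if res.status == 2:
        return FluxSolution("infeasible", None, {}, res.message)
    if res.status == 3:
        return FluxSolution("unbounded", None, {}, res.message)
    if res.status != 0:
        raise FbaError(f"LP solver failure: {res.message}")

    v = res.x
    obj_val = v[rxn_ids.index(obj_id)]

    if secondary_objective or parsimonious:
        fix = dict(bounds)
        fix[obj_id] = (obj_val - 1e-10, obj_val + 1e-10)
        A2, b2, lp2, _ = _build_lp(model, fix)
        if secondary_objective:
            c2 = np.zeros(n)
            for rid, w in secondary_objective.items():
                c2[rxn_ids.index(rid)] = -w
            res2 = linprog(c2, A_eq=A2, b_eq=b2, bounds=lp2, method="highs")
            if res2.status == 0:
                v = res2.x
        if parsimonious:
            # split v = p - q, p,q >= 0; min sum(p+q)
            A3 = np.hstack([A2, -A2])
            lb3 = []
            for lo, hi in lp2:
                lb3.append((max(lo, 0.0), max(hi, 0.0)))
            ub3 = []
            for lo, hi in lp2:
                ub3.append((max(-hi, 0.0), max(-lo, 0.0)))
            res3 = linprog(np.ones(2 * n), A_eq=A3, b_eq=b2,
                           bounds=lb3 + ub3, method="highs")
            if res3.status == 0:
                v = res3.x[:n] - res3.x[n:]

    v = np.where(np.abs(v) < ZERO_TOL, 0.0, v)
    residual = np.abs(A_eq @ v)
    if residual.size and residual.max() > 1e-6:
        raise FbaError(f"constraint residual {residual.max():.3e} after solve")
    fluxes = {rid: float(v[i]) for i, rid in enumerate(rxn_ids)}
    return FluxSolution("optimal", float(fluxes[obj_id]), fluxes, res.message)


@dataclass
class YieldResult:
    substrate: str
    yield_mgdw_per_mmol: float
    solution: FluxSolution


def carbon_exchanges(model: MetabolicModel) -> list[str]:
    """Exchange reactions whose metabolite contains carbon (CO2 excluded)."""
    out = []
    for rxn in model.exchanges():
        (mid,) = rxn.stoichiometry
        met = model.metabolites[mid]
        if met.formula and "C" in met.elements and met.formula != "CO2":
            out.append(rxn.id)
    return out


def biomass_yield(
    model: MetabolicModel,
    substrate_exchange: str,
    amount: float = 1.0,
    maintenance: bool = True,
) -> YieldResult:
    """Biomass yield in mgDW per mmol substrate at a fixed uptake.

    All other organic-carbon exchanges are closed to uptake, the named
    exchange is fixed at ``amount`` mmol/gDW/h of uptake, and the biomass
    objective is maximized; yield = 1000 * mu / amount. With
    ``maintenance=False`` any maintenance reaction's lower bound is lifted
    for this solve.
    """
    if substrate_exchange not in model.reactions:
        raise KeyError(f"unknown exchange {substrate_exchange}")
    if not maintenance:
        model = model.copy()
        for rxn in model.reactions.values():
            if rxn.kind == "maintenance" and rxn.lower_bound > 0:
                rxn.lower_bound = 0.0
    extra: dict = {}
    for rid in carbon_exchanges(model):
        if rid != substrate_exchange:
            extra[rid] = (0.0, None)  # no uptake; secretion stays allowed
    pins = {substrate_exchange: -abs(amount)}
    sol = solve_fba(model, extra_bounds=extra or None, pinned_fluxes=pins)
    if not sol.optimal or sol.objective_value is None:
        return YieldResult(substrate_exchange, 0.0, sol)
    y = 1000.0 * max(sol.objective_value, 0.0) / abs(amount)
    return YieldResult(substrate_exchange, y, sol)
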