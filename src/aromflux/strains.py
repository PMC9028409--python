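"""In-silico strain construction and product-yield optimization.

Strain edits are small, serializable records (gene knockout, reaction
delete/add, demethylase swap, ratio-constraint removal, product
coupling) applied in order to a model copy, so an engineered strain is
reproducible from the wild-type model plus its edit list.

Product accumulation follows the overexpression-strain scheme: the
product exchange flux is tied to a fixed fraction of substrate uptake
(mol product per mol substrate) through a flux-ratio constraint, which
diverts carbon from growth without making the product compete in the
objective. For strains whose aromatic catabolism is fully blocked (the
PDC-accumulating strain), aromatic exchange fluxes are pinned each dFBA
cycle to the fluxes of a wild-type reference solve, simulating forced
funneling despite zero growth benefit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .dfba import BatchState, BatchTrajectory, run_dfba
from .fba import solve_fba
from .kinetics import ParamTable
from .model import MetabolicModel, Metabolite, Reaction, parse_formula
from .synthetic import (
    DEMETHYLASE_TEMPLATES,
    DEMETHYLATION_SLOTS,
    demethylation_stoichiometry,
)


class StrainEditError(ValueError):
    pass


# -- gene association evaluation ----------------------------------------------

_GPR_TOKEN = re.compile(r"[A-Za-z0-9_.\-]+|\(|\)")


def evaluate_gpr(expression: str, knocked_out: set[str]) -> bool:
    """Evaluate a boolean gene-association string under a knockout set.

    Genes not in ``knocked_out`` are present (True); the reaction is
    active iff the expression evaluates True.
    """
    pieces = []
    for tok in _GPR_TOKEN.findall(expression):
        if tok in ("(", ")"):
            pieces.append(tok)
        elif tok.lower() in ("and", "or", "not"):
            pieces.append(tok.lower())
        else:
            pieces.append("False" if tok in knocked_out else "True")
    src = " ".join(pieces)
    if not re.fullmatch(r"[ TrueFalsandort()]+", src):  # defense in depth
        raise StrainEditError(f"cannot parse gene association {expression!r}")
    return bool(eval(src, {"__builtins__": {}}))  # noqa: S307 - sanitized above


# -- strain edits -------------------------------------------------------------

EDIT_KINDS = ("gene_knockout", "reaction_delete", "reaction_add",
              "demethylase_swap", "ratio_constraint_remove", "product_coupling")


@dataclass
class StrainEdit:
    kind: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EDIT_KINDS:
            raise StrainEditError(f"unknown edit kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "payload": self.payload}

    @classmethod
    def from_dict(cls, d: dict) -> "StrainEdit":
        return cls(kind=d["kind"], payload=dict(d.get("payload", {})))


def save_edits(edits, path) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in edits], fh, indent=1)
        fh.write("\n")


def load_edits(path) -> list[StrainEdit]:
    with open(path) as fh:
        return [StrainEdit.from_dict(d) for d in json.load(fh)]


def apply_knockout(model: MetabolicModel, ids) -> MetabolicModel:
    """Knock out genes and/or reactions; returns an edited copy.

    Gene ids are resolved through each reaction's gene association: a
    reaction whose expression turns false gets bounds (0, 0). Reaction
    ids are disabled directly.
    """
    if isinstance(ids, str):
        ids = [ids]
    out = model.copy()
    genes = out.genes
    gene_ids = {i for i in ids if i in genes}
    rxn_ids = {i for i in ids if i in out.reactions}
    unknown = set(ids) - gene_ids - rxn_ids
    if unknown:
        raise KeyError(f"unknown gene/reaction id(s) {sorted(unknown)}")
    for rid in rxn_ids:
        out.reactions[rid].lower_bound = 0.0
        out.reactions[rid].upper_bound = 0.0
    if gene_ids:
        for rxn in out.reactions.values():
            if rxn.gene_association and not evaluate_gpr(rxn.gene_association, gene_ids):
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
    return out


def swap_demethylase(model: MetabolicModel, variant: str) -> MetabolicModel:
    """Replace every demethylation slot with the given variant's chemistry.

    Slots are the reactions named in :data:`DEMETHYLATION_SLOTS`; the
    THF-carrier recycle reaction is added or removed alongside, so the
    result is structurally identical to generating the model with that
    variant from the start.
    """
    if variant not in DEMETHYLASE_TEMPLATES:
        raise StrainEditError(f"unknown demethylase variant {variant!r}")
    slots = [s for s in DEMETHYLATION_SLOTS if s in model.reactions]
    if not slots:
        raise StrainEditError("model has no demethylation reaction slots")
    out = model.copy()
    for slot in slots:
        rxn = out.reactions[slot]
        rxn.stoichiometry = demethylation_stoichiometry(slot, variant)
        rxn.gene_association = DEMETHYLASE_TEMPLATES[variant]["gpr"]
        rxn.name = f"{slot.split('_')[1]} O-demethylation ({variant})"
    if variant == "native_THF":
        if "MTHF_recycle" not in out.reactions:
            out.add_reaction(Reaction(
                id="MTHF_recycle", name="methyl-THF oxidation to CO2",
                stoichiometry={"mthf_c": -1.0, "h2o_c": -2.0, "nad_c": -3.0,
                               "thf_c": 1.0, "co2_c": 1.0, "nadh_c": 3.0,
                               "h_c": 3.0},
                lower_bound=0.0, upper_bound=1000.0,
                gene_association="folD and fdh"))
    elif "MTHF_recycle" in out.reactions:
        out.remove_reaction("MTHF_recycle")
    return out


def pin_wildtype_fluxes(
    wild_model: MetabolicModel,
    mutant_model: MetabolicModel,
    exchange_ids,
    extra_bounds: dict | None = None,
) -> tuple[MetabolicModel, dict]:
    """Fix named exchange fluxes of the mutant to the wild-type solution.

    Solves the wild model (optionally under ``extra_bounds``), records the
    listed exchange fluxes, and returns a mutant copy whose bounds pin
    them, plus the pin map. Raises with the binding pin named if a pin
    makes the mutant infeasible.
    """
    for rid in exchange_ids:
        if rid not in wild_model.reactions or rid not in mutant_model.reactions:
            raise KeyError(f"exchange {rid} not shared by both models")
    wild = solve_fba(wild_model, extra_bounds=extra_bounds)
    if not wild.optimal:
        raise StrainEditError(f"wild-type solve not optimal: {wild.status}")
    pins = {rid: wild.fluxes.get(rid, 0.0) for rid in exchange_ids}
    out = mutant_model.copy()
    for rid, v in pins.items():
        out.reactions[rid].lower_bound = v
        out.reactions[rid].upper_bound = v
    check = solve_fba(out, extra_bounds=extra_bounds)
    if not check.optimal:
        for rid, v in pins.items():
            probe = out.copy()
            probe.reactions[rid].lower_bound = -1000.0
            probe.reactions[rid].upper_bound = 1000.0
            if solve_fba(probe, extra_bounds=extra_bounds).optimal:
                raise StrainEditError(
                    f"pinning {rid} to {v:.4g} makes the mutant infeasible")
        raise StrainEditError("pinned mutant infeasible (joint pins)")
    return out, pins


def add_product_pathway(
    model: MetabolicModel,
    reactions=(),
    substrate_exchange: str = "",
    coupling_fraction: float = 0.0,
    product_exchange: str | None = None,
    metabolites=(),
) -> MetabolicModel:
    """Install a product pathway and couple secretion to substrate uptake.

    ``coupling_fraction`` is mol product per mol substrate; the coupling
    is the ratio constraint ``v_product_exchange = fraction * |uptake|``.
    Added reactions are element-checked where formulas are available.
    """
    if coupling_fraction < 0:
        raise StrainEditError("coupling fraction must be >= 0")
    out = model.copy()
    for met in metabolites:
        if met.id not in out.metabolites:
            out.add_metabolite(met)
    added = []
    for rxn in reactions:
        out.add_reaction(rxn)
        added.append(rxn.id)
    if product_exchange is None:
        cands = [r for r in added if out.reactions[r].kind == "exchange"]
        if len(cands) != 1:
            raise StrainEditError("product_exchange not given and not inferable")
        product_exchange = cands[0]
    for rid in (substrate_exchange, product_exchange):
        if rid not in out.reactions:
            raise KeyError(f"unknown reaction {rid}")
    from .model import check_mass_balance

    violations, _ = check_mass_balance(out)
    bad = [v for v in violations if v.reaction_id in added]
    if bad:
        raise StrainEditError(
            f"added reactions not mass balanced: "
            f"{[(v.reaction_id, v.element, v.imbalance) for v in bad]}")
    if coupling_fraction > 0:
        # uptake flux is negative: v_prod - (-f) * v_sub = 0
        out.add_ratio_constraint(product_exchange, substrate_exchange,
                                 -coupling_fraction, id="product_coupling")
    return out


def apply_edits(model: MetabolicModel, edits) -> MetabolicModel:
    """Replay a strain-edit list (order-sensitive) on a model copy."""
    out = model.copy()
    for edit in edits:
        p = edit.payload
        if edit.kind == "gene_knockout":
            out = apply_knockout(out, p["ids"])
        elif edit.kind == "reaction_delete":
            out.remove_reaction(p["reaction_id"])
        elif edit.kind == "reaction_add":
            for m in p.get("metabolites", []):
                if m["id"] not in out.metabolites:
                    out.add_metabolite(Metabolite(**m))
            r = p["reaction"]
            out.add_reaction(Reaction(
                id=r["id"], name=r.get("name", ""),
                stoichiometry=r["stoichiometry"],
                lower_bound=r.get("lower_bound", 0.0),
                upper_bound=r.get("upper_bound", 1000.0),
                kind=r.get("kind", "transformation"),
                gene_association=r.get("gene_association")))
        elif edit.kind == "demethylase_swap":
            out = swap_demethylase(out, p["variant"])
        elif edit.kind == "ratio_constraint_remove":
            out.remove_ratio_constraint(p["constraint_id"])
        elif edit.kind == "product_coupling":
            out = add_product_pathway(
                out, substrate_exchange=p["substrate_exchange"],
                coupling_fraction=p["coupling_fraction"],
                product_exchange=p["product_exchange"])
    return out


# -- the PDC-accumulating strain ----------------------------------------------

def pdc_strain_edits(model: MetabolicModel) -> list[StrainEdit]:
    """Edit list turning the wild-type toy into the PDC-accumulating strain.

    Deletes the PDC hydrolase and the CHMOD->gallate escape (the pathway
    removed by gene deletion in the engineered strain) and lifts the 15%
    side-branch ratio constraint, which only applies to the wild type.
    """
    edits = [StrainEdit("gene_knockout", {"ids": ["ligI"]})]
    if any(rc.id == "chmod_side_ratio" for rc in model.ratio_constraints):
        edits.append(StrainEdit("ratio_constraint_remove",
                                {"constraint_id": "chmod_side_ratio"}))
    if "CHMOD_GAL" in model.reactions:
        edits.append(StrainEdit("gene_knockout", {"ids": ["desCD"]}))
    if "DEMETH_mga" in model.reactions:
        # the gallate demethylation escape is part of the deleted pathway
        edits.append(StrainEdit("reaction_delete", {"reaction_id": "DEMETH_mga"}))
    return edits


def make_pdc_strain(model: MetabolicModel) -> MetabolicModel:
    return apply_edits(model, pdc_strain_edits(model))


# -- shipped product recipes (three or fewer added reactions each) ------------

def product_recipes() -> dict:
    """Toy product pathways: metabolites, reactions, product exchange.

    Each recipe adds at most three reactions (synthesis, export,
    exchange) to the funneling model, mirroring how candidate products
    reachable within a few enzymatic steps are screened.
    """
    def export(key, formula, name, synth):
        mets = [Metabolite(id=f"{key}_c", name=name, compartment="c", formula=formula),
                Metabolite(id=f"{key}_e", name=name, compartment="e", formula=formula)]
        rxns = synth + [
            Reaction(id=f"T_{key}", name=f"{name} export",
                     stoichiometry={f"{key}_c": -1.0, f"{key}_e": 1.0},
                     lower_bound=0.0, kind="transport"),
            Reaction(id=f"EX_{key}", name=f"{name} exchange",
                     stoichiometry={f"{key}_e": -1.0}, lower_bound=0.0,
                     kind="exchange"),
        ]
        return {"metabolites": mets, "reactions": rxns, "exchange": f"EX_{key}"}

    recipes = {
        # PDC: already an intermediate of the funnel; only needs export,
        # which the toy model carries natively.
        "pdc": {"metabolites": [], "reactions": [], "exchange": "EX_pdc"},
        "ccma": {
            "metabolites": [
                Metabolite(id="cat_c", name="catechol", compartment="c", formula="C6H6O2"),
                Metabolite(id="ccma_c", name="cis,cis-muconic acid", compartment="c", formula="C6H6O4"),
                Metabolite(id="ccma_e", name="cis,cis-muconic acid", compartment="e", formula="C6H6O4"),
            ],
            "reactions": [
                Reaction(id="PCA_DC", name="protocatechuate decarboxylase",
                         stoichiometry={"pca_c": -1.0, "cat_c": 1.0, "co2_c": 1.0},
                         lower_bound=0.0, gene_association="aroY"),
                Reaction(id="CAT_DIOX_P", name="catechol 1,2-dioxygenase",
                         stoichiometry={"cat_c": -1.0, "o2_c": -1.0, "ccma_c": 1.0},
                         lower_bound=0.0, gene_association="catA"),
                Reaction(id="EX_ccma_path", name="ccMA export + exchange (lumped)",
                         stoichiometry={"ccma_c": -1.0, "ccma_e": 1.0},
                         lower_bound=0.0, kind="transport"),
                Reaction(id="EX_ccma", name="cis,cis-muconic acid exchange",
                         stoichiometry={"ccma_e": -1.0}, lower_bound=0.0,
                         kind="exchange"),
            ],
            "exchange": "EX_ccma",
        },
        "acetate": export(
            "ac", "C2H4O2", "acetate",
            [Reaction(id="ACK", name="acetate kinase (net)",
                      stoichiometry={"accoa_c": -1.0, "adp_c": -1.0, "pi_c": -1.0,
                                     "h_c": -1.0, "ac_c": 1.0, "coa_c": 1.0,
                                     "atp_c": 1.0},
                      lower_bound=0.0, gene_association="ackA and pta")]),
        "glycerol": export(
            "glyc", "C3H8O3", "glycerol",
            [Reaction(id="GLYC_SYNTH", name="glycerol synthesis from pyruvate (lumped)",
                      stoichiometry={"pyr_c": -1.0, "nadh_c": -2.0, "h_c": -2.0,
                                     "glyc_c": 1.0, "nad_c": 2.0},
                      lower_bound=0.0, gene_association="gpd and gpp")]),
    }
    return recipes


def install_product(model: MetabolicModel, product: str,
                    substrate_exchange: str,
                    coupling_fraction: float) -> tuple[MetabolicModel, str]:
    """Install a shipped recipe and return (model, product exchange id)."""
    recipes = product_recipes()
    if product not in recipes:
        raise KeyError(f"no shipped recipe for {product!r}; "
                       f"available: {sorted(recipes)}")
    rec = recipes[product]
    out = add_product_pathway(
        model,
        reactions=[r for r in rec["reactions"] if r.id not in model.reactions],
        metabolites=rec["metabolites"],
        substrate_exchange=substrate_exchange,
        coupling_fraction=coupling_fraction,
        product_exchange=rec["exchange"])
    return out, rec["exchange"]


# -- sweeps -------------------------------------------------------------------

def product_molar_mass(model: MetabolicModel, product_exchange: str) -> float:
    from .model import formula_mass

    (mid,) = model.reactions[product_exchange].stoichiometry
    formula = model.metabolites[mid].formula
    if not formula:
        raise StrainEditError(f"product of {product_exchange} has no formula")
    return formula_mass(formula)


def production_rate(model: MetabolicModel, traj: BatchTrajectory,
                    product_exchange: str,
                    exhaustion_threshold: float = 0.01) -> tuple[float, float]:
    """(rate g/L/h, titer g/L): cumulative titer over time-to-exhaustion.

    Time-to-exhaustion is the first time all substrates fall below the
    threshold; if they never do, the trajectory's end time is used.
    """
    mw = product_molar_mass(model, product_exchange)
    titer = traj.final.product_conc.get(product_exchange, 0.0) * mw / 1000.0
    t_exh = None
    for st in traj.states:
        if all(v < exhaustion_threshold for v in st.substrate_conc.values()):
            t_exh = st.time
            break
    horizon = t_exh if t_exh else traj.final.time
    return (titer / horizon if horizon > 0 else 0.0), titer


@dataclass
class SweepResult:
    grid: list[tuple]  # (coupling_fraction, rate g/L/h, titer g/L)
    best: tuple

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.grid,
                            columns=["coupling_fraction", "rate_g_L_h", "titer_g_L"])


def yield_sweep(
    model: MetabolicModel,
    product: str,
    substrate_exchange: str,
    substrate_conc: float = 5.0,
    grid_step: float = 0.01,
    f_max: float = 1.0,
    params_table: ParamTable | None = None,
    media_caps: dict | None = None,
    substrate_classes: dict | None = None,
    initial_biomass: float = 0.05,
    dt: float = 0.5,
    t_end: float = 200.0,
) -> SweepResult:
    """Scan product-coupling fractions and report the rate-maximizing one.

    For each fraction on the grid the recipe is installed with that
    coupling, a batch dFBA is run from ``substrate_conc`` mmol/L of the
    single substrate, and the production rate (titer over
    time-to-exhaustion) is recorded. Infeasible fractions score 0.
    """
    if not 0 < grid_step <= 0.1:
        raise ValueError("grid_step must be in (0, 0.1]")
    if params_table is None:
        from .synthetic import make_kinetics_table

        params_table = make_kinetics_table()
    import numpy as np

    fractions = np.round(np.arange(0.0, f_max + grid_step / 2, grid_step), 10)
    grid = []
    for f in fractions:
        strain, pex = install_product(model, product, substrate_exchange, float(f))
        init = BatchState(0.0, initial_biomass, {substrate_exchange: substrate_conc})
        traj = run_dfba(
            strain, init, params_table, dt=dt, t_end=t_end,
            media_caps=media_caps, products=(pex,),
            substrate_classes=substrate_classes,
            solve_kwargs={"secondary_objective": {pex: 1.0}})
        if traj.termination == "infeasible" and len(traj.steps) <= 1:
            grid.append((float(f), 0.0, 0.0))
            continue
        rate, titer = production_rate(strain, traj, pex)
        grid.append((float(f), rate, titer))
    best = max(grid, key=lambda g: (g[1], -g[0]))
    return SweepResult(grid, best)


def aromatic_glucose_ratio_sweep(
    wild_model: MetabolicModel,
    aromatic_exchange: str,
    ratios=((9, 1), (3, 1), (3, 2), (1, 1), (2, 3), (1, 3), (1, 9)),
    total_conc: float = 5.0,
    params_table: ParamTable | None = None,
    media_caps: dict | None = None,
    substrate_classes: dict | None = None,
    initial_biomass: float = 0.0125,
    dt: float = 0.25,
    t_end: float = 300.0,
):
    """PDC production rate across aromatic:glucose molar ratios.

    Builds the PDC-accumulating strain, splits ``total_conc`` mmol/L
    between the aromatic and glucose at each molar ratio, and runs dFBA
    with the aromatic exchange pinned each cycle to the wild-type flux.
    Returns a list of (ratio_string, aromatic_fraction, rate, titer).
    """
    if params_table is None:
        from .synthetic import make_kinetics_table

        params_table = make_kinetics_table()
    strain = make_pdc_strain(wild_model)
    results = []
    for a, g in ratios:
        fa = a / (a + g)
        conc = {aromatic_exchange: total_conc * fa,
                "EX_glc": total_conc * (1 - fa)}
        init = BatchState(0.0, initial_biomass, dict(conc))
        traj = run_dfba(
            strain, init, params_table, dt=dt, t_end=t_end,
            media_caps=media_caps, products=("EX_pdc",),
            substrate_classes=substrate_classes,
            pin_reference=wild_model, pin_exchanges=(aromatic_exchange,))
        rate, titer = production_rate(strain, traj, "EX_pdc")
        results.append((f"{a}:{g}", fa, rate, titer))
    return results
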