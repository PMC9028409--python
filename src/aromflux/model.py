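"""Constraint-based model data structures and I/O.

A :class:`MetabolicModel` is the in-memory form of a stoichiometric
reconstruction: metabolites with compartments and (optionally) elemental
formulas, reactions with signed stoichiometry, flux bounds, gene
associations and a kind tag, a single linear objective, and a list of
flux-ratio constraints (``v_a - ratio * v_b = 0``) that standard SBML-FBC
has no slot for.

Two serialisations are supported: a native JSON document that round-trips
every field including ratio constraints (schema in ``docs/native_model_schema.md``),
and SBML Level 3 + FBC via cobrapy, which drops ratio constraints with a
warning on export.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

COMPARTMENTS = ("c", "p", "e")  # cytoplasm, periplasm, extracellular
REACTION_KINDS = (
    "transformation",
    "transport",
    "exchange",
    "demand",
    "biomass",
    "maintenance",
)

# Monoisotopic-free average atomic masses (g/mol), enough for the formulas
# that appear in small-molecule metabolism.
ATOMIC_MASS = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Fe": 55.845, "Mg": 24.305, "K": 39.098, "Na": 22.990,
    "Ca": 40.078, "Cl": 35.45, "Zn": 65.38, "Mn": 54.938, "Cu": 63.546,
    "Co": 58.933, "Mo": 95.95, "Se": 78.971,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    """Structural invariant of a model or one of its parts is violated."""


class ModelParseError(ValueError):
    """A model file could not be parsed in the declared dialect."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula like ``C6H12O6`` into counts."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ModelParseError(f"malformed formula: {formula!r}")
    counts: dict[str, int] = {}
    for element, num in _FORMULA_TOKEN.findall(formula):
        if not element:
            continue
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    return counts


def formula_mass(formula: str) -> float:
    """Molar mass in g/mol of a neutral formula."""
    counts = parse_formula(formula)
    unknown = set(counts) - set(ATOMIC_MASS)
    if unknown:
        raise ModelParseError(f"no atomic mass for element(s) {sorted(unknown)}")
    return sum(ATOMIC_MASS[el] * n for el, n in counts.items())


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    @property
    def elements(self) -> dict[str, int] | None:
        return parse_formula(self.formula) if self.formula else None

    @property
    def molar_mass(self) -> float | None:
        """g/mol from the formula, or None when no formula is set."""
        return formula_mass(self.formula) if self.formula else None

    def validate(self, compartments=COMPARTMENTS) -> None:
        if not self.id:
            raise ModelValidationError("metabolite with empty id")
        if self.compartment not in compartments:
            raise ModelValidationError(
                f"metabolite {self.id}: compartment {self.compartment!r} "
                f"not in {compartments}"
            )
        if self.formula is not None and not self.molar_mass > 0:
            raise ModelValidationError(f"metabolite {self.id}: non-positive molar mass")


# COBRA-convention sentinel for "unbounded"
DEFAULT_BOUND = 1000.0


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_association: str | None = None
    kind: str = "transformation"

    def validate(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction with empty id")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id}: unknown kind {self.kind!r}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> set[str]:
        """Gene ids referenced by the boolean gene association."""
        if not self.gene_association:
            return set()
        tokens = re.findall(r"[^\s()]+", self.gene_association)
        return {t for t in tokens if t.lower() not in ("and", "or")}


@dataclass
class RatioConstraint:
    """v_a - ratio * v_b = 0, appended to every steady-state solve."""

    reaction_a: str
    reaction_b: str
    ratio: float
    id: str | None = None

    def __post_init__(self):
        if self.id is None:
            self.id = f"ratio_{self.reaction_a}_{self.reaction_b}"


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective: str | None = None
    objective_direction: str = "max"
    ratio_constraints: list[RatioConstraint] = field(default_factory=list)
    compartments: tuple = COMPARTMENTS

    # -- construction helpers -------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id}")
        met.validate(self.compartments)
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id}")
        rxn.validate()
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id} references unknown metabolite {mid}"
                )
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, rxn_id: str) -> None:
        if rxn_id not in self.reactions:
            raise KeyError(f"unknown reaction {rxn_id}")
        del self.reactions[rxn_id]
        self.ratio_constraints = [
            rc for rc in self.ratio_constraints
            if rc.reaction_a != rxn_id and rc.reaction_b != rxn_id
        ]

    def add_ratio_constraint(self, reaction_a: str, reaction_b: str,
                             ratio: float, id: str | None = None) -> RatioConstraint:
        for rid in (reaction_a, reaction_b):
            if rid not in self.reactions:
                raise KeyError(f"unknown reaction {rid}")
        rc = RatioConstraint(reaction_a, reaction_b, float(ratio), id)
        self.ratio_constraints.append(rc)
        return rc

    def remove_ratio_constraint(self, constraint_id: str) -> None:
        before = len(self.ratio_constraints)
        self.ratio_constraints = [
            rc for rc in self.ratio_constraints if rc.id != constraint_id
        ]
        if len(self.ratio_constraints) == before:
            raise KeyError(f"unknown ratio constraint {constraint_id}")

    # -- views ---------------------------------------------------------------

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes()
        return out

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def stoichiometric_matrix(self):
        """Dense S matrix plus row (metabolite) and column (reaction) orders."""
        import numpy as np

        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coeff in self.reactions[rid].stoichiometry.items():
                S[met_index[mid], j] = coeff
        return S, met_ids, rxn_ids

    def validate(self) -> None:
        """Check all structural invariants; raise ModelValidationError on failure."""
        for met in self.metabolites.values():
            met.validate(self.compartments)
        for rxn in self.reactions.values():
            rxn.validate()
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {mid}"
                    )
            if rxn.kind == "exchange":
                if len(rxn.stoichiometry) != 1:
                    raise ModelValidationError(
                        f"exchange {rxn.id} must touch exactly one metabolite"
                    )
                (mid,) = rxn.stoichiometry
                if self.metabolites[mid].compartment != "e":
                    raise ModelValidationError(
                        f"exchange {rxn.id} metabolite {mid} is not extracellular"
                    )
        if self.objective is not None and self.objective not in self.reactions:
            raise ModelValidationError(f"objective reaction {self.objective} missing")
        for rc in self.ratio_constraints:
            for rid in (rc.reaction_a, rc.reaction_b):
                if rid not in self.reactions:
                    raise ModelValidationError(
                        f"ratio constraint {rc.id} references unknown reaction {rid}"
                    )

    def copy(self) -> "MetabolicModel":
        import copy as _copy

        return _copy.deepcopy(self)


# -- mass balance -------------------------------------------------------------

@dataclass
class MassBalanceViolation:
    reaction_id: str
    element: str
    imbalance: float  # net atoms produced minus consumed


def check_mass_balance(model: MetabolicModel, tol: float = 1e-6):
    """Element-by-element balance check for internal reactions.

    Boundary pseudo-reactions (exchange/demand), the biomass sink and
    maintenance are skipped by construction; reactions with any
    formula-less participant are skipped and counted.

    Returns ``(violations, n_skipped_missing_formula)``.
    """
    violations: list[MassBalanceViolation] = []
    skipped = 0
    for rxn in model.reactions.values():
        if rxn.kind in ("exchange", "demand", "biomass", "maintenance"):
            continue
        parts = [(model.metabolites[mid], coeff) for mid, coeff in rxn.stoichiometry.items()]
        if any(met.formula is None for met, _ in parts):
            skipped += 1
            continue
        totals: dict[str, float] = {}
        for met, coeff in parts:
            for el, n in met.elements.items():
                totals[el] = totals.get(el, 0.0) + coeff * n
        for el, net in sorted(totals.items()):
            if abs(net) > tol:
                violations.append(MassBalanceViolation(rxn.id, el, net))
    return violations, skipped


def write_mass_balance_report(violations, path) -> None:
    """TSV report: reaction_id, element, imbalance."""
    import pandas as pd

    pd.DataFrame(
        [(v.reaction_id, v.element, v.imbalance) for v in violations],
        columns=["reaction_id", "element", "imbalance"],
    ).to_csv(path, sep="\t", index=False)


# -- native JSON format -------------------------------------------------------

_NATIVE_VERSION = 1


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "format": "aromflux-model",
        "version": _NATIVE_VERSION,
        "id": model.id,
        "compartments": list(model.compartments),
        "metabolites": [
            {k: v for k, v in {
                "id": m.id, "name": m.name, "compartment": m.compartment,
                "formula": m.formula, "charge": m.charge,
            }.items() if v is not None}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {k: v for k, v in {
                "id": r.id, "name": r.name, "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                "gene_association": r.gene_association, "kind": r.kind,
            }.items() if v is not None}
            for r in model.reactions.values()
        ],
        "objective": model.objective,
        "objective_direction": model.objective_direction,
        "ratio_constraints": [
            {"id": rc.id, "reaction_a": rc.reaction_a,
             "reaction_b": rc.reaction_b, "ratio": rc.ratio}
            for rc in model.ratio_constraints
        ],
    }


def _model_from_dict(doc: dict) -> MetabolicModel:
    if doc.get("format") != "aromflux-model":
        raise ModelParseError("not an aromflux native model document")
    known = {"format", "version", "id", "compartments", "metabolites",
             "reactions", "objective", "objective_direction", "ratio_constraints"}
    for key in set(doc) - known:
        log.warning("ignoring unknown model annotation %r", key)
    model = MetabolicModel(
        id=doc.get("id", "model"),
        compartments=tuple(doc.get("compartments", COMPARTMENTS)),
    )
    for m in doc.get("metabolites", []):
        try:
            model.add_metabolite(Metabolite(
                id=m["id"], name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"), charge=m.get("charge"),
            ))
        except KeyError as exc:
            raise ModelParseError(f"metabolite entry missing field {exc}: {m}") from exc
    for r in doc.get("reactions", []):
        try:
            model.add_reaction(Reaction(
                id=r["id"], name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gene_association=r.get("gene_association"),
                kind=r.get("kind", "transformation"),
            ))
        except KeyError as exc:
            raise ModelParseError(f"reaction entry missing field {exc}: {r.get('id')}") from exc
    model.objective = doc.get("objective")
    model.objective_direction = doc.get("objective_direction", "max")
    for rc in doc.get("ratio_constraints", []):
        model.add_ratio_constraint(rc["reaction_a"], rc["reaction_b"],
                                   rc["ratio"], rc.get("id"))
    model.validate()
    return model


# -- SBML via cobrapy ---------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    cm.compartments = {"c": "cytoplasm", "p": "periplasm", "e": "extracellular"}
    mets = {}
    for m in model.metabolites.values():
        cmet = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment,
            formula=m.formula, charge=m.charge,
        )
        mets[m.id] = cmet
    for r in model.reactions.values():
        crxn = cobra.Reaction(r.id, name=r.name,
                              lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([crxn])
        crxn.add_metabolites({mets[mid]: c for mid, c in r.stoichiometry.items()})
        if r.gene_association:
            crxn.gene_reaction_rule = r.gene_association
    if model.objective is not None:
        cm.objective = model.objective
        cm.objective_direction = model.objective_direction
    return cm


def _classify_cobra_reaction(crxn, model: MetabolicModel) -> str:
    sto = crxn.metabolites
    if len(sto) == 1:
        met = next(iter(sto))
        if met.compartment == "e" or crxn.id.upper().startswith("EX_"):
            return "exchange"
        return "demand"
    if crxn.id.lower().startswith(("biomass", "bio")):
        return "biomass"
    if crxn.id.upper().startswith("ATPM") or "maintenance" in crxn.name.lower():
        return "maintenance"
    comps = {m.compartment for m in sto}
    return "transport" if len(comps) > 1 else "transformation"


def _from_cobra(cm) -> MetabolicModel:
    model = MetabolicModel(id=cm.id or "model")
    comps = set()
    for m in cm.metabolites:
        comps.add(m.compartment)
    model.compartments = tuple(sorted(comps)) if comps - set(COMPARTMENTS) else COMPARTMENTS
    for m in cm.metabolites:
        model.add_metabolite(Metabolite(
            id=m.id, name=m.name or "", compartment=m.compartment,
            formula=m.formula or None,
            charge=int(m.charge) if m.charge is not None else None,
        ))
    objective_ids = set()
    try:
        from cobra.util.solver import linear_reaction_coefficients

        objective_ids = {r.id for r in linear_reaction_coefficients(cm)}
    except Exception:  # pragma: no cover - solver-interface quirks
        pass
    for r in cm.reactions:
        rxn = Reaction(
            id=r.id, name=r.name or "",
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            lower_bound=r.lower_bound, upper_bound=r.upper_bound,
            gene_association=r.gene_reaction_rule or None,
        )
        rxn.kind = _classify_cobra_reaction(r, model)
        model.reactions[r.id] = rxn  # bypass add_reaction: cobra order guaranteed
    if objective_ids:
        model.objective = sorted(objective_ids)[0]
        model.objective_direction = cm.objective_direction or "max"
    return model


# -- public I/O ---------------------------------------------------------------

def load_model(path, format: str = "native_json") -> MetabolicModel:
    """Load a model from the native JSON format or SBML L3+FBC.

    Raises :class:`ModelParseError` for malformed files and
    :class:`ModelValidationError` for structurally inconsistent ones
    (e.g. duplicate reaction ids).
    """
    if format == "native_json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelParseError(f"{path}: invalid JSON ({exc})") from exc
        return _model_from_dict(doc)
    if format == "sbml":
        import cobra

        cm = cobra.io.read_sbml_model(str(path))
        model = _from_cobra(cm)
        model.validate()
        return model
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path, format: str = "native_json") -> None:
    """Write a model; SBML export drops ratio constraints with a warning."""
    model.validate()
    if format == "native_json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if format == "sbml":
        if model.ratio_constraints:
            log.warning(
                "SBML-FBC has no slot for flux-ratio constraints; dropping %d",
                len(model.ratio_constraints),
            )
        import cobra

        cobra.io.write_sbml_model(_to_cobra(model), str(path))
        return
    raise ValueError(f"unknown model format {format!r}")


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 0.0) -> bool:
    """Structural equality (ids, stoichiometries, bounds, objective, ratios)."""
    da, db = _model_to_dict(a), _model_to_dict(b)
    if tol == 0.0:
        return da == db
    return json.dumps(da, sort_keys=True) == json.dumps(db, sort_keys=True)
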