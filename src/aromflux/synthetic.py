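"""Reduced aromatic-funneling model generator.

This module builds a small, fully element-balanced constraint-based model
of lignin-aromatic funneling in an aerobic alpha-proteobacterium: G-, S-
and H-type monomers (vanillic, syringic, p-hydroxybenzoic acid) plus
optional ferulic acid, G-diketone, the beta-O-4 dimer GGE, and glucose.

Pathway topology (all reactions carry real elemental formulas and are
balanced; check_mass_balance reports zero violations):

* Aromatic import costs 1 ATP + 1 extracellular H+ per molecule
  (TonB/ABC-style transport).
* O-demethylation comes in three interchangeable variants:
  - ``native_THF``: methyl transferred to tetrahydrofolate; the loaded
    carrier is re-oxidized to CO2 yielding 3 NADH.
  - ``hypothetical_nonTHF``: O2-dependent removal to formate, no
    cofactor recovery at the demethylation step.
  - ``VanAB``: O2- and NADH-consuming oxygenase releasing formaldehyde.
  Formaldehyde and formate dehydrogenases are present, so the one-carbon
  products can still be oxidized to CO2 at 1 NADH each; methanol is a
  terminal byproduct (the organism is not a methylotroph).
* G route: vanillate -> protocatechuate -> (4,5-cleavage, O2) CHMS ->
  (NADP+ dehydrogenase) PDC; the CHMS dehydrogenase is the extra NADPH
  source that distinguishes the G and H routes from the S route.
* H route: p-HBA -> (O2/NADH monooxygenase) protocatechuate, then as G.
* S route: syringate -> 3-O-methylgallate (first demethylation slot);
  3-O-methylgallate is either demethylated again to gallate (second
  variant-dependent slot) or ring-cleaved (O2) to CHMOD, which splits to
  PDC + methanol, with a side branch CHMOD -> gallate + formate held at
  a fixed fraction (default 15%) of the PDC branch by a flux-ratio
  constraint. Gallate is cleaved (O2) to 4-oxalomesaconate and
  hydrated/split to pyruvate + oxaloacetate.
* PDC hydrolysis to pyruvate + oxaloacetate closes the funnel in the
  wild type; deleting it (plus the gallate escape) yields the
  PDC-accumulating strain.
* Side chains: ferulate -> vanillate + acetyl-CoA (CoA ligase + NAD+
  dehydrogenase); G-diketone, an isomer of ferulate, follows the same
  lysis but without the NADH gain (its side-chain reduction consumes the
  equivalent); GGE is cleaved to guaiacol + HPV, HPV is trimmed to
  vanillate + acetyl-CoA, guaiacol is demethylated to catechol and ring-
  cleaved to cis,cis-muconate, then to 2 pyruvate.
* Lumped central metabolism: glycolysis, pyruvate dehydrogenase, a
  one-reaction TCA (acetyl-CoA -> 2 CO2 + 4 NADH + ATP), oxaloacetate
  decarboxylase, pyruvate carboxylase, NADH respiration at a fixed P/O
  ratio, and soluble (free, NADPH->NADH) plus ATP-driven (NADH->NADPH)
  transhydrogenases.
* Biomass drains pyruvate, oxaloacetate, acetyl-CoA, NH3, NADPH and GAM
  ATP per gDW; a standalone maintenance reaction carries NGAM.

Generation is deterministic; ``perturb_kinetics`` offers a seeded noise
hook for robustness testing only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kinetics import KineticParams, ParamTable
from .model import MetabolicModel, Metabolite, Reaction

SUBSTRATES = ("glucose", "vanillic", "syringic", "p-HBA", "ferulic",
              "G-diketone", "GGE")

DEMETHYLASE_VARIANTS = ("native_THF", "hypothetical_nonTHF", "VanAB")

#: exchange reaction id and substrate class for each supported substrate
SUBSTRATE_INFO = {
    "glucose": ("EX_glc", "non-aromatic"),
    "vanillic": ("EX_van", "G-type"),
    "syringic": ("EX_syr", "S-type"),
    "p-HBA": ("EX_phb", "H-type"),
    "ferulic": ("EX_fer", "G-type"),
    "G-diketone": ("EX_gdk", "G-type"),
    "GGE": ("EX_gge", "G-type"),
}

# neutral-molecule elemental formulas
FORMULAS = {
    "glc": "C6H12O6", "van": "C8H8O4", "syr": "C9H10O5", "phb": "C7H6O3",
    "fer": "C10H10O4", "gdk": "C10H10O4", "gge": "C17H20O6",
    "gui": "C7H8O2", "hpv": "C10H12O4", "cat": "C6H6O2", "ccma": "C6H6O4",
    "pca": "C7H6O4", "chms": "C7H6O6", "pdc": "C7H4O6",
    "mga": "C8H8O5", "chmod": "C8H8O7", "gal": "C7H6O5", "oma": "C7H6O7",
    "pyr": "C3H4O3", "oaa": "C4H4O5",
    "atp": "C10H12N5O13P3", "adp": "C10H12N5O10P2", "pi": "HO4P",
    "nad": "C21H26N7O14P2", "nadh": "C21H27N7O14P2",
    "nadp": "C21H25N7O17P3", "nadph": "C21H26N7O17P3",
    "thf": "C19H23N7O6", "mthf": "C20H25N7O6",
    "coa": "C21H36N7O16P3S", "accoa": "C23H38N7O17P3S",
    "o2": "O2", "co2": "CO2", "nh3": "H3N", "h2o": "H2O", "h": "H",
    "meoh": "CH4O", "fald": "CH2O", "formate": "CH2O2",
}

NAMES = {
    "glc": "D-glucose", "van": "vanillic acid", "syr": "syringic acid",
    "phb": "p-hydroxybenzoic acid", "fer": "ferulic acid",
    "gdk": "guaiacyl diketone", "gge": "guaiacylglycerol-beta-guaiacyl ether",
    "gui": "guaiacol", "hpv": "hydroxypropiovanillone",
    "cat": "catechol", "ccma": "cis,cis-muconic acid",
    "pca": "protocatechuic acid",
    "chms": "4-carboxy-2-hydroxymuconate-6-semialdehyde",
    "pdc": "2-pyrone-4,6-dicarboxylic acid",
    "mga": "3-O-methylgallic acid",
    "chmod": "4-carboxy-2-hydroxy-6-methoxy-6-oxohexa-2,4-dienoate",
    "gal": "gallic acid", "oma": "4-oxalomesaconate",
    "pyr": "pyruvate", "oaa": "oxaloacetate",
}


class ToySpecError(ValueError):
    pass


@dataclass
class ToySpec:
    """Specification of the reduced funneling model.

    ``biomass_stoichiometry`` is mmol precursor per gDW; ``transport_cost``
    is (ATP, extracellular H+) per aromatic molecule imported.
    """

    substrates: tuple = ("glucose", "vanillic", "syringic", "p-HBA")
    demethylase: str = "native_THF"
    pdc_branch: bool = True
    side_ratio: float = 0.15
    biomass_stoichiometry: dict = field(default_factory=lambda: {
        "pyr": 6.0, "oaa": 4.0, "accoa": 2.0, "nh3": 10.0,
    })
    gam_atp: float = 40.0  # mmol ATP / gDW
    nadph_demand: float = 12.0  # mmol NADPH / gDW
    ngam: float = 0.0  # mmol ATP / gDW / h, lower bound of the maintenance rxn
    po_ratio: float = 2.0  # ATP per NADH respired
    transport_cost: tuple = (1.0, 1.0)

    def validate(self) -> None:
        unknown = set(self.substrates) - set(SUBSTRATES)
        if unknown:
            raise ToySpecError(f"unknown substrates {sorted(unknown)}")
        if not self.substrates:
            raise ToySpecError("at least one substrate required")
        if self.demethylase not in DEMETHYLASE_VARIANTS:
            raise ToySpecError(f"unknown demethylase variant {self.demethylase!r}")
        if not 0.0 <= self.side_ratio <= 1.0:
            raise ToySpecError("side_ratio must lie in [0, 1]")
        if self.pdc_branch and not (set(self.substrates) - {"glucose"}):
            raise ToySpecError("PDC branch requires at least one aromatic substrate")

    @property
    def aromatics(self) -> list[str]:
        return [s for s in self.substrates if s != "glucose"]


def _met(model, mid, compartment):
    key = mid.rsplit("_", 1)[0]
    return model.add_metabolite(Metabolite(
        id=mid, name=NAMES.get(key, key), compartment=compartment,
        formula=FORMULAS[key],
    ))


def _rxn(model, rid, name, stoich, lb=0.0, ub=1000.0, kind="transformation", gpr=None):
    return model.add_reaction(Reaction(
        id=rid, name=name, stoichiometry=stoich,
        lower_bound=lb, upper_bound=ub, kind=kind, gene_association=gpr,
    ))


# Demethylation templates shared by the generator and strain_lab's
# swap_demethylase: maps variant -> extra stoichiometry applied to
# "substrate_c -> product_c" demethylation slots.
# native_THF moves CH2 onto THF; the carrier recycle reaction is separate.
DEMETHYLASE_TEMPLATES = {
    "native_THF": {
        "extra_substrates": {"thf_c": -1.0},
        "extra_products": {"mthf_c": 1.0},
        "gpr": "desA or ligM",
    },
    "hypothetical_nonTHF": {
        "extra_substrates": {"o2_c": -1.0},
        "extra_products": {"formate_c": 1.0},
        "gpr": "demX",
    },
    "VanAB": {
        "extra_substrates": {"o2_c": -1.0, "nadh_c": -1.0, "h_c": -1.0},
        "extra_products": {"fald_c": 1.0, "h2o_c": 1.0, "nad_c": 1.0},
        "gpr": "vanA and vanB",
    },
}

#: demethylation slots: reaction id -> (substrate met, product met)
DEMETHYLATION_SLOTS = {
    "DEMETH_van": ("van_c", "pca_c"),
    "DEMETH_syr": ("syr_c", "mga_c"),
    "DEMETH_mga": ("mga_c", "gal_c"),
    "DEMETH_gui": ("gui_c", "cat_c"),
}


def demethylation_stoichiometry(slot_id: str, variant: str) -> dict[str, float]:
    """Full stoichiometry for one demethylation slot under a variant."""
    sub, prod = DEMETHYLATION_SLOTS[slot_id]
    tpl = DEMETHYLASE_TEMPLATES[variant]
    sto = {sub: -1.0, prod: 1.0}
    for mid, c in tpl["extra_substrates"].items():
        sto[mid] = sto.get(mid, 0.0) + c
    for mid, c in tpl["extra_products"].items():
        sto[mid] = sto.get(mid, 0.0) + c
    return sto


def make_toy_model(spec: ToySpec | None = None) -> MetabolicModel:
    """Build the reduced funneling model for a :class:`ToySpec`."""
    spec = spec or ToySpec()
    spec.validate()
    model = MetabolicModel(id="toy_funnel")

    cyt = ["pyr", "oaa", "atp", "adp", "pi", "nad", "nadh", "nadp", "nadph",
           "coa", "accoa", "o2", "co2", "nh3", "h2o", "h",
           "meoh", "fald", "formate", "thf", "mthf"]
    ext = ["o2", "co2", "nh3", "h2o", "h", "meoh", "fald", "formate"]

    need = set(spec.substrates)
    if "vanillic" in need or "ferulic" in need or "G-diketone" in need or "GGE" in need:
        need.add("vanillic")  # side-chain routes funnel through vanillate
    use_G = "vanillic" in need
    use_S = "syringic" in need
    use_H = "p-HBA" in need
    use_gge = "GGE" in need

    if use_G or use_H:
        cyt += ["pca", "chms"]
    if use_S:
        cyt += ["mga", "chmod", "gal", "oma"]
    if use_G or use_H or use_S:
        cyt += ["pdc"]
        ext += ["pdc"]
    if use_gge:
        cyt += ["gui", "hpv", "cat", "ccma"]
        # secretion outlets so a blocked branch dead-ends gracefully
        ext += ["gui", "hpv"]

    sub_key = {"glucose": "glc", "vanillic": "van", "syringic": "syr",
               "p-HBA": "phb", "ferulic": "fer", "G-diketone": "gdk",
               "GGE": "gge"}
    for s in sorted(need, key=SUBSTRATES.index):
        key = sub_key[s]
        cyt.append(key)
        ext.append(key)

    seen = set()
    for key in cyt:
        if key not in seen:
            _met(model, f"{key}_c", "c")
            seen.add(key)
    for key in ext:
        _met(model, f"{key}_e", "e")

    # -- exchanges ------------------------------------------------------------
    free = ("o2", "h2o", "h")
    for key in ext:
        lb = -1000.0 if key in free else 0.0
        if key in (sub_key[s] for s in need):
            lb = -1000.0  # substrate uptake allowed; kinetics tighten per solve
        _rxn(model, f"EX_{key}", f"{NAMES.get(key, key)} exchange",
             {f"{key}_e": -1.0}, lb=lb, ub=1000.0, kind="exchange")
    model.reactions["EX_nh3"].lower_bound = -1000.0

    # -- transport ------------------------------------------------------------
    atp_cost, h_cost = spec.transport_cost

    def aromatic_transport(key, gpr=None):
        sto = {f"{key}_e": -1.0, f"{key}_c": 1.0}
        if atp_cost:
            sto.update({"atp_c": -atp_cost, "h2o_c": -atp_cost,
                        "adp_c": atp_cost, "pi_c": atp_cost, "h_c": atp_cost})
        if h_cost:
            sto["h_e"] = sto.get("h_e", 0.0) - h_cost
            sto["h_c"] = sto.get("h_c", 0.0) + h_cost
        _rxn(model, f"T_{key}", f"{NAMES.get(key, key)} import (ATP + PMF)",
             sto, kind="transport", gpr=gpr)

    for s in sorted(need, key=SUBSTRATES.index):
        key = sub_key[s]
        if s == "glucose":
            _rxn(model, "T_glc", "glucose ABC import",
                 {"glc_e": -1.0, "atp_c": -1.0, "h2o_c": -1.0,
                  "glc_c": 1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
                 kind="transport", gpr="gtsABC")
        else:
            aromatic_transport(key, gpr="tonB")

    for key in ("o2", "co2", "nh3", "h2o", "h", "meoh", "fald", "formate"):
        _rxn(model, f"T_{key}", f"{key} diffusion",
             {f"{key}_e": -1.0, f"{key}_c": 1.0}, lb=-1000.0, kind="transport")
    if use_G or use_H or use_S:
        _rxn(model, "T_pdc", "PDC export",
             {"pdc_c": -1.0, "pdc_e": 1.0}, kind="transport")
    if use_gge:
        for key in ("gui", "hpv"):
            _rxn(model, f"T_{key}", f"{NAMES[key]} secretion",
                 {f"{key}_c": -1.0, f"{key}_e": 1.0}, kind="transport")

    # -- demethylation slots + folate recycle ---------------------------------
    slots = []
    if use_G:
        slots.append("DEMETH_van")
    if use_S:
        slots.append("DEMETH_syr")
        slots.append("DEMETH_mga")
    if use_gge:
        slots.append("DEMETH_gui")
    for slot in slots:
        sto = demethylation_stoichiometry(slot, spec.demethylase)
        _rxn(model, slot, f"{slot.split('_')[1]} O-demethylation ({spec.demethylase})",
             sto, gpr=DEMETHYLASE_TEMPLATES[spec.demethylase]["gpr"])
    if spec.demethylase == "native_THF" and slots:
        # methyl-THF re-oxidation: CH2 unit -> CO2, 3 NADH recovered
        _rxn(model, "MTHF_recycle", "methyl-THF oxidation to CO2",
             {"mthf_c": -1.0, "h2o_c": -2.0, "nad_c": -3.0,
              "thf_c": 1.0, "co2_c": 1.0, "nadh_c": 3.0, "h_c": 3.0},
             gpr="folD and fdh")

    # -- one-carbon oxidation (methanol is a terminal byproduct: the
    # organism is not a methylotroph, so no methanol dehydrogenase) ----------
    _rxn(model, "FALD_DH", "formaldehyde dehydrogenase",
         {"fald_c": -1.0, "h2o_c": -1.0, "nad_c": -1.0,
          "formate_c": 1.0, "nadh_c": 1.0, "h_c": 1.0}, gpr="fdhA")
    _rxn(model, "FOR_DH", "formate dehydrogenase",
         {"formate_c": -1.0, "nad_c": -1.0, "co2_c": 1.0, "nadh_c": 1.0, "h_c": 1.0},
         gpr="fdh")

    # -- G/H convergence on protocatechuate -----------------------------------
    if use_G or use_H:
        _rxn(model, "PCA_45_DIOX", "protocatechuate 4,5-dioxygenase",
             {"pca_c": -1.0, "o2_c": -1.0, "chms_c": 1.0}, gpr="ligA and ligB")
        _rxn(model, "CHMS_DH", "CHMS dehydrogenase (NADP+)",
             {"chms_c": -1.0, "nadp_c": -1.0,
              "pdc_c": 1.0, "nadph_c": 1.0, "h_c": 1.0}, gpr="ligC")
    if use_H:
        # NADH-coupled monooxygenase; with the NADP+-coupled CHMS
        # dehydrogenase downstream this makes both the G and H routes net
        # NADPH sources relative to the S route
        _rxn(model, "PHB_HYDROX", "p-hydroxybenzoate 3-monooxygenase",
             {"phb_c": -1.0, "o2_c": -1.0, "nadh_c": -1.0, "h_c": -1.0,
              "pca_c": 1.0, "h2o_c": 1.0, "nad_c": 1.0}, gpr="pobA")

    # -- S route --------------------------------------------------------------
    if use_S:
        _rxn(model, "MGA_DIOX", "3-O-methylgallate ring cleavage",
             {"mga_c": -1.0, "o2_c": -1.0, "chmod_c": 1.0}, gpr="ligAB2")
        _rxn(model, "CHMOD_PDC", "CHMOD to PDC (methanol release)",
             {"chmod_c": -1.0, "pdc_c": 1.0, "meoh_c": 1.0}, gpr="ligU")
        _rxn(model, "CHMOD_GAL", "CHMOD to gallate (formate release)",
             {"chmod_c": -1.0, "gal_c": 1.0, "formate_c": 1.0}, gpr="desCD")
        _rxn(model, "GAL_DIOX", "gallate dioxygenase",
             {"gal_c": -1.0, "o2_c": -1.0, "oma_c": 1.0}, gpr="desB")
        _rxn(model, "OMA_HYD", "4-oxalomesaconate hydratase/aldolase",
             {"oma_c": -1.0, "h2o_c": -1.0, "pyr_c": 1.0, "oaa_c": 1.0},
             gpr="ligJ and ligK")
        if spec.side_ratio is not None and spec.pdc_branch:
            model.add_ratio_constraint("CHMOD_GAL", "CHMOD_PDC",
                                       spec.side_ratio, id="chmod_side_ratio")

    # -- PDC hydrolysis (wild-type funnel closure) ----------------------------
    if use_G or use_H or use_S:
        _rxn(model, "PDC_HYDROL", "PDC hydrolase to pyruvate + oxaloacetate",
             {"pdc_c": -1.0, "h2o_c": -2.0, "pyr_c": 1.0, "oaa_c": 1.0},
             gpr="ligI")

    # -- side chains ----------------------------------------------------------
    if "ferulic" in need:
        _rxn(model, "FER_CLEAVE", "ferulate CoA-ligase/lyase/dehydrogenase",
             {"fer_c": -1.0, "coa_c": -1.0, "atp_c": -1.0, "h2o_c": -2.0,
              "nad_c": -1.0, "van_c": 1.0, "accoa_c": 1.0, "adp_c": 1.0,
              "pi_c": 1.0, "h_c": 2.0, "nadh_c": 1.0}, gpr="ferA and ferB")
    if "G-diketone" in need:
        # same lysis as ferulate, but side-chain reduction consumes the
        # NADH the aldehyde oxidation would have yielded
        _rxn(model, "GDK_CLEAVE", "G-diketone reduction and side-chain lysis",
             {"gdk_c": -1.0, "coa_c": -1.0, "atp_c": -1.0, "h2o_c": -2.0,
              "van_c": 1.0, "accoa_c": 1.0, "adp_c": 1.0,
              "pi_c": 1.0, "h_c": 3.0}, gpr="ligD2")
    if use_gge:
        _rxn(model, "GGE_CLEAVE", "GGE beta-etherase (to guaiacol + HPV)",
             {"gge_c": -1.0, "gui_c": 1.0, "hpv_c": 1.0}, gpr="ligDEF and ligG")
        _rxn(model, "HPV_CLEAVE", "HPV side-chain cleavage to vanillate",
             {"hpv_c": -1.0, "coa_c": -1.0, "nad_c": -2.0, "h2o_c": -1.0,
              "van_c": 1.0, "accoa_c": 1.0, "nadh_c": 2.0, "h_c": 2.0},
             gpr="hpvZ")
        _rxn(model, "CAT_DIOX", "catechol 1,2-dioxygenase",
             {"cat_c": -1.0, "o2_c": -1.0, "ccma_c": 1.0}, gpr="catA")
        _rxn(model, "CCMA_CATAB", "muconate lactonization branch (lumped)",
             {"ccma_c": -1.0, "h2o_c": -2.0, "nad_c": -1.0,
              "pyr_c": 2.0, "nadh_c": 1.0, "h_c": 1.0}, gpr="catBCD")

    # -- central metabolism ---------------------------------------------------
    if "glucose" in need:
        _rxn(model, "GLYCOLYSIS", "glycolysis (lumped)",
             {"glc_c": -1.0, "adp_c": -2.0, "pi_c": -2.0, "nad_c": -2.0,
              "pyr_c": 2.0, "atp_c": 2.0, "nadh_c": 2.0, "h2o_c": 2.0},
             gpr="pgi and pfk and eno and pyk")
    _rxn(model, "PDH", "pyruvate dehydrogenase",
         {"pyr_c": -1.0, "coa_c": -1.0, "nad_c": -1.0,
          "accoa_c": 1.0, "co2_c": 1.0, "nadh_c": 1.0, "h_c": 1.0},
         gpr="aceEF and lpd")
    _rxn(model, "TCA", "acetyl-CoA oxidation (lumped TCA)",
         {"accoa_c": -1.0, "nad_c": -4.0, "adp_c": -1.0, "pi_c": -1.0,
          "h2o_c": -2.0, "coa_c": 1.0, "co2_c": 2.0, "nadh_c": 4.0,
          "atp_c": 1.0, "h_c": 3.0}, gpr="gltA and icd and sucAB and mdh2")
    _rxn(model, "OAA_DC", "oxaloacetate decarboxylase",
         {"oaa_c": -1.0, "pyr_c": 1.0, "co2_c": 1.0}, gpr="oadA")
    _rxn(model, "PYR_CARB", "pyruvate carboxylase",
         {"pyr_c": -1.0, "co2_c": -1.0, "atp_c": -1.0, "h2o_c": -1.0,
          "oaa_c": 1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0}, gpr="pyc")
    po = spec.po_ratio
    _rxn(model, "RESP", f"NADH respiration (P/O = {po:g})",
         {"nadh_c": -1.0, "o2_c": -0.5, "adp_c": -po, "pi_c": -po,
          "h_c": -(1 + po), "nad_c": 1.0, "atp_c": po,
          "h2o_c": 1 + po}, gpr="nuo and atpABC")
    _rxn(model, "THD_SOL", "soluble transhydrogenase (NADPH -> NADH)",
         {"nadph_c": -1.0, "nad_c": -1.0, "nadp_c": 1.0, "nadh_c": 1.0},
         gpr="sthA")
    _rxn(model, "THD_ATP", "energy-dependent transhydrogenase (NADH -> NADPH)",
         {"nadh_c": -1.0, "nadp_c": -1.0, "atp_c": -1.0, "h2o_c": -1.0,
          "nad_c": 1.0, "nadph_c": 1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
         gpr="pntAB")

    # -- biomass and maintenance ----------------------------------------------
    bs = spec.biomass_stoichiometry
    bio = {f"{k}_c": -v for k, v in bs.items()}
    bio["atp_c"] = bio.get("atp_c", 0.0) - spec.gam_atp
    bio["h2o_c"] = bio.get("h2o_c", 0.0) - spec.gam_atp
    bio["nadph_c"] = bio.get("nadph_c", 0.0) - spec.nadph_demand
    bio["adp_c"] = spec.gam_atp
    bio["pi_c"] = spec.gam_atp
    bio["h_c"] = spec.gam_atp
    bio["nadp_c"] = spec.nadph_demand
    bio["coa_c"] = bs.get("accoa", 0.0)
    _rxn(model, "BIOMASS", "biomass sink (precursor demands per gDW)",
         bio, kind="biomass", gpr="bio1")
    _rxn(model, "ATPM", "non-growth-associated maintenance",
         {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
         lb=spec.ngam, kind="maintenance")

    model.objective = "BIOMASS"
    model.objective_direction = "max"
    model.validate()
    return model


# -- media --------------------------------------------------------------------

@dataclass
class Media:
    """Batch medium: initial carbon pools plus specific flux caps.

    ``carbon`` maps substrate exchange ids to initial concentrations in
    mmol/L. ``caps`` maps exchange ids to maximum specific uptake rates in
    mmol/gDW/h (None = unconstrained); by default the SMB-like medium caps
    O2 (gas transfer) and the mineral nutrients and leaves water and
    protons free.
    """

    name: str = "SMB_like"
    carbon: dict = field(default_factory=dict)
    caps: dict = field(default_factory=dict)

    def exchange_bounds(self) -> dict[str, tuple]:
        return {rid: (-cap, None) for rid, cap in self.caps.items()
                if cap is not None}


def make_media(model: MetabolicModel, carbon: dict[str, float],
               name: str = "SMB_like", o2_cap: float | None = 4.0,
               nh3_cap: float | None = 5.0) -> Media:
    """SMB-like medium for the toy model.

    ``carbon`` maps substrate names (as in :data:`SUBSTRATES`) or exchange
    ids to mmol/L. O2 carries a finite specific transfer cap by default;
    pass ``o2_cap=None`` for unconstrained oxygen.
    """
    conc = {}
    for key, mmol in carbon.items():
        rid = SUBSTRATE_INFO[key][0] if key in SUBSTRATE_INFO else key
        if rid not in model.reactions:
            raise KeyError(f"unknown substrate exchange {rid}")
        conc[rid] = float(mmol)
    caps = {}
    if o2_cap is not None:
        caps["EX_o2"] = o2_cap
    if nh3_cap is not None and "EX_nh3" in model.reactions:
        caps["EX_nh3"] = nh3_cap
    return Media(name=name, carbon=conc, caps=caps)


def substrate_classes(model: MetabolicModel) -> dict[str, str]:
    """Map each substrate exchange id present in the model to its class."""
    out = {}
    for name, (rid, cls) in SUBSTRATE_INFO.items():
        if rid in model.reactions:
            out[rid] = cls
    return out


def make_kinetics_table() -> ParamTable:
    """Illustrative per-class kinetic parameters (editable via TSV).

    One row per substrate class; identical Vmax/Ks across classes so that
    co-consumption ordering in simulations reflects network energetics
    rather than transporter kinetics. Ki defaults to Ks.
    """
    table = ParamTable()
    for cls in ("non-aromatic", "G-type", "S-type", "H-type"):
        table.add(KineticParams(substrate=cls, Vmax=10.0, Ks=0.1, Ki=None,
                                substrate_class=cls))
    return table


def perturb_kinetics(table: ParamTable, rel_sd: float = 0.1, seed: int = 0) -> ParamTable:
    """Seeded multiplicative noise on kinetic parameters (robustness tests)."""
    import numpy as np

    rng = np.random.default_rng(seed)
    out = ParamTable()
    for p in list(table.by_substrate.values()) + list(table.by_class.values()):
        f = rng.lognormal(mean=0.0, sigma=rel_sd, size=3)
        out.add(KineticParams(
            substrate=p.substrate, Vmax=p.Vmax * f[0], Ks=p.Ks * f[1],
            Ki=p.Ki * f[2], substrate_class=p.substrate_class,
        ))
    return out
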