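"""Biomass-reaction assembly from macromolecular composition, plus growth
unit conversions.

A biomass reaction drains precursor metabolites in proportions matching
the measured dry-weight composition (protein, DNA, RNA, lipid pools)
with monomer distributions taken from genome statistics (amino-acid
frequencies from annotated coding regions, base frequencies from the
genome). Coefficients are mmol precursor per gDW; after assembly the
reaction is rescaled by a single factor so that the summed precursor
mass is exactly 1.000 g per mmol of biomass, the conventional
normalization for growth-rate units.

Cell-density conversions follow a Klett-colorimeter standard curve:
100 Klett units correspond to 0.25 gDW/L, and 1 KU to 8e6 CFU/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Reaction

KLETT_GDW_PER_L = 0.25 / 100.0  # gDW/L per Klett unit
KLETT_CFU_PER_ML = 8.0e6  # CFU/mL per Klett unit


class CompositionError(ValueError):
    pass


@dataclass
class BiomassComposition:
    """Dry-weight mass fractions and monomer frequency maps.

    ``macromolecules`` maps pool name (protein, dna, rna, phospholipid,
    sphingolipid, other...) to its dry-weight mass fraction;
    ``monomer_freqs`` maps pool name to a precursor-id -> mole-fraction
    map (a pool absent here is drained as the single precursor named by
    ``pool_precursors``). ``gam_atp`` is growth-associated maintenance in
    mmol ATP per gDW.
    """

    macromolecules: dict[str, float]
    monomer_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    pool_precursors: dict[str, str] = field(default_factory=dict)
    gam_atp: float = 0.0

    def validate(self) -> None:
        if not self.macromolecules:
            raise CompositionError("empty composition")
        for pool, frac in self.macromolecules.items():
            if frac < 0:
                raise CompositionError(f"negative fraction for {pool}")
        total = sum(self.macromolecules.values())
        if total > 1.0 + 1e-9:
            raise CompositionError(
                f"mass fractions sum to {total:.4f} > 1.0")
        for pool, freqs in self.monomer_freqs.items():
            s = sum(freqs.values())
            if abs(s - 1.0) > 1e-6:
                raise CompositionError(
                    f"{pool} monomer frequencies sum to {s:.8f}, not 1")
        for pool in self.macromolecules:
            if pool not in self.monomer_freqs and pool not in self.pool_precursors:
                raise CompositionError(
                    f"pool {pool!r} has neither monomer frequencies nor a "
                    f"precursor id")


def build_biomass_reaction(
    comp: BiomassComposition,
    metabolite_masses: dict[str, float],
    reaction_id: str = "BIOMASS",
    atp_id: str = "atp_c",
    adp_id: str = "adp_c",
    pi_id: str = "pi_c",
    h2o_id: str = "h2o_c",
    h_id: str = "h_c",
) -> Reaction:
    """Assemble a biomass reaction whose coefficients reproduce the
    composition's mass fractions.

    For a pool with mass fraction f distributed over monomers m with
    mole fractions x_m and molar masses M_m, each monomer coefficient is
    1000 * f * x_m / (sum_m x_m M_m) mmol/gDW, so the pool's drained mass
    is exactly f grams per gDW. GAM ATP hydrolysis is appended when
    ``comp.gam_atp`` > 0.
    """
    comp.validate()
    sto: dict[str, float] = {}
    for pool, frac in comp.macromolecules.items():
        if frac == 0:
            continue
        if pool in comp.monomer_freqs:
            freqs = comp.monomer_freqs[pool]
        else:
            freqs = {comp.pool_precursors[pool]: 1.0}
        try:
            mean_mass = sum(x * metabolite_masses[m] for m, x in freqs.items())
        except KeyError as exc:
            raise CompositionError(f"no molar mass for precursor {exc}") from exc
        if mean_mass <= 0:
            raise CompositionError(f"non-positive mean monomer mass in {pool}")
        for m, x in freqs.items():
            if x == 0:
                continue
            coeff = 1000.0 * frac * x / mean_mass
            sto[m] = sto.get(m, 0.0) - coeff
    if comp.gam_atp > 0:
        for mid, sign in ((atp_id, -1), (h2o_id, -1), (adp_id, 1),
                          (pi_id, 1), (h_id, 1)):
            sto[mid] = sto.get(mid, 0.0) + sign * comp.gam_atp
    return Reaction(id=reaction_id, name="biomass (assembled from composition)",
                    stoichiometry=sto, lower_bound=0.0, upper_bound=1000.0,
                    kind="biomass")


def biomass_mass_per_mmol(reaction: Reaction,
                          metabolite_masses: dict[str, float],
                          currency: tuple = ("atp_c", "adp_c", "pi_c",
                                             "h2o_c", "h_c")) -> float:
    """Net drained precursor mass in g per mmol biomass flux.

    Currency metabolites (the GAM ATP cycle) are excluded: they do not
    contribute dry weight.
    """
    total = 0.0
    for mid, coeff in reaction.stoichiometry.items():
        if coeff >= 0 or mid in currency:
            continue
        try:
            total += -coeff * metabolite_masses[mid] / 1000.0
        except KeyError as exc:
            raise CompositionError(f"no molar mass for precursor {exc}") from exc
    return total


def scale_biomass_to_unit_mass(
    reaction: Reaction,
    metabolite_masses: dict[str, float],
    currency: tuple = ("atp_c", "adp_c", "pi_c", "h2o_c", "h_c"),
) -> Reaction:
    """Rescale precursor coefficients so the drained mass is 1.000 g/mmol.

    A draft reaction assembled from raw measurements can come out above
    1 g/mmol (e.g. 1.08); a single scalar 1/mass restores the unit
    normalization. Currency (GAM) coefficients are left untouched.
    Idempotent: scaling an already-unit reaction returns it unchanged.
    """
    mass = biomass_mass_per_mmol(reaction, metabolite_masses, currency)
    if mass <= 0:
        raise CompositionError("biomass reaction drains zero precursor mass")
    scalar = 1.0 / mass
    sto = {}
    for mid, coeff in reaction.stoichiometry.items():
        sto[mid] = coeff if mid in currency else coeff * scalar
    return Reaction(id=reaction.id, name=reaction.name, stoichiometry=sto,
                    lower_bound=reaction.lower_bound,
                    upper_bound=reaction.upper_bound, kind=reaction.kind,
                    gene_association=reaction.gene_association)


def klett_to_gdw(ku: float) -> float:
    """Klett units -> gDW/L (100 KU = 0.25 gDW/L)."""
    if ku < 0:
        raise ValueError("negative Klett reading")
    return ku * KLETT_GDW_PER_L


def klett_to_cfu_per_ml(ku: float) -> float:
    """Klett units -> CFU/mL (1 KU = 8e6 CFU/mL)."""
    if ku < 0:
        raise ValueError("negative Klett reading")
    return ku * KLETT_CFU_PER_ML


def read_composition_tsv(path) -> tuple[BiomassComposition, dict[str, float]]:
    """Composition TSV: component, fraction, precursor_id, MW, monomer_frac.

    Rows sharing a component form that pool's monomer distribution;
    returns the composition plus the molar-mass map collected from the
    MW column.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    macro: dict[str, float] = {}
    freqs: dict[str, dict[str, float]] = {}
    masses: dict[str, float] = {}
    for comp_name, group in df.groupby("component", sort=False):
        macro[comp_name] = float(group["fraction"].iloc[0])
        fr = {}
        for _, row in group.iterrows():
            mono = row["precursor_id"]
            fr[mono] = float(row.get("monomer_frac", 1.0 / len(group)))
            masses[mono] = float(row["MW"])
        freqs[comp_name] = fr
    return BiomassComposition(macromolecules=macro, monomer_freqs=freqs), masses
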