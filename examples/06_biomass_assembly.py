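"""Assembling and normalizing a biomass reaction from composition data.

Takes dry-weight mass fractions (protein, DNA, RNA, lipid) with monomer
distributions, builds the biomass drain whose coefficients (mmol/gDW)
reproduce those fractions, and rescales it so one mmol of biomass flux
drains exactly 1.000 g — the normalization that makes the biomass flux
read directly as specific growth rate. Also shows the Klett-unit
conversions used to put growth measurements on gDW/L scale.
"""

from aromflux import (
    BiomassComposition,
    build_biomass_reaction,
    klett_to_cfu_per_ml,
    klett_to_gdw,
    scale_biomass_to_unit_mass,
)
from aromflux.biomass import biomass_mass_per_mmol

masses = {"ala_c": 89.09, "glu_c": 147.13, "damp_c": 331.22,
          "amp_c": 347.22, "palm_c": 256.43}

comp = BiomassComposition(
    macromolecules={"protein": 0.55, "dna": 0.03, "rna": 0.12,
                    "lipid": 0.27},  # measured pools; 0.03 unaccounted
    monomer_freqs={"protein": {"ala_c": 0.6, "glu_c": 0.4}},
    pool_precursors={"dna": "damp_c", "rna": "amp_c", "lipid": "palm_c"},
    gam_atp=40.0,
)

draft = build_biomass_reaction(comp, masses)
print(f"draft mass balance: {biomass_mass_per_mmol(draft, masses):.3f} g/mmol")
scaled = scale_biomass_to_unit_mass(draft, masses)
print(f"after scaling:      {biomass_mass_per_mmol(scaled, masses):.3f} g/mmol")
print("precursor coefficients (mmol/gDW):")
for mid, coeff in scaled.stoichiometry.items():
    if coeff < 0 and mid != "atp_c" and mid != "h2o_c":
        print(f"  {mid:<8s} {-coeff:8.3f}")

print(f"\n100 Klett units = {klett_to_gdw(100):.2f} gDW/L; "
      f"1 KU = {klett_to_cfu_per_ml(1):.1e} CFU/mL")
print("The single rescaling factor preserves the measured composition")
print("ratios while pinning the reaction's mass balance at 1 g/mmol.")
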