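# Native JSON model format

A single JSON document with `"format": "aromflux-model"` at the top
level. Unlike SBML-FBC it has first-class slots for flux-ratio
constraints and reaction kinds, so a model round-trips without loss.
Unknown top-level keys are ignored with a logged warning.

```json
{
 "format": "aromflux-model",
 "version": 1,
 "id": "toy_funnel",
 "compartments": ["c", "p", "e"],
 "metabolites": [
  {"id": "van_c", "name": "vanillic acid", "compartment": "c",
   "formula": "C8H8O4", "charge": 0}
 ],
 "reactions": [
  {"id": "DEMETH_van", "name": "van O-demethylation (native_THF)",
   "stoichiometry": {"van_c": -1.0, "thf_c": -1.0,
                     "pca_c": 1.0, "mthf_c": 1.0},
   "lower_bound": 0.0, "upper_bound": 1000.0,
   "gene_association": "desA or ligM",
   "kind": "transformation"}
 ],
 "objective": "BIOMASS",
 "objective_direction": "max",
 "ratio_constraints": [
  {"id": "chmod_side_ratio", "reaction_a": "CHMOD_GAL",
   "reaction_b": "CHMOD_PDC", "ratio": 0.15}
 ]
}
```

Field notes:

- **metabolites.compartment** — one of the model's declared compartments;
  the shipped convention is `c` (cytoplasm), `p` (periplasm),
  `e` (extracellular), mirrored by `_c`/`_p`/`_e` id suffixes.
- **metabolites.formula** — optional Hill-style elemental formula
  (`C8H8O4`); enables mass-balance checking and molar-mass derivation.
  `charge` is optional.
- **reactions.stoichiometry** — metabolite id to signed coefficient,
  negative = consumed. Must be non-empty.
- **reactions bounds** — mmol/gDW/h. When omitted, the conventional
  "unbounded" sentinels apply: `(-1000, 1000)`.
- **reactions.kind** — `transformation`, `transport`, `exchange`,
  `demand`, `biomass`, or `maintenance`. Exchange reactions must touch
  exactly one extracellular metabolite; exchange flux < 0 is uptake.
- **reactions.gene_association** — boolean expression over gene ids
  (`"A and (B or C)"`); a reaction is disabled when the expression is
  false under a knockout assignment.
- **ratio_constraints** — each entry adds `v_a - ratio * v_b = 0` to
  every steady-state solve; entries are removable by `id`. SBML export
  drops them with a warning since SBML-FBC has no equivalent.
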