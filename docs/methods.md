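# Methods

## Scope and model form

`aromflux` implements constraint-based analysis of aromatic "funneling"
metabolism — the convergent catabolism by which bacteria such as
*Novosphingobium aromaticivorans* channel the guaiacyl (G, one ring
methoxy), syringyl (S, two) and *p*-hydroxyphenyl (H, none) monomers of
depolymerized lignin into a handful of central intermediates. The
package covers four layers:

1. steady-state flux balance analysis (FBA) with flux-ratio constraints,
2. batch dynamic FBA (dFBA) with concentration-dependent uptake bounds,
3. in-silico strain engineering (knockouts, demethylase swaps, coupled
   product pathways, wild-type flux pinning), and
4. breakeven technoeconomics for candidate bioproducts.

Any SBML L3+FBC or native-JSON reconstruction can be analyzed; the
shipped synthetic generator (`aromflux.synthetic`) provides a reduced,
fully element-balanced funneling network used throughout the tests and
examples.

## Flux balance analysis

The steady-state problem is the standard LP: maximize the biomass (or
any designated) flux subject to S·v = 0 and per-reaction bounds
(mmol/gDW/h; exchange flux < 0 is uptake). Flux-ratio constraints
(v_a − r·v_b = 0) are appended as extra zero-RHS equality rows rather
than bound manipulations, so they compose with pins and kinetic bounds
and can be removed by id. Solving uses scipy's HiGHS interface.

Numerical contract: after an optimal solve, fluxes below 1e-9 in
magnitude are snapped to zero and all equality residuals are verified
(< 1e-6 raises; the S·v residual at reported optima is < 1e-9 in the
test suite). Only the objective value is contractual — flux vectors are
one of possibly many alternate optima, and no test asserts on non-unique
fluxes. A parsimonious cleanup (minimize Σ|v| at fixed objective) is
available but off by default, as results are reported at objective
level. A lexicographic secondary objective (re-optimize a second linear
function at the fixed primary optimum) supports product-coupled strains
whose uptake is otherwise degenerate at zero growth.

Yields are reported as mgDW per mmol substrate: the named exchange is
pinned at the given uptake, all other organic-carbon exchanges are
closed to uptake (secretion stays open), and yield = 1000·μ/uptake.
Maintenance can be toggled per yield computation; the toy's default NGAM
is zero, so the toggle matters only for models that carry one.

## Uptake kinetics

Batch simulations bound each substrate exchange by substrate-inhibited
Monod kinetics,

    q(S) = Vmax · S/(S + Ks) · 1/(1 + S/Ki),

with Vmax in mmol/gDW/h and Ks, Ki in mmol/L. Ki defaults to Ks when no
inhibition constant is known. Vmax is a biomass-specific rate because
dFBA multiplies it by the biomass concentration; literature values
reported as bulk velocities (e.g. mmol/min for a culture) must be
divided by the culture's biomass (gDW) and converted to hours
(×60/gDW) before entering the table. q is 0 at S = 0, peaks at √(Ks·Ki) and
decays to 0 — the inhibition term encodes the delayed growth commonly
seen at high aromatic loads. Parameters are per-exchange with a
substrate-class fallback (non-aromatic, G-, S-, H-type), editable as a
TSV. The shipped defaults (Vmax = 10, Ks = Ki = 0.1 for every class) are
deliberately illustrative and identical across classes, so that any
ordering among substrates in simulations is attributable to network
energetics rather than transporter kinetics. Fitted organism-specific
constants, where available, should be supplied by the user. Fixed caps
(no kinetics) apply to mineral nutrients.

## Dynamic FBA

Forward-Euler batch iteration with default dt = 0.1 h: per cycle, uptake
bounds are computed from current concentrations, additionally capped by
availability S/(X·dt) — which prevents concentration overshoot at the
source instead of clamping after the fact — the LP is solved, and

    S_i ← S_i + v_i·X·dt,  X ← X(1 + μ·dt)

with products accumulated analogously. Halving dt changes final biomass
by < 2% on the toy model. The loop is deterministic (no RNG), stops at
t_end, on an infeasible LP (recorded in the trajectory, not raised), or
once growth *and* substrate consumption have both been negligible for
three consecutive steps; the consumption clause keeps zero-growth
product-coupled strains running until their substrate is spent. Each
step records which exchange bounds were binding, reproducing the
"one substrate at its maximum allowed flux" diagnostic.

Carbon closure over a trajectory integrates every carbon-carrying
exchange (CO2, methanol, formate, formaldehyde, products) and compares
initial substrate carbon with final substrate + product + biomass +
escaped carbon; on the carbon-closed toy model the relative error is at
machine precision, and 1% is the documented tolerance.

## The reduced funneling network

The generator emulates the funneling topology with real elemental
formulas throughout (the mass-balance checker reports zero violations):

- **Transport.** Aromatics pay 1 ATP + 1 extracellular H⁺ per molecule
  (TonB/ABC-style import); glucose pays 1 ATP.
- **Demethylation** is a set of "slots" (vanillate→protocatechuate,
  syringate→3-O-methylgallate, 3-O-methylgallate→gallate,
  guaiacol→catechol) filled by one of three variants: native THF-
  dependent transfer (the loaded carrier is re-oxidized to CO2 for
  3 NADH per methyl), a hypothetical non-THF oxygenase (methyl leaves as
  formate), or VanAB (consumes NADH + O2, releases formaldehyde).
  Formate and formaldehyde dehydrogenases allow either one-carbon
  product to be oxidized at 1 net NADH, which is why the two oxygenase
  variants predict identical yields; methanol has no dehydrogenase (the
  organism is not a methylotroph) and is a terminal byproduct.
- **G/H convergence.** Protocatechuate is ring-cleaved (O2) to CHMS,
  whose NADP⁺-coupled dehydrogenase to PDC is the G/H routes' extra
  NADPH source; the H route's monooxygenase consumes NADH. The S route
  reaches PDC through CHMOD with obligatory methanol release, with the
  CHMOD→gallate side branch held at 15% of the PDC branch by a ratio
  constraint in the wild type.
- **Side chains.** Ferulate is cleaved to vanillate + acetyl-CoA (ATP-
  activated, NAD⁺ aldehyde oxidation); the G-diketone isomer follows the
  same lysis minus the NADH gain (its side-chain reduction consumes the
  equivalent); GGE splits into guaiacol + HPV, each with its own lumped
  route and a secretion outlet so branch knockouts dead-end gracefully.
- **Central metabolism** is lumped: glycolysis, pyruvate dehydrogenase,
  one-reaction TCA (acetyl-CoA → 2 CO2 + 4 NADH + ATP), OAA
  decarboxylase, pyruvate carboxylase, respiration at a parameterized
  P/O (default 2), and paired transhydrogenases (free NADPH→NADH;
  ATP-driven NADH→NADPH).
- **Biomass** drains 6 pyruvate + 4 OAA + 2 acetyl-CoA + 10 NH3 +
  40 ATP + 12 NADPH per gDW (≈38 mmol C/gDW); NGAM is a standalone
  maintenance reaction, default 0.

The default SMB-like medium caps specific O2 transfer at 4 mmol/gDW/h
and ammonia at 5 mmol/gDW/h; water and protons are free. The finite O2
cap is a deliberate design choice: with oxygen scarce the LP expresses a
substrate preference (biomass return per unit O2), and the observed
depletion order of a batch mixture becomes an emergent prediction of the
demethylation energetics — vanillate first (extra NADPH), then
syringate, then *p*-HBA, glucose before all aromatics, and *p*-HBA
overtaking syringate when THF recovery is removed. With unconstrained O2
(supported via the media caps) substrates are co-consumed at their
kinetic bounds and deplete nearly simultaneously.

What the toy does *not* emulate: the full reconstruction's 645-reaction
inventory and gene complement, absolute yield values (orderings are
calibrated, magnitudes are not claimed), pH/O2-transfer physics, product
toxicity, and nitrogen-source diversity. Passing tests therefore
demonstrate correctness of the algorithms and the qualitative
thermodynamic structure, not quantitative agreement with any organism.

## Strain engineering

Edits are serializable records replayed in order: gene knockouts
evaluate boolean gene-association strings (a reaction turns off when its
expression is false under the knockout set), demethylase swaps rewrite
the slot reactions from the shared variant templates (and add/remove the
THF recycle), and product pathways install up to three reactions
(shipped recipes: PDC, cis,cis-muconate via protocatechuate
decarboxylase, acetate, glycerol) plus a coupling constraint
v_product = f·|v_substrate| in mol/mol. The PDC-accumulating strain
deletes the PDC hydrolase and the gallate escape and lifts the 15%
ratio constraint. Because that strain gains nothing from aromatics, its
dFBA pins the aromatic exchange flux each cycle to a wild-type reference
solve under the same bounds — the flux-pinning scheme for forced
funneling.

The coupling basis is mol product per mol substrate, not per mol carbon:
the breakeven arithmetic below is only consistent with a mol/mol
reading, and per-carbon yields above 1 would otherwise be impossible. A
converter between the two bases through formula carbon counts is
provided.

## Sweeps and production rate

`yield_sweep` scans the coupling fraction on a grid (default step 0.01,
range [0, 1]), runs a batch dFBA per point (defaults: 5 mmol/L
substrate, 0.05 gDW/L inoculum, dt 0.5 h, horizon 200 h — sizes chosen
to resolve the sweep shape at desk scale), and reports production rate =
final titer (g/L) ÷ time-to-exhaustion (or the horizon when substrate
remains). The rate rises with coupling until growth — the autocatalyst —
is starved, then falls: an interior optimum. The aromatic:glucose ratio
sweep runs the PDC strain across molar ratios 9:1…1:9 at fixed total
carbon and shows the same interior structure, peaking near a 3:1–3:2
aromatic excess on the toy.

## Biomass assembly and units

`build_biomass_reaction` turns mass fractions + monomer frequency maps
into precursor coefficients 1000·f·x_m/Σx_mM_m (mmol/gDW), appends GAM
ATP hydrolysis, and `scale_biomass_to_unit_mass` rescales all
non-currency coefficients by a single scalar so the drained mass is
1.000 g/mmol ± 1e-6 (a 1.08 g/mmol draft gets scalar 1/1.08; scaling is
idempotent). Klett conversions: 100 KU = 0.25 gDW/L, 1 KU = 8×10⁶
CFU/mL.

## Breakeven economics

For a product with breakeven titer T (g/L), molar mass Mp, molar yield Y
(mol/mol) from a substrate of molar mass Ms, the required substrate
concentration is (T/Mp)/Y·Ms. Molar masses are neutral free-acid/base
values from a shipped reference table. Zero yield reports an infinite
requirement; ranking is ascending with a stable name tie-break. Reported
requirements keep full precision, with a printed mode that rounds to
integers. Two rows of the published screen this module mirrors (citrate
and urea) are known not to reconstruct from their printed columns under
any yield basis — likely unrounded internal yields or nitrogen-limited
simulation effects — and are excluded from exact reproduction.

## Numerical choices and edge cases

- LP zero-snap tolerance 1e-9; residual guard 1e-6; pins must lie within
  structural bounds (validated before solving).
- Degenerate uptake at zero growth is resolved by the secondary
  objective, applied only when μ < 1e-6 to save a second LP per cycle.
- Depletion threshold for ordering readouts: 0.01 mmol/L; never-depleted
  substrates are appended last and flagged with a `None` time.
- Ties in the sweep grid resolve toward the smaller coupling fraction.
- Generation is deterministic; the only randomness hooks (kinetic
  parameter perturbation, test model generation) take explicit seeds.

## Known limitations

Absolute yields, rates and time courses from the toy network are not
comparable to any organism's data; only orderings and shapes are
designed to be meaningful. The dFBA integrator is first-order Euler —
adequate at the default step sizes but not symplectic or adaptive. The
LP layer is dense (fine below ~10³ reactions; a genome-scale model
solves in well under a second, but repeated dFBA on very large models
would benefit from a sparse backend). SBML round-trips preserve
structure but drop flux-ratio constraints, which only the native JSON
format carries.
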