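# Methods

## Model representation and I/O

A model is a plain stoichiometric network: compartments, metabolites with
optional elemental formulas and charge, reactions with flux bounds
(negative coefficient = substrate), and designated objective, biomass and
maintenance (NGAM) reactions. SBML Level 3 with the FBC package is read
and written through python-libsbml; both bound encodings found in the wild
are accepted (FBC parameter references and legacy kinetic-law
`LOWER_BOUND`/`UPPER_BOUND` locals). Gene associations are kept as opaque
rule strings; annotations, SBO terms and kinetics are ignored — none of
them affect FBA. Because SBML has no standard slot for "which reaction is
biomass/maintenance", those ids are written into the model notes and, for
third-party files, guessed from id patterns (`Biomass*`, `rxn00062`,
`ATPM`, `NGAM`); both the patterns and the result are overridable. A
simple tabular dialect (single JSON document, or a TSV pair plus header)
with human-writable equation strings (`2 co2 + 4 red -> accoa + 2 h2o`)
serves as fixture format; both dialects round-trip exactly.

An exchange reaction is one touching exactly one metabolite that lives in
the extracellular compartment; positive flux is export. The magnitude
1000 is treated as the conventional "unbounded" sentinel.

## Community assembly

Single-species models are merged by the compartment-per-species
construction: `tag_species` suffixes every non-extracellular compartment,
metabolite and reaction id with the species tag (`acetate` → `acetate_aw`)
while the shared extracellular pool keeps its ids; `merge_models` then
unifies duplicate extracellular metabolites and collapses duplicate
exchange reactions, taking the union interval of their bounds (min of
lowers, max of uppers) so the community is never more constrained than any
member. Per-species transport reactions survive tagging, so each species
exchanges with the shared pool through its own transporters.

Each species biomass reaction produces a species-biomass pseudo-metabolite
(`biomass_aw`, …). The community biomass reaction `EX_Biomass_e` drains
`fraction_i` units of each per unit of community biomass flux. This makes
the three cFBA constraints mutually consistent by construction: fixing the
community flux to `X·μ` and each species flux to `f_i·X·μ` is exactly the
steady state of that drain. The fractions are interpreted as cell-dry-
weight fractions; re-parametrizing them rewrites one reaction, no rebuild.

`apply_condition` works on a fresh copy and, in order: rebuilds the
community biomass stoichiometry from the condition's fractions; scales
every *finite* per-species bound by `f_i·X` (specific → environmental
units), leaving ±1000 sentinels untouched; pins the species and community
biomass fluxes; and applies the exchange-bound overrides. A fraction of
exactly zero shuts that species down completely (all its reactions bounded
to zero) — with zero biomass a species can carry no flux, and leaving its
sentinel-bounded catabolism open would let an absent organism work.

## FBA, feasibility, and scans

The LP `max c·v s.t. S·v = 0, lb ≤ v ≤ ub` is solved with HiGHS (via
`scipy.optimize.linprog`). Returned solutions are revalidated against the
equalities and bounds at 1e−6; a violating or failed solve surfaces as an
explicit `solver_failure` status, never as a silent zero. On every ≤8-
reaction fixture the optimum is tested against an independent brute-force
vertex-enumeration oracle at 1e−8.

A scenario is feasible iff the LP is optimal. Because all constraints are
affine in μ (biomass pins scale linearly, everything else is fixed), the
feasible set of (v, μ) is convex and the feasible μ-set at fixed ratios,
biomass and feed is an interval; the grid scan asserts this contiguity on
every ratio row. Ratio grids default to a 0.1 lattice of fractions
summing to 1.

Alternate optima make single FBA flux vectors arbitrary, so flux-level
statements are always made on sampling means, never on one LP solution.

## Flux sampling

Artificial-centering hit-and-run over the flux polytope. Warm-up points
are LP vertices from per-coordinate min/max sweeps (models ≤ 80 reactions)
plus randomized objectives; chord directions are differences between a
stored point and the running center. Numerically, the chain walks on an
orthonormal basis of the *augmented* equality system {S·v = 0, vᵢ = bound
for every pinned flux}, computed once per model (`scipy.linalg.null_space`),
with an anchor point refined by least squares and periodic re-projection
of the walker. This matters: normalizing near-degenerate chord directions
amplifies any rounding noise lying outside the subspace, and without the
projection long chains drift past the 1e−6 validity tolerance. Every
returned sample is re-checked against S·v = 0 and the bounds; the sampler
is bitwise deterministic for a given seed. Default thinning is 50 steps
per kept sample in the acceptance runs (100 in the API default); on a 1-D
polytope each chord spans the whole segment, so draws there are iid and
the uniform moments (mean, sd) are recovered within standard errors.

One caveat inherent to bound-only polytopes: internal flux distributions
include thermodynamically infeasible cycles (e.g. ethanol secreted by one
species, re-oxidized to acetate + H₂ by another, and re-reduced by the
first), whose circulation is limited only by the ±1000 transport bounds
and can dominate the sampled means of the participating *internal*
reactions. Net exchange fluxes are unaffected — every cycle cancels in
the shared-pool bookkeeping — so scenario tables and all product-level
claims are stated on exchanges. Loopless sampling is deliberately out of
scope.

## The synthetic three-species community

The toy models emulate the stoichiometric structure the analysis needs
while staying small enough for exhaustive verification. All reactions are
balanced for C, H, O, N (checked in the suite), and every catabolic lump
additionally closes the degree-of-reduction balance Σ γ·coefficient = 0
with γ = 4C + H − 2O (NH₃ reference for N).

Electron carriers are collapsed to one reduced-equivalent pool `red`
worth 2 e⁻ (formula H₂), so elemental balance doubles as electron
balance. ATP is a massless phosphoryl moiety (`atp`/`adp`, formula "P")
conserved by construction. ATP coupling lives *inside* the catabolic
lumps as configurable coefficients rather than in a standalone
electrons→ATP reaction: a free-standing reaction of that kind either
breaks elemental balance or, written as red → H₂ + ATP next to the
hydrogenase H₂ → red, closes a perpetual ATP-generating cycle. For the
same reason the ethanol-oxidation lumps yield no ATP (they supply
electrons and acetate); their ATP arrives through the acrylate and
elongation lumps. These yields are toy parameters chosen so each species
grows on its native substrate and fails without it — they are not asserted
against any measured value.

Key reactions (acetogen): CODH `CO + H₂O → CO₂ + red`; hydrogenase
`H₂ → red`; Wood–Ljungdahl lump `2 CO₂ + 4 red → acetyl + 2 H₂O`; acetate
kinase `acetyl (+1 ATP)` vs ethanol branch `acetyl + 2 red (+0.25 ATP)`;
CO-driven acid-to-alcohol reductions `acid + 2 red → alcohol + H₂O` for
C2–C6. Propionigen: acrylate lump `3 ethanol + 2 CO₂ → 2 propionate +
acetate + H₂O (+1 ATP)` (propionate:acetate 2:1 pure, continuously tunable
down by mixing in ethanol oxidation) and `ethanol + H₂O → acetate + 2 H₂`.
Elongator: `ethanol + acid_Cn → acid_Cn+2 + H₂O (+0.4 ATP)` for the
C2→C4→C6 and C3→C5→C7 series plus the same H₂-evolving oxidation.

Biomass has composition CH₁.₈O₀.₅N₀.₂ (≈24.6 g per C-mol); biomass flux is
in g h⁻¹, so the synthesis reaction consumes per gram: 1000/24.6 × (0.5
acetyl-units + 0.2 NH₃ + 0.1 red) plus the growth-associated maintenance
(GAM, default 40 mmol ATP g⁻¹); NGAM hydrolyses ATP at ≥0.3 mmol gCDW⁻¹
h⁻¹. Both defaults are ordinary anaerobe-scale values and are config
fields. Default scenario conditions mirror chemostat practice: μ = 0.02
h⁻¹ (HRT 50 h), X = 0.32 g, CO exchange confined to [−3.5, −1] mmol h⁻¹
([−3.5, −2.5] in H₂ scans), feed media export-only for organics with free
water and ammonium.

What the toy does *not* emulate: genome-scale redundancy and alternative
cofactor routes, uptake kinetics and gas–liquid transfer, thermodynamic
displacement, inhibition, and the acetogen's facultative ethanol *uptake*
(ethanol is product-only for it). Consequently the toy's odd-chain output
is limited by the partners' ATP demand rather than by electron supply, and
H₂ co-feeding — which robustly suppresses CO₂ venting in both the toy and
full-scale models — does not specifically boost odd chains here. Passing
tests therefore demonstrate the correctness of the machinery (assembly,
constraint conversion, LP, sampling, balances) and the stoichiometric
limit behaviors, not quantitative predictions for the real organisms.

The monoculture H₂-ratio scan is run in catabolic mode (μ = 0, NGAM = 0):
the zero-CO₂ endpoint at CO/H₂ = 0.5 is a pure stoichiometric limit (all
electrons fit exactly into ethanol at 1.5 mmol h⁻¹ per 3 CO + 6 H₂), and
under growth the pinned-gas version of that endpoint has no electron sink
in a lumped network. The reported trend metric is the ethanol share of
exported *carbon* (CO₂ included), which falls out of the electron balance
and is monotone; shares computed over acids + alcohols alone need not be.

## Bioprocess calculations

Dilution rate D = 1/HRT. Gas flows convert to molar rates by the ideal
gas law at an explicitly supplied temperature and pressure — there is no
hidden STP default, because percentage-level results depend on the
convention (4 mL min⁻¹ of 70 % CO gives 7.50 mmol h⁻¹ at 0 °C/101.325 kPa
but 6.87 at 25 °C). Consumption percentage is 100·uptake/inflow.
Steady-state liquid rates are D·V·(c_out − c_in). The undissociated-acid
fraction is Henderson–Hasselbalch, 1/(1 + 10^(pH−pKa)); per-acid pKa
values (acetate 4.76 … caproate 4.88) ship alongside the 4.83 average-pKa
convention. Carbon/electron balance recoveries weight amounts by carbon
number or degree of reduction; biomass uses the toy composition unless
overridden. A chemostat observation simulator (multiplicative Gaussian
noise on steady-state concentrations, default class ±5 %) closes the loop
for testing rate recovery.

## Numerical conventions

LP and sampling validity tolerance 1e−6; oracle agreement 1e−8; fraction
sums checked at 1e−9; direction components below 1e−9 treated as inactive;
chords re-centered when numerically stuck on a face. Problem sizes in the
shipped runs — ≤ 75 reactions per model, 300–1500 samples at thinning
10–50, feasibility grids of a few dozen cells — keep the full suite and
the reproduction script in the seconds-to-minutes range on one core.

## Known limitations

Sampling means carry chain autocorrelation (no convergence diagnostics
beyond seed-to-seed stability); no loopless or thermodynamic constraints;
no kinetic, proteome-cost or variable-biomass extensions; SBML support is
the FBA-relevant subset only; the CLI scan commands operate on the bundled
toy community (library calls accept any model).
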