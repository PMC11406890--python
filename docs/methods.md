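# Methods

## The model

`weanflux` predicts how complementary foods, combined with breastmilk, shift
the organic-acid output of an infant colonic microbial community. The core is
steady-state community flux balance analysis (FBA): for a community of genera
with relative abundances `a_i` (taken to equal relative biomass fractions),
per-gDW flux vectors `v_i` and a shared lumen compartment, every metabolite
balance must close, `S v = 0`, within per-reaction flux bounds. Each genus
carries a biomass pseudo-reaction normalized to produce 1 g dry weight per
unit flux, so its flux is the growth rate `mu_i` (1/h), and community growth
is defined (not fitted) as

    mu_c = sum_i a_i * mu_i.

Per-gDW exchange fluxes enter the shared lumen balances scaled by `a_i`; for
every lumen metabolite `m`,

    sum_i a_i * v_i^(ex,m) - v^(EX,m) = 0,

with the community diet exchange `v^(EX,m)` in the COBRA sign convention
(negative = uptake) and its lower bound set to minus the dietary
availability of `m` in mmol/h. Uptake is therefore capped by the diet while
secretion can always leave the system.

### Cooperative trade-off

Maximizing `mu_c` alone lets the most efficient genus absorb all growth. The
trade-off is computed in two steps: (1) maximize `mu_c` to get `mu_c_max`;
(2) among states achieving `sum_i a_i mu_i >= alpha * mu_c_max`
(`alpha` in (0, 1]), minimize `sum_i mu_i^2`. When no other constraint binds
the optimum is the closed form

    mu_i = alpha * mu_c_max * a_i / (a' a),

growth proportional to abundance. The quadratic step is solved exactly with
Wolfe's minimum-norm-point algorithm on the projection of the flux polytope
onto the `mu` coordinates: each linear-minimization oracle call is one HiGHS
LP over the full model, the corral lives in at most `n_taxa` dimensions, and
the algorithm terminates finitely. This avoids any dedicated QP dependency
while matching a dense active-set QP oracle to < 5e-6 on toy problems (see
`tests/test_solver.py`). A failure of the minor cycle to converge within the
iteration cap is reported as status `numerically-unstable` with the partial
allocation retained.

Growth rates pin only part of the flux vector; the remaining degeneracy is
resolved by a minimal-total-flux (L1) polish LP with the growth rates clamped
to within 1e-7 of the allocation, which makes all reported fluxes
deterministic. An L1 allocation objective is exposed
(`SolverConfig.step2_norm="l1"`) for sensitivity analyses only.

### Optimal alpha

The "optimal" trade-off per diet is selected by scanning a descending grid
(default 1.0, 0.9, …, 0.1) and keeping the solution at the **largest** alpha
that maximizes the number of genera growing above the negligible-growth
threshold (1e-6 /h). The scan exits early once every genus grows, since no
lower alpha can improve the count. The grid step of 0.1 bounds runtime and
keeps the selection deterministic.

### Numerical choices

* All LPs go through `scipy.optimize.linprog(method="highs")`; identical
  inputs give identical outputs, so screens are reproducible byte-for-byte
  (and consequently no statistical testing across repeats is meaningful).
* Step 2 uses a target `alpha*mu_c_max` relaxed by a relative 1e-9 slack so
  the constraint stays feasible at `alpha = 1` despite the finite precision
  of step 1; the solution invariant `mu_c >= alpha*mu_c_max - 1e-6` is
  asserted in tests.
* Solutions are validated by `check_solution`: max |S v| residual, the
  `mu_c = sum a_i mu_i` identity, and a trade-off-respected flag (no genus
  below 1e-6 /h).
* Degenerate inputs: an all-zero medium is feasible (zero growth); an
  infeasible LP is reported as status `infeasible`, and per-combination
  failures are recorded in the screen output rather than aborting the run.

## Diet construction

A diet design assigns caloric fractions to foods: 85% breastmilk with 15%
complementary food (single foods) or 7.5% + 7.5% (pairs), at 608 kcal/day
for a 6-month-old (7.6 kg at 85 kcal/kg/day; the printed total of 608 is
used as the constant). Grams per food follow from energy density; compound
fluxes in mmol/day from composition tables; then, in fixed order:

1. **unit conversion** — mmol/day ÷ 24 → mmol/h (guarded against double
   conversion);
2. **absorption** — compounds flagged as absorbed in the small intestine
   (simple sugars, amino acids, lipids, vitamins) are multiplied by 0.2; the
   absorbed-compound set is configuration (a flag per compound in the food
   table) rather than being derived from a host metabolic network;
3. **host secretions** — mucin cores and the bile acids glycocholate and
   taurocholate are added at 1 mmol/h each (the absorbed set and secretion
   set are required to be disjoint, which makes steps 2 and 3 commute);
4. **medium completion** — for each genus alone, an LP finds the minimal
   total supplemental flux (mmol/h) letting it reach the floor growth rate
   of 0.01 /h; the element-wise maximum of the per-genus supplements is
   added. Completion is solved per genus and unioned (rather than jointly)
   so a supplement needed by one genus is never hidden by another's surplus;
   the post-condition is re-verified by single-genus FBA. Completion never
   removes or reduces an existing flux.

## The synthetic scenario and what it does (not) show

The generator emulates the study design — a ~10-genus weaning-infant
community spanning >10% and 1–3% abundances plus one sub-1% genus (removed
by the 1% filter), a breastmilk item, and 12 complementary foods across
fruit/vegetable/cereal/legume/animal-protein/dairy groups — with composition
jitter of ±8% drawn from a seeded generator. Defaults: 10 retained genera,
12 foods, 66 pairs, seed 7.

Each genus is a fermentation archetype with a **private** substrate (e.g.
milk oligosaccharides for *Bifidobacterium*, pectin for *Bacteroides*,
amino acids for the proteolytic BCFA producers) and a **private** vitamin
cofactor. This is the key design decision: with private resources the set of
achievable growth vectors is a box, every genus grows at every alpha, the
alpha scan settles at 1.0, each genus ferments its substrate completely, and
community metabolite totals reduce to stoichiometry × substrate supply. The
generator exploits this to compute expected SCFA/BCFA totals and
increase/decrease/no-change directions for all 78 combinations with
independent arithmetic (no solver), and asserts well-posedness: every genus
clears the completion floor on every diet, no cofactor is limiting, and no
expected variation sits within 0.01 percentage points of the ±1% band edge.
Breastmilk carries every substrate and vitamin at levels that keep all
genera above the 0.01 /h floor on any 85%-milk diet, so completion is the
identity on scenario diets; a cofactor-stripped milk diet is provided
separately to exercise completion.

What the scenario deliberately lacks, and hence what passing tests do *not*
demonstrate about real data: substrate competition between genera,
cross-feeding (available behind an off-by-default flag, without ground
truth), realistic genome-derived stoichiometry, alternative metabolic
routes, sample-to-sample abundance variation, and any situation where the
alpha scan must settle below 1.0 (that regime is covered by hand-built toy
communities in the solver tests instead). Product stoichiometries are chosen
so acetate > propionate > butyrate on milk-like media, qualitatively
matching infant colonic physiology; the exact values are free parameters.

## Screening and classification

Community production of a metabolite is aggregated as
`v_tot^m = sum_i a_i * max(v_i^(ex,m), 0)` — the positive-part ("producers")
mode, so consumers do not offset producers; the plain weighted sum ("net")
is available via configuration. Total SCFA = acetate + propionate +
butyrate; total BCFA = isobutyrate + isovalerate. Each combination is
expressed as signed percent variation versus the breastmilk-only control
(undefined when the control flux is zero, rendered `NA`) and classified
increase / decrease / no-change with a symmetric ±1% band (the band is a
package choice; reports store full precision and print one decimal). Results
are ordered by absolute total SCFA flux, descending. Genus growth-rate
variations are reported the same way, with genera below 1e-6 /h suppressed.
An infant-formula control can be enabled as a second fraction-1.0
"food". After the 1% abundance filter the retained profile is renormalized
to sum to 1 by default (`renormalize=false` available for sensitivity runs);
with abundance-proportional allocation this only rescales growth rates, and
the scenario's metabolite totals are invariant to it.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| abundance filter threshold | 0.01 | fraction | drop low-abundance genera that add cost but little metabolite mass |
| total energy | 608 | kcal/day | 6-month-old intake |
| milk caloric fraction | 0.85 | — | breastmilk share at 6 months |
| absorption factor | 0.2 | — | fraction of absorbable compounds reaching the colon |
| host secretions | 1 each | mmol/h | mucin + two bile acids |
| completion floor | 0.01 | 1/h | minimum viable growth per genus |
| negligible growth | 1e-6 | 1/h | threshold for "not growing" in the alpha scan |
| alpha grid | 1.0…0.1 step 0.1 | — | trade-off scan |
| no-change band | ±1 | % | classification dead-zone |
| default flux bounds | ±1000 | mmol/(gDW·h) | conventional "unbounded" |

## Pan-model pooling

Genus pan models are the union of strain reconstructions: duplicate
reactions (same id and identical stoichiometry) merge with bounds widened to
the interval hull, so pooling never shrinks the feasible set; the same id
with different stoichiometry is a hard conflict, not a silent rename. The
pan biomass reaction is taken from the first strain in input order — a
deterministic choice among reasonable alternatives (averaging compositions,
largest-genome strain); strain-internal compartments are renamed to the pan
taxon.

## Known limitations

* The solver scales to tens of genera, not hundreds: the polish LP doubles
  the variable count and the alpha scan multiplies solve counts.
* Aggregated production is per gram of community dry weight per hour;
  translating to concentrations would need transit time and biomass density,
  which are out of scope.
* The analysis scripts use problem sizes of 10 genera × 79 combinations,
  matching the generated scenario; the numbers they print are
  scenario-specific and carry no claim about real foods.
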