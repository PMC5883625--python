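# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `pmaflux`, in the order a user meets them.

## The reduced central-carbon model

The route scan requires a stoichiometric model of *A. pullulans* central
carbon metabolism. Genome-scale reconstructions of this organism are not
redistributable here, so the package ships an explicit reduced model
(`pmaflux/data/apullulans_core.json`, also constructed programmatically by
`build_reduced_model()`). Design principles:

* **Three compartments** — cytosol, mitochondrion, extracellular — with
  explicit transport for pyruvate, malate, oxaloacetate, citrate, acetyl
  units and fumarate. The reductive malate branch is purely cytosolic
  (pyruvate carboxylase, cytosolic MDH); the classical TCA reactions are
  mitochondrial isozymes, and a distinct cytosolic aconitase feeds the
  glyoxylate shunt.
* **Lumping** — glycolysis is a single reaction
  (glucose → 2 pyruvate + 2 ATP + 2 NADH; fructose identical), sucrose
  hydrolysis is carbon- and energy-neutral
  (sucrose + H2O → glucose + fructose, no ATP), acetyl-/succinyl-CoA are
  represented by their acyl moieties, and ATP/NADH/FADH2 are pooled
  bookkeeping species with empty formulas. Oxidative phosphorylation uses
  P/O = 1.5 (NADH) and 1.0 (FADH2); an ATP maintenance drain exists but is
  not enforced (lower bound 0), so zero-uptake states remain feasible.
* **Balancing** — carbon is balanced strictly on every internal reaction
  (`carbon_balance_report` asserts imbalance 0, sign convention: positive =
  net carbon created); hydrogen and oxygen are only checked modulo free
  water and protons, because lumped reactions cannot be proton-exact
  without inventing detail.
* **Products and valves** — PMA synthesis is
  malate + 1 ATP → extracellular malyl residue (C4H4O4) + H2O; biomass is
  13 pyruvate + 30 ATP per gDW (≈ 39 mmol C/gDW, a typical cell-carbon
  density), labeled in gDW/h. Three valves keep the scan protocol feasible
  on a small network where a genome-scale model would use its breadth:
  pyruvate overflow secretion, cytosolic malic enzyme
  (malate → pyruvate + CO2 + NADH) as the malate overflow, a lumped
  purine-nucleotide-cycle fumarate source (OAA + ATP → fumarate) plus
  succinate secretion for glyoxylate-shunt operation when succinate
  dehydrogenase is silenced. CO2 exchange is reversible so that pyruvate
  carboxylase can draw on the dissolved CO2/bicarbonate pool.
* **Default bounds** — glucose uptake 10 mmol/gDW/h; sucrose disabled by
  default and opened at 5 mmol/gDW/h (the hexose equivalent) for
  carbon-matched comparisons; O2 uptake 15 mmol/gDW/h, a typical aerobic
  fungal respiratory capacity. The finite O2 bound is what separates the
  NADH-heavy oxidative route from the NADH-consuming reductive route on a
  network this small.

Every lumping choice is repeated in the model file's `notes` array so the
fixture is self-describing.

## FBA and the brute-force oracle

`solve_fba` is a thin contract over linear programming (HiGHS via
`scipy.optimize.linprog`): maximize one flux subject to S·v = 0 and box
bounds, with overrides that *replace* declared bounds (a scan must fix
fluxes outside their default range). Feasibility is honored to 1e−9
(relative to the largest coefficient); test assertions use 1e−6. Only the
optimal objective value is guaranteed reproducible — flux vectors at
degenerate optima are returned as found and flagged. Infeasible and
unbounded statuses are reported faithfully; scan cells that are infeasible
carry a NaN marker, never 0, because "no feasible state" and "PMA = 0" are
different findings.

`brute_force_optimum` enumerates polytope vertices (every choice of
bound-fixed coordinate subset, remaining fluxes solved by least squares,
feasibility-filtered). It is exponential, restricted to ≤ 12 reactions, and
deliberately shares no code with the LP path; agreement to 1e−6 on 200
random networks is part of the acceptance checks.

## The route-scan protocol

For each route — oxidative TCA (oxoglutarate dehydrogenase, aconitate
hydratase, fumarase, succinate dehydrogenase, succinate-CoA ligase),
reductive TCA (cytosolic malate dehydrogenase), glyoxylate shunt (fumarase,
isocitrate lyase, malate synthase) — the scan fixes all reactions of the
scanned route to one common imposed flux (flux coupling: one scalar per
grid point), fixes the other two routes' reactions to 0, fixes the
mitochondrial MDH to 0 (the reductive branch is cytosolic by assumption),
fixes biomass to the grid's growth value, and maximizes PMA synthesis.
Interpretation choices, each deliberate:

* "Constrained from 0 to X" is read as an equality grid scan — each grid
  point *fixes* the route flux — because the protocol fixes the competing
  routes with the same verb and plots the optimum as a function of route
  flux.
* Fumarase belongs to both the oxidative and the glyoxylate lists; when it
  is part of the scanned route the scanned constraint wins (otherwise the
  glyoxylate scan is infeasible for any positive flux).
* "Glyoxylate lyase" maps to malate synthase (the glyoxylate-consuming,
  malate-forming step).
* Growth is fixed per grid point (not merely capped): the surfaces plot
  the optimum against both axes.
* Default grid: 71 flux points on [0, 140] (step 2) × 21 growth points on
  [0, 1] (step 0.05); both configurable. The full three-route default scan
  is ~4,500 LPs and runs in seconds.

`summarize` reports, per route, the grid optimum, the arg-max flux (ties
toward the smallest flux), the cutoff — the smallest scanned flux at or
above the arg-max whose best-over-growth optimum is 0 or infeasible — and
the optimum at zero growth. On the packaged model the glucose defaults give
optima 14 / 8 / 4 mmol/gDW/h and cutoffs 50 / 6 / 6 for the reductive /
glyoxylate / oxidative routes: the reductive route wins on both optimum and
robustness, and sucrose at carbon-matched uptake reproduces the surfaces
exactly because its hydrolysis is carbon- and energy-neutral. These numbers
characterize the reduced fixture; absolute genome-scale values differ, but
the ordering, the growth competition (optimum non-increasing in imposed
growth), the concavity of the optimum in route flux (a parametric-LP
property) and the existence of collapse fluxes are the model-independent
structure the tests assert.

## Metabolome statistics

* **Normalization** divides each sample column by the geometric mean of its
  internal-standard intensities; standards stay in the table but are
  excluded from statistics. The whole pipeline is equivariant to rescaling
  any metabolite row (tested).
* **Unit-variance scaling** centers each metabolite and divides by its
  (n−1) standard deviation; zero-variance rows are dropped with a warning.
* **PCA** is the SVD of the scaled matrix; component signs are fixed by
  making the largest-magnitude loading positive.
* **PLS-DA VIP** uses NIPALS PLS1 on the scaled matrix against the centered
  class indicator (2 components by default, truncated at rank with a
  warning). VIP_j = sqrt(p · Σ_a SSY_a w_aj² / Σ_a SSY_a), so
  Σ_j VIP_j² = p identically. Orthogonal signal correction is deliberately
  omitted: with a single response the discriminant subspace is the same and
  VIP is well defined for plain PLS-DA.
* **Tests** are two-sided pooled-variance Student's t on log-transformed
  *normalized* (not UV-scaled) intensities — UV scaling would erase the
  mean differences being tested. Zero pooled variance yields t = 0, p = 1
  (conservative). BH-FDR is applied within each contrast, not pooled
  across contrasts.
* **Fold changes** are log2 ratios of group means of normalized raw
  intensities (the control group mean defines 1.00).
* **Selection**: p < 0.05 ∧ VIP > 1 ∧ q ≤ 0.05, all thresholds exposed as
  arguments.
* **Clustering** is Ward linkage on Euclidean distances of scaled profiles
  (scipy), with a naive O(n³) Lance–Williams oracle in the test suite.

## Synthetic data

The metabolome generator draws
intensity = exp(Normal(baseline + effect·ln 2, σ)) × injection factor, with
per-metabolite baselines ~ Normal(12, 1.5) on the natural-log scale
(typical GC–MS peak areas), replicate noise σ = 0.5, lognormal injection
factors (σ = 0.2) removed exactly by the internal standards, and effects
planted on the log2 scale so the ground truth of every fold change is exact
by construction. The default design is 2 carbon sources × 2 timepoints ×
6 replicates, 81 metabolites + 2 standards. For power experiments the
default plants |log2 FC| = 2 on 24 of 81 metabolites (~30%, the fraction of
the metabolome typically found differential in carbon-source comparisons
of this organism), alternating sign. Under these conditions the full
selection rule recovers ≈ 94% of planted effects and selects < 0.1% of
metabolites on null tables — comfortably inside the ≥ 90% / ≤ 5% targets.
What the generator does *not* emulate: correlated metabolite blocks,
heteroscedastic peak-area noise, missingness/censoring at the detection
limit, and drift within batches — so passing tests demonstrate correctness
of the statistics, not robustness to those real-data pathologies.

The time-course generator uses the closed-form logistic biomass solution
with Luedeking–Piret product kinetics (growth-associated α = 0.3 g/g,
non-growth β = 0.025 g/g/h, μ = 0.15 1/h, Xmax = 20 g/L, 95 g/L initial
sugar, 60 h horizon — a realistic batch on sucrose-rich feedstock) and
yield-coupled substrate draw-down; with noise off, the quantitation
operations recover planted yields and productivities exactly. Toy-network
generation always includes a linear uptake→…→secretion chain so every
network has a nonzero optimum, and every reaction is carbon-balanced by
construction.

Each generator derives its stream as `SeedSequence([seed, generator_id])`,
so adding generators never perturbs existing outputs for a given seed.

## Numerical conventions and degenerate inputs

Comparisons against printed values use round-half-up at the printed
precision (`round_half_up`); raw values are carried at full precision. The
polymer/monomer factor is always an explicit argument — published
PMA/MA pairs are not mutually consistent under any single factor, so the
package never infers it from data. Empty models are valid and trivially
optimal at 0; empty reaction lists, single-cell scan grids, all-zero grids,
constant metabolite rows, single p-values and identical groups all have
defined, tested behavior.

## Known limitations

Absolute scan optima are fixture-dependent; OPLS-DA's orthogonal filtering
is omitted; t tests assume equal variances (the classical Student form);
yields are computed per substrate *consumed*, which published tables do not
always report; and the CLI exposes only flat CSV/JSON outputs (no surface
plotting).
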