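# Methods

## Model representation and preparation

A model is a list of metabolites (id, compartment), reactions (stoichiometry,
bounds, GPR rule, subsystem), a gene list, and a designated biomass reaction.
A reaction is an *exchange* iff exactly one metabolite has a nonzero
coefficient; negative exchange flux is uptake, positive is secretion. The
JSON dialect mirrors the common COBRA JSON schema so fixtures are
hand-writable and readable by cobrapy; SBML Level 3 goes through
cobrapy/libSBML. The reader is tolerant: genes referenced by GPRs but missing
from the gene list are appended with a warning, and the reader reports
whatever counts the file contains without reconciling them against any other
source.

`prepare_template` puts the template into the state every extraction assumes:
all exchanges opened to ±1000, internal bounds reset to ±1000 according to
reversibility, and the biomass lower bound fixed at 1 h⁻¹ (flux units are
mmol·gDW⁻¹·h⁻¹ in genome-scale models, dimensionless in toys). The biomass
rate is nominal — only relative growth is ever reported — and a template
that cannot reach it is rejected outright.

## Optimization layer

All LPs and MILPs are solved with scipy's HiGHS backend, which is
deterministic for a fixed problem, so identical inputs give identical models
without solver-level seeding. Numerical policy: flux support uses
|v| > 1e-6; flux consistency uses eps = 1e-4; parsimonious FBA fixes growth
inside [(1 − 1e-9)·μ*, μ*] rather than at an exact equality to avoid
numerical infeasibility; MILPs run with zero relative gap (problem sizes here
are small). Σ|v| objectives are linearized by splitting each reaction into
irreversible forward/backward parts.

Flux consistency is implemented twice by design: a block algorithm (repeated
LPs maximizing auxiliary variables z ≤ v over the unconfirmed set, both
signs, with a per-reaction fall-back) used everywhere, and a brute-force
per-reaction maximize/minimize oracle used only in tests and the acceptance
script. Degenerate alternative optima in pFBA and LP10 are permitted; the
test fixtures are engineered so the optima checked are unique (e.g. parallel
routes of unequal length, and the toy network's spare drain closed in the
minimal-support check).

## Extraction methods

All six methods consume the same per-sample reaction activity levels (RAL)
and share the activity cutoff 5 ln 2. The biomass reaction is pinned above
the cutoff, so it lands in every high-activity/core set; INIT instead gives
it a large positive weight (2·max|w| + 1 by default). Method-specific
choices, all exposed in `ExtractionConfig`:

- **GIMME** penalizes flux through reactions with RAL below the cutoff
  (penalty = cutoff − RAL) subject to ≥ 90% of maximal growth, then keeps
  active reactions, unscored reactions, all exchanges, biomass, and any
  penalized reaction that still carries flux.
- **iMAT** (eps = 1 flux unit) maximizes the count of high-activity
  reactions forced to |v| ≥ eps plus low-activity reactions forced to zero.
  Retention drops zero-flux low-activity reactions and then restores flux
  consistency; a classification-based retention variant was considered and
  rejected as redundant with the consistency pass at these scales.
- **INIT** weights each scored reaction by RAL − cutoff and maximizes the
  weighted sum over binary keep indicators (keep ⇔ |v| ≥ eps, drop ⇔ v = 0),
  with strict steady state — no net-production relaxation, because the
  template already enforces biomass production.
- **FASTCORE** (eps = 1e-4) runs on the flux-consistent part of the
  template with core = active reactions ∪ biomass, alternating LP7
  (activate core) and LP10 (minimal L1 of non-core flux) with bound flips
  for reversible core reactions; inconsistent core members are dropped with
  a warning.
- **MBA** protects a high-confidence core (RAL ≥ cutoff) absolutely and a
  medium-confidence core (≥ half the cutoff by default) through the rule
  |lost ∩ medium| ≤ 0.5·|lost \ medium| per removal. One random ordering per
  model by default — at one model per sample the original
  thousand-orderings protocol is disproportionate — with >50% keep-voting
  across orderings when more are requested; eps = ∞ demotes the medium core
  entirely (the documented limit case).
- **mCADRE** ranks non-core reactions by expression evidence
  min(RAL/cutoff, 1) (unscored → 0) then connectivity evidence (mean
  evidence over stoichiometric neighbors), and removes them in order unless
  removal breaks the growth requirement or makes any core reaction
  inconsistent — such removals are *skipped*, never fatal.

Every extraction records wall time, prunes orphan genes and metabolites, and
flags the model non-functional if it cannot reach the biomass lower bound;
non-functional models are excluded from all downstream summaries.

## Tasks and functional accuracy

A task closes **all** exchange reactions (both directions), relaxes the
biomass lower bound to zero — otherwise every task would be infeasible by
construction, a step the task convention leaves implicit — and appends
temporary uptake reactions for inputs and demand reactions for outputs with
the task's bounds. Feasibility is a plain LP; the caller's model is never
mutated. Tasks referencing compartments a model lacks are remapped to the
cytoplasm; tasks referencing absent metabolites are flagged unresolvable and
score 0.

Task→reaction attribution runs once on the template: minimize Σ|v| subject
to the task bounds (no growth term; for unit-lower-bound demands this is
equivalent to minimal flux at forced unit demand) and keep the
gene-associated support. The inferred task score is the mean RAL over those
reactions (gene-associated only — RAL is undefined for the rest; a toggle
admits the full support), binarized at 5 ln 2 with ties counting as active.
Predicted scores are per-model task feasibility. Functional accuracy is the
normalized Hamming distance between inferred and predicted vectors; the
template baseline scores the all-ones prediction (it performs every filtered
task) against each sample's inferred vector.

## PCA and factor attribution

Model × feature matrices (binary reaction presence, binary task feasibility,
or fluxes) are column-standardized to zero mean and unit variance —
binary columns included, accepting the statistical quirk — after dropping
zero-variance columns (reported; a pseudo-count alternative was rejected as
it distorts distances). PCA is a singular value decomposition with PC signs
fixed by making each PC's largest-magnitude loading positive, so score
tables are reproducible. A factor's share of a PC's score variance is the
maximum over all orderings of its levels of the squared Pearson correlation
between scores and integer-coded labels; the permutation count is capped
(10 levels) with an explicit error rather than silent sampling. Hierarchical
clustering uses average linkage with Jaccard distance for binary matrices
and Euclidean otherwise.

## Synthetic data

The generator emulates the study conditions end to end. The template has
`n_modules` precursor slots, each with `redundancy` parallel routes of
unequal length (2 and 3 reactions by default, making parsimonious optima
unique) from an exchanged substrate to a biomass precursor; biomass consumes
every precursor, so each context's active route set supports growth. Even
slots switch routes with life stage, odd slots with feed group. Expression
is gene-level (no transcript mapping, since scoring collapses to model genes
first): base 50 CPM-like units, ×10 for genes of context-active routes,
optional lognormal noise. The design is unbalanced (4 freshwater vs 3
saltwater samples per feed cell, 28 samples) echoing the 112/96-style
imbalance of real cohorts.

Three accessory secretion branches per slot give the extraction methods
genuinely different material, the way accessory pathways do in real
networks: a constant *medium* gene (0.68× base → score ≈ 0.75 cutoff,
protected only by MBA's medium core), a *near-threshold* gene (0.93× base →
score ≈ 0.95 cutoff, additionally inside mCADRE's evidence core), and an
*unannotated* branch without GPR (kept by GIMME/iMAT/INIT, which retain
unscored reactions, dropped by the core-based methods). The branch levels
were chosen so that accessory genes stay under 25% of pooled values, keeping
the pooled-floor threshold at the base level.

The reference design uses **zero noise**, a deliberate choice: the
90th-percentile threshold rule makes above-threshold calls tie-based
whenever a gene is high in more than 10% of samples — at zero noise a high
sample sits exactly at its threshold, scores exactly 5 ln 2, and the ≥ rule
counts it active. Parameter recovery (≥ 90% of context-active reactions
recovered, ≥ 90% of expression-inactive module reactions removed by
GIMME/iMAT/INIT) is therefore exact at zero noise and necessarily degrades
with noise; the context-vs-template distance comparison is robust to
moderate noise and is additionally tested on noisy cohorts. Ground-truth
performable tasks are defined by parsimonious attribution (a task counts as
performable in a context when the route its template attribution uses is
active), which keeps inferred scores and ground truth exactly consistent at
zero noise.

## Validation scales

Tests and the acceptance script run at desk scale by the package's own
choice: the fixed 9-reaction toy network for hand-derived LP values and
enumeration oracles (≤ 3^7 activation patterns), the 53-reaction standard
synthetic template with 28 samples for recovery and distance checks, and a
12-sample, 4-method cohort for factor attribution. What passing shows about
real data is limited in the usual ways: the generator has clean module
structure, no transcript-level noise sources, no compartment complexity
beyond cytosol/extracellular, and task lists that probe planted pathways
rather than curated biochemistry.

## Known limitations

- RAL uses the maximum gene score over a reaction's flat gene set (the
  field's literal convention); a GPR-aware min/max mode exists but is off by
  default, and AND-complexes are therefore scored optimistically.
- MILP time limits return the incumbent with a `timeout` status flag; at
  the scales shipped here timeouts do not occur, so that path is exercised
  only structurally.
- The MBA voting step can in principle return a non-growing majority model;
  consistency is restored afterwards and the functional flag catches the
  rest.
- Binary-matrix standardization before PCA inflates the influence of rare
  presence/absence differences; this follows the stated convention rather
  than a statistical optimum.
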