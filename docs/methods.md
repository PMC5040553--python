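# Methods

`heptflux` reimplements, as a tested library, the quantitative analysis
chain used in studies of medium-chain carboxylic-acid stress in *E. coli*:
specific-rate estimation from batch cultures, constraint-based flux analysis
of a small central-carbon network, maintenance-energy estimation from
cofactor balances, one-color microarray fold-change analysis, and the
phenotype quantifications (glutamate-decarboxylase activity, acid-challenge
survival, whole-cell biotransformation yield). A synthetic-data module
replaces the wet-lab inputs so the whole chain is testable end to end.

## The metabolic network

The bundled model (`ecoli_core_heptanoate`) is a central-carbon
reconstruction with exactly 57 metabolites (48 internal, 9 external boundary
species) and 58 reactions: glycolysis/gluconeogenesis (including a
PTS-type phosphorylation route), the pentose-phosphate pathway, the TCA
cycle with the glyoxylate shunt and a fumarate-reductase branch,
anaplerosis (PEP carboxylase, PEP carboxykinase, both malic enzymes),
acetate (phosphotransacetylase/acetate kinase and pyruvate oxidase),
lactate and ethanol fermentation, nitrogen assimilation through glutamate
dehydrogenase, a two-branch respiratory chain, both transhydrogenases, a
dedicated ATP-hydrolysis (maintenance) reaction, a lumped biomass reaction,
and 9 exchange reactions (glucose, O2, CO2, acetate, lactate, ethanol,
ammonium, water, biomass).

Choices that matter:

* **Sign convention.** Exchange reactions are written `internal <=>
  external`; uptake is negative flux, secretion positive. This is the
  standard constraint-based convention and is the one place it is defined.
* **P/O ratios.** Oxidative phosphorylation is lumped: the
  proton-pumping NADH branch yields 2 ATP per NADH, the flavoprotein branch
  1 ATP per FADH2. A non-phosphorylating NADH dehydrogenase (no ATP) is
  included, as in *E. coli*. The ratios are written into the model file and
  can be edited there.
* **Biomass.** Precursor demands follow the familiar core-model
  coefficients (mmol per gDCW: 1.496 3-phosphoglycerate, 3.748 acetyl-CoA,
  1.787 oxaloacetate, 4.941 glutamate with 4.118 2-oxoglutarate returned,
  etc.), with a growth-associated ATP requirement (GAM) of 45 mmol·gDCW⁻¹.
  The phosphate bound in sugar-phosphate precursors is returned as
  orthophosphate because the model carries no phosphate exchange; without
  this the phosphorus moiety would be conserved and growth infeasible.
* **Default bounds.** Glucose uptake is capped at 10 mmol·gDCW⁻¹·h⁻¹;
  fermentation products are secretion-only by default (capacity constraints
  override bounds where rates were measured); oxygen and ammonium uptake
  are unbounded (aerobic shake flasks, rich nitrogen).

The reaction inventory of the original published network is not public;
this reconstruction reproduces its size and scope, not necessarily its
exact reaction list. Model files are a TSV pair (metabolites table +
reactions table with textual equations) or equivalent JSON; SBML is out of
scope.

## Specific rates

During unlimited exponential growth, X(t) = X0·e^{μt} and a species
exchanged at constant biomass-specific rate q follows
C(t) = C0 + (q·X0/μ)(e^{μt} − 1). μ is the least-squares slope of ln OD600
against time over a user-declared exponential window (at least 3 points,
all OD positive); q is fitted to the closed form by linear least squares
(linear in C0 and q once μ is known), with X0 taken from the log-linear OD
fit at the window start times a dry-weight conversion (default
0.4 gDCW·L⁻¹ per OD600 unit, overridable — instrument-specific and not
universal). Declining cultures are reported with their fitted (negative) μ
and flagged, never clamped. Whether rates should be fitted through the
biomass integral or two-point differences is immaterial on clean data —
both coincide with the closed form — and the closed-form fit is the
testable choice.

## Flux balance analysis

`solve_fba` maximizes the biomass flux subject to S·v = 0 over internal
metabolites and bounds, using HiGHS through `scipy.optimize.linprog`.
Measured rates enter as two-sided capacity constraints (rate ± absolute
tolerance) on exchange reactions: measured consumption and production
rates are treated as fixed capacities, not loose bounds. Growth LPs are
routinely degenerate, so a secondary LP minimizes Σ|v| at the fixed
optimum; the returned flux map is therefore unique and bitwise
reproducible. Infeasible or unbounded problems return a status and no flux
map. Flux distributions can be reported raw or normalized so the glucose
exchange has magnitude 100 (mol per 100 mol glucose).

## Maintenance energy

`cofactor_balance` books each carrier's (ATP, NADH, NADPH, FADH2)
production and consumption across all reactions of a flux distribution,
with a per-reaction breakdown. Because carriers are balanced internal
metabolites, production equals consumption at steady state; the breakdown
is the informative part.

Non-growth-associated maintenance (NGAM) is the ATP left over after
biosynthesis and growth: ngam = ATP production − metabolic consumption −
gam·μ, where metabolic consumption excludes the biomass reaction (its ATP
is the growth-associated term gam·μ, default gam = 45 matching the biomass
reaction) and the dedicated hydrolysis reaction (whose flux is the estimate
itself). Negative estimates are reported and flagged.

Because the model contains a non-phosphorylating respiratory branch, the
ATP surplus at measured rates is degenerate in a growth-maximizing LP —
redox can be discarded without making ATP. `estimate_maintenance_from_rates`
therefore uses the classic excess-ATP construction: growth is pinned to the
measured μ, measured exchanges are fixed, and the dedicated hydrolysis flux
is maximized; the surplus ATP the network can form at full coupling is the
maintenance energy. This is an upper-bound-style estimator and is best read
comparatively (stressed vs control), which is how the package's tests use
it: the stressed phenotype (doubled glucose uptake, overflow acetate, halved
growth) always shows the larger estimate.

## Microarray fold changes

The one-color pipeline runs in a fixed order, enforced by
`process_expression`: floor raw intensities at 5.0 → divide each chip by
its median (per-chip median becomes exactly 1) → keep probes flagged
present (P) with intensity ≥ local background in every sample of the
contrast → average normalized intensities over replicates and aggregate
probes to genes by mean → fold = mean(test)/mean(control) → call up if
fold ≥ 2, down if fold ≤ 0.5 (both inclusive). No multiple-testing
correction is applied: differential expression here is a pure fold-change
criterion, as in the GeneSpring-era workflow this reproduces.

Orientation: ratios are test over control (stressed over unstressed), so a
stress induction gives a positive log2 ratio; the log2 ratio is computed
as log2(mean test) − log2(mean control), which makes the contrast-swap
anti-symmetry exact in floating point. A reader for GEO series-matrix
files is provided; that format carries processed values without flags or
background, so probes default to P with zero background, and the
sample-to-condition grouping must be supplied explicitly rather than
guessed.

## Phenotype assays

* **GadA/B activity.** The GABase-coupled readout forms one NADPH per
  GABA; NADPH from ΔA340 by Beer–Lambert with ε = 6220 M⁻¹cm⁻¹ (standard
  NADPH value, configurable). Specific activity is reported as
  nmol GABA·min⁻¹·mg protein⁻¹ over the decarboxylase incubation (default
  60 min). Blank-above-signal readings give negative activities, flagged.
* **Survival.** survival % = 100 · CFU(post)/CFU(pre), on
  dilution-corrected counts.
* **GC/MS quantification.** conc = (area/IS area)·IS conc / response
  factor against a palmitic-acid internal standard; response factors
  default to 1.0 unless a calibration is supplied.
* **Conversion yield.** 100 · product/substrate on a molar basis; the
  emulated pathway cleaves one substrate molecule into one molecule of each
  product, so either product's yield is product over substrate loading.
  Product-formation rates are least-squares slopes over a declared interval.

## Synthetic data

Every generator inverts its estimator at zero noise, and all randomness
derives from a single seed (distinct fixed stream tags per generator, so
outputs are independent of call order). Noise models are multiplicative
log-normal (unit median) for OD, concentrations, intensities, absorbances
and peak areas — typical of these instruments — and Poisson for plate
counts (switchable to expectations for exact-inversion tests).

The default scenario pack mirrors a two-strain design: a stress-sensitive
strain (μ0 = 0.65 h⁻¹, growth inhibition 0.117 h⁻¹ per mM acid, i.e.
roughly half-maximal at 3 mM) and a tolerant strain (μ0 = 0.70 h⁻¹,
0.042 h⁻¹·mM⁻¹, half-maximal near 10 mM), at 0–10 mM acid. The stressed
sensitive strain doubles its glucose uptake (−8 → −16 mmol·gDCW⁻¹·h⁻¹)
and raises acetate production 18-fold; the tolerant strain carries the
glutamate-decarboxylase expression response in its planted log2 effects.
Time courses default to 7 h at 15-min sampling from OD 0.1 with 55.5 mM
(10 g/L) glucose: a full exponential phase consuming ~46 mM, chosen so
concentration changes are large against 5%-CV measurement noise (a
4-hour course leaves the consumed-glucose signal of ~6 mM buried in noise
on the 55 mM baseline, and no estimator could meet the recovery targets).
Genes with planted expression effects are assigned bright baselines so
that scaling them never moves a chip median; this is what makes zero-noise
recovery of planted log2 effects exact rather than approximate.

What the generators deliberately do not emulate: substrate-limitation and
stationary-phase kinetics (growth is purely exponential inside the declared
window), probe-level sequence effects and spatial artifacts on arrays,
chromatographic drift, and mechanistic regulation of the acid-resistance
systems. Passing tests therefore demonstrate correctness of the estimators
under the stated statistical structure, not robustness to every real-data
pathology.

## Numerical choices

* Steady state is enforced as equality in the LP; optimal solutions are
  verified to satisfy max |S·v| < 1e-9 and all bounds to 1e-9.
* LP determinism comes from the min-Σ|v| secondary objective; if the
  secondary solve fails the primary vertex is returned.
* The LP oracle used in tests enumerates pin/free assignments (3^n for
  n ≤ 6 reactions) and compares objectives to 1e-8.
* Degenerate inputs: empty model files, zero chip medians, zero reference
  fluxes, zero protein or substrate, and inverted thresholds all raise
  errors naming the offending quantity; fold-change records are impossible
  to divide by zero after flooring.

## Known limitations

* The bundled network is a didactic-scale reconstruction; absolute flux
  values and the excess-ATP maintenance estimates are comparative tools,
  not genome-scale predictions.
* The GEO reader handles the single-table series-matrix layout only.
* Bradford calibration assumes linearity over the standard range.
* No kinetic (Monod/inhibition) growth models; rate estimation requires a
  user-declared exponential window.
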