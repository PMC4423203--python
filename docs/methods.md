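# Methods

This note documents the models and conventions implemented in `hyperdom`,
the choices made where the field's practice leaves room, and what the
synthetic-data tests do and do not demonstrate.

## Data model and inclusion protocol

The unit of record is a stem observed across plot censuses: diameter `d_cm`
at a point of measurement `pom_m`, an alive flag, and a census date in
decimal years (ISO dates are converted on read; intervals are simple date
differences). Structural invariants are enforced at load time: one
observation per (stem, census), strictly increasing dates within a stem,
positive diameters on live records, no live record after a dead one, and
referential integrity to plots and taxa. Morphospecies and any taxon not
resolved to species rank are treated as unidentified (at genus, family or
no rank).

Analysis plots are old-growth terra firme below 500 m elevation, excluding
cerrado; stems enter at the 10-cm diameter census threshold (a stem whose
first live diameter is below 10 cm is dropped; later shrinkage below 10 cm
is retained, as in real census data). An optional per-plot minimum fraction
of species-identified stems (0.80) reproduces the identification-sensitivity
subset. Filtering is idempotent.

Wood density is assigned per stem by first match species → genus → family →
plot mean, where the plot mean is the *stem-weighted* mean over the plot's
already-resolved stems (the convention had to be chosen; species-weighted
means differ negligibly in practice but are not what a field-sheet workflow
computes). A plot with no resolvable stem falls back to the dataset mean
with a warning. Provenance is recorded per stem and the provenance histogram
always sums to the stem count.

Regions are the five Amazon substrate regions (Guiana Shield, Brazilian
Shield, East-Central, Northwestern, Southwestern). Plots may carry explicit
labels; the label `W` (Western Amazonia) is split at −8° latitude — strictly
south goes Southwestern, the boundary itself Northwestern. Unlabelled plots
fall through to a crude rectangular boundary table that users should replace
with their own delineation; synthetic data always carries explicit labels.

## Allometry

Height is never an input; it is always modeled from diameter with the
per-region Weibull form H = a(1 − exp(−b·D^c)) (a in m; H < a, strictly
increasing). Dicot aboveground biomass is AGB = 0.0509·ρ·D²·H in kg (D cm,
ρ g cm⁻³, H m) — exactly linear in ρ and H, quadratic in D. Monocots
(Arecaceae and Strelitziaceae) use a diameter-only power law
ln AGB = c₀ + c₁ ln D; they ignore wood density and height entirely.
Coefficients live in a versioned YAML (`hyperdom/data/allometry.yaml`,
transcribed from the standard published models) and are echoed into every
manifest; the test suite pins synthetic coefficients so correctness never
depends on transcription. Changing a stem's region changes its biomass only
through modeled height. Conversion to Mg happens at aggregation, not inside
the allometry calls.

## Productivity accounting

Productivity uses plots with at least two censuses spanning at least two
years, and the stems alive at the plot's first census plus recruits. For
each stem, P_i = [B(D_end) − B(D_start)]/Δt over each census interval in
which it is present, and P_stem is the arithmetic mean of those P_i. The
divisor is the number of *intervals* used (the "number of censuses" phrasing
found in field protocols is off by one from the number of intervals; the
interval count is the only choice that makes a single-interval stem's
P_stem equal its P_1). Negative interval productivities (shrinkage,
measurement error) are retained everywhere except log-scale regressions,
which can only use positive contributions. A stem dead before its second
census has no productivity; a species all of whose stems are in that
situation keeps its stem and biomass records with productivity = none.

Recruits get a productivity for their recruitment interval assuming
D = 10 cm at the previous plot census; a recruit first measured below 10 cm
is clamped to a 10-cm start with a warning (its recruitment-interval
productivity is then negative and retained).

### POM standardization

When a stem's point of measurement changes, the raw diameter series is
disjoint. The series is split into constant-POM segments; the newest
segment is kept verbatim and each earlier segment is shifted *additively*
so that the growth imputed across the join equals the stem's mean
within-segment growth rate times the join interval (zero, with a warning,
when the stem has no within-segment increment). Additive splicing is the
only correction that preserves every post-change diameter and every
increment actually measured at a single POM; a multiplicative ratio
adjustment would rescale the pre-change increments, distorting the very
growth the correction is meant to protect. The schema records one diameter
per census, so an overlap-based ratio (which needs the same census measured
at both POMs) is not representable and never used.

### Palm necromass-equilibrium estimator

Palms lack radial growth, so their productivity is estimated from mortality
under an equilibrium assumption: for each stem of the species that died,
P_stem = (B_final − B_10cm)/(C_dead − C₁), with B_final the palm biomass at
the last recorded diameter, B_10cm the 10-cm palm biomass (subtracted so the
quantity matches the dicot accounting, which also excludes the 10-cm entry
cylinder), C₁ the initial plot census date, and C_dead the census at which
the death was recorded. Species productivity is the sum over dead stems.
The estimator needs an adequate mortality sample, so it is applied only to
monocot species that are stem hyperdominants of the productivity data set;
stems of rarer palm species are excluded from the productivity numerator
*and* denominator (symmetrically, with the affected stem count logged), and
unidentified monocot stems likewise.

A short analysis of the estimator's expectation, used to design its test:
in a stationary population with per-year mortality m observed over a single
interval of length T, the expected estimate is q(1−q^T)/(mT) times the true
biomass production rate (q = 1−m) — about 6% low at m = 0.02, T = 5, because
dying stems' growth after their last measurement goes uncounted. With k > 1
equal intervals the "allocate from C₁" rule multiplies the expectation by
roughly the harmonic number H_k, so the estimator is only approximately
unbiased for short observation windows. The equilibrium test therefore uses
the minimal two-census window, where the analytic bias sits well inside the
Monte-Carlo 3-SE band.

## Species aggregation and dominance statistics

Stem abundance and biomass are taken from the first census of each plot;
all plots are pooled with no area weighting (the dataset is treated as one
sample of the forest). Unidentified stems contribute only to the
denominators of the percentage contributions, never as species rows, so
identified-species percentages sum to at most 100. Two contribution tables
are maintained — the full data set and the multi-census productivity data
set — because cross-metric comparisons must hold the denominator population
fixed.

A hyperdominant set for a metric is the minimal prefix of species, sorted
by descending contribution (ties broken by taxon id for determinism), whose
cumulative percentage reaches 50. Minimality is verified against brute-force
prefix search in the tests. The "percent of species" uses only species with
a defined value for that metric.

Species maximum diameter is the 95th percentile (linear interpolation
between order statistics — the numpy default, recorded in outputs) of
per-stem maximum *raw* diameters over all censuses, for species with at
least 20 individuals; the per-stem maximum uses recorded diameters, not
POM-standardized ones, because the trait targets the size the stem actually
reached. The wood-density trait requires a species-level entry in the
lookup table; taxonomic fallback values are imputations, not traits.

Cumulative trait curves order species from highest to lowest trait value
and accumulate the percentage of species, stems, biomass and productivity.
The axes are normalized *within the trait-annotated subset*: that makes
"the largest 50% of species hold X% of stems" read as a statement about
those species, and equals ≈50% exactly when contribution is independent of
the trait. Trait values at the 50% crossing of each metric are linearly
interpolated between adjacent species.

Contribution regressions are OLS on natural-log-transformed percentage
contributions (slope and R² are log-base invariant; the intercept is not,
and the base is recorded in the output). Species with non-positive
contributions are excluded. Trait effects "after abundance" are OLS of the
abundance-regression residuals on ln(trait). A constant response returns a
zero slope and zero R² rather than an undefined fit. Regressions need at
least three points.

The regional analysis reruns the aggregation and hyperdominance per region
(skipping, with a warning, any region lacking plots or multi-census plots
for productivity) and tallies, for each dataset-wide hyperdominant, the
number of regions (0–5) in which it is regionally dominant. The
ratio-scaling estimate round(n_ref · n_metric / n_stem) carries a dataset's
metric-to-stem hyperdominant ratio onto an independent reference count of
stem hyperdominants.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale (defaults: 25 one-hectare plots, ~200 stems ha⁻¹ ≈ 5,000 stems,
Fisher's α = 70 giving ≈300 species, three censuses at 5-year intervals —
about 2–3% of a full plot-network campaign, chosen to keep a full pipeline
run near a second while leaving stable dominance curves):

* **Abundance**: species count S = α·ln(1 + N/α); per-species weights are
  iid log-series draws with x = N/(N+α), so the realized pool recovers the
  target α (tested to 10%). Stems are multinomial in those weights; plot
  totals are Poisson, so stem counts scale linearly with plot count.
* **Traits**: wood density is a bounded normal (0.63 ± 0.15 g cm⁻³ clipped
  to 0.2–1.1); species maximum size d95 is lognormal (median 40 cm);
  diameters are 10 cm plus an exponential whose 95th percentile targets the
  species' d95. Growth rates are lognormal (median 0.2 cm yr⁻¹) with
  stem-level Gaussian noise; first-census diameters cannot fall below the
  10-cm protocol threshold but later shrinkage below it is allowed.
* **Dynamics**: Bernoulli mortality (2% yr⁻¹), recruitment Poisson-matched
  to deaths entering just above 10 cm, POM changes (2% per stem per census)
  that raise the POM by 0.5 m and multiply the recorded diameter by 0.9
  from then on.
* **Identity**: 3% of species are monocots, drawn half from the most
  abundant decile (the large arborescent palms are among the commonest
  Amazonian trees, which also guarantees the palm productivity route is
  exercised); 21% of stems are stripped to genus- (half), family- (quarter)
  or fully-unidentified (quarter) morphotaxa, reproducing a ~79%
  species-identification rate. A configurable fraction of species (10%)
  lacks a species-level wood-density entry, exercising the fallback chain.

Ground truth (per-species stems, biomass, productivity and contributions)
is computed inside the generator from the true diameters and identities by
an independent accounting loop. Under the clean configuration (no
stripping, no POM changes, no palms, complete wood-density table) the
pipeline reproduces truth bit-for-bit; with realism features on, the
differences are exactly the documented estimator behaviors (fallback wood
densities, POM splicing, palm estimator).

The stationary palm population for the equilibrium test initializes ages
from the geometric stationary distribution, runs an annual
grow–die–recruit loop with a drift check over burn-in, and observes two
censuses. Palms approach a determinate adult diameter (default 35 cm;
growth stops there), which is both how arborescent palms behave and what
keeps the estimator's Monte-Carlo variance finite enough for a meaningful
3-SE comparison — with unbounded exponential size structure a handful of
giant dying palms dominates the sum.

What the generator does *not* emulate: spatial structure and species
geography (regions differ only in labels and height parameters), climate
or disturbance drivers, correlated measurement error, within-species trait
variation, and flooded/successional forest types. Passing recovery tests
therefore demonstrates the correctness of the accounting and estimators
under the stated statistical assumptions, not robustness to the full messiness
of field data.

## Numerical and degenerate-input conventions

Dates are decimal years; zero-length census intervals are errors. Ties in
descending sorts break by taxon id (stable mergesort), making every
hyperdominant count deterministic. Exact floating-point boundary crossings
of the 50% threshold are resolved by a post-hoc minimality sweep. Empty
filter results warn rather than silently returning. The simulator is fully
deterministic under its seed (byte-identical CSV output). All randomness in
tests is seeded or hypothesis-managed.

## Known limitations

* Census-interval bias corrections (unobserved growth of stems dying
  mid-interval, varying interval lengths) are out of scope beyond the rules
  above; the palm estimator analysis shows the kind of bias this leaves.
* The default region boundary boxes are placeholders for a real
  delineation; real analyses should pass per-plot labels.
* The archived species-level validation path assumes the package's own
  aggregate-table layout; files lacking percentage columns get
  identified-only denominators, which slightly understates hyperdominant
  counts relative to the unidentified-inclusive convention.
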