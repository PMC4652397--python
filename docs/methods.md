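# Methods

## The problem

Indoor radon is a geogenic lung carcinogen with no safe concentration.
Jurisdictions nevertheless publish *reference levels* — concentrations above
which remediation is recommended (WHO 100 Bq m⁻³, Health Canada 200 Bq m⁻³,
EU 200–400 Bq m⁻³) — and radon risk maps classify areas relative to such a
level. The choice of level changes which areas are flagged, how many people
live in them, and how well the classification can be learned from sparse
survey data. This package implements that whole policy-evaluation pipeline as
reusable, tested code, indexed by a *ladder* of thresholds
(50, 100, 150, 200, 300, 400, 500, 600 Bq m⁻³ by default).

## Vulnerability response

The unit of analysis is a mapping unit formed by intersecting a parent census
area with a geology class. A unit with at least one indoor radon measurement
is summarised by the 95th percentile (P95) of its observed concentrations;
for a threshold T the unit is *high* vulnerability iff P95 ≥ T. Conventions,
fixed here for bit-reproducibility because they are genuinely open choices:

- **Quantile**: linear interpolation of order statistics with plotting
  position h = (n−1)·0.95 + 1 (the common "linear"/type-7 default). A single
  measurement is its own P95.
- **Tie at the threshold → high**: a home measuring exactly at a guideline
  should be actionable under the ALARA principle.
- Labels across the ladder are nested by construction: high at T implies high
  at every T′ < T.

## Balanced bootstrap forest

One classifier is trained per threshold on the measured units. Each tree of
the ensemble is grown on a *balanced bootstrap*: n_min draws with replacement
from each class, n_min being the minority class size, so in-bag class counts
are always equal; this counters the heavy imbalance at high thresholds.
Trees are maximally grown (default `min_leaf_size=1`), splitting on
`⌈√d⌉` randomly chosen covariates per node (if none of them admits a valid
split the search falls back to all covariates before declaring a leaf), with
Gini impurity decrease as the criterion:

- continuous covariates split at midpoints of consecutive observed values;
- categorical covariates are split over binary partitions of the observed
  levels; for a binary response the optimal partition is found exactly by
  ordering levels by their within-node high-class proportion and scanning
  that order — no exponential subset search;
- leaf (and vote) ties resolve to *high*, the conservative choice for a
  screening map.

Out-of-bag (OOB) evaluation: each unit's class is the majority over the
votes of all trees whose bootstrap excluded it. Pooled over trees this is the
internal analogue of a holdout estimate (the suite verifies |OOB κ −
holdout κ| ≤ 0.1 at ≥1,000 units and 500 trees). The published configuration
of this design is 20 runs × 10,000 trees; since runs are pooled by summing
vote tallies, pooling is equivalent to one larger forest with stratified
seeds, and the desk default (2 runs × 100 trees) keeps the structure while
running in seconds. Units uncovered by any OOB tree are flagged and excluded
from metrics (the fit warns below 99% coverage).

**Eligibility.** A unit whose categorical covariates include a level never
observed in the training data is INELIGIBLE for prediction — the forest has
no evidence about that level — and is reported as its own class, never folded
into *low*.

## Performance metrics and diagnostics

From the 2×2 OOB confusion matrix (rows observed, columns predicted):
class accuracy = row-normalised diagonal, class precision = column-normalised
diagonal (undefined denominators are reported as missing, not 0), and
Cohen's κ = (p_o − p_e)/(1 − p_e). The κ *gain* of a threshold is its κ minus
that of the next-higher threshold (highest threshold: 0), the headline
comparison across ladder models.

Spatial independence of the response is checked with Geary's c,
c = (N−1)·Σ w_ij (x_i−x_j)² / (2W·Σ(x_i−x̄)²), expectation 1 under spatial
randomness. Weights default to symmetrised 8-nearest-neighbour adjacency on
unit centroids (configurable — no weight specification is canonical for this
data). The p-value is a two-sided permutation test (default 999 relabelings,
add-one correction (r+1)/(B+1)).

## Population at risk

Unit populations are apportioned from the parent census area by area share
(parent_population × unit_area / parent_area), kept fractional until final
reporting (then rounded half-to-even). Regional summaries report the
area-weighted fraction of a region classified high plus the population in
high, low, and ineligible classes; populations are conserved exactly at every
aggregation level. The fold change of the high-class population between two
thresholds quantifies how lowering a reference level expands the population
at risk.

## Mortality trends

Death records are filtered to natural causes (ICD-10 first letter outside
T..Y — this also drops V codes) among adults 20+; lung cancer is a cause code
starting with C34; malformed codes are dropped with a logged count. Each
death is assigned (a) the vulnerability class of its unit under each
threshold map, (b) a higher/lower smoking class — its health area's
prevalence strictly above the median of all area estimates (ties and the
median itself → lower; even counts use the midpoint median), and (c) sex.
Deaths in INELIGIBLE units are excluded from trend numerators and
denominators (not assigned low, which would dilute that stratum) and counted
in an exclusion log.

The *crude lung cancer mortality ratio* is annual lung deaths over annual
all-natural deaths within a stratum; years with no natural deaths are
missing. Trend lines are LOESS: at each year the q = ⌈span·n⌉ nearest
observed years get tricube weights w = (1−(d/d_max)³)³ and a weighted
least-squares polynomial is fitted (defaults span 0.75, degree 2; the
smoother is named by the design but not parameterised, so both are exposed
flags). The implementation matches a brute-force WLS oracle to 1e-9 at every
fit point.

The stratum summary table reports, per stratum, the percent of all natural
deaths and of all lung deaths, and their ratio. By default the ratio is
computed from the percentages rounded to 1 decimal as they are printed
(e.g. 26.2/22.9 → 1.14) with a flag to use unrounded counts instead.

The misclassification sensitivity operation moves assumed fractions of the
high group's lung and other-natural deaths into the low group (the low group
assumed correctly classified) by exact expected-count arithmetic and
recomputes both ratios as lung/(lung+other). Note that an alternative
reading — reporting lung/other rather than lung/(lung+other) for the
corrected high group — gives materially different numbers; this package
implements the lung-share convention explicitly and documents it, because
published sensitivity narratives of this kind are not always reconstructible
from their stated inputs.

## Synthetic-province generator

No real provincial radon, census, or vital-statistics data are redistributed
with this package, so every pipeline stage is exercised on a generator that
emulates the data *structure* with a known ground truth:

- **Units**: n_parent parents on a planar grid (areas log-normal around
  8 km²) each split into 1 + Poisson(mean−1) units with Dirichlet area
  shares (areas and populations conserve exactly). Parents map contiguously
  to ~8 regions and 83 health areas.
- **Geology and latent radon**: five lithology classes with geometric means
  25–180 Bq m⁻³ and GSDs 2.2–2.6 (GSDs of 2–3 are typical of regional indoor
  radon surveys). Class weights follow a region gradient, so region R00 is
  deliberately radon-prone — giving a known "highest-risk region" for rank
  tests. Each unit's latent GM multiplies a log-normal unit effect
  (σ_log = 0.40 default).
- **Covariates**: categoricals correlated with geology (6 levels; one
  covariate has 12 Zipf-weighted levels so rare unseen levels occur and the
  eligibility rule is exercised); continuous covariates are linear in the
  unit's latent log GM plus Gaussian noise (σ = 0.35 default), with one pure
  noise covariate always present as a robustness control.
- **Measurements**: units are sampled Bernoulli with probability
  ∝ (GM/mean GM)^0.5 scaled to ~25% of units — emulating surveys that
  oversampled known high-radiation areas — then receive a zero-truncated
  Poisson count (mean 4.1, matching ~4,300 measurements over ~1,050 measured
  units in the motivating survey compilation) of log-normal concentrations
  from the unit's latent GM/GSD.
- **Deaths**: per unit-year Poisson counts at a crude rate of 0.0065/person
  /year over a 16-year window starting 1998. Among natural deaths the lung
  probability is logistic-linear in the unit's true radon stratum (latent
  P95 ≥ 200), the health area's smoking class, sex, and scaled year, with
  configurable odds ratios (defaults 1.5 radon, 1.6 smoking, 1.4 male, flat
  trend, base lung share 0.07). A configurable fraction of external-cause
  codes (8%) and under-20 ages (1%) exists purely to exercise the filters.

All randomness flows from one root seed through named `SeedSequence`
substreams per stage (and per tree), so the entire study — and the whole
pipeline, including file hashes in the run manifest — is reproducible
bit-for-bit.

**What the generator does not emulate**: real GIS intersection of census and
lithology polygons, postal-code geocoding, seasonal correction of radon
tests, spatially autocorrelated residual radon beyond the regional geology
gradient, age structure of mortality, or migration. Passing tests therefore
demonstrate correctness of the algorithms and recoverability of known
effects under this generative model, not predictive performance on real
provincial data.

## Problem sizes and evaluation scenarios

The desk-scale province is ~2,000 units with ~500 measured — large enough
for stable OOB estimates at 100–500 trees while a full 8-threshold pipeline
runs in well under a minute. Parameter-recovery evaluations use a
"strong-signal" generator variant (5 measurements per measured unit,
covariate noise 0.25, unit effect 0.35) defined once in
`radonvuln.synthetic.strong_signal_config`; mortality-trend evaluations
raise the crude death rate to 0.03 to put ≥200,000 deaths in the window.
Under these conditions OOB κ at the 200 Bq m⁻³ threshold is comfortably
above 0.3, permuted-label κ is at chance, the generating radon odds ratio is
recovered within 10% by Mantel-Haenszel counting stratified on smoking and
sex, and the high-vulnerability LOESS curve lies above the low curve in
essentially all years.

## Numerical and degenerate-input conventions

- Split scores compare weighted child Gini via exact integer-count
  cumulative sums; score ties keep the first candidate in (deterministic)
  feature order. Midpoints that collapse to an endpoint under floating-point
  fall back to routing on `x <= left value`.
- κ returns 0 by convention when chance agreement p_e = 1; metrics with
  empty denominators are missing, never 0.
- Geary's c refuses constant values, asymmetric weights, or N < 3.
- LOESS windows whose tricube weights leave fewer than degree+1 positive
  weights fall back to equal weights over the window; coincident fit points
  (d_max = 0) return the local mean.
- CSV writers use fixed `%.10g` float formatting so manifests hash stably
  across runs and platforms.

## Known limitations

- Missing covariate values are unsupported (the generator never emits them);
  real data would need imputation or surrogate splits first.
- The forest stores full trees in memory and serialises them to JSON;
  published-scale ensembles (200,000 trees) are out of desk scope, though
  nothing in the design caps them.
- Predicted maps need not nest across thresholds even though training labels
  do; the mapping stage warns (not errors) when the predicted high fraction
  is not monotone.
- No variable importances, probability calibration, or formal inference on
  trend differences — the trends are exploratory visual comparisons by
  design, not an epidemiologic effect analysis.
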