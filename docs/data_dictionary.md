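# Data dictionary

All tables are UTF-8 CSV with a header row, comma separators, '.' decimals,
ISO integer years, and floats written at 10 significant digits. Readers
validate the mandatory columns below and preserve any extra columns.

## units.csv
| column | type | description |
|---|---|---|
| unit_id | str | mapping-unit identifier (unique) |
| parent_id | str | parent census area |
| region_id | str | reporting region (aggregates parents) |
| health_area_id | str | health administration area |
| geology | str | simplified lithology class |
| area_km2 | float | unit area; per-parent areas sum to the parent area |
| parent_area_km2 | float | parent area |
| parent_population | int | parent census population |
| population | float | area-apportioned unit population (fractional) |
| x, y | float | planar centroid (synthetic CRS) |
| cov_cat_* | str | categorical covariates |
| cov_num_* | float | continuous covariates (last one pure noise) |

## measurements.csv
unit_id (str), concentration_bq_m3 (float, > 0), survey_id (str, optional),
date (YYYY-MM, optional).

## deaths.csv
unit_id, health_area_id (str), year (int), sex (male/female), age (int),
cause_code (ICD-10-style string; C34* = lung cancer, first letter T..Y =
external cause).

## health_areas.csv
health_area_id (str), smoking_prevalence (fraction in [0, 1]).

## truth.csv  (synthetic ground truth)
unit_id, gm_true (Bq m^-3), gsd_true (> 1), p95_true = gm * gsd^1.6449,
true_high (bool, p95_true >= the generator's radon stratum threshold).

## labels.csv
unit_id, p95 (observed 95th percentile), one `class_<T>` column per
threshold with values high/low.

## map_T\<threshold\>.csv
unit_id, `class_<T>` in {high, low, INELIGIBLE}.

## report.csv
threshold, accuracy_low, precision_low, accuracy_high, precision_high,
kappa, kappa_gain — one row per threshold, descending.

## regional_summary.csv
region_id, threshold, fraction_units_high (area-weighted), population_high,
population_low, population_ineligible.

## trends_T\<threshold\>_\<stratum\>.csv
vulnerability (high/low), optional smoking (higher/lower) or sex, year,
lung_deaths, natural_deaths, ratio, smoothed (LOESS fit).

## stratum_summary.csv
stratum (total / higher_smoking / high_radon), threshold (for high_radon
rows), natural_deaths, lung_deaths, pct_natural, pct_lung,
ratio_of_percentages.

## units.geojson (optional)
RFC 7946 FeatureCollection; rectangular placeholder polygons in the
synthetic planar CRS with unit_id/region/geology (and class) properties.

## manifest.json
Effective pipeline configuration, per-stage log, and SHA-256 of every
written file; identical across reruns with the same seed.
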