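# Methods

This note records the models, conventions and numerical choices behind
`reefpipe`, and what the synthetic-data generator does and does not
emulate.

## Thermal-stress chain

The local heat-stress metric follows the operational degree-heating
logic anchored to an in-situ climatology rather than a satellite
product.

**Daily summaries.** A logger series (default sanity band 10–40 °C;
out-of-band readings are flagged, never silently dropped) is reduced to
per-calendar-day min/mean/max. Any day with at least one reading is
summarised (`min_readings` configurable); days without readings are
absent, never interpolated.

**Climatology and MMM.** For each calendar month we average the
year-month means of daily mean temperature across the baseline years,
so a year with missing days is not down-weighted; a pooled variant
(all daily values of a month together) is available via
`method="pooled"`. The Maximum Monthly Mean (MMM) is the warmest of the
12 climatological means. A baseline month with no data in any year is
an error — a 12-month climatology cannot be formed from 11 months.

**Threshold and stress.** The bleaching threshold is MMM + offset with
offset defaulting to 1 °C. Daily thermal stress is the daily *maximum*
temperature minus the threshold (a daily-mean basis is available for
buoy-only inputs), clamped at zero before any averaging. No separate
≥ 1 °C hot-spot gate is applied: the +1 °C already lives in the
threshold. Clamping before weekly averaging means cool days never
offset warm days.

**DHW.** For focal day d the window is the 84 days [d−83, d], inclusive
of d (an exclusive variant ends at d−1). DHW is the sum over the twelve
consecutive 7-day blocks of each block's mean clamped stress, which
equals the 84-day stress sum divided by 7; the unit is °C-weeks. Rolling
windows anchored to the focal day are used rather than calendar weeks.
Windows with missing days are computed from the available days and
flagged `complete_window=False` (strict mode raises instead); missing
days contribute zero rather than being imputed.

**Alert bands.** The operational bands overlap at their printed edges
("0–1", "1–4", "4–8", ">8"); we adopt half-open bands [0,1), [1,4),
[4,8], (8,∞), assigning 4 to Alert Level 1 and 8 to Level 1 as well,
with Level 2 strictly above 8.

## Storm indicators and cold wakes

Station wind is averaged within each station-day and then across
stations; rainfall is accumulated to station-day totals and then
averaged across stations; buoy wave height keeps the daily maximum.
Days with a subset of stations reporting are averaged over the
reporting stations. A storm day is any day with wind ≥ 4 m s⁻¹,
rain ≥ 50 mm or wave ≥ 150 cm — thresholds inclusive, criteria
combined with OR, each criterion also reported separately.

A typhoon's cold wake at one site is
drop = min(daily mean T inside the inclusive event window) − mean(daily
mean T over [start−7, start−1]). The daily *mean* is the default basis
(a daily-minimum variant exists). Warming windows yield positive drops
and are reported as-is. Regional aggregation is the mean ± sample SD
(n−1) over sites with data; a site lacking window data is omitted, not
imputed, and the site count is recorded. Overlapping event windows are
taken verbatim — a background window may include a prior storm's days;
no correction is attempted. The largest consecutive-day cooling scans
only calendar-consecutive day pairs, breaking ties by earliest date.

## Benthic cover and bleaching

Percent cover of a category in a grouping cell is 100 × points on the
category / points in the cell, so covers over an exhaustive partition
sum to 100 exactly; aggregation to major categories, morphotypes or
groups sums member-OTU covers (OTUs without a morphotype go to a
"none" class to keep the partition exhaustive). Cover SDs across
replicate cells use the sample SD.

Bleaching extent counts only "totally bleached" points; "discolored"
points remain part of an OTU's live cover but not of the headline
extent. Community extent divides by all points; assemblage extent
divides by scleractinian + octocoral points. Per-OTU shares of the
bleached points sum to 100 % whenever anything bleached.

Shannon diversity uses the natural log. α-diversity is operationalised
as the mean ± sample SD of per-site-per-survey OTU richness — the scale
on which monitoring programmes usually tabulate it. Surveys never
conducted in an area are missing cells, not zeros.

## Community statistics

The multivariate sampling unit is the transect (5 per site per survey);
rows of the transect × OTU matrix are proportion covers in [0, 1].
The chain is: arcsin(√p) transform → drop OTUs with nonzero values in
strictly fewer than 5 % of the pooled transect rows (the filter is
global, applied before any subsetting) → Bray–Curtis
d(i,j) = Σ|x_i−x_j| / Σ(x_i+x_j).

PERMANOVA partitions squared distances: SS_total = (1/N)Σ_{i<j}d²,
SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d², pseudo-F =
(SS_between/(a−1))/(SS_within/(N−a)). The p-value uses the add-one
estimator (1 + #{F* ≥ F}) / (1 + n_perm) under seeded label
permutation, so p is never zero; an exact mode enumerates all distinct
label arrangements for small N. Pairwise post-hocs run the same test on
each pair's submatrix with Benjamini–Hochberg adjustment by default
(none/Holm/Bonferroni configurable). Permutation F comparisons use a
1e-12 slack so exact ties count as exceedances.

Kruskal–Wallis uses midranks with the standard tie correction
1 − Σ(t³−t)/(N³−N); if every observation is identical the correction
degenerates and H is reported as 0 with p = 1. Dunn's
z = (R̄_i−R̄_j)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i+1/n_j)] with
two-sided normal p, unadjusted by default. The sign test drops zero
differences, counts S = #{x−y > 0} and doubles the smaller exact
Binomial(n, ½) tail, capped at 1; the sign convention (x−y vs y−x) is
configurable and recorded, since it changes S but not p.

## Synthetic data: what it emulates, what it does not

`simulate_temperature` writes T(t) = mean + seasonal cosine + diurnal
cosine + AR(1) noise + heatwave boxcars − cold-wake pulses at 30-min
sampling by default. `ar1_sd` is the *stationary* SD (innovations are
scaled by √(1−ρ²)). A cold wake holds its full depth for one day and
then recovers linearly over `recovery_days`; because an evenly sampled
diurnal cosine averages to zero within a day, the 7-day-background drop
metric recovers the injected depth exactly on noiseless runs. The
generator does not emulate tidal upwelling, monsoon-scale weather
regimes, sensor drift or logger failure.

`simulate_meteo` draws quiet baselines (wind ~2.5 m s⁻¹, exponential
rain ~3 mm day⁻¹, wave ~80 cm — all well below the storm thresholds)
and overwrites injected storm-day values identically at every station,
so aggregation returns them exactly. There is no spatial structure
across stations and no wind–wave coupling.

`simulate_benthic` draws each transect's composition from a Dirichlet
around the area's concentration vector (total concentration mass
controls transect-level overdispersion) and assigns 105 × 50 points per
transect multinomially, matching the photo-quadrat sampling design
(5 transects, 105 photos, 50 points). Points on
Symbiodiniaceae-associated OTUs bleach with probability
logistic(β0 + β1·DHW); the defaults (β0 = −5, β1 = 0.75) put roughly
6–7 % of susceptible points bleached at DHW ≈ 3 °C-weeks — the extent a
mild heat-stress season produces — and an optional discoloration layer
(off by default) models the intermediate state. The default scenario
uses the study layout (3 + 3 + 5 sites in three areas, five surveys)
and a turf-dominated composition (~38 % turf, ~18 % encrusting coral,
~7 % octocoral) as a realistic demo; the generator does not model coral
demography, storm mechanical damage or within-photo spatial clustering,
so passing tests demonstrate estimator correctness under the assumed
sampling model, not realism of any particular reef.

## Problem sizes for stochastic checks

Calibration checks are sized to give tight Monte-Carlo error at
interactive runtimes: PERMANOVA type-I error over 1 000 null data sets
(N = 12 rows, 199 permutations; the p-value is then uniform on
{1/200, …, 1} so the nominal rate is exactly 0.05), power over 100
seeds of the two-area scenario at full per-transect point counts, and
cold-wake recovery over 200 seeds of ~40-day series at 30-min sampling.
The uniformity check of the permutation p-value uses 400 null
replicates against the discrete uniform.

## Known limitations

- The DHW window uses days, not ISO weeks; series crossing daylight
  shifts are treated as naive local time.
- PERMANOVA is one-way only (no nesting, strata or dispersion test),
  matching the analyses this pipeline targets.
- The rare-OTU filter and arcsine transform assume proportions, so the
  statistics stage must be fed proportion covers (the benthic stage's
  transect matrix does this).
- Climatology quality depends on the baseline series supplied; the
  pipeline does not detect heatwave contamination of a short baseline.
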