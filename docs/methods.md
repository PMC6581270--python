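# Methods

## The pipeline model

`ntakit` treats an NTA experiment as a matrix of per-bin particle
concentrations C[b, m] (particles/mL) over a uniform size grid of width
w nm, with half-open bins [centre − w/2, centre + w/2). Measurement m
belongs to one biological sample, one syringe injection of that sample,
and one video (technical replicate); the sample was diluted 1:d before
measurement. The undiluted concentration is recovered per row as
`true_count = count × d`, with d the bare fold factor parsed from the
measurement name — ratio strings such as `1:500` are rejected rather
than guessed at.

Replicate aggregation is a sequence of independent group-wise passes
(`nanolyze`), each emitting N, mean, sd (sample standard deviation,
N−1 denominator, matching the R convention most NTA users compare
against) and se = sd/√N under a caller-chosen prefix. On balanced
designs, averaging technical replicates and then injections is exactly
the grand mean per sample; this equivalence is asserted to relative
1e-9 in the tests. `nanocount` is a plain sum of the chosen value
column over bins within a group; an optional `normalize_bin_width`
factor converts the sum to an integral for non-unit bins (default off,
since 1-nm exports are the norm and a silent rescaling would surprise).

## File dialect

The instrument's own export layout is proprietary and versioned, so the
reader targets a documented stand-in dialect: a preamble of
`key: value` lines that must contain `NTA Version: <x.y>`, optional
`Bin width (nm)` / `Size min (nm)` / `Size max (nm)` keys, then a header
row starting `Bin centre (nm)` followed by one unique name per
measurement, then one row per bin. The measurement count is always
inferred from the header, never supplied by the caller. Versions other
than 3.2 parse with a logged warning rather than failing, so newer
exports in the same layout still load. Blank cells abort with the row
and column named: silently coercing gaps to zero is exactly the
spreadsheet failure mode this package exists to prevent. The reader is
a single function behind the module surface, so a second dialect can be
added without touching the rest of the pipeline.

Numbers are written with 12 significant digits, which keeps
write→read→write byte-stable and round-trips counts well within the
guaranteed relative 1e-9.

## Statistics

* **Shapiro–Wilk screen** (`nano_shapiro`): per-group W and p from
  scipy's implementation (which agrees with R's `shapiro.test` to
  ~1e-10 on the frozen test vectors); a group is called "parametric"
  iff p > α (default 0.05, explicit parameter) and the overall
  suggestion requires every group to pass. Both the threshold and the
  all-groups rule are choices, not inferences; they are exposed so a
  user can disagree. Valid for 3 ≤ n ≤ 5000 with nonzero variance.
* **One-way ANOVA** (`one_way_anova`): the standard decomposition
  SS_total = SS_between + SS_within computed directly; p from the
  F(k−1, N−k) upper tail. The all-values-identical case returns
  F = 0, p = 1 by convention instead of 0/0.
* **Tukey–Kramer** (`nano_tukey`): the Kramer form of the studentized
  statistic is used throughout because real NTA studies have unequal
  group sizes (n = 5–7 per group in the bundled design); adjusted
  p-values and simultaneous 95% intervals come from the
  studentized-range distribution with parameters (k, df_within). The
  implementation is checked against statsmodels' `pairwise_tukeyhsd`
  to 1e-6 in the tests; statsmodels is never the implementation.
* **Welch's t** (`welch_t`): direct formula with Welch–Satterthwaite
  degrees of freedom; two-sided p. Used for two-group designs where
  equal variances should not be assumed.
* A non-parametric fallback is deliberately not implemented: the screen
  only *suggests* a test class, and silently substituting a different
  test would hide an analysis decision that belongs to the user.

## Synthetic experiments

The generator emulates the hierarchical design of a plasma-EV time
course: groups → biological samples → injections → videos. Defaults are
the bundled "study" configuration: 6 groups with (7,6,6,6,6,6)
biological samples (37 total), 2 injections × 3 videos each = 222
measurements, dilutions cycling through 125 / 250 / 500 per sample, and
a 0.5–999.5 nm grid at 1 nm — spanning the microvesicle upper bound.

* **Size distribution**: one lognormal per group, parameterised by mode
  (default 100 nm, the empirical peak of plasma-EV distributions) and
  geometric SD (default 1.4, giving realistic unimodal width).
  Per-bin expected mass is the lognormal CDF increment over the bin,
  normalized to the grid so ground-truth totals equal the binned curve
  exactly. Mixtures (e.g. a microvesicle shoulder) would be a config
  extension, not a default.
* **Noise**: multiplicative mean-1 lognormal factors at each level,
  with coefficients of variation cv_biological = 0.25,
  cv_injection = 0.05, cv_technical = 0.10 by default — concentrations
  are positive and instrument scatter scales with signal, and ~10%
  video-to-video CV with smaller injection-to-injection spread is
  typical of syringe-loaded NTA runs. A mean-1 parameterisation makes
  replicate averaging unbiased, so recovery checks compare estimates
  to the latent sample total directly.
* **Dilution**: the emitted file holds the *diluted* per-bin
  concentrations, so the pipeline's back-calculation is exercised; the
  per-sample dilution cycles deterministically through the design's
  list, which keeps measurement names independent of the seed (only
  values change when the seed changes).
* **What it does not emulate**: Brownian-motion tracking, camera level,
  detection threshold, counting (Poisson) noise at the bin level, or
  bin-to-bin correlated errors. Passing recovery tests therefore shows
  the pipeline's arithmetic and plumbing are correct under the stated
  noise model, not that any instrument meets that model.

`recovery_report` runs read → tidy → nanolyze(technical) →
nanolyze(injection) → nanocount and compares each sample's estimated
total to its latent truth, with a standard error taken from the
one-pass spread of the six per-video totals. That SE treats videos as
independent, so the within-3-SE coverage check applies to designs with
technical noise only; when injection-level noise is on, the two videos
of a syringe share a factor and the naive SE understates the error —
a known limitation, visible in the simulation itself.

## Validation sizes and numerical choices

The test suite and acceptance script run the full 222-measurement ×
1000-bin study for end-to-end checks, 200 randomized small tables
(2–30 bins, 1–6 measurements) for round-trip identity at relative 1e-9,
2,000 null datasets (3 groups × 6) for the ANOVA type-I calibration
against the [0.035, 0.065] band, and 50 seeded study-scale simulations
for the ≥95% within-3-SE coverage check — sizes chosen so each property
is measured with useful precision while the whole suite stays quick to
run locally.

Other fixed conventions: grid agreement uses relative tolerance 1e-9;
boxplot quartiles use linear interpolation (`numpy.percentile` default)
with whiskers at the most extreme point within 1.5 × IQR; factor level
order is first appearance in measurement order, never alphabetical, and
never depends on row order; figures pin the SVG hash salt and drop date
metadata so identical inputs give byte-identical files.

## Known limitations

* The file dialect is a documented stand-in; real NanoSight exports
  need a dialect mapping before import (or manual cleaning to the
  wide layout, which the reader also accepts).
* The statistics layer analyses one total per biological replicate;
  it does not fit mixed-effects models honoring the replicate
  hierarchy — replicates are averaged first, as is standard practice
  in the field.
* Name parsing is single-separator token splitting by design; factor
  values therefore may not contain the separator character.
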