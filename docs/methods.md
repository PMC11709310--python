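# Methods

## The index

`qcindex` builds a Quality-of-Care Index (QCI) for a single cause — the
reference use case is orofacial clefts (ICD-10 Q37) — from six routinely
estimated burden measures: incidence, prevalence, deaths, YLLs, YLDs and
DALYs, as published per (location, year, sex) in Global Burden of
Disease-style result tables. Four dimensionless ratios summarize care
quality indirectly:

| ratio | definition | direction |
|---|---|---|
| `r_pi` | prevalence / incidence | ambiguous: longer survival *or* slower resolution |
| `r_mi` | deaths / incidence | lower = better care |
| `r_dp` | DALYs / prevalence | lower = less burden per prevalent case |
| `r_ly` | YLLs / YLDs | lower = smaller fatal share of burden |

The index is the first principal component of these four ratios:

1. **Pooling.** One PCA is fitted over *all* observation units together —
   every location, every year, and the three sex groups (male, female,
   both). A common model is what makes a country's 1990 and 2019 scores
   comparable and what makes the male/female ratio meaningful; fitting
   per-year or per-sex models would destroy both comparisons.
2. **Standardization.** Each ratio column is z-scored (population standard
   deviation, divide by *n*). The ratios live on wildly different scales
   (`r_pi` in the tens, `r_mi` near zero), so the PCA is correlation-based;
   any single ratio column can be rescaled by a positive constant without
   changing a single score.
3. **Eigendecomposition.** The 4×4 covariance of the standardized matrix is
   decomposed with a symmetric eigensolver; components are ordered by
   explained variance. Before any semantic step, each loading column is
   signed so its largest-magnitude element is positive — a pure
   reproducibility convention that removes backend-dependent sign flips.
4. **Orientation.** The sign of PC1 is chosen so the oriented score
   correlates *positively* with the standardized mortality-to-incidence
   column — the one ratio whose direction is unambiguous (higher mortality
   per incident case = worse care). If that correlation is exactly zero the
   DALYs-to-prevalence column is the fallback anchor. Larger oriented score
   = worse care.
5. **Rescaling.** Scores are min-max mapped to [0, 100] using the pooled
   extrema, so the pooled worst observation scores 0 and the best scores
   100. The anchors are frozen into the saved model; new observations
   scored against a stored model are clamped to [0, 100]. Ties at the
   extrema are left as ties.

Observation units missing any of the measures, or with a zero denominator,
are excluded from the fitting pool and propagate NaN scores — never
imputed, never epsilon-padded: padding choices would silently distort the
loadings, while exclusion is auditable in the logs.

Degenerate inputs fail loudly: a constant ratio column, fewer than two
complete rows, fewer rows than columns, or a PC1 orthogonal to both anchor
columns each raise a typed error.

## Disparity and grouping

The gender disparity ratio (GDR) is male QCI / female QCI per
location-year. Bands, with the pinned boundary convention:
[0, 0.5), [0.5, 0.95), **[0.95, 1.05]** (optimal, closed on both ends),
(1.05, 1.5], (1.5, ∞). Closing the optimal band at both ends makes a ratio
of exactly 0.95 or 1.05 "optimal", which is what "between 0.95 and 1.05"
means in plain reading; the adjacent bands shrink accordingly. A zero
female score leaves the ratio undefined (logged) rather than infinite.

Quintiles of the QCI within a year are rank-based: stable sort by
(QCI, location name) ascending, cut into five near-equal groups whose sizes
differ by at most one; largest-remainder extras go to the extreme quintiles
first, in the order 1, 5, 2, 4, 3 (so 7 locations split 2,1,1,1,2).
Quintile 5 is the highest-QCI fifth. The alphabetical tie-break is
arbitrary but deterministic.

Group summaries (World Bank income levels, SDI quintiles, custom schemes)
prefer a published group-level aggregate row when the scored table carries
one, because an unweighted mean of member countries ignores population
size; the fallback member mean is flagged in the output's `mode` column.

Change columns are `value(2019) − value(1990)` — a falling DALY rate gives
a negative change, matching the sign convention of published change tables.

## Validation tools

`correlate_with_reference` is plain Pearson correlation between QCI and an
external index (e.g. a Healthcare Access and Quality-style index) on the
(location, year) overlap, with n reported.

`fit_random_intercept` regresses QCI on panel covariates with a country
random intercept. The default estimator is a transparent two-stage moment
method: (i) pooled within-country OLS on demeaned data for the fixed
slopes; (ii) country intercepts from country means, with the
between-country variance estimated as
`max(0, var(â_i) − σ̂²_e · mean(1/n_i))` — the raw intercept variance minus
its expected sampling-noise inflation. It is deterministic, closed-form and
easily testable; `method="reml"` offers a full-likelihood fit (statsmodels
MixedLM) behind the same interface, and the two agree on well-behaved
panels. Covariates with no within-country variation get slope 0 by
convention; linear dependence among the remaining covariates raises an
error naming the collinear set.

## Synthetic data generator

The generator emulates the *shape* of a GBD results-tool extract — long
CSV, one row per (location, year, sex, measure), age-standardized rates per
100,000 with uncertainty bounds — driven by a latent care-quality factor
`q ∈ [0, 1]` per location so that recovery of `q` by the full pipeline is a
testable claim.

Latent structure: `q(location, year, sex) = clamp(q0 + trend·(year−start) ±
d/2, 0, 1)` with `q0 ~ U(quality_range)` and a per-location sex offset
`d ~ N(0, sex_offset_sd)` (male +d/2, female −d/2). Measures:

* incidence `I` = `base_incidence_rate` (care does not change how many
  children are born with a congenital anomaly);
* deaths `D = m_max·(1−q)·I` with `m_max = 0.2`;
* prevalence `P = I·(20 + 40q)` — better care, longer lives, larger
  prevalent pool (this is why the prevalence-to-incidence ratio is
  direction-ambiguous in general and left to the empirical loading);
* `YLD = 0.05·P`; `YLL = D·(60 − 20q)` (deaths under poor care occur
  earlier in life); `DALY = YLL + YLD` *after* noise, so the defining
  identity holds exactly even in noisy tables.

Multiplicative lognormal noise (unit mean, coefficient of variation
`noise_cv`) is applied per (location, year, measure) and **shared between
the sexes**: sex-specific estimates of one location-year come out of one
estimation process and carry strongly correlated errors, so the latent sex
offset is the only systematic source of male–female asymmetry. With
independent per-sex noise even cv = 0.1 throws roughly half of all
location-years out of the ±5% parity band, which no one would read as a
property of symmetric sexes.

Defaults, chosen once to mirror the reference study conditions and fixed:
100 locations, years 1990–2019, `quality_range = (0.05, 0.75)`,
`trend_per_year = 0.008` (≈ +0.23 latent quality over 29 years, matching a
~24-point index climb), `sex_offset_sd = 0.05` (near-parity by 2019),
`base_incidence_rate = 10` per 100,000, `noise_cv = 0.1`. The structural
constants (`m_max`, duration, disability weight, residual life expectancy)
are arbitrary but fixed and exposed via `SyntheticConfig.structure`; they
put the four ratios at realistic orders of magnitude for a congenital,
low-lethality condition. All randomness flows through one
`numpy.random.default_rng` (PCG64) stream per seed, drawn in a fixed order.

What the generator does **not** emulate: age structure (a single
"Age-standardized" label is emitted; there are no age pyramids or birth
cohorts), uncertainty-interval propagation (bounds are a fixed ±1.96·cv
envelope), spatial correlation between countries, and reporting artifacts
of real registries. Passing recovery tests therefore show the pipeline is
correct *given* the monotone-latent-factor model, not that real GBD
extracts satisfy that model.

## Problem sizes and tolerances

The test suite and the acceptance script run the full defaults pool
(100 locations × 30 years × 3 sexes = 9,000 observation units, 54,000
table rows), which completes in seconds; PCA-level checks use 10–100-row
pools. Numerical tolerances: orthonormality and oracle agreement at 1e-8;
z-score means at 1e-9; exact identities (DALY = YLL + YLD, determinism,
canonical-CSV fixed point) asserted to machine precision.

## Known limitations

* The index is relative to its fitting pool: scores are comparable only
  within one fitted model, and adding observations changes every score.
* No uncertainty propagation: the GBD 95% intervals are carried through
  I/O but not into the index.
* The orientation anchor assumes the mortality-to-incidence ratio loads
  non-trivially on PC1; for causes where mortality is essentially zero
  everywhere, the fallback anchor (DALYs-to-prevalence) decides.
* Group summaries in fallback mode weight member countries equally.
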