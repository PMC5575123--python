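# Methods notes

## Exposure assignment

Exposure is Section-month mass of pesticide active ingredients (kg AI).
An application contributes entirely to the calendar month of its date;
all windows are whole calendar months, since every aggregation the design
uses is month-based. The gestational window is the birth month plus the 8
previous months for births on or after the 15th, otherwise the 9 preceding
months — counting backwards from birth rather than forwards from the last
menstrual period avoids anchoring windows on a quantity exposure itself
might shift. Trimester 1 is the *earliest* three months of the window.
That ordering convention is isolated in `trimester_windows` so it can be
flipped if a conception-side convention is preferred; nothing downstream
depends on which block is called "1". Trimester 0 is the three months
before conception, trimester 4 the three months after birth (the placebo
window, disjoint from gestation by construction).

High-exposure indicators are 1 when a measure is **at or above** its 95th
percentile ("top 95th percentile or above"); each measure (gestational sum,
toxicity groups, trimesters, aerial/ground) is binarized at its own cutoff,
computed on the all-births sample (post base restrictions, before the
year drop, including any dropped-covariate year). Quantiles use the
inverted-CDF (lower empirical) definition, which stays well defined when
the majority of the distribution is a point mass at zero; the definition is
recorded in the cutoffs sidecar. The restricted cubic spline basis (knots
at the 75/95/99th percentiles, natural boundary behaviour, truncated-power
construction) refuses tied knots rather than silently merging them —
with majority-zero exposure the 75th-percentile knot can collide with the
zero mass point, and that is a modelling decision the caller must make.

## Cohort filters

All printed inequalities are strict as stated: gestation kept in
[182, 350] d, weight kept in [250, 5500] g (250 g exactly retained), total
births to the same mother kept when ≤ 15, match scores kept only when
> 85. Missing covariates are explicit category levels, never dropped rows;
missing outcomes are dropped and tallied. The focal predicate is
"pesticides in at least one year AND births in every study year"; the
stricter "pesticides in every year" reading is available via
`require_pesticides_every_year=True`. The interior buffer uses Chebyshev
distance to the Section edge; a 200 m buffer on a 1609.344 m Section
removes 1 − (1209.344/1609.344)² ≈ 43.5% of its area.

## Estimator

Township-year fixed effects are absorbed by within-group demeaning; month
and covariate dummies are few and kept explicit, which keeps the degrees of
freedom bookkeeping transparent (K counts explicit columns plus absorbed
groups). By Frisch–Waugh the demeaned OLS coefficients and their
cluster-sandwich blocks equal the explicit-dummy fit; the test suite checks
this to 1e-8 on random instances, and the CR1 sandwich against a
brute-force loop over clusters. Collinear columns are dropped greedily in
column order by Gram–Schmidt with re-orthogonalization (tolerance 1e-8
relative), so which column survives a collinear pair is deterministic and
reported.

Finite-sample choices, recorded because the design leaves them open: the
cluster correction is CR1, G/(G−1)·(N−1)/(N−K); p-values use t with G−1
degrees of freedom (conservative). Linear-probability fits are not
clipped; the count of fitted values outside [0, 1] is carried as a
diagnostic. R² is reported on the original outcome scale (1 − SSR/SST),
with residuals identical to the full-dummy regression's.

## Synthetic data generator

The generator emulates the *structure* of a linked birth–pesticide panel,
not any real geography: a rectangular grid of 1-mile Sections nested
36-per-Township, zipcodes built as contiguous 4–9-Section blocks cutting
across Townships (so the clustering level differs from both the exposure
unit and the FE unit), and a zero-inflated, heavy-tailed application
process. A fixed share (36%) of Sections is agricultural — the share is
exact by permutation rather than Bernoulli, the way a fixed landscape
would be, which keeps the exposed-birth share stable across seeds. Each
agricultural Section carries a lognormal latent intensity (σ = 1.25);
each of its months is zero with probability 0.45, otherwise lognormal
(μ = 5.0, σ = 1.0) scaled by intensity and a summer-peaked seasonal factor,
split into 1–5 records. These four numbers were calibrated once so that a
10 000-birth batch reproduces the target facts — ≈ 64% of births with zero
gestational exposure, mean ≈ 700–900 kg, 75/95/99th percentiles near
250–500 / 3500–4500 / 10 000–18 000 kg — and are not tuned per run.

Births are uniform over Sections with uniform within-Section coordinates
(the within-Section residential distribution is unknown; uniformity is an
assumption, flagged here). Binary outcomes come from a linear-probability
process — baseline rate + covariate shifts + Township-year effect + month
effect + injected effect × (gestational exposure ≥ its 95th percentile) —
clipped to [0.001, 0.999], so the estimand coincides with the estimator.
Township-year effects are partially loaded (weight 0.5) on the
Township-year's mean log exposure, so the fixed effects are genuinely
needed, and removed exactly by them. Gestation length and birth weight are
drawn conditionally on the preterm/low-weight flags so the binary and
continuous outcomes never contradict each other; injected log-outcome
effects act multiplicatively on the conditional draws, which makes
log-outcome effect recovery approximate rather than exact — the recovery
oracle therefore targets the binary preterm effect. Small fractions of
out-of-range or missing gestation/weight values and sub-threshold match
scores are injected so the cohort filters are exercised; they are
independent of exposure, so they do not bias recovery.

What passing tests on this generator do **not** show about real data:
no geocoding error structure beyond a scalar match score, no pesticide
drift across Section boundaries, no spatial autocorrelation in covariates,
no correlation between residential choice and exposure beyond the
Township-year level, and no chemical-specific toxicology (toxicity classes
are exchangeable labels).

## Validation studies and problem sizes

Recovery and placebo studies use 200 replicates of 10 000 births over two
years on a 3×3-Township grid (324 Sections, ≈ 55 zipcode clusters,
18 Township-year groups) — large enough for ≈ 500 high-exposure births per
replicate and stable CR1 inference, small enough that a replicate runs in
well under a second. The injected preterm effect, 0.0075, is recovered
with |bias| within Monte-Carlo error and 95% CI coverage ≈ 0.95; the
placebo study injects the same effect through gestational exposure only
and finds the trimester-4 coefficient rejecting at ≈ 5%, i.e. the
serial correlation of Section-level exposure does not leak a detectable
post-birth artefact at this effect size. The analysis drivers use one
15-year, 30 000-birth study with a 2006-style missing-tobacco year.

## Known limitations

The percent-change convention for log outcomes is the first-order
100·θ (the exact 100·(e^θ−1) is available); at the effect sizes involved
the difference is far below reporting precision. The battery's robustness
panels reuse the focal sample, so its > 100 coefficients are correlated
tests — the Bonferroni flag (α/25 = 0.002 at 5 outcomes × 5 terms) is the
only multiplicity device, matching the design it implements. Zipcode-year
fixed effects and Township-level clustering are available as variants but
the shipped battery holds the Township-year + zipcode-cluster structure.
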