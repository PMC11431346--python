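# Methods

## Ridit scores

Ordered socioeconomic groups (education in years of study: 0–4, 5–8, 9–11,
12+; per-capita income in minimum wages: 0–1, 1.1–2, 2.1–3, 3.1+) are
scored by the midpoint of each group's range in the weighted cumulative
population distribution. The ordering is fixed by configuration, most
disadvantaged first, never inferred from the data. Scores are computed
within each analysis domain and each survey wave, so between-wave shifts in
group composition change the covariate rather than biasing comparisons;
a flag allows national scores to be reused in regional analyses instead.
Zero-share categories are dropped with a warning (their midpoint would sit
on a bin edge and carries no observations); a distribution concentrated in
a single category is an error, since no gradient is then estimable.
Identities maintained and tested: share-weighted mean score exactly 0.5,
reflection of the ordering maps scores m to 1 − m, merging adjacent
categories preserves the mean, and scores are invariant to rescaling all
weights.

## SII / RII estimation

Both indices come from a weighted binomial GLM of the binary outcome on the
ridit score plus additive adjusters (sex and age group by default):
identity link for the SII (prevalence difference over the full
socioeconomic range), log link for the RII (prevalence ratio,
exponentiated coefficient). Survey weights enter as frequency-style
analysis weights in the likelihood.

The fitter is iteratively reweighted least squares with two feasibility
safeguards, because identity- and log-link binomial models can push fitted
probabilities out of (0, 1): fitted values are clamped to (eps, 1 − eps)
with eps = 1e−8, and each IRLS step is halved (up to 30 times) until the
deviance does not deteriorate. Convergence is declared when the deviance
change falls below 1e−12 relative. Non-convergence is never silent: the
identity link falls back to a weighted linear-probability least-squares fit
with robust covariance, the log link refits with the always-well-behaved
logit link and recovers the ratio by marginal standardization (predict all
records at score 1 and at score 0, weighted-average, take the ratio, delta
method on the log scale); the estimate object carries the convergence flag
and fallback name.

Variance is a cluster-robust sandwich: bread from the IRLS information,
meat from score contributions summed within primary sampling units, scaled
by G/(G − 1) for G clusters. When strata are supplied, cluster scores are
centered on their stratum mean with an n_h/(n_h − 1) factor per stratum
(Taylor-linearization form). Without PSU identifiers every record is its
own cluster, which reduces to a heteroskedasticity-robust estimator.
Confidence intervals are 95% Wald with normal quantiles — natural scale
for the SII, log scale then exponentiated for the RII (so the RII interval
is always positive). Normal rather than t quantiles are used; with the
cluster counts of national surveys (thousands of census sectors) the
difference is negligible, and the sandwich already carries the
small-sample factor. No multiple-testing correction is applied.

A grouped-data oracle provides an independent route: a grouped distribution
(shares + prevalences) is expanded to two weighted pseudo-records per group
— the sufficient statistics of any binomial GLM on the group structure —
and fitted identically; a closed-form share-weighted least-squares variant
(slope of group prevalences, or log prevalences, on midpoints) is also
available for cross-checks. Grouped and microdata fits with identical
aggregates agree to 1e−6, and in the two-group saturated case the GLM
interpolates exactly, giving the closed forms SII = Δp/Δx and
RII = exp(Δlog p/Δx).

## Trend between waves

Change in either index between exactly two waves is a Wald test of the
ridit-by-wave interaction in the pooled weighted GLM. By default the
adjusters also interact with wave, so the pooled model is a saturated
reparametrization of the two per-wave fits and the interaction equals the
contrast of the per-wave indices exactly (difference for SII, ratio for
RII); this mirrors how published per-wave values relate to their printed
interaction terms. `shared_adjusters=True` constrains adjuster effects to
be equal across waves, trading that exactness for efficiency. Exchanging
the wave labels negates the SII difference and inverts the RII ratio.

## Predictive margins

Adjusted prevalences by income × education come from a weighted logistic
model with the full interaction plus region, sex and age group. Margins
are "at observed covariates" averages (marginal standardization /
g-computation), not at-means: for each cell, all records are assigned to
the cell and predictions averaged with the survey weights. Delta-method
CIs use the cluster-robust covariance, truncated to [0, 1]. Cells with no
observations are reported as non-estimable with a reason, never
extrapolated. Exact identities hold and are tested in the settings where
the algebra guarantees them: an intercept-only model returns the weighted
overall prevalence in every cell, and with the saturated interaction and
no other covariates the margins equal the observed weighted cell
prevalences, so their weighted average equals the overall fitted
prevalence (to 1e−6). With additional correlated covariates the
average-of-margins identity is approximate, which is the expected behavior
of predictive margins.

## Synthetic data

The generator emulates the structure of a two-wave national household
survey: per-wave group shares; truth specified either as group prevalences
(to mirror published tables), linear-in-ridit p = a + b·x (true SII = b),
or log-linear (true RII = exp(b)); additive sex/age risk offsets; PSU
clustering with within-cluster outcome correlation induced by pushing one
uniform draw per PSU through each record's beta quantile function
(mean-preserving, correlation ≈ icc); optional socioeconomic segregation
of PSUs (per-PSU Dirichlet group shares) — the feature that makes cluster
sampling actually inflate the variance of the inequality slope, since a
cluster effect orthogonal to the covariate would inflate only the
intercept; and optionally informative sampling, where the sampled group
distribution is tilted and weights are the inverse tilt, so weighted
estimators stay consistent while unweighted ones drift. Any cell
probability outside (0, 1) aborts before sampling. Identical design and
seed give identical records.

What the generator does not emulate: the three-stage sample selection of a
real national survey (households within sectors, one adult per household),
item nonresponse mechanisms, measurement error in self-reports, and
spatial structure beyond PSU labels. Passing tests therefore demonstrate
correctness of the estimators under a correctly specified sampling model,
not robustness to those real-data features.

Default validation problem sizes: parameter recovery uses 200 replicates
at n = 50,000 with linear truth b = 0.30 (mean within ±0.01, CI coverage
in [0.92, 0.98]); the trend type-I check uses 500 two-wave replicates at
n = 5,000 per wave (rejection rate in [0.03, 0.07] at α = 0.05). Both run
unadjusted and unclustered, matching the truth used to generate the data.

## Recoding conventions

The income bins printed as "0–1, 1.1–2, 2.1–3, 3.1 or more" minimum wages
are implemented as the half-open partition (0, 1], (1, 2], (2, 3],
(3, ∞) — the printed labels are read as rounded displays, giving an
exhaustive partition with no gap between 1 and 1.1. Minimum-wage values
are per-wave configuration (BRL 678.00 for 2013, BRL 998.00 for 2019).
Education course labels map to years-of-study bins via a declarative
config; unfinished-course handling lives in that mapping, defaulting to
the standard category list. Analysis is complete-case with a per-reason
reject tally; accepted plus rejected rows always equal the input count.
Missing PSU/stratum is permitted and degrades variance estimation to the
heteroskedasticity-robust form.

## Reference distributions

The published 2013/2019 grouped education and income distributions are
bundled with shares renormalized to 1. Known issues are flagged rather
than patched: the income-2013 shares as printed sum to 90.38% (the 1.1–2
MW share appears to duplicate another cell), so that distribution carries
a data-quality flag and is excluded from overall-prevalence consistency
checks; one education-2013 confidence-interval bound is internally
inconsistent in the source and CI bounds are not bundled at all.

## Known limitations

Identity-link binomial feasibility is handled by clamping and step-halving
rather than constrained maximization; in pathological separations the
linear-probability fallback is reported instead. The trend test supports
exactly two waves. Weights are treated as analysis weights — the
finite-population correction of a fully specified multistage design is not
implemented, only PSU/stratum linearization. The RII fallback through
logit margins estimates a marginal, not conditional, ratio; it is labelled
as a fallback in the output.
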