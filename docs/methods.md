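# Methods

This note documents the statistical models, defaults and numerical
choices behind `centiledesign`, and what the synthetic-data generator
does and does not emulate.

## The centile engine

All charts are parametric normal: conditional on gestational age (GA),
the measurement is N(μ(GA), σ²(GA)), so the *p*-th centile is
μ + z_p·σ and z-scores are (y − μ)/σ.  This is the standard working
assumption for fetal biometry; it is *not* adequate for skewed outcomes
such as birth weight, which need transformation or skewness modelling
and are outside this package's scope.  The goodness-of-fit diagnostics
(per-week mean/SD of z-scores; observed vs nominal proportions below
fitted centiles with exact Clopper–Pearson intervals) are the intended
guard: a per-week z-score SD drifting from 1, or extreme-centile
proportions outside their intervals, signals that the normal engine
should not be used for that outcome.

GA is stored in integer days (0–301) and exposed in decimal weeks;
"completed weeks" is floor(days/7) and is the binning unit of all
reporting tables.  Models refuse to extrapolate outside the fitted GA
domain rather than extrapolating silently.

## Fitting μ(GA) and σ(GA)

Both curves are polynomials in GA (weeks), default degrees 2 (mean) and
1 (SD).  The basis is centred at 28 weeks during fitting to reduce
collinearity; stored and exported coefficients are de-centred to raw
weeks so published equations apply directly.  The SD curve is fitted by
regressing the absolute mean-fit residuals on the same basis and
scaling by √(π/2) (E|X| = σ√(2/π) for centred normals).  Absolute
residuals were chosen over squared residuals for resistance to
outliers; the efficiency loss is modest (relative SE of the fitted
scale ≈ √((π/2−1)/n) versus √(1/2n)).  A fit whose σ(GA) is not
strictly positive over the observed range is rejected outright, which
also means literally noise-free data cannot be fitted — the
interpolation limit is exercised in tests with a 1e−9 noise floor.

Identifiability requirements: at least max(mean_degree, sd_degree)+1
distinct GA values and mean_degree+sd_degree+2 observations.  The
degenerate all-one-GA schedule (needed as a closed-form oracle case for
the design factor) therefore fits degree-0 curves.

## Precision and sample size

`centile_se` implements SE_p = SD·√((1 + ½z_p²)/n); the %CV form is the
same formula on the relative scale.  `sample_size_for_se` returns the
exact integer inverse (ceiling), floored at n = 2, and satisfies the
bracketing property SE(n) ≤ target < SE(n−1).  Attrition inflation is
ceil(n/(1−rate)).  The Monte-Carlo oracle simulates the *plug-in*
estimator x̄ + z_p·s, the object the formula describes; the empirical
order statistic has a larger SE and is deliberately not simulated.

A documented discrepancy: a published worked trio of sample sizes
(3680/2800/2160 at CV 6%, target %SE 0.50, for the 2.5th/5th/10th
centile pairs) is mutually inconsistent with the formula itself, which
yields 421/339/263 for those inputs.  The package reproduces and
verifies (by simulation) the formula-side numbers and does not guess at
an unstated convention behind the larger trio.  The WHO 1995 rule of
thumb (≥200 individuals) is surfaced only as a CLI warning threshold.

## Design factor

D = Var_CS(centile)/Var_long(centile) at equal subject counts.  The
simulator induces within-subject correlation ρ with a subject-level
random intercept (exchangeable structure — recorded in the output;
AR-type structures are not modelled), simulates both designs, fits each
with the standard chart fitter, and compares the across-replicate
variance of the fitted centile at a reference GA (default: 97.5th
centile at 28 weeks).  The Monte-Carlo error of D uses the
fourth-moment formula for the variance of a sample variance.

The closed form m/(1 + (m−1)ρ) is the variance ratio for a *mean* of m
exchangeable measurements.  It is exact for the simulated D at the
median centile with a single-GA schedule, and that is where the
simulator-vs-closed-form agreement is asserted; at p ≠ 0.5 the centile
estimate also carries Var(σ̂), whose longitudinal/cross-sectional ratio
differs from the mean's once ρ > 0, so the closed form there is a
magnitude guide only.  At ρ = 0 the ratio is m for every centile, which
is asserted directly.

Default fetal-like design: four scans at 20/24/28/32 weeks, ρ = 0.6,
150 subjects per arm.  Under these defaults D ≈ 2.6, i.e. a
longitudinal study needs roughly half to a third the subjects of a
cross-sectional one — consistent with published simulation work on
biparietal diameter (D ≈ 2.3), which is treated as a magnitude anchor,
not a reproduction target, since its variance components are not
available.  Note that D here exceeds the fixed-GA closed form
(4/(1+3·0.6) ≈ 1.43) because with visits spread over GA the subject
intercept inflates only the level component of the fitted curves.

## Multicentre poolability

Standardized differences delta = (site centile − pooled centile)/pooled
σ(GA) are computed on a grid (default: every completed week of the
common domain) for the 3rd/50th/97th centiles (the chart-defining
extremes plus the median), and a site is poolable when max|delta| stays
below the prespecified threshold (default 0.5 SD — Cohen's "medium").
Differences are standardized by the *pooled* model's σ because the
criterion guards the pooled standard; whose SD to use is not settled in
the field and is recorded as a package decision in the output
provenance block, along with the threshold.  No significance testing is
performed anywhere in the module: with realistic site sizes trivial
differences are significant, and the question is whether they are
large.

Operating characteristics worth knowing (measured by the test suite):
with eight equal sites, a site shifted by s SD sits only s·7/8 SD from
the pooled curves (its own data pull the pool), and the shift inflates
the pooled σ̂ slightly, so a +0.6 SD site has an expected maximum
standardized difference of ≈ 0.55 SD.  Detecting it against the 0.5
threshold with ≥95% probability therefore needs per-site fit noise
below ≈ 0.03 SD (≈ 3500 subjects per site for the default generator);
at 500 subjects per site detection probability is ≈ 93%.  Null sites
pass essentially always at either size.

## Replicates

Aggregation rules: median of triplicates, mean of duplicates, or a
seeded single random replicate.  Missing-replicate policy (the source
protocols specify intent but no rule): the same statistic is applied to
what is present — median of 2 equals mean of 2, a single survivor is
used as-is — and the provenance column marks the row `-incomplete`;
strict mode rejects instead.  Variance components use the one-way
layout: within = mean within-group variance, between = variance of
group means − within/m̄, floored at zero.

The sensitivity analysis fits the chart twice — aggregated series vs
seeded single-measurement series on the same subjects — and reports the
σ̂(GA) ratio and 3rd–97th centile-width ratio (identical for a normal
chart).  With triplicate medians the residual replicate-noise variance
is ≈ 0.449·w² versus w² for singles, so the aggregated chart is
systematically tighter whenever w > 0.  No variance-correction factor
is applied to either fit: the repeated-measures Bland–Altman correction
is available (`bland_altman_repeated`) as a clearly labelled
sensitivity output only, since it is reported to overestimate
variability for growth data.

## Quality control

Digit preference: values are rounded to the declared instrument
resolution, the terminal digit (value in resolution units, mod 10) is
tabulated, and χ² against uniform (df = 9) is reported, with digits
beyond 3 binomial SEs of 0.10 flagged and n < 50 marked low-power.
TEM = √(Σd²/2n) over duplicate pairs, relative TEM = 100·TEM/grand
mean.  Bland–Altman: bias ± 1.96·SD of differences; constant
differences collapse the limits and are flagged rather than rejected.
CUSUM: one-sided upper and lower reset-at-zero recursions with
conventional defaults k = 0.5, h = 4 on the standardised-error scale;
alarm indices are 0-based.  Under pure duplicate error, SD(differences)
estimates √2·TEM — asserted as a cross-check between the two error
scales.

## The synthetic-data generator

One replicate of subject i at GA t in site s is

    value = μ(t) + shift_s·σ(t) + c_b·σ(t)·d_i + bias(observer) + ε,
    d_i ~ N(0,1),  ε ~ N(0, w²)

Default truth: μ(t) = −30 + 9t − 0.05t² mm, σ(t) = 1 + 0.2t mm over
14–42 weeks (head-circumference-scale values with variability
increasing with GA).  Defaults: 8 sites × 300 subjects, five visits at
5-week spacing from a uniform 14–22-week entry, triplicate replicates,
w = 2 mm, c_b = 1 (so the error-free single-measurement SD is exactly
σ(t)), no heaping, no attrition, LMP recall error SD 7 days.  The
between-subject scale multiplies σ(t) rather than being an absolute
constant so that a cross-sectional fit recovers the generating σ(t)
curve — the package's parameter-recovery tests depend on this.

Contamination knobs: digit heaping rounds a seeded fraction of values
toward terminal digit 0 or 5 (3:1, reflecting the dominance of
whole-ten heaping in real audits); attrition drops a seeded subject
subset's visits from a uniform dropout visit onward; dating error adds
a rounded-to-whole-days normal error to the LMP estimate (ultrasound is
taken as the reference).  Because the error is recorded in whole days,
the share failing the 7-day rule at error SD 7 is 2(1−Φ(7.5/7)) ≈ 0.284,
not the continuous-limit 2(1−Φ(1)) ≈ 0.317.

What the generator does *not* emulate: growth-restricted or otherwise
pathological trajectories, skewed outcomes, AR-type visit-to-visit
correlation (the subject effect d_i is GA-stable, i.e. tracking
correlation 1 for error-free values — an upper bound on real fetal
tracking), GA-dependent attrition, or observer drift over time.
Passing tests therefore demonstrate correctness of the machinery under
a clean, well-specified data-generating process, not robustness to
every failure mode of real studies.

## Numerical choices and problem sizes

* Normal quantiles/CDF: scipy.stats.norm; exact binomial intervals:
  scipy.stats.binomtest; polynomial least squares: numpy.polynomial.
* Sample sizes are always rounded up; minimum returned n is 2.
* The coverage check of the fitted 95% reference interval uses a
  200,000-draw training study and 10⁶ fresh test draws, sized so that
  training noise (≈0.04 pp of coverage, driven by Var(σ̂):
  d(coverage) ≈ 0.229·dσ/σ) is negligible against the ±0.1 pp
  assertion.  At a 2000-subject training study (the acceptance script's
  end-to-end setting) the per-seed coverage spread is ≈ ±0.4 pp.
* Simulation-based tests use 100 seeds (pooling), 60 seeds
  (replicates), and 1000–1500 replicates (design factor), keeping the
  full suite under a minute on one CPU while leaving ≥3 MC errors of
  headroom on every agreement assertion.
* Pregnancy dating keeps the LMP estimate when LMP and ultrasound agree
  within the tolerance (7 days by default) and falls back to ultrasound
  otherwise; the preferred compatible source is configurable since
  practice varies.
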