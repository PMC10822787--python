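# Methods

## Model

For one phenotype, family data are organised into five twin groups (MZM,
DZM, MZF, DZF, DZOS) and two singleton groups (SGM, SGF).  Each family's
observation vector is modelled as multivariate normal with group-specific
moments.  Two model families are implemented.

**Constrained correlation model.**  Means and variances are free per sex but
shared across birth order, zygosity group and twin/singleton status within
sex; one correlation is free per twin group.  Nine parameters: two means,
two variances, five correlations.  This is the maximum-likelihood analogue
of reporting per-group Pearson correlations while letting singletons and
incomplete pairs inform the means and variances.

**ACE sex-limitation ladder.**  Per sex s, path coefficients (a_s, c_s, e_s)
give total variance v_s = a_s² + c_s² + e_s², MZ covariance a_s² + c_s²,
same-sex DZ covariance 0.5 a_s² + c_s², and opposite-sex covariance
rA_mf·a_m·a_f + rC_mf·c_m·c_f.  The ladder members are:

| label | free parameters | count |
|---|---|---|
| FULL_HET_QUAL_A | sex-specific paths + free rA_mf (rC_mf = 1) | 9 |
| FULL_HET_QUAL_C | sex-specific paths + free rC_mf (rA_mf = 0.5) | 9 |
| QUANT_HET | sex-specific paths, rA_mf = 0.5, rC_mf = 1 | 8 |
| SCALAR_NO_SEXDIF | shared paths + female SD scalar k | 6 |
| HOMOGENEITY | shared paths, k = 1 | 5 |

(each count includes the two sex-specific means).  The two qualitative
models are never combined: the opposite-sex covariance is a single statistic
and cannot identify both cross-sex correlations jointly; requesting both
raises an identification error.

Parameterizing by path coefficients bounded below at zero enforces
A, C, E ≥ 0 without inequality machinery; boundary solutions sit at a path
of exactly 0, which is why boundary components print as `0.00 [0.00–x]`.
E is bounded away from zero (1e-3 on the path) because it contains
measurement error and a zero-E model is degenerate on real data.  Means are
always free per sex even on residualized (≈ centred) inputs: two parameters
buy robustness against non-centred inputs.  The scalar k multiplies the
female standard deviation with male as the reference sex.

## Likelihood and optimization

The objective is FIML on raw data: each family contributes −2 log of the
normal density restricted to its observed entries (complete pairs bivariate,
half-missing pairs and singletons univariate).  Per group the data are
collapsed to sufficient statistics by missingness pattern (count, sum, sum
of outer products), making one objective evaluation independent of sample
size; this is what keeps replicate-heavy simulations cheap.

Optimization is L-BFGS-B with finite-difference gradients, convergence
tolerance 1e-11 on the relative change of −2LL, bounds as above, and
jittered multi-starts (default 3) around a data-driven start (pooled
moments, per-group Pearson correlations, and the closed-form approximation
A = 2(rMZ − rDZ), C = 2 rDZ − rMZ).  Ladder fits run from most to least
constrained and each fuller model receives its nested predecessor's solution
as an extra start, which guarantees −2LL monotonicity along nested chains up
to numerical noise.  A non-positive-definite proposal is answered with a
large finite penalty; with the chosen parameterization the interior of the
feasible box is always positive definite (Cauchy–Schwarz bounds the
opposite-sex covariance whenever e > 0), so penalties arise only at
degenerate edges.

## Model comparison and selection

Nested pairs are compared by Δ(−2LL) referred to chi-square with df equal to
the difference in free-parameter count.  Negative deltas within 1e-6 are
numerical noise and are clipped to zero (larger negative deltas cannot arise
with chain warm starts; they would be clipped too, with the raw value kept
on the comparison object).  The best-fitting label is the most constrained
model not rejected at α = 0.05 against the least constrained ACE model
(whichever qualitative variant fits better), scanning in parsimony order
HOMOGENEITY → SCALAR → QUANT_HET; if all are rejected the qualitative
baseline is kept.  This parsimony-preferring stepwise rule reproduces the
qualitative labels seen in applied reports; AIC is available per fit for
transparency.  Testing C = 0 (or A = 0) places the null on the boundary of
the parameter space, which makes the naive chi-square reference
conservative; the naive test is reported as is conventional for this
design.

## Confidence intervals

95% bounds are profile-likelihood: the value of the target at which the
re-optimized deviance exceeds its minimum by 3.841.  Named parameters
(e.g. the five group correlations) are profiled by bisection on the profiled
deviance (parameter tolerance 1e-4), with a parameter-space limit reported
(and flagged) when the deviance never crosses the threshold before the
limit — this yields the exact `0.00` lower bounds of boundary components.
Standardized components are functions of several paths, so their bounds are
computed as constrained extrema of the component subject to the deviance
budget (SLSQP); a solution is accepted only if feasible and consistent with
the point estimate, otherwise the bound falls back to bisection on an
equality-constrained profiled deviance.  Both routes agree on named
parameters (cross-checked in the test suite).  Coverage of the generating A
is 90–99% across 200 simulated cohorts at realistic register size (checked
in the acceptance suite).

## Synthetic-data generator

The generator emulates a population twin register: five twin groups plus
singletons with default sizes of 242/164/326/221 same-sex pairs, 373
opposite-sex pairs and 353/566 male/female singletons (matching the scale of
a real South Asian register with roughly 2 900 twins and 1 000 singletons);
ages uniform on 19–91 years and shared within pair; optional linear age and
sex effects on the mean; latent A/C/E scores constructed so cross-twin
correlations are exact (co-twin score r·X₁ + √(1−r²)·Z); optional
count-like measurement through the monotone link round(exp(0.8·z + 0.7)) of
the standardized liability; and optional outlier contamination shifting a
Bernoulli subset by +m·SD.  Default generating components are
A = 0.30, C = 0.22, E = 0.48 equal across sexes — a moderate-heritability,
nonzero-C configuration typical of food-frequency and anthropometric
phenotypes.

What the generator does not emulate: non-normal residual structure beyond
the count link, informative missingness (missingness is injected at random),
age-moderated variance components, assortative mating, or household
clustering beyond the twin pair.  Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the stated model,
not robustness to these real-data features.

## Preprocessing conventions

Cleaning order is: raw-scale outlier handling, then OLS residualization on
age and sex, then an optional natural-log transform applied to
positivity-shifted residuals (shift chosen so the minimum maps to ln 1 = 0
and recorded in the run info).  The two outlier rules are (i) replacement of
values above an absolute cutoff by the mean of the remaining values
(reported rounded to 2 decimals), and (ii) a single-pass 3-SD rule: mean and
SD computed once on all observed values, entries strictly beyond the cutoff
set to missing (a value exactly at mean ± 3 SD is retained).  Skewness is
the adjusted Fisher–Pearson sample coefficient and kurtosis is sample excess
kurtosis; the excess convention is the one under which mildly platykurtic
measures print small negative values.  A covariate that does not vary is
dropped from the residualization design; a design with no varying covariate
raises a degenerate-design error.

## Sizes used in tests and validation

Recovery runs use 20 replicates at 5 000 pairs per group (Monte-Carlo error
on a mean standardized component ≈ 0.005, comfortably inside the ±0.03
check); selection-consistency runs use 100 replicates at the default
register size; CI coverage uses 200 such replicates; the closed-form
simulator check uses 50 000 pairs per group.  These sizes were chosen so
every stochastic check is decisively inside its tolerance at desk scale.

## Known limitations

Univariate phenotypes only (the screen gates, but the package does not fit,
bivariate Cholesky models); no extended pedigrees or non-twin siblings; no
ordinal/threshold liability models — count data are treated through
transform-then-Gaussian analysis; LRT p-values for boundary hypotheses are
conservative as noted; profile bounds assume a unimodal deviance in the
profiled direction, which holds for this likelihood in practice but is not
verified globally.
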