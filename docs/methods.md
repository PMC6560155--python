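# Methods

This note records the statistical model, the estimators, the synthetic data
generator, and the numerical choices made in `aarratio`. Everything stated
here is implemented and exercised by the test suite; no empirical claim is
made beyond what the code computes.

## Quantities

For region i and age stratum j, let `D_ij` be the event count and `n_ij` the
person-years at risk. With standard-population weights `w_j` (summing to 1),
the age-adjusted rate (AAR) is

```
R_i = 100000 * sum_j w_j * D_ij / n_ij
```

The parent-area rate `R_Omega` uses the stratum-pooled counts
`sum_i D_ij / sum_i n_ij`. The target of inference is the rate ratio
`RR_i = R_i / R_Omega`. Because region i's cases are inside the parent
totals, `R_i` and `R_Omega` are positively correlated, with the correlation
governed by the region's population share `p_i = n_i / n_Omega`.

## Closed-form interval methods

**Direct.** Let `rho_i = R_i / R_(-i)` compare the region to the parent with
the region removed; the two rates are then independent linear combinations of
Poisson counts. Delta-method moments

```
E[rho] = mu_i / mu_(-i)
Var[rho] = (sigma_i^2 mu_(-i)^2 + sigma_(-i)^2 mu_i^2) / mu_(-i)^4
```

with the Poisson plug-in `Var(R_i) = sum_j w_j^2 r_ij / n_ij` give a
log-normal interval `rho * exp(+/- z * CV)`. The reported point estimate is
the ratio to the full parent, `R_i / R_Omega`.

**Overlap.** The identity `R_Omega = p_i R_i + (1 - p_i) R_(-i)` (which is
exact when the region's age composition matches the parent's, as it does in
the synthetic population by construction) yields

```
RR_i = rho / (p_i * rho + 1 - p_i)
```

a strictly increasing map, so the Direct interval endpoints transform
directly. Near the null (`rho ~ 1`) the map's derivative is `1 - p_i < 1`, so
the Overlap interval is shorter; its derivative is globally bounded by
`1 / (1 - p_i)`, so in the rare case of an interval sitting entirely far
below the null the Overlap interval can exceed the Direct one by at most that
factor (observed: 8 of 12,000 synthetic intervals, by at most 0.03% of the
length).

**Spatial.** The log-scale variance of the ratio decomposes into the region
variance, the parent variance, their population-overlap covariance, and the
spatial autocorrelation between regions. The first three are what the Overlap
interval already encodes, so the Spatial interval removes the autocorrelation
component from it. An exponential semivariogram
`gamma(d) = c0 + c1 (1 - exp(-d/a))` is fitted to the log AARs by weighted
least squares (pair-count weights on binned semivariances). On the
correlation scale the fitted model says two regions at distance d have
log-rate correlation `rho(d) = c1 exp(-d/a) / (c0 + c1)` — the nugget `c0`
carries the spatially uncorrelated noise. Linearising `ln R_Omega` as the
share-weighted mixture of region log rates, the removable variance fraction
for region i is

```
rho_bar_i = sum_{i' != i} share_i' * rho(d_ii')   in [0, 1)
```

and the Spatial interval shrinks the Overlap interval's log offsets by
`sqrt(1 - rho_bar_i)`. Consequences: a zero fitted sill reproduces the
Overlap interval exactly; a positive sill always tightens, and the interval
can never collapse to zero width or invert. An earlier formulation that
subtracted the raw fitted covariance from the (Poisson-noise-only) overlap
variance could drive the variance negative and collapse intervals; the
correlation-scale formulation avoids that failure mode by construction.

**Semivariogram identifiability.** Beyond the observed distance support, the
range `a` trades off freely against the sill (`c1 (1 - exp(-d/a)) ~ c1 d / a`
for `d << a`), so the fit constrains `a` to at most the largest bin distance
and caps `c0`, `c1` at twice the larger of the field variance and the largest
bin semivariance. A near-constant field returns a zero-sill model with a
warning rather than failing.

**Zero counts.** A region with zero total count gets 0.5 events spread over
its strata proportionally to population so log-scale intervals stay finite;
such estimates are flagged `degenerate`.

## Bayesian convolution model (BCM)

```
D_ij ~ Poisson(e_ij * theta_i)
log theta_i = alpha0 + v_i + u_i
v_i ~ N(0, 1/tau_v)                      (exchangeable heterogeneity)
u | tau_u ~ intrinsic CAR                 (spatial smoothness)
alpha0 ~ N(0, sigma_alpha^2), sigma_alpha ~ U(0, 100)
tau_v, tau_u ~ Gamma(shape 2, rate 0.5)
```

`e_ij` is the expected count offset (population times pooled stratum rate by
default, or user-supplied). The intrinsic CAR prior is used in the
convention where each unordered neighbour pair contributes
`-(tau_u/2)(u_i - u_j)^2` to the log density, which makes the site
conditional exactly `N(neighbour mean, 1/(tau_u * n_neighbours))`; the test
suite verifies the proportionality on a grid. The improper CAR level is fixed
by recentring `u` to mean zero every sweep (the mean is absorbed by
`alpha0`).

**Sampler.** Metropolis-within-Gibbs: random-walk Metropolis for `alpha0`,
`v`, and `sigma_alpha`; Metropolis updates for `u` vectorised over
graph-colouring classes (all regions in a colour class have no neighbours in
common and update simultaneously); conjugate Gamma draws for `tau_v` and
`tau_u` (`Gamma(shape + I/2, rate + quadform/2)`). Proposal scales adapt
toward 20–45% acceptance during burn-in only, so the retained chain is a
valid fixed-kernel Markov chain. Correctness anchor: on a two-region toy
with fixed precisions, the sampler's posterior mean of `alpha0` matches full
numerical integration of the same unnormalised posterior within 0.02.

**Intervals.** For each retained draw g, counts are simulated from the fitted
model (`D^P ~ Poisson(e_ij theta_i^(g))`), AARs and rate ratios are recomputed
exactly as for observed data, and equal-tailed percentile intervals are
reported. These posterior-predictive intervals include count-level noise and
hyper-parameter uncertainty, which is why the BCM intervals are the widest of
the four methods.

**Identifiability.** When `e_ij` is computed from the data itself, the
pooled rate absorbs the level of `theta`, so `alpha0` is not identified
against a generating value; parameter-recovery checks pass the generating
baseline offsets explicitly and compare `alpha0` to the identified quantity
`alpha0_true + mean(v_true)` (the CAR field is centred by construction).

## Synthetic data generator

The study region is a 10x12 rook lattice of 120 counties in three population
tiers of 40 (tier mean person-years 191,000 / 48,000 / 24,000; log-normal
within tier, rescaled so tier means are exact; tiers scattered over the
lattice by a seeded permutation so size is not confounded with location).
All counties share one age distribution (weights 0.25/0.25/0.2/0.2/0.1 over
five strata), which makes the population-share identity behind the Overlap
method hold exactly. Three generating scenarios for the relative-risk field:

- **T1** (convolution): `log theta_i = alpha0 + v_i + u_i`, with the ICAR
  field sampled *exactly* on its sum-to-zero subspace via the graph-Laplacian
  eigenbasis (no MCMC in the generator).
- **T2** (common spatial trend): linear trend in standardised lattice
  coordinates plus an age random effect.
- **T3** (uncorrelated): independent county and age effects.

Counts are `D_ij ~ Poisson(b * n_ij * theta_ij)` with `b` calibrated per
replicate so the conditional expected total equals the target (3,000 for a
rare disease, 13,000 for a common one); realised totals are unbiased within
Monte-Carlo error. Because `b` is calibrated, only the relative variation of
`theta` matters; the plausibility check that relative risks stay roughly in
(0.3, 3.0) is applied to `theta` normalised by its population-weighted mean,
and a warning is emitted if more than 1% of values fall outside.

Realism notes: population tier structure, age standardisation, count scales
and the spatial field follow published small-area surveillance settings; the
lattice geometry and the shared age distribution are idealisations (real
county systems have irregular adjacency and varying age structure).

## Evaluation

Per (method, tier): mean 95% CI length, coverage, and SD of CI length. Tiers
are population-rank thirds (ties broken by roster order). Coverage has two
readings shipped side by side: the standard fraction of intervals containing
the per-region true rate ratio (primary), and the mean fractional overlap of
each interval with a reference interval (secondary, since the source wording
for this criterion is ambiguous). The "true" rate ratio of a synthetic region
is the mean observed ratio over replicates. Method agreement is summarised by
robust IRLS regression (weights `1 / max(|residual|, 1e-6)`, tolerance 1e-8)
of one method's interval lengths on another's, raw and z-scored.

## Numerical choices

- Log-scale variances floored at 1e-12 so intervals are always well defined.
- Interval endpoints are widened (never narrowed) to contain the point
  estimate in the rare case the rho-interval maps to one side of it.
- All randomness flows from explicit seeds; CLI substreams are spawned with
  `numpy.random.SeedSequence` so each pipeline stage is independently
  reproducible and full reruns are byte-identical.
- MCMC defaults (10,000 iterations, 5,000 burn-in, thin 5) suit the 120-region
  problem; the correctness tests use shorter, validated configurations.

## Limitations

- The Spatial method's variance decomposition is a first-order construction:
  the semivariogram is fitted to a single cross-section of noisy log rates,
  and the removable fraction relies on a linearisation of the parent log
  rate. It guarantees sensible behaviour (never wider than Overlap, never
  degenerate) but is not an exact variance for any explicit generative model.
- The Overlap transform assumes the region's age composition matches the
  parent's; with strongly differing compositions the population-share
  identity is only approximate.
- The intrinsic CAR prior is improper; its level is fixed by recentring,
  which is standard but means `u` is only interpretable up to contrasts.
- Posterior-predictive intervals are calibrated for *predicted* ratios; they
  are conservative for the underlying risk-ratio parameters.
- The delta-method intervals rely on large-ish counts; the 0.5-event
  continuity correction keeps zero-count regions finite but their intervals
  are flagged and should be read with caution.
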