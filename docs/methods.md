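# Methods

This note documents the statistical models implemented in `capdyn`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Observation model: two-session capture histories

A closed population of N individuals is sampled on two adjacent trapping
sessions; mortality and migration between the two days are ignored. With
session capture probabilities (p_{i1}, p_{i2}) and independent sessions
(the M_th structure: probabilities vary with session and with individual
covariates, but there is no behavioural response to first capture), the
four history categories have probabilities

    c_i0 = (1−p_{i1})(1−p_{i2}),  c_i1 = p_{i1}(1−p_{i2}),
    c_i2 = (1−p_{i1})p_{i2},      c_i3 = p_{i1}p_{i2}.

The number of never-captured animals is unknown, so the likelihood
conditions on capture: categories 1–3 follow a multinomial with
probabilities c_ik/(1−c_i0), modelled as a multinomial logit with
category-specific linear predictors V_ik = Σ_r γ_kr z_ir in the individual
covariates z_ir (weight, sex, …). Only differences γ_kr − γ_lr are
identifiable; the fit therefore fixes one category's coefficients at zero
(category 1 by default — the reported differences are invariant to this
choice, which is covered by a test). The two reported difference vectors

    δ1_r = γ_3r − γ_2r = logit-scale coefficients of p_{i1}
    δ2_r = γ_3r − γ_1r = logit-scale coefficients of p_{i2}

recover per-individual session probabilities and hence ĉ_{i0}.

Fitting is Newton–Raphson with analytic gradient and Hessian on the
conditional multinomial log-likelihood. Convergence requires gradient norm
< 1e−8 or relative log-likelihood change < 1e−10; at most 500 iterations.
An empty observed category raises an estimation-degeneracy error naming
the category; quasi-separation is detected as parameter divergence and
raised as a convergence error carrying the iteration trace. Categorical
covariates use treatment coding with the alphabetically first level as
baseline (documented because fitted probabilities on external data depend
on it).

The same likelihood can be rewritten as a Poisson log-linear model on an
augmented table (3 rows per individual, a free intercept per individual).
`CaptureModel.fit_poisson_augmented` implements this route through a
Poisson GLM and is used as an equivalence check (agreement to 1e−6 in the
δ's); the direct conditional fit is the default because it avoids n
nuisance intercepts. Some formulations add tiny Gaussian error terms to
the augmented model's linear predictor for computational reasons; the
likelihood here omits them (the limit of infinite error precision).

An optional Bayesian mode maximizes the posterior under a zero-mean
Gaussian coefficient prior (sd 10, weakly informative) and reports the
Gaussian (Laplace-style) approximation at the mode. AIC/BIC are defined
only for the ML fit; requesting them from a Bayesian-mode fit raises.

## Abundance

The Horvitz–Thompson estimator N̂ = Σ_i (1 − ĉ_{i0})⁻¹ is applied per time
point over the individuals captured there, using each individual's own
ĉ_{i0}. N̂ ≥ n always. Time points with zero captures are flagged missing
rather than imputed as zero (the log is undefined); downstream AR(2)
fitting refuses series with gaps and asks for splitting, mirroring the
field practice of dropping stations with insufficient observations. For
the Poisson (P) variant N̂_t is rounded to the nearest positive integer so
it can serve as a count; the A variant keeps the real value. No analytic
variance of N̂ is provided; first-stage uncertainty is propagated by
posterior sampling (below).

## Process model: AR(2) log-abundance dynamics

    x_t = ln η + φ1 x_{t−1} + φ2 x_{t−2} + ε_t,  ε_t ~ N(0, σ²_ε)

φ1 is direct, φ2 delayed density dependence. Stationarity is checked with
the standard triangle (|φ2| < 1, φ1 + φ2 < 1, φ2 − φ1 < 1);
pseudoperiodicity (complex characteristic roots, the quasi-cyclic regime)
as φ1² + 4φ2 ≤ 0. The stationary variance closed form

    Var(x) = σ²_ε (1−φ2) / [(1+φ2)((1−φ2)² − φ1²)]

is verified in tests against an independent autocovariance routine and
against long-run Monte-Carlo variance. Simulation draws the first two
points from the exact bivariate stationary distribution (Yule–Walker lag-1
correlation φ1/(1−φ2)) rather than burning in, so T = 20 series are exactly
stationary.

The default fit is Gaussian conditional maximum likelihood: least squares
of x_t on (1, x_{t−1}, x_{t−2}) for t ≥ 3, innovation variance = mean
squared residual, coefficient covariance σ̂²(XᵀX)⁻¹, central 95 % intervals
with Gaussian quantiles. This is an explicit stand-in for latent-Gaussian
(INLA-style) posterior inference with penalized-complexity priors used in
comparable analyses: the prior hyperparameters of that workflow are not
reproducible here, and consequences are noted under Limitations. An exact
stationary-likelihood option (`method="exact"`) wraps statsmodels ARIMA.
Coefficient estimates are invariant (to 1e−10) to adding a constant to the
series — so a constant multiplicative bias in abundance (e.g. homogeneous
undetection) does not move (φ̂1, φ̂2), which is why modelling heterogeneity
only matters when detection varies.

### Poisson–log-normal latent rates (P variant)

y_t ~ Poisson(exp(β0 + e_t)) with e_t iid N(0, κ_e⁻¹). The marginal
likelihood integrates each e_t with 30-node Gauss–Hermite quadrature,
adaptively recentred at the per-observation Laplace mode (verified against
brute-force numerical integration to 1e−8); (β0, ln σ²_e) are maximized by
Nelder–Mead with ln σ²_e box-limited to [−12, 6] to keep the collapse-to-
Poisson limit (constant counts) well behaved. The AR(2) is then fitted to
the posterior-mean log rates λ̂_t = β0 + E[e_t | y_t].

## Synthetic-data generator

The generator emulates a two-day rodent trapping study with T = 20
seasonal time points and mean abundance 20:

- **Abundance**: stationary AR(2) on ln N_t at the chosen (φ1, φ2, σ²_ε),
  with offset ln η set so the stationary mean of ln N_t is
  ln 20 − Var(ln N_t)/2, making E(N_t) = 20 by the log-normal mean
  identity (so sample size does not confound comparisons across parameter
  combinations); rounded to integers and clamped at ≥ 1 so the log exists
  (the clamp count is recorded per series; it only matters at the highest
  process variance).
- **Weights**: per time point a mean weight μ_t ~ Lognormal(ln 30, ln 5)
  models seasonal turnover in population composition; individual weights
  are Lognormal(ln μ_t, ln σ_w) with σ_w = 1.2, then scaled by the pooled
  sample SD across the whole series (one scale per series, not per time
  point) to a dimensionless covariate.
- **Capture**: p_{i1} = logistic(δ1 z_i), p_{i2} = logistic(δ2 z_i) with
  δ1 = logit(0.55), δ2 = logit(0.75) and weight the sole covariate (no
  intercept), so an individual at z = 1 has exactly the population-level
  session probabilities; sessions independent.
- **Observation**: category-(0,0) individuals are dropped; the truth is
  retained alongside.

One master seed spawns independent substreams per (replicate, stage), so
replicate i is identical no matter how many replicates are requested.

What the generator does **not** emulate: open-population turnover between
sessions, behavioural trap response, station/space structure, sex effects,
non-log-normal weight distributions, and observation-model
misspecification (the capture model fitted is the model that generated
the data). Passing benchmarks therefore demonstrate correct estimation
under the stated sampling model, not robustness to its violation.

## Study driver

Per replicate series the driver produces AR(2) fits for baseline
(true ln N_t), cr_fit (capture chain) and obs_count (ln n_t), each in A
and P variants; a `cr_external_hook` route accepts externally estimated
never-capture probabilities. The capture model is fitted once per series,
pooling all time points (matching pooled fits on comparable real data).
Replicates where a route fails (a zero-capture time point makes the log
series undefined; a degenerate capture fit) are excluded from that cell's
averages with counts reported, and cells with > 10 % failures are flagged.
Metrics: coverage of the 95 % intervals per coefficient, joint coverage
(both intervals cover), RMSE per coefficient, joint RMSE, averaged with
equal weight across the 15 coefficient combinations per variance level.

`propagate_uncertainty` draws B = 200 coefficient vectors from the capture
fit's Gaussian approximation, recomputes the abundance series and refits
the AR(2) per draw; the spread of (φ̂1, φ̂2) across draws measures how much
first-stage sampling uncertainty contributes (empirically: much less than
between-replicate process noise, which justifies the sequential, rather
than jointly propagated, design).

Default problem sizes (M = 200 replicates per cell in the acceptance
script, M = 100 in the test suite; T = 20; E(N) = 20) are the study
conditions the generator is calibrated to; the reduced test-suite M only
widens Monte-Carlo tolerance, not the conditions.

## Limitations

- Interval estimates are Gaussian observed-information approximations
  around (penalized) ML estimates, not posterior credible intervals under
  penalized-complexity priors. For φ1 the two are empirically
  interchangeable in these designs; for φ2 the prior-based posteriors are
  materially tighter and more shrunk toward zero, so prior-based workflows
  report lower φ2 coverage (and larger φ2 RMSE) than this package under
  identical conditions.
- At T = 20 the conditional-ML small-sample bias pulls φ1 toward zero at
  every |φ1| > 0 and pulls φ2 toward zero only when |φ2| is large; at weak
  delayed dependence (φ2 = −0.2) the φ2 bias points away from zero. The
  toward-zero attenuation of both coefficients reappears in the
  capture-chain and observed-count estimates, where sampling error in the
  series dominates.
- The P variant's latent-rate smoothing is approximately a linear
  shrinkage of the log counts toward their mean, to which AR(2)
  coefficient estimation is largely invariant; A and P variants therefore
  differ less here than under prior-regularized latent models.
- Two capture sessions only (the category expansion for τ > 2 is out of
  scope), no behavioural-response models, no random-effect (station/time)
  terms in the capture model, no variance estimator for N̂.
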