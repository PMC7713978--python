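# capdyn

Density-dependence estimation from capture–recapture time series.

Ecologists monitoring cyclic animal populations — classically small rodents
trapped alive on two adjacent days, twice a year — want the strength of
direct and delayed density dependence: the coefficients (φ₁, φ₂) of an
AR(2) model for log abundance,

    ln N_t = ln η + φ₁ ln N_{t−1} + φ₂ ln N_{t−2} + ε_t,   ε_t ~ N(0, σ²_ε).

Fitting this to raw trap counts ignores that detection is imperfect and
heterogeneous (heavier animals are easier to trap), which biases the
density-dependence estimates when the process variance σ²_ε is small.
`capdyn` implements a sequential chain that models the sampling process
explicitly without a full state-space model:

1. **Capture model.** For each captured individual the two-day history
   falls into category (1,0), (0,1) or (1,1) with probabilities derived
   from session capture probabilities p_{i1}, p_{i2} (M_th heterogeneity:
   probabilities vary by session and by individual covariates, sessions
   independent). A conditional multinomial logit is fitted to the captured
   individuals; only coefficient differences are identifiable, and the two
   that matter, δ₁ᵣ = γ₃ᵣ − γ₂ᵣ and δ₂ᵣ = γ₃ᵣ − γ₁ᵣ, are exactly the
   logit-scale coefficients of p_{i1} and p_{i2}. The same likelihood can
   be maximised through the multinomial–Poisson transformation (an
   augmented count table with per-individual intercepts); both routes are
   implemented and agree to optimizer tolerance.
2. **Abundance.** The never-capture probability ĉ_{i0} = (1 − p̂_{i1})(1 − p̂_{i2})
   feeds the Horvitz–Thompson estimator N̂_t = Σᵢ (1 − ĉ_{i0})⁻¹ per time point.
3. **Dynamics.** An AR(2) is fitted to ln N̂_t (variant A) or to the
   posterior-mean log rates of a Poisson–log-normal latent model for the
   counts (variant P), by Gaussian conditional maximum likelihood with
   central 95 % intervals from the observed-information approximation.

The package also contains the synthetic-data generator for a realistic
two-day trapping study (AR(2) abundance, log-normal weights driving
detectability) and a study driver that benchmarks the chain against
fitting the AR(2) to the true log abundance (`baseline`) and to raw log
counts (`obs_count`), reporting coverage and RMSE of (φ̂₁, φ̂₂).

## Worked example

```python
import numpy as np
import capdyn as cd

cfg = cd.SimulationConfig(phi1=0.5, phi2=-0.2, sigma2_eps=0.08)
pop = cd.simulate_population(cfg, seed=42)
obs = pop.observed()
print(f"{pop.total} individuals generated, {len(obs)} captured at least once")

fit = cd.CaptureModel.from_records(obs, covariates=["weight"]).fit()
print(fit.summary())

series = cd.abundance_series(obs, fit.c0_hat, time_points=np.arange(1, 21))
ar2 = cd.AR2Model(series.log_N_hat).fit()
print(ar2.summary())
```

prints

```
405 individuals generated, 329 captured at least once
Two-session capture model (conditional multinomial likelihood)
  n = 329, covariates = 1, mode = ML
  log-likelihood = -332.5995
  AIC = 669.1991, BIC = 676.7912
  coef                      estimate     std err      [0.025      0.975]
  delta1[weight]             0.16532     0.08493    -0.00114     0.33178
  delta2[weight]             1.12179     0.20842     0.71329     1.53029
AR(2) fit (cml), T = 20
  log-likelihood = -4.1519, sigma2_eps = 0.09287
  param           estimate     std err      [0.025      0.975]
  intercept        4.46029     0.83872     2.81643     6.10415
  phi1            -0.00849     0.20105    -0.40253     0.38556
  phi2            -0.51377     0.19985    -0.90547    -0.12207
```

The capture fit recovers the generator's weight effects (truth
δ₁ = logit 0.55 ≈ 0.201, δ₂ = logit 0.75 ≈ 1.099): weight raises
detectability, much more strongly on day 2. The AR(2) point estimates on
one T = 20 series are noisy — that is precisely why the package's study
driver quantifies coverage and RMSE over hundreds of replicates.

A command-line interface mirrors the library
(`capdyn simulate | fit-capture | estimate-abundance | fit-ar2 | study`);
see `capdyn --help`.

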