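"""Synthetic capture-recapture datasets over AR(2) population dynamics.

The generator emulates a two-day small-rodent trapping study:

1. True log abundance follows a stationary AR(2) with chosen (phi1, phi2)
   and process variance; the offset is set so E(N_t) equals a target mean
   abundance (20 by default), using the log-normal mean identity
   ln(eta-part) = ln E(N) - Var(ln N)/2.  The series is rounded to integer
   abundances (clamped at >= 1 so the log stays defined).
2. Every individual gets a positive body weight: the time-point mean mu_t
   is log-normal (median 30, log-sd ln 5) to mimic seasonal turnover in
   population composition, and individual weights are log-normal around
   mu_t with log-sd ln(sigma_w).  Weights are scaled by the pooled sample
   standard deviation across the whole series, making the covariate
   dimensionless with unit spread.
3. Weight drives detectability: session capture probabilities are
   p_i1 = logistic(delta1 * z_i), p_i2 = logistic(delta2 * z_i), with
   delta1 = logit(p1), delta2 = logit(p2) chosen so an individual at z = 1
   has the population-level session probabilities (0.55 and 0.75 by
   default).  The two sessions are independent (M_th, no behavioural
   response).
4. Individuals never captured, history (0,0), are dropped from the
   observed dataset; the truth (N_t and all histories) is retained
   alongside for evaluation.

Reproducibility: a master seed spawns independent substreams per
(replicate, stage), so any scenario cell or single replicate can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .ar2 import AR2Spec, simulate_ar2, stationary_variance
from .exceptions import DomainError

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "generate_abundance",
    "generate_weights",
    "assign_capture_histories",
    "simulate_population",
    "run_scenario",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulation scenario.

    Defaults are the reference trapping-study conditions: T = 20 time
    points, mean abundance 20, session probabilities (0.55, 0.75) at unit
    scaled weight, weight spread multiplier sigma_w = 1.2 and time-point
    weight medians log-normal(ln 30, ln 5).
    """

    phi1: float
    phi2: float
    sigma2_eps: float
    T: int = 20
    target_mean_abundance: float = 20.0
    p1: float = 0.55
    p2: float = 0.75
    sigma_w: float = 1.2
    weight_mu_log_mean: float = float(np.log(30.0))
    weight_mu_log_sd: float = float(np.log(5.0))
    site: str = "sim"

    def __post_init__(self):
        if not (0 < self.p1 < 1 and 0 < self.p2 < 1):
            raise DomainError("session probabilities must lie in (0, 1)")
        if self.sigma_w <= 1.0:
            raise DomainError("sigma_w must exceed 1 (log-sd ln(sigma_w) > 0)")
        if self.target_mean_abundance <= 0:
            raise DomainError("target mean abundance must be positive")
        # raises DomainError when (phi1, phi2) is not stationary
        stationary_variance(self.phi1, self.phi2, self.sigma2_eps)

    @property
    def delta1(self) -> float:
        """Weight coefficient of session-1 capture, logit(p1)."""
        return float(logit(self.p1))

    @property
    def delta2(self) -> float:
        """Weight coefficient of session-2 capture, logit(p2)."""
        return float(logit(self.p2))

    def ar2_spec(self) -> AR2Spec:
        """AR(2) spec with the variance-corrected offset.

        The offset makes the stationary mean of ln N_t equal
        ln(target) - Var(ln N_t)/2, so E(N_t) = target by the log-normal
        mean identity.
        """
        var = stationary_variance(self.phi1, self.phi2, self.sigma2_eps)
        mean_log = np.log(self.target_mean_abundance) - 0.5 * var
        offset = mean_log * (1.0 - self.phi1 - self.phi2)
        return AR2Spec(
            phi1=self.phi1,
            phi2=self.phi2,
            sigma2_eps=self.sigma2_eps,
            offset_log_eta=float(offset),
            T=self.T,
        )


@dataclass
class SimulatedPopulation:
    """One simulated series: true abundances plus per-individual truth.

    ``individuals`` has one row per generated individual (captured or not)
    with columns ``id, site, time, weight_raw, weight, p1, p2, w1, w2``;
    ``weight`` is the pooled-SD-scaled covariate used in the capture model.
    """

    config: SimulationConfig
    N_true: np.ndarray
    individuals: pd.DataFrame
    clamped_points: int = 0  # rounded abundances lifted to 1

    @property
    def total(self) -> int:
        """Total generated individuals across all time points."""
        return int(self.N_true.sum())

    @property
    def time_points(self) -> np.ndarray:
        return np.arange(1, self.config.T + 1)

    def observed(self) -> pd.DataFrame:
        """Captured-individual records (category-0 rows removed)."""
        obs = self.individuals[
            (self.individuals["w1"] + self.individuals["w2"]) > 0
        ].reset_index(drop=True)
        return obs

    def observed_counts(self) -> np.ndarray:
        """n_t: captured individuals per time point."""
        obs = self.observed()
        counts = np.zeros(self.config.T, dtype=int)
        got = obs.groupby("time").size()
        counts[got.index.to_numpy() - 1] = got.to_numpy()
        return counts


def generate_abundance(config: SimulationConfig, rng) -> tuple[np.ndarray, int]:
    """True integer abundances N_t (>= 1); also returns how many points
    were lifted to 1 by the clamp."""
    rng = np.random.default_rng(rng)
    log_n = simulate_ar2(config.ar2_spec(), rng)
    n = np.round(np.exp(log_n)).astype(int)
    clamped = int((n < 1).sum())
    return np.maximum(n, 1), clamped


def generate_weights(
    N_t: np.ndarray, config: SimulationConfig, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw and pooled-SD-scaled weights for every individual.

    Returns ``(time_index, weight_raw, weight_scaled)`` with one entry per
    individual; ``time_index`` is 1-based.
    """
    rng = np.random.default_rng(rng)
    N_t = np.asarray(N_t, dtype=int)
    mu_t = rng.lognormal(config.weight_mu_log_mean, config.weight_mu_log_sd, len(N_t))
    times = np.repeat(np.arange(1, len(N_t) + 1), N_t)
    raw = rng.lognormal(np.log(mu_t)[times - 1], np.log(config.sigma_w))
    scale = raw.std(ddof=1) if len(raw) > 1 else raw[0]
    return times, raw, raw / scale


def assign_capture_histories(
    z: np.ndarray, config: SimulationConfig, rng
) -> pd.DataFrame:
    """Session probabilities and Bernoulli capture indicators per individual."""
    rng = np.random.default_rng(rng)
    z = np.asarray(z, dtype=float)
    p1 = expit(config.delta1 * z)
    p2 = expit(config.delta2 * z)
    w1 = rng.random(len(z)) < p1
    w2 = rng.random(len(z)) < p2
    return pd.DataFrame(
        {"p1": p1, "p2": p2, "w1": w1.astype(int), "w2": w2.astype(int)}
    )


def simulate_population(config: SimulationConfig, seed) -> SimulatedPopulation:
    """Generate one complete series (truth plus capture histories).

    ``seed`` may be an int, a SeedSequence, or a Generator; the three
    generation stages (abundance, weights, histories) use independent
    substreams so each is individually reproducible.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, np.random.Generator):
        ss = np.random.SeedSequence(seed.integers(2**31))
    else:
        ss = np.random.SeedSequence(seed)
    s_ab, s_wt, s_cap = ss.spawn(3)
    N_t, clamped = generate_abundance(config, np.random.default_rng(s_ab))
    times, raw, scaled = generate_weights(N_t, config, np.random.default_rng(s_wt))
    hist = assign_capture_histories(scaled, config, np.random.default_rng(s_cap))
    individuals = pd.DataFrame(
        {
            "id": [f"ind{j:05d}" for j in range(len(times))],
            "site": config.site,
            "time": times,
            "weight_raw": raw,
            "weight": scaled,
        }
    ).join(hist)
    return SimulatedPopulation(
        config=config, N_true=N_t, individuals=individuals, clamped_points=clamped
    )


def run_scenario(config: SimulationConfig, M: int, master_seed) -> list:
    """M independent replicate series under one scenario, reproducibly.

    The master seed spawns one substream per replicate, so
    ``run_scenario(cfg, M, s)[i]`` equals the i-th element of any longer
    run with the same seed.
    """
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    return [simulate_population(config, child) for child in ss.spawn(M)]
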