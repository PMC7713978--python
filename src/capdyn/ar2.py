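"""Second-order autoregressive dynamics of log abundance.

The process model for density dependence is

    x_t = ln(eta) + phi1 * x_{t-1} + phi2 * x_{t-2} + eps_t,
    eps_t ~ N(0, sigma2_eps) i.i.d.,

where x_t = ln(N_t).  phi1 measures direct and phi2 delayed density
dependence; complex characteristic roots (phi1^2 + 4 phi2 <= 0) produce the
pseudoperiodic fluctuations typical of cyclic small-mammal populations.

Fitting is by Gaussian conditional maximum likelihood (least squares on the
two lags) with central 95% intervals from the observed-information Gaussian
approximation; an exact stationary-likelihood option wraps statsmodels
ARIMA.  Coefficient estimates are invariant to adding a constant to the
series, so any multiplicative bias in the abundance estimates feeding the
model leaves (phi1, phi2) untouched.

The module also provides the Poisson-log-normal observation alternative: a
latent log rate lambda_t = beta0 + e_t with exchangeable Gaussian e_t,
counts y_t ~ Poisson(exp(lambda_t)); the AR(2) model can be fitted to the
posterior-mean log rates instead of log abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import norm

from .exceptions import (
    DegenerateDataError,
    DomainError,
    InputError,
    InsufficientDataError,
    MissingValuesError,
)

__all__ = [
    "AR2Spec",
    "check_stationarity",
    "stationary_variance",
    "simulate_ar2",
    "AR2Model",
    "AR2Results",
    "PoissonRateModel",
    "PoissonRateResults",
]

_Z975 = norm.ppf(0.975)


def check_stationarity(phi1: float, phi2: float) -> tuple[bool, bool]:
    """Stationarity and pseudoperiodicity of an AR(2) coefficient pair.

    Returns ``(stationary, pseudoperiodic)`` where stationarity is the
    standard triangle ``|phi2| < 1, phi1 + phi2 < 1, phi2 - phi1 < 1`` and
    pseudoperiodicity means complex characteristic roots,
    ``phi1**2 + 4*phi2 <= 0``.
    """
    phi1, phi2 = float(phi1), float(phi2)
    stationary = (abs(phi2) < 1.0) and (phi1 + phi2 < 1.0) and (phi2 - phi1 < 1.0)
    pseudoperiodic = phi1 * phi1 + 4.0 * phi2 <= 0.0
    return stationary, pseudoperiodic


def stationary_variance(phi1: float, phi2: float, sigma2_eps: float) -> float:
    """Marginal variance of the stationary AR(2) process.

    ``sigma2 * (1 - phi2) / ((1 + phi2) * ((1 - phi2)**2 - phi1**2))``.
    """
    if sigma2_eps < 0:
        raise DomainError("sigma2_eps must be nonnegative")
    stationary, _ = check_stationarity(phi1, phi2)
    if not stationary:
        raise DomainError(f"({phi1}, {phi2}) is not in the stationary region")
    return float(
        sigma2_eps
        * (1 - phi2)
        / ((1 + phi2) * ((1 - phi2) ** 2 - phi1**2))
    )


@dataclass(frozen=True)
class AR2Spec:
    """Parameters of an AR(2) process on the log scale."""

    phi1: float
    phi2: float
    sigma2_eps: float
    offset_log_eta: float = 0.0
    T: int = 20

    @property
    def is_stationary(self) -> bool:
        return check_stationarity(self.phi1, self.phi2)[0]

    @property
    def is_pseudoperiodic(self) -> bool:
        return check_stationarity(self.phi1, self.phi2)[1]

    @property
    def stationary_mean(self) -> float:
        return self.offset_log_eta / (1.0 - self.phi1 - self.phi2)

    @property
    def stationary_var(self) -> float:
        return stationary_variance(self.phi1, self.phi2, self.sigma2_eps)


def simulate_ar2(spec: AR2Spec, rng) -> np.ndarray:
    """Simulate a stationary AR(2) series of length ``spec.T``.

    The first two values are drawn from the exact bivariate stationary
    distribution (Yule-Walker covariances), so short series need no
    burn-in.  ``rng`` is a numpy Generator or a seed.
    """
    rng = np.random.default_rng(rng)
    if not spec.is_stationary:
        raise DomainError(
            f"({spec.phi1}, {spec.phi2}) is not stationary; cannot simulate"
        )
    if spec.T < 1:
        raise InputError("T must be >= 1")
    mu = spec.stationary_mean
    gamma0 = spec.stationary_var
    rho1 = spec.phi1 / (1.0 - spec.phi2)
    x = np.empty(spec.T)
    if spec.sigma2_eps == 0.0:
        x[:] = mu
        return x
    cov = gamma0 * np.array([[1.0, rho1], [rho1, 1.0]])
    x[:2] = rng.multivariate_normal([mu, mu], cov)[: spec.T]
    sd = np.sqrt(spec.sigma2_eps)
    eps = rng.normal(0.0, sd, size=max(spec.T - 2, 0))
    for t in range(2, spec.T):
        x[t] = (
            spec.offset_log_eta
            + spec.phi1 * x[t - 1]
            + spec.phi2 * x[t - 2]
            + eps[t - 2]
        )
    return x


class AR2Model:
    """AR(2) model for a real-valued (log abundance) series.

    Parameters
    ----------
    series : array-like
        Observed series, T >= 5, no missing values (a series with gaps
        should be split into contiguous segments first).
    """

    def __init__(self, series):
        series = np.asarray(series, dtype=float)
        if series.ndim != 1:
            raise InputError("series must be one-dimensional")
        if np.isnan(series).any():
            raise MissingValuesError(
                "series contains missing values; split it into contiguous "
                "segments and fit each separately"
            )
        if len(series) < 5:
            raise InsufficientDataError(
                f"need at least 5 observations to fit an AR(2); got {len(series)}"
            )
        self.series = series

    def fit(self, method: str = "cml") -> "AR2Results":
        """Fit by conditional ML (``"cml"``) or exact stationary ML (``"exact"``).

        Conditional ML regresses x_t on (1, x_{t-1}, x_{t-2}) for
        t = 3..T; the innovation variance is the mean squared residual and
        the coefficient covariance is the observed-information (Gaussian)
        approximation sigma2 * (X'X)^{-1}.
        """
        x = self.series
        T = len(x)
        if method == "cml":
            y = x[2:]
            X = np.column_stack([np.ones(T - 2), x[1:-1], x[:-2]])
            XtX = X.T @ X
            try:
                beta = np.linalg.solve(XtX, X.T @ y)
            except np.linalg.LinAlgError as exc:
                raise DegenerateDataError(
                    "constant or collinear series; AR(2) not estimable"
                ) from exc
            resid = y - X @ beta
            sigma2 = float(resid @ resid) / (T - 2)
            cov = sigma2 * np.linalg.inv(XtX)
            return AR2Results(
                series=x,
                intercept=float(beta[0]),
                phi1=float(beta[1]),
                phi2=float(beta[2]),
                sigma2_eps=sigma2,
                cov_params=cov,
                llf=float(
                    -0.5 * (T - 2) * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1.0)
                ),
                method="cml",
            )
        elif method == "exact":
            from statsmodels.tsa.arima.model import ARIMA

            res = ARIMA(x, order=(2, 0, 0), trend="c").fit()
            phi1, phi2 = res.arparams
            mu_c = res.params[0]  # statsmodels parameterizes the mean, not offset
            cov_full = np.asarray(res.cov_params())
            cov = cov_full[:3, :3]
            return AR2Results(
                series=x,
                intercept=float(mu_c * (1 - phi1 - phi2)),
                phi1=float(phi1),
                phi2=float(phi2),
                sigma2_eps=float(res.params[-1]),
                cov_params=cov,
                llf=float(res.llf),
                method="exact",
            )
        raise InputError(f"unknown AR(2) fit method {method!r}")


@dataclass
class AR2Results:
    """Point estimates, 95% intervals and diagnostics for an AR(2) fit."""

    series: np.ndarray
    intercept: float
    phi1: float
    phi2: float
    sigma2_eps: float
    cov_params: np.ndarray  # order: intercept, phi1, phi2
    llf: float
    method: str = "cml"
    variant: str = "A"
    source: str = ""

    @property
    def kappa(self) -> float:
        """Innovation precision 1/sigma2_eps."""
        return 1.0 / self.sigma2_eps if self.sigma2_eps > 0 else np.inf

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def ci_phi1(self) -> tuple[float, float]:
        se = self.bse[1]
        return (self.phi1 - _Z975 * se, self.phi1 + _Z975 * se)

    @property
    def ci_phi2(self) -> tuple[float, float]:
        se = self.bse[2]
        return (self.phi2 - _Z975 * se, self.phi2 + _Z975 * se)

    def covers(self, phi1_true: float, phi2_true: float) -> tuple[bool, bool]:
        """Whether each 95% interval contains the given true coefficient."""
        lo1, hi1 = self.ci_phi1
        lo2, hi2 = self.ci_phi2
        return (lo1 <= phi1_true <= hi1, lo2 <= phi2_true <= hi2)

    def summary(self) -> str:
        lines = [
            f"AR(2) fit ({self.method}), T = {len(self.series)}"
            + (f", variant {self.variant}" if self.source else ""),
            f"  log-likelihood = {self.llf:.4f}, sigma2_eps = {self.sigma2_eps:.5f}",
            f"  {'param':<12}{'estimate':>12}{'std err':>12}{'[0.025':>12}{'0.975]':>12}",
        ]
        names = ("intercept", "phi1", "phi2")
        vals = (self.intercept, self.phi1, self.phi2)
        for i, (nm, val) in enumerate(zip(names, vals)):
            se = self.bse[i]
            lines.append(
                f"  {nm:<12}{val:>12.5f}{se:>12.5f}"
                f"{val - _Z975 * se:>12.5f}{val + _Z975 * se:>12.5f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "variant": self.variant,
            "T": int(len(self.series)),
            "intercept": self.intercept,
            "phi1": self.phi1,
            "phi2": self.phi2,
            "ci_phi1": list(self.ci_phi1),
            "ci_phi2": list(self.ci_phi2),
            "sigma2_eps": self.sigma2_eps,
            "loglike": self.llf,
        }


# ---------------------------------------------------------------------------
# Poisson-log-normal latent rate model
# ---------------------------------------------------------------------------


class PoissonRateModel:
    """Poisson counts with an exchangeable log-normal latent rate.

        y_t ~ Poisson(exp(beta0 + e_t)),   e_t ~ N(0, 1/kappa_e) i.i.d.

    The marginal likelihood integrates each e_t out with adaptive
    Gauss-Hermite quadrature (default 30 nodes, recentred at the per-
    observation Laplace mode); ``fit`` maximizes it over (beta0, kappa_e)
    and returns the posterior-mean log rates lambda_hat_t = beta0 +
    E[e_t | y_t], the smoothed series the AR(2) model is fitted to in the
    Poisson (P) variant.
    """

    def __init__(self, counts, n_quad: int = 30):
        counts = np.asarray(counts)
        if counts.ndim != 1:
            raise InputError("counts must be one-dimensional")
        if np.isnan(np.asarray(counts, dtype=float)).any():
            raise MissingValuesError("counts contain missing values")
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
            raise InputError("counts must be nonnegative integers")
        if len(counts) < 5:
            raise InsufficientDataError(
                f"need at least 5 observations; got {len(counts)}"
            )
        if (counts == 0).all():
            raise DegenerateDataError("all counts are zero; the log rate diverges")
        self.counts = counts.astype(float)
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self._nodes = nodes
        self._logw = np.log(weights)

    # -- internals ---------------------------------------------------------

    def _laplace_modes(self, beta0: float, sigma2: float):
        """Per-observation mode and curvature of ln p(y_t|e) + ln p(e)."""
        y = self.counts
        m = np.zeros_like(y)
        for _ in range(100):
            lam = np.exp(beta0 + m)
            grad = y - lam - m / sigma2
            hess = -lam - 1.0 / sigma2
            step = grad / hess
            m_new = m - step
            if np.max(np.abs(m_new - m)) < 1e-12:
                m = m_new
                break
            m = m_new
        s2 = 1.0 / (np.exp(beta0 + m) + 1.0 / sigma2)
        return m, s2

    def _quad(self, beta0: float, sigma2: float):
        """Log marginal likelihood per obs and posterior means of e_t."""
        y = self.counts[:, None]
        m, s2 = self._laplace_modes(beta0, sigma2)
        s = np.sqrt(s2)
        e = m[:, None] + np.sqrt(2.0) * s[:, None] * self._nodes[None, :]
        logint = (
            y * (beta0 + e)
            - np.exp(beta0 + e)
            - gammaln(y + 1.0)
            - 0.5 * e**2 / sigma2
            - 0.5 * np.log(2 * np.pi * sigma2)
        )
        # ln integral via GH: sum_j w_j exp(x_j^2) f(m + sqrt(2) s x_j) * sqrt(2) s
        logterms = self._logw[None, :] + self._nodes[None, :] ** 2 + logint
        M = logterms.max(axis=1, keepdims=True)
        terms = np.exp(logterms - M)
        Z = terms.sum(axis=1)
        ll_t = M[:, 0] + np.log(Z) + 0.5 * np.log(2.0) + np.log(s)
        e_post = (terms * e).sum(axis=1) / Z
        return ll_t, e_post

    def loglike(self, beta0: float, sigma2: float) -> float:
        ll_t, _ = self._quad(beta0, sigma2)
        return float(ll_t.sum())

    def fit(self) -> "PoissonRateResults":
        """Maximize the marginal likelihood over (beta0, log sigma2_e)."""
        y = self.counts
        ybar = max(y.mean(), 0.5)
        logvar = np.var(np.log(np.maximum(y, 0.5)))
        x0 = np.array([np.log(ybar), np.log(max(min(logvar, 9.0), 1e-3))])

        def nll(theta):
            beta0, logs2 = theta
            if not (-12.0 <= logs2 <= 6.0) or abs(beta0) > 30:
                return 1e10
            return -self.loglike(beta0, np.exp(logs2))

        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        beta0, logs2 = res.x
        sigma2 = float(np.exp(logs2))
        ll_t, e_post = self._quad(beta0, sigma2)
        return PoissonRateResults(
            counts=self.counts,
            beta0=float(beta0),
            kappa_e=1.0 / sigma2,
            lambda_hat=beta0 + e_post,
            llf=float(ll_t.sum()),
            converged=bool(res.success),
        )


@dataclass
class PoissonRateResults:
    """Fitted Poisson-log-normal latent rate model."""

    counts: np.ndarray
    beta0: float
    kappa_e: float
    lambda_hat: np.ndarray  # posterior-mean log rate per time point
    llf: float
    converged: bool = True

    def summary(self) -> str:
        return (
            f"Poisson log-normal rate model, T = {len(self.counts)}\n"
            f"  beta0 = {self.beta0:.5f}, kappa_e = {self.kappa_e:.5g} "
            f"(sigma_e = {self.kappa_e ** -0.5:.5f})\n"
            f"  log marginal likelihood = {self.llf:.4f}"
        )
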