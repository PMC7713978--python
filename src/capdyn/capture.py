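"""Two-session closed-population capture model with individual heterogeneity.

Individuals are trapped on two adjacent sessions (days), so each capture
history falls into one of four categories::

    0 <-> (0,0)   never captured      (unobserved)
    1 <-> (1,0)   first session only
    2 <-> (0,1)   second session only
    3 <-> (1,1)   both sessions

Under the M_th model (capture probability varies with session and with
individual covariates, sessions independent) the category probabilities for
individual i with session probabilities (p_i1, p_i2) are

    c_i0 = (1-p_i1)(1-p_i2),   c_i1 = p_i1(1-p_i2),
    c_i2 = (1-p_i1)p_i2,       c_i3 = p_i1 p_i2.

Because the never-captured count is unknown, estimation conditions on
capture: the observed categories 1..3 follow a multinomial distribution with
probabilities c_ik/(1-c_i0), modelled by a multinomial logit whose linear
predictors are category-specific linear combinations of individual
covariates (weight, sex, ...).  Only coefficient *differences* are
identifiable; the two differences

    delta1_r = gamma_3r - gamma_2r     (logit of session-1 probability)
    delta2_r = gamma_3r - gamma_1r     (logit of session-2 probability)

recover the individual session probabilities

    p_i1 = logistic(sum_r delta1_r z_ir),  p_i2 = logistic(sum_r delta2_r z_ir),

and hence the never-capture probability c_i0 feeding the Horvitz-Thompson
abundance estimator.

The same likelihood can be rewritten, via the multinomial-Poisson
transformation, as a Poisson log-linear model on an augmented table with one
row per (individual, category) pair and a free per-individual intercept;
:meth:`CaptureModel.fit_poisson_augmented` implements that route and agrees
with the direct conditional fit to optimizer tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .exceptions import (
    ConvergenceError,
    DomainError,
    EmptyCategoryError,
    InputError,
    UnsupportedOperationError,
)

__all__ = [
    "CATEGORY_OF_HISTORY",
    "HISTORY_OF_CATEGORY",
    "CategoryProbs",
    "category_probabilities",
    "CaptureDesign",
    "build_design",
    "expand_to_poisson",
    "CaptureModel",
    "CaptureResults",
]

#: capture history (w1, w2) -> category index
CATEGORY_OF_HISTORY = {(0, 0): 0, (1, 0): 1, (0, 1): 2, (1, 1): 3}
HISTORY_OF_CATEGORY = {v: k for k, v in CATEGORY_OF_HISTORY.items()}

_OBSERVED_CATEGORIES = (1, 2, 3)


@dataclass(frozen=True)
class CategoryProbs:
    """Category probabilities of a two-session capture history."""

    p1: float
    p2: float
    c0: float
    c1: float
    c2: float
    c3: float
    c_tilde1: float
    c_tilde2: float
    c_tilde3: float


def category_probabilities(p1: float, p2: float) -> CategoryProbs:
    """Category probabilities for session capture probabilities ``(p1, p2)``.

    Parameters
    ----------
    p1, p2 : float
        Capture probabilities on sessions 1 and 2, each in the open
        interval (0, 1).

    Returns
    -------
    CategoryProbs
        The four unconditional category probabilities and the three
        probabilities conditional on being captured at least once.
    """
    p1 = float(p1)
    p2 = float(p2)
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 < p < 1.0:
            raise DomainError(f"{name}={p} must lie in the open interval (0, 1)")
    c0 = (1 - p1) * (1 - p2)
    c1 = p1 * (1 - p2)
    c2 = (1 - p1) * p2
    c3 = p1 * p2
    seen = 1.0 - c0
    return CategoryProbs(p1, p2, c0, c1, c2, c3, c1 / seen, c2 / seen, c3 / seen)


def _category_of(w1, w2) -> np.ndarray:
    w1 = np.asarray(w1, dtype=int)
    w2 = np.asarray(w2, dtype=int)
    if not (np.isin(w1, (0, 1)).all() and np.isin(w2, (0, 1)).all()):
        raise InputError("capture indicators w1, w2 must be 0 or 1")
    return w1 + 2 * w2  # (0,0)->0 (1,0)->1 (0,1)->2 (1,1)->3


@dataclass
class CaptureDesign:
    """Design for the conditional multinomial capture model.

    Attributes
    ----------
    y : ndarray of shape (n, 3)
        One-hot indicators over observed categories 1, 2, 3.
    z : ndarray of shape (n, v)
        Covariate matrix (categorical covariates already expanded).
    columns : list of str
        Covariate column names, in deterministic order.
    frame : DataFrame or None
        The source records (with ``time`` etc.) if built from records.
    """

    y: np.ndarray
    z: np.ndarray
    columns: list
    frame: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.y.ndim != 2 or self.y.shape[1] != 3:
            raise InputError("y must have shape (n, 3)")
        if not np.allclose(self.y.sum(axis=1), 1.0):
            raise InputError("each response row must be one-hot over categories 1..3")
        if self.z.ndim != 2 or self.z.shape[0] != self.y.shape[0]:
            raise InputError("z must have one row per individual")
        if self.z.shape[1] < 1:
            raise InputError("at least one covariate column is required")

    @property
    def nobs(self) -> int:
        return self.y.shape[0]

    @property
    def ncov(self) -> int:
        return self.z.shape[1]

    @property
    def categories(self) -> np.ndarray:
        """Observed category (1, 2 or 3) per individual."""
        return self.y.argmax(axis=1) + 1


def build_design(
    records: pd.DataFrame,
    covariates: Sequence[str],
    add_intercept: bool = False,
) -> CaptureDesign:
    """Build a :class:`CaptureDesign` from captured-individual records.

    ``records`` must contain columns ``w1`` and ``w2``; every row must be
    captured at least once.  Categorical (non-numeric) covariates are
    expanded to treatment-coded indicators with the alphabetically first
    level as baseline.
    """
    covariates = list(covariates)
    if not covariates and not add_intercept:
        raise InputError("at least one covariate (or an intercept) is required")
    for col in ("w1", "w2"):
        if col not in records.columns:
            raise InputError(f"records are missing required column {col!r}")
    cat = _category_of(records["w1"].to_numpy(), records["w2"].to_numpy())
    if (cat == 0).any():
        bad = int(np.nonzero(cat == 0)[0][0])
        raise InputError(
            f"record at position {bad} has capture history (0,0); "
            "never-captured individuals cannot enter the conditional fit"
        )
    y = np.zeros((len(records), 3))
    y[np.arange(len(records)), cat - 1] = 1.0

    blocks, names = [], []
    if add_intercept:
        blocks.append(np.ones((len(records), 1)))
        names.append("intercept")
    for name in covariates:
        if name not in records.columns:
            raise InputError(f"covariate {name!r} missing from records")
        col = records[name]
        if col.isna().any():
            raise InputError(f"covariate {name!r} has missing values on captured rows")
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            blocks.append(col.to_numpy(dtype=float)[:, None])
            names.append(name)
        else:
            levels = sorted(map(str, col.astype(str).unique()))
            # treatment coding, first level alphabetically is the baseline
            for level in levels[1:]:
                blocks.append(
                    (col.astype(str).to_numpy() == level).astype(float)[:, None]
                )
                names.append(f"{name}[{level}]")
    z = np.hstack(blocks)
    return CaptureDesign(y=y, z=z, columns=names, frame=records.reset_index(drop=True))


def expand_to_poisson(design: CaptureDesign) -> pd.DataFrame:
    """Augmented table for the multinomial-Poisson transformation.

    One row per (individual, category) pair, ``3 n`` rows in total, with the
    0/1 count ``y``, an ``individual`` label for the auxiliary per-individual
    intercept, and category-specific covariate columns ``<cov>:cat<k>`` for
    the non-reference categories k = 2, 3 (category 1 is the reference, so
    its interaction columns are identically zero and omitted).  Fitting a
    log-link Poisson model with a free intercept per individual on this
    table maximizes a likelihood proportional to the conditional multinomial
    likelihood and reproduces the same coefficient differences.
    """
    n, v = design.nobs, design.ncov
    rows = {
        "individual": np.repeat(np.arange(n), 3),
        "category": np.tile([1, 2, 3], n),
        "y": design.y.reshape(-1),
    }
    for k in (2, 3):
        for r, name in enumerate(design.columns):
            col = np.zeros(3 * n)
            col[rows["category"] == k] = design.z[:, r]
            rows[f"{name}:cat{k}"] = col
    return pd.DataFrame(rows)


class CaptureModel:
    """Conditional multinomial logit for two-session capture histories.

    Parameters
    ----------
    design : CaptureDesign
        Response and covariates for the captured individuals.
    reference : int
        Observed category (1, 2 or 3) whose coefficients are fixed at zero
        for identifiability.  The coefficient differences delta1, delta2
        reported by the fit are invariant to this choice.

    Examples
    --------
    >>> model = CaptureModel.from_records(records, covariates=["weight"])
    >>> res = model.fit()
    >>> res.delta1, res.delta2
    """

    def __init__(self, design: CaptureDesign, reference: int = 1):
        if reference not in _OBSERVED_CATEGORIES:
            raise InputError("reference category must be 1, 2 or 3")
        counts = design.y.sum(axis=0)
        for k in _OBSERVED_CATEGORIES:
            if counts[k - 1] == 0:
                raise EmptyCategoryError(k)
        self.design = design
        self.reference = reference
        # the two non-reference categories, in ascending order
        self.free_categories = tuple(k for k in _OBSERVED_CATEGORIES if k != reference)

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        covariates: Sequence[str],
        add_intercept: bool = False,
        reference: int = 1,
    ) -> "CaptureModel":
        return cls(build_design(records, covariates, add_intercept), reference=reference)

    # ---- likelihood machinery -------------------------------------------

    def _predictors(self, params: np.ndarray) -> np.ndarray:
        """n x 3 matrix of linear predictors V_ik, reference column zero."""
        v = self.design.ncov
        V = np.zeros((self.design.nobs, 3))
        for j, k in enumerate(self.free_categories):
            V[:, k - 1] = self.design.z @ params[j * v : (j + 1) * v]
        return V

    def loglike(self, params: np.ndarray) -> float:
        """Conditional multinomial log-likelihood."""
        V = self._predictors(params)
        return float((V * self.design.y).sum() - logsumexp(V, axis=1).sum())

    def _probs(self, params: np.ndarray) -> np.ndarray:
        V = self._predictors(params)
        V = V - V.max(axis=1, keepdims=True)
        e = np.exp(V)
        return e / e.sum(axis=1, keepdims=True)

    def score(self, params: np.ndarray) -> np.ndarray:
        P = self._probs(params)
        resid = self.design.y - P  # n x 3
        return np.concatenate(
            [self.design.z.T @ resid[:, k - 1] for k in self.free_categories]
        )

    def hessian(self, params: np.ndarray) -> np.ndarray:
        """Hessian of the log-likelihood (negative definite at the mode)."""
        P = self._probs(params)
        v = self.design.ncov
        H = np.zeros((2 * v, 2 * v))
        for a, ka in enumerate(self.free_categories):
            for b, kb in enumerate(self.free_categories):
                pa, pb = P[:, ka - 1], P[:, kb - 1]
                w = pa * pb - (pa if ka == kb else 0.0)
                H[a * v : (a + 1) * v, b * v : (b + 1) * v] = (
                    self.design.z.T * w
                ) @ self.design.z
        return H

    # ---- fitting ---------------------------------------------------------

    def fit(
        self,
        method: str = "newton",
        maxiter: int = 500,
        gtol: float = 1e-8,
        lltol: float = 1e-10,
        bayes: bool = False,
        prior_sd: float = 10.0,
        start_params: np.ndarray | None = None,
    ) -> "CaptureResults":
        """Maximize the conditional multinomial likelihood.

        With ``bayes=True`` a zero-mean Gaussian prior (sd ``prior_sd``) is
        placed on the coefficients and the returned covariance is the
        Gaussian (Laplace-style) posterior approximation at the penalized
        mode; otherwise the fit is plain maximum likelihood with the
        observed-information covariance.
        """
        if method != "newton":
            raise InputError(f"unknown fit method {method!r}")
        nparam = 2 * self.design.ncov
        if self.design.nobs < self.design.ncov + 1:
            raise InputError("need at least v+1 captured individuals")
        theta = (
            np.zeros(nparam) if start_params is None else np.asarray(start_params, float)
        )
        prec = (1.0 / prior_sd**2) if bayes else 0.0

        def objective(t):
            return self.loglike(t) - 0.5 * prec * (t @ t)

        ll = objective(theta)
        trace = [(0, ll, np.nan)]
        converged = False
        for it in range(1, maxiter + 1):
            g = self.score(theta) - prec * theta
            H = self.hessian(theta) - prec * np.eye(nparam)
            gnorm = float(np.linalg.norm(g))
            if gnorm < gtol:
                converged = True
                break
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(
                    f"singular Hessian at iteration {it} (separated or collinear "
                    "covariates?)",
                    trace,
                ) from exc
            # backtracking line search on the (penalized) log-likelihood
            alpha, ll_new = 1.0, -np.inf
            for _ in range(40):
                cand = theta + alpha * step
                ll_new = objective(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-14:
                    break
                alpha *= 0.5
            theta = theta + alpha * step
            trace.append((it, ll_new, gnorm))
            if abs(ll_new - ll) <= lltol * (abs(ll) + 1.0) and gnorm < 1e-4:
                converged = True
                ll = ll_new
                break
            ll = ll_new
        if not converged:
            raise ConvergenceError(
                f"capture model did not converge in {maxiter} iterations "
                f"(|grad|={gnorm:.3g}); data may be separated",
                trace,
            )
        if not bayes and float(np.linalg.norm(theta)) > 50.0 / max(
            1e-12, float(np.abs(self.design.z).mean())
        ):
            raise ConvergenceError(
                "capture model estimates diverged (quasi-separation): "
                f"|theta| = {np.linalg.norm(theta):.3g}",
                trace,
            )
        H = self.hessian(theta) - prec * np.eye(nparam)
        cov = np.linalg.inv(-H)
        return CaptureResults(
            model=self,
            params=theta,
            cov_params=cov,
            loglike=self.loglike(theta),
            bayes=bayes,
            niter=len(trace) - 1,
        )

    def fit_poisson_augmented(self) -> "CaptureResults":
        """Fit via the multinomial-Poisson transformation.

        Builds the augmented count table (one Poisson row per individual x
        category with a free per-individual intercept) and fits a log-link
        Poisson regression.  The category-coefficient differences agree with
        :meth:`fit` to optimizer tolerance; used mainly as the equivalence
        route.
        """
        import statsmodels.api as sm

        table = expand_to_poisson(self.design)
        n, v = self.design.nobs, self.design.ncov
        # per-individual auxiliary intercepts beta_i then interaction columns
        indiv = pd.get_dummies(table["individual"], dtype=float)
        inter_cols = [c for c in table.columns if ":cat" in c]
        X = np.hstack([indiv.to_numpy(), table[inter_cols].to_numpy()])
        glm = sm.GLM(table["y"].to_numpy(), X, family=sm.families.Poisson())
        res = glm.fit(maxiter=200, tol=1e-12)
        gamma = res.params[n:]  # a2 (v coefs) then a3 (v coefs), ref = category 1
        cov = res.cov_params()[n:, n:]
        if self.reference != 1:
            raise UnsupportedOperationError(
                "the augmented-Poisson route uses category 1 as reference"
            )
        # conditional multinomial log-likelihood at the recovered coefficients
        return CaptureResults(
            model=self,
            params=np.asarray(gamma, dtype=float),
            cov_params=np.asarray(cov, dtype=float),
            loglike=self.loglike(np.asarray(gamma, dtype=float)),
            bayes=False,
            niter=int(res.fit_history.get("iteration", 0))
            if hasattr(res, "fit_history")
            else 0,
        )


class CaptureResults:
    """Results of a fitted :class:`CaptureModel`.

    Exposes the identifiable coefficient differences, the implied
    per-individual session capture probabilities and never-capture
    probabilities, and standard model summaries.
    """

    def __init__(self, model, params, cov_params, loglike, bayes=False, niter=0):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov_params = np.asarray(cov_params, dtype=float)
        self.llf = float(loglike)
        self.bayes = bool(bayes)
        self.niter = int(niter)

    # ---- coefficient differences ----------------------------------------

    def _gamma_full(self) -> np.ndarray:
        """3 x v matrix of category coefficients with reference row zero."""
        v = self.model.design.ncov
        G = np.zeros((3, v))
        for j, k in enumerate(self.model.free_categories):
            G[k - 1] = self.params[j * v : (j + 1) * v]
        return G

    def _delta_jacobian(self) -> np.ndarray:
        """Jacobian of (delta1, delta2) w.r.t. the free parameter vector."""
        v = self.model.design.ncov
        J = np.zeros((2 * v, 2 * v))
        # delta1 = gamma3 - gamma2, delta2 = gamma3 - gamma1; gamma_ref = 0
        coef = {k: np.zeros(2) for k in _OBSERVED_CATEGORIES}
        coef[3][0] += 1
        coef[2][0] -= 1
        coef[3][1] += 1
        coef[1][1] -= 1
        for j, k in enumerate(self.model.free_categories):
            for d in range(2):
                J[d * v : (d + 1) * v, j * v : (j + 1) * v] = coef[k][d] * np.eye(v)
        return J

    @property
    def delta1(self) -> np.ndarray:
        """gamma_3r - gamma_2r: logit coefficients of session-1 capture."""
        G = self._gamma_full()
        return G[2] - G[1]

    @property
    def delta2(self) -> np.ndarray:
        """gamma_3r - gamma_1r: logit coefficients of session-2 capture."""
        G = self._gamma_full()
        return G[2] - G[0]

    @property
    def cov_delta(self) -> np.ndarray:
        """Covariance of the stacked (delta1, delta2) vector (delta method)."""
        J = self._delta_jacobian()
        return J @ self.cov_params @ J.T

    @property
    def bse_delta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_delta))

    # ---- fitted probabilities --------------------------------------------

    @property
    def p1_hat(self) -> np.ndarray:
        """Fitted session-1 capture probability per captured individual."""
        return expit(self.model.design.z @ self.delta1)

    @property
    def p2_hat(self) -> np.ndarray:
        """Fitted session-2 capture probability per captured individual."""
        return expit(self.model.design.z @ self.delta2)

    @property
    def c0_hat(self) -> np.ndarray:
        """Fitted never-capture probability per captured individual."""
        return (1.0 - self.p1_hat) * (1.0 - self.p2_hat)

    # ---- information criteria --------------------------------------------

    @property
    def df_model(self) -> int:
        return self.params.size

    @property
    def aic(self) -> float:
        if self.bayes:
            raise UnsupportedOperationError(
                "AIC is undefined for a Bayesian-mode fit (no maximized likelihood)"
            )
        return -2.0 * self.llf + 2.0 * self.df_model

    @property
    def bic(self) -> float:
        if self.bayes:
            raise UnsupportedOperationError(
                "BIC is undefined for a Bayesian-mode fit (no maximized likelihood)"
            )
        return -2.0 * self.llf + self.df_model * np.log(self.model.design.nobs)

    # ---- posterior sampling ----------------------------------------------

    def sample_params(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw coefficient vectors from the Gaussian approximation at the mode."""
        return rng.multivariate_normal(self.params, self.cov_params, size=size)

    def delta_from_params(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(delta1, delta2) implied by an arbitrary free-parameter vector."""
        saved, self.params = self.params, np.asarray(params, dtype=float)
        try:
            return self.delta1.copy(), self.delta2.copy()
        finally:
            self.params = saved

    # ---- reporting -------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the coefficient differences."""
        names = self.model.design.columns
        d1, d2 = self.delta1, self.delta2
        se = self.bse_delta
        v = len(names)
        z975 = norm.ppf(0.975)
        lines = [
            "Two-session capture model (conditional multinomial likelihood)",
            f"  n = {self.model.design.nobs}, covariates = {v}, "
            f"mode = {'Bayesian (Gaussian approx.)' if self.bayes else 'ML'}",
            f"  log-likelihood = {self.llf:.4f}",
        ]
        if not self.bayes:
            lines.append(f"  AIC = {self.aic:.4f}, BIC = {self.bic:.4f}")
        lines.append(
            f"  {'coef':<22}{'estimate':>12}{'std err':>12}{'[0.025':>12}{'0.975]':>12}"
        )
        for r, name in enumerate(names):
            for label, val, s in (
                (f"delta1[{name}]", d1[r], se[r]),
                (f"delta2[{name}]", d2[r], se[v + r]),
            ):
                lines.append(
                    f"  {label:<22}{val:>12.5f}{s:>12.5f}"
                    f"{val - z975 * s:>12.5f}{val + z975 * s:>12.5f}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable fit report."""
        names = self.model.design.columns
        v = len(names)
        se = self.bse_delta
        out = {
            "n": self.model.design.nobs,
            "loglike": self.llf,
            "mode": "bayes" if self.bayes else "ml",
            "delta1": {nm: float(x) for nm, x in zip(names, self.delta1)},
            "delta2": {nm: float(x) for nm, x in zip(names, self.delta2)},
            "se_delta1": {nm: float(x) for nm, x in zip(names, se[:v])},
            "se_delta2": {nm: float(x) for nm, x in zip(names, se[v:])},
        }
        if not self.bayes:
            out["aic"] = self.aic
            out["bic"] = self.bic
        return out
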