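"""Horvitz-Thompson abundance estimation from fitted capture probabilities.

Each captured individual i contributes the inverse of its estimated
inclusion probability 1 - c_i0 (the probability of being captured at least
once), so the abundance estimate at a time point is

    N_hat = sum_i 1 / (1 - c_hat_i0)

over the individuals captured there.  N_hat >= n always, with equality only
under perfect detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, InputError

__all__ = ["horvitz_thompson", "AbundanceSeries", "abundance_series"]


def horvitz_thompson(c0) -> float:
    """Horvitz-Thompson abundance estimate from never-capture probabilities.

    Parameters
    ----------
    c0 : array-like
        Estimated never-capture probability per captured individual, each in
        ``[0, 1)``.

    Returns
    -------
    float
        ``sum_i (1 - c0_i)**-1``; at least the number of individuals.
    """
    c0 = np.asarray(c0, dtype=float)
    if c0.size == 0:
        raise InputError("no captured individuals")
    if (c0 < 0).any() or (c0 >= 1).any() or not np.isfinite(c0).all():
        raise DomainError("never-capture probabilities must lie in [0, 1)")
    return float(np.sum(1.0 / (1.0 - c0)))


@dataclass
class AbundanceSeries:
    """Per-time-point observed counts and Horvitz-Thompson estimates.

    Time points with zero captures carry ``n = 0`` and ``N_hat = nan``
    (marked missing rather than zero, since the log is undefined); how to
    handle them is left to the downstream series model.
    """

    site: str
    series: str
    time_points: np.ndarray
    n: np.ndarray
    N_hat: np.ndarray
    log_N_hat: np.ndarray = field(init=False)

    def __post_init__(self):
        self.time_points = np.asarray(self.time_points, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        self.N_hat = np.asarray(self.N_hat, dtype=float)
        if not (len(self.time_points) == len(self.n) == len(self.N_hat)):
            raise InputError("time_points, n and N_hat must have equal length")
        if (np.diff(self.time_points) <= 0).any():
            raise InputError("time points must be strictly increasing")
        ok = ~np.isnan(self.N_hat)
        if (self.N_hat[ok] < self.n[ok] - 1e-9).any():
            raise InputError("Horvitz-Thompson estimates cannot fall below counts")
        with np.errstate(invalid="ignore"):
            self.log_N_hat = np.log(self.N_hat)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of time points flagged missing (zero captures)."""
        return np.isnan(self.N_hat)

    def rounded_counts(self) -> np.ndarray:
        """N_hat rounded to the nearest positive integer (Poisson-variant input)."""
        out = np.round(self.N_hat)
        out[~np.isnan(out)] = np.maximum(out[~np.isnan(out)], 1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site,
                "series": self.series,
                "time": self.time_points,
                "n": self.n,
                "N_hat": self.N_hat,
                "log_N_hat": self.log_N_hat,
            }
        )


def abundance_series(
    frame: pd.DataFrame,
    c0,
    site: str = "sim",
    series: str = "1",
    time_points=None,
) -> AbundanceSeries:
    """Horvitz-Thompson estimates per time point for one site/series.

    Parameters
    ----------
    frame : DataFrame
        Captured-individual records with a ``time`` column, aligned row-wise
        with ``c0``.
    c0 : array-like
        Fitted never-capture probability per record (e.g.
        ``CaptureResults.c0_hat``).
    time_points : sequence of int, optional
        The full grid of time points the series should cover.  Points
        without captures are flagged missing.  Defaults to the observed
        range ``min..max``.
    """
    if "time" not in frame.columns:
        raise InputError("records need a 'time' column")
    c0 = np.asarray(c0, dtype=float)
    if len(c0) != len(frame):
        raise InputError("c0 must align with the records")
    t = frame["time"].to_numpy(dtype=int)
    if time_points is None:
        time_points = np.arange(t.min(), t.max() + 1)
    time_points = np.asarray(time_points, dtype=int)
    n_t = np.zeros(len(time_points), dtype=int)
    N_hat = np.full(len(time_points), np.nan)
    for j, tp in enumerate(time_points):
        mask = t == tp
        n_t[j] = int(mask.sum())
        if n_t[j] > 0:
            N_hat[j] = horvitz_thompson(c0[mask])
    return AbundanceSeries(
        site=site, series=series, time_points=time_points, n=n_t, N_hat=N_hat
    )
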