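"""Population-level Hill dose-response fits and the sensitivity-distribution duality.

A binary (live/dead) dose response observed at the population level,

    f(T) = 1 / (1 + (T / IC50)^n),

is the survival function of the distribution of single-cell log-dose death
thresholds ("sensitivities") kappa: f(T) = P(kappa > log T) with
kappa ~ Logistic(log IC50, 1/n).  The mean sensitivity is therefore log IC50
and the variance of sensitivities is pi^2 / (3 n^2) — steep curves mean a
homogeneous population, shallow curves a heterogeneous one.  This module fits
the Hill curve and converts between the two parameterizations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InvalidInputError, NonIdentifiableError

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "SensitivityDistribution",
    "HillCurve",
    "fit_hill",
    "hill_to_sensitivity_sd",
    "sensitivity_sd_to_hill",
    "sensitivity_distribution",
]

_SQRT3 = math.sqrt(3.0)


@dataclass
class DoseResponseCurve:
    """A fraction-alive-versus-dose curve, optionally with raw counts.

    Parameters
    ----------
    doses : array-like
        Ligand concentrations (ng/mL).  Zero doses are retained but excluded
        from log-space fitting.
    fraction_alive : array-like
        Fraction of the population alive at each dose, in [0, 1].
    counts : optional sequence of (alive, total) integer pairs
        When given, ``fraction_alive`` must equal alive/total and binomial
        maximum likelihood becomes available as a fit objective.
    replicate_id : str
        Free-form label.
    """

    doses: np.ndarray
    fraction_alive: np.ndarray
    counts: np.ndarray | None = None
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.fraction_alive = np.asarray(self.fraction_alive, dtype=float)
        if self.doses.shape != self.fraction_alive.shape:
            raise InvalidInputError("doses and fraction_alive must align")
        if np.any(self.doses < 0):
            raise InvalidInputError("doses must be non-negative")
        if np.any((self.fraction_alive < 0) | (self.fraction_alive > 1)):
            raise InvalidInputError("fraction_alive must lie in [0, 1]")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=int)
            if self.counts.shape != (self.doses.size, 2):
                raise InvalidInputError("counts must be (alive, total) pairs per dose")
            alive, total = self.counts[:, 0], self.counts[:, 1]
            if np.any((alive < 0) | (alive > total)):
                raise InvalidInputError("need 0 <= alive <= total")
            if not np.allclose(self.fraction_alive, alive / total):
                raise InvalidInputError("fraction_alive inconsistent with counts")

    @classmethod
    def from_counts(cls, doses, alive, total, replicate_id: str = "") -> "DoseResponseCurve":
        alive = np.asarray(alive, dtype=int)
        total = np.asarray(total, dtype=int)
        return cls(
            doses=np.asarray(doses, dtype=float),
            fraction_alive=alive / total,
            counts=np.column_stack([alive, total]),
            replicate_id=replicate_id,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, replicate_id: str = "") -> "DoseResponseCurve":
        """Build from a table with columns ``dose, alive, total`` or ``dose, fraction``."""
        cols = set(df.columns)
        if {"dose", "alive", "total"} <= cols:
            return cls.from_counts(df["dose"], df["alive"], df["total"], replicate_id)
        if {"dose", "fraction"} <= cols:
            return cls(df["dose"].to_numpy(float), df["fraction"].to_numpy(float),
                       replicate_id=replicate_id)
        raise InvalidInputError(
            "table needs columns (dose, alive, total) or (dose, fraction); "
            f"got {sorted(cols)}"
        )


@dataclass
class HillFit:
    """Fitted Hill parameters with local-curvature standard errors."""

    ic50: float
    n: float
    se_ic50: float = float("nan")
    se_n: float = float("nan")
    residual: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.ic50 > 0 and self.n > 0):
            raise InvalidInputError("HillFit requires ic50 > 0 and n > 0")

    def predict(self, doses) -> np.ndarray:
        """Fraction alive at each dose (1 at T=0)."""
        T = np.asarray(doses, dtype=float)
        out = np.ones_like(T, dtype=float)
        pos = T > 0
        # expit(n*(log ic50 - log T)) == 1/(1+(T/ic50)^n), overflow-safe
        out[pos] = special.expit(self.n * (math.log(self.ic50) - np.log(T[pos])))
        return out if out.ndim else float(out)

    def to_json(self) -> str:
        d = asdict(self)
        d["units"] = {"ic50": "ng/mL"}
        return json.dumps(d)


@dataclass
class SensitivityDistribution:
    """Marginal distribution of single-cell sensitivities kappa (log ng/mL).

    Logistic with location ``mu`` = log IC50 and scale ``s`` = 1/n, so that
    its survival function in u = log T reproduces the Hill curve pointwise.
    """

    mu: float
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise InvalidInputError("scale must be positive")

    @property
    def variance(self) -> float:
        return math.pi**2 * self.scale**2 / 3.0

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    @property
    def frozen(self) -> stats.distributions.rv_frozen:
        return stats.logistic(loc=self.mu, scale=self.scale)

    def survival(self, u) -> np.ndarray:
        """P(kappa > u): the fraction of cells alive at log-dose u."""
        return special.expit(-(np.asarray(u, dtype=float) - self.mu) / self.scale)

    def pdf(self, u) -> np.ndarray:
        return self.frozen.pdf(u)

    def rvs(self, size: int, random_state=None) -> np.ndarray:
        return self.frozen.rvs(size=size, random_state=random_state)


def hill_to_sensitivity_sd(n: float) -> float:
    """Standard deviation of single-cell sensitivities implied by Hill slope n.

    sigma = pi / (n * sqrt(3)); steeper curves imply a tighter distribution.
    """
    if not n > 0:
        raise InvalidInputError(f"Hill coefficient must be positive, got {n}")
    return math.pi / (n * _SQRT3)


def sensitivity_sd_to_hill(sigma: float) -> float:
    """Hill coefficient implied by a sensitivity sd: n = pi / (sigma * sqrt(3))."""
    if not sigma > 0:
        raise InvalidInputError(f"sensitivity sd must be positive, got {sigma}")
    return math.pi / (sigma * _SQRT3)


def sensitivity_distribution(fit: HillFit) -> SensitivityDistribution:
    """The logistic sensitivity distribution dual to a fitted Hill curve."""
    return SensitivityDistribution(mu=math.log(fit.ic50), scale=1.0 / fit.n)


class HillCurve(RegressorMixin, BaseEstimator):
    """Hill dose-response estimator.

    Fits f(T) = 1/(1 + (T/IC50)^n) to fraction-alive data by weighted least
    squares (default) or binomial maximum likelihood when counts are given.
    A deterministic log-spaced grid over (IC50 in the dose range, n in
    ``n_start_bounds``) seeds a quasi-Newton refinement, which avoids local
    minima on shallow curves.

    Parameters
    ----------
    objective : {"ls", "binomial"}
        Fit criterion.  "binomial" requires per-dose (alive, total) counts.
    n_start_bounds : pair of float
        Range of Hill coefficients scanned for starting values.
    grid_size : (int, int)
        Grid resolution in (log IC50, log n) for the starting scan.
    tol : float
        Optimizer tolerance.

    Attributes
    ----------
    ic50_, n_ : float
        Fitted parameters (ng/mL, dimensionless).
    se_ic50_, se_n_ : float
        Standard errors from the local curvature of the objective.
    residual_ : float
        Sum of squared residuals of the fitted curve.
    result_ : HillFit
    """

    def __init__(self, objective: str = "ls", n_start_bounds=(0.25, 16.0),
                 grid_size=(25, 13), tol: float = 1e-10):
        self.objective = objective
        self.n_start_bounds = n_start_bounds
        self.grid_size = grid_size
        self.tol = tol

    # -- objective pieces ---------------------------------------------------
    @staticmethod
    def _predict_theta(theta, log_T):
        log_ic50, log_n = theta
        return special.expit(np.exp(log_n) * (log_ic50 - log_T))

    def fit(self, X, y=None, counts=None, sample_weight=None):
        """Fit to doses ``X`` and fractions alive ``y``.

        Accepts either a :class:`DoseResponseCurve` as ``X`` or arrays.
        """
        if isinstance(X, DoseResponseCurve):
            curve = X
        else:
            doses = np.asarray(X, dtype=float).ravel()
            curve = DoseResponseCurve(doses, np.asarray(y, dtype=float).ravel(),
                                      counts=counts)
        pos = curve.doses > 0
        log_T = np.log(curve.doses[pos])
        f_obs = curve.fraction_alive[pos]
        if np.unique(curve.doses[pos]).size < 3:
            raise InvalidInputError(
                "need at least 3 distinct positive doses for a Hill fit"
            )
        if f_obs.min() > 0.95 or f_obs.max() < 0.05:
            raise NonIdentifiableError(
                "no transition observed: all fractions are ~1 or ~0, "
                "(IC50, n) are not identifiable"
            )
        w = np.ones_like(f_obs) if sample_weight is None else \
            np.asarray(sample_weight, dtype=float).ravel()[pos]

        if self.objective == "binomial":
            if curve.counts is None:
                raise InvalidInputError("binomial objective requires counts")
            alive = curve.counts[pos, 0].astype(float)
            total = curve.counts[pos, 1].astype(float)

            def loss(theta):
                p = np.clip(self._predict_theta(theta, log_T), 1e-12, 1 - 1e-12)
                return -np.sum(alive * np.log(p) + (total - alive) * np.log1p(-p))
        elif self.objective == "ls":
            def loss(theta):
                r = self._predict_theta(theta, log_T) - f_obs
                return float(np.sum(w * r * r))
        else:
            raise InvalidInputError(f"unknown objective {self.objective!r}")

        theta = self._minimize(loss, log_T)
        self._store(theta, loss, log_T, f_obs, w)
        return self

    def _minimize(self, loss, log_T):
        g1, g2 = self.grid_size
        lo, hi = math.log(self.n_start_bounds[0]), math.log(self.n_start_bounds[1])
        mu_grid = np.linspace(log_T.min(), log_T.max(), g1)
        ln_grid = np.linspace(lo, hi, g2)
        best, best_val = None, np.inf
        for mu in mu_grid:
            for ln in ln_grid:
                v = loss((mu, ln))
                if v < best_val:
                    best, best_val = (mu, ln), v
        span = log_T.max() - log_T.min()
        res = optimize.minimize(
            loss, best, method="L-BFGS-B", tol=self.tol,
            bounds=[(log_T.min() - 2 * span - 1, log_T.max() + 2 * span + 1),
                    (math.log(1e-3), math.log(1e4))],
        )
        return res.x

    def _store(self, theta, loss, log_T, f_obs, w):
        log_ic50, log_n = theta
        self.ic50_ = math.exp(log_ic50)
        self.n_ = math.exp(log_n)
        resid = self._predict_theta(theta, log_T) - f_obs
        self.residual_ = float(np.sum(w * resid * resid))
        cov = self._curvature_cov(theta, loss, len(f_obs))
        # delta method: theta is (log ic50, log n)
        self.se_ic50_ = self.ic50_ * math.sqrt(max(cov[0, 0], 0.0))
        self.se_n_ = self.n_ * math.sqrt(max(cov[1, 1], 0.0))
        self.result_ = HillFit(self.ic50_, self.n_, self.se_ic50_, self.se_n_,
                               self.residual_)

    def _curvature_cov(self, theta, loss, m):
        H = _fd_hessian(loss, np.asarray(theta, float))
        try:
            Hinv = np.linalg.pinv(H)
        except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
            return np.full((2, 2), np.nan)
        if self.objective == "ls":
            dof = max(m - 2, 1)
            sigma2 = loss(theta) / dof
            return 2.0 * sigma2 * Hinv
        return Hinv  # observed information for the likelihood objective

    def predict(self, X) -> np.ndarray:
        return self.result_.predict(np.asarray(X, dtype=float).ravel())

    def sensitivity_distribution(self) -> SensitivityDistribution:
        return sensitivity_distribution(self.result_)


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def fit_hill(curve: DoseResponseCurve, weights: Sequence[float] | None = None,
             objective: str = "ls") -> HillFit:
    """Fit the Hill model to a dose-response curve; see :class:`HillCurve`."""
    est = HillCurve(objective=objective)
    est.fit(curve, sample_weight=weights)
    return est.result_
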