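"""The single-cell Hill model.

A cell's sensitivity kappa — the log dose at which it dies — is expanded to
first order in the log abundances of the pathway components x_i:

    kappa = log IC50 + sum_i k_i * (log x_i - log <x_i>) + eps,

with k_i the partial derivative of kappa with respect to log x_i at the
population mean and eps an unmodeled residual.  Conditioning on one measured
component rho (mitochondria density, MitoTracker/FSC) gives a conditional
IC50 that scales as a power law in rho and a conditional Hill coefficient set
by the *remaining* variance:

    IC50(rho) = IC50 * (rho/<rho>)^k_rho
    n_rho     = pi / sqrt(3 * sum_{i != rho} k_i^2 sigma_i^2 + 3 sigma_eps^2)

which combine into the conditional survival probability

    P(alive | rho, T) = (rho/<rho>)^(k_rho n_rho)
                        / ((rho/<rho>)^(k_rho n_rho) + (T/IC50)^n_rho).

All arithmetic is done in log-dose / log-density space; the survival
probability is evaluated through a log-sum formulation so extreme exponents
k_rho * n_rho cannot overflow.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .errors import InvalidInputError

__all__ = [
    "Component",
    "SensitivityExpansion",
    "SingleCellHillParams",
    "sensitivity_of_cell",
    "conditional_ic50",
    "conditional_hill",
    "p_alive",
    "variance_explained",
]

_PI2_3 = math.pi**2 / 3.0


@dataclass(frozen=True)
class Component:
    """One term of the sensitivity expansion.

    k is dimensionless (d kappa / d log x); log_mean is log<x>; sigma2 is the
    variance of log x across cells, contributing k^2*sigma2 to Var(kappa).
    """

    name: str
    k: float
    log_mean: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise InvalidInputError(f"sigma2 must be >= 0 for {self.name!r}")


@dataclass
class SensitivityExpansion:
    """First-order expansion of kappa in component log abundances."""

    log_ic50: float
    components: list[Component] = field(default_factory=list)
    sigma2_intrinsic: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2_intrinsic < 0:
            raise InvalidInputError("sigma2_intrinsic must be >= 0")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise InvalidInputError("component names must be unique")
        if not self.total_variance > 0:
            raise InvalidInputError("total sensitivity variance must be positive")

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise InvalidInputError(f"unknown component {name!r}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def attributed_variance(self, name: str) -> float:
        """Variance of kappa attributed to one component: k_i^2 sigma_i^2."""
        c = self.component(name)
        return c.k**2 * c.sigma2

    @property
    def total_variance(self) -> float:
        return sum(c.k**2 * c.sigma2 for c in self.components) + self.sigma2_intrinsic

    def to_json(self) -> str:
        return json.dumps({
            "log_ic50": self.log_ic50,
            "units": {"ic50": "ng/mL", "kappa": "log ng/mL"},
            "components": [vars(c).copy() for c in self.components],
            "sigma2_intrinsic": self.sigma2_intrinsic,
        })

    @classmethod
    def from_json(cls, s: str) -> "SensitivityExpansion":
        d = json.loads(s)
        return cls(
            log_ic50=d["log_ic50"],
            components=[Component(**c) for c in d["components"]],
            sigma2_intrinsic=d.get("sigma2_intrinsic", 0.0),
        )


@dataclass
class SingleCellHillParams:
    """Parameters of the conditional (single-covariate) Hill model.

    log_ic50 in log ng/mL; n_rho > 0 is the conditional Hill coefficient;
    k_rho is dimensionless; rho_mean > 0 is the reference density <rho>.
    """

    log_ic50: float
    n_rho: float
    k_rho: float
    rho_mean: float = 1.0

    def __post_init__(self) -> None:
        if not self.n_rho > 0:
            raise InvalidInputError("n_rho must be positive")
        if not self.rho_mean > 0:
            raise InvalidInputError("rho_mean must be positive")

    @property
    def ic50(self) -> float:
        return math.exp(self.log_ic50)

    @property
    def residual_variance(self) -> float:
        """Variance of kappa left after conditioning on rho: pi^2/(3 n_rho^2)."""
        return _PI2_3 / self.n_rho**2

    def to_json(self) -> str:
        d = vars(self).copy()
        d["units"] = {"ic50": "ng/mL"}
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "SingleCellHillParams":
        d = json.loads(s)
        d.pop("units", None)
        return cls(**d)


def sensitivity_of_cell(log_components: dict[str, float],
                        expansion: SensitivityExpansion) -> float:
    """kappa for one cell from its component log abundances (no residual)."""
    kappa = expansion.log_ic50
    for c in expansion.components:
        if c.name not in log_components:
            raise InvalidInputError(f"missing value for component {c.name!r}")
        kappa += c.k * (log_components[c.name] - c.log_mean)
    return kappa


def conditional_ic50(rho, params: SingleCellHillParams):
    """IC50 of cells at density rho: IC50 * (rho/<rho>)^k_rho (ng/mL)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise InvalidInputError("rho must be positive")
    out = np.exp(params.log_ic50 + params.k_rho * (np.log(rho) - math.log(params.rho_mean)))
    return out if out.ndim else float(out)


def conditional_hill(expansion: SensitivityExpansion, exclude: str) -> float:
    """Hill coefficient after removing one component's variability.

    n = pi / sqrt(3 * remaining variance).  Removing a variance source never
    decreases n; a zero remaining variance means a deterministic threshold
    response (infinite steepness) and is rejected.
    """
    expansion.component(exclude)  # raises if unknown
    remaining = expansion.total_variance - expansion.attributed_variance(exclude)
    if remaining <= 0:
        raise InvalidInputError(
            "remaining variance is zero: the conditional response is a "
            "deterministic threshold with no finite Hill coefficient"
        )
    return math.pi / math.sqrt(3.0 * remaining)


def p_alive(rho, T, params: SingleCellHillParams):
    """P(alive | rho, T): logistic survival of kappa ~ Logistic(log IC50(rho), 1/n_rho).

    Evaluated as expit(-n_rho*(log T - log IC50 - k_rho*dlog rho)), which is
    algebraically identical to the power-law ratio form but immune to
    overflow.  T = 0 returns 1; broadcasting over rho and T is supported.
    """
    rho = np.asarray(rho, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(rho <= 0):
        raise InvalidInputError("rho must be positive")
    if np.any(T < 0):
        raise InvalidInputError("T must be non-negative")
    rho_b, T_b = np.broadcast_arrays(rho, T)
    out = np.ones(rho_b.shape, dtype=float)
    pos = T_b > 0
    dlog = np.log(rho_b[pos]) - math.log(params.rho_mean)
    z = params.n_rho * (np.log(T_b[pos]) - params.log_ic50 - params.k_rho * dlog)
    out[pos] = special.expit(-z)
    return out if out.ndim else float(out)


def variance_explained(expansion: SensitivityExpansion, component: str) -> float:
    """Fraction of sensitivity variance attributable to one component.

    k_i^2 sigma_i^2 / (sum_j k_j^2 sigma_j^2 + sigma_eps^2), in [0, 1].
    """
    return expansion.attributed_variance(component) / expansion.total_variance
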