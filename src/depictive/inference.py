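"""Semi-supervised inference of the single-cell Hill model from live-only data.

Flow cytometry of apoptosis yields an asymmetric dataset: every cell
contributes to the per-dose alive/dead counts, but the mitochondrial stain is
corrupted by the death process, so the covariate u = log rho is observed only
in *live* cells.  Standard logistic regression is impossible — one of the two
classes has no covariate measurements.

The likelihood used here combines the two pieces of information that remain:

* the per-dose fraction alive, A_j out of N_j, is binomial with success
  probability Z_j = integral g(u, T_j) p0(u) du, where g is the conditional
  survival probability P(alive | u, T) and p0 the baseline (unperturbed)
  covariate density; and
* each live cell's covariate value u is a draw from the survivor density
  p(u | alive, T_j) = g(u, T_j) p0(u) / Z_j  (Bayes' rule).

so that

  loglik = sum_j [ log Binom(A_j; N_j, Z_j)
                   + sum_{i in live_j} ( log g(u_ji, T_j) + log p0(u_ji)
                                         - log Z_j ) ].

p0 is a Gaussian kernel density estimated from live cells pooled over the
lowest ("baseline") doses; Z_j is evaluated by trapezoid quadrature on the
KDE grid.  Maximizing over (log IC50, log n_rho, k_rho) with multi-start
quasi-Newton refinement recovers the conditional Hill model; uncertainties
come from a cell-level bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .errors import ConvergenceError, InvalidInputError, NonIdentifiableError
from .singlecell import SingleCellHillParams, p_alive

__all__ = [
    "LiveOnlyDataset",
    "BaselineDensity",
    "FitResult",
    "estimate_baseline_density",
    "loglik_semisupervised",
    "DepictiveEstimator",
    "fit",
    "bootstrap_se",
    "variance_explained_from_fit",
]

_PI2_3 = math.pi**2 / 3.0
_DENSITY_FLOOR = 1e-300


@dataclass
class LiveOnlyDataset:
    """Per-dose counts plus covariate values for the live cells only.

    doses : ng/mL, one entry per dose condition
    n_total, n_alive : integer counts per dose, 0 <= A_j <= N_j
    live_values : list of arrays; log-covariate values of the live cells at
        each dose (length A_j, or a stated subsample)
    baseline_doses : subset of doses treated as unperturbed; their live
        values are pooled to estimate the baseline density p0
    covariate : label of the measured channel (e.g. "log_rho")
    """

    doses: np.ndarray
    n_total: np.ndarray
    n_alive: np.ndarray
    live_values: list[np.ndarray]
    baseline_doses: np.ndarray | None = None
    covariate: str = "log_rho"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.n_total = np.asarray(self.n_total, dtype=int)
        self.n_alive = np.asarray(self.n_alive, dtype=int)
        if not (self.doses.size == self.n_total.size == self.n_alive.size
                == len(self.live_values)):
            raise InvalidInputError("per-dose fields must align")
        if np.any(self.n_alive < 0) or np.any(self.n_alive > self.n_total):
            raise InvalidInputError("need 0 <= alive <= total at every dose")
        self.live_values = [np.asarray(v, dtype=float) for v in self.live_values]
        for a, v in zip(self.n_alive, self.live_values):
            if v.size > a:
                raise InvalidInputError(
                    "more live covariate values than live cells at a dose"
                )
        if self.baseline_doses is None:
            order = np.argsort(self.doses)
            self.baseline_doses = self.doses[order[: min(3, self.doses.size)]]
        self.baseline_doses = np.asarray(self.baseline_doses, dtype=float)
        missing = set(self.baseline_doses) - set(self.doses)
        if missing:
            raise InvalidInputError(f"baseline doses {sorted(missing)} not in doses")

    @property
    def fraction_alive(self) -> np.ndarray:
        return self.n_alive / self.n_total

    def baseline_values(self) -> np.ndarray:
        """Live covariate values pooled over the baseline doses."""
        mask = np.isin(self.doses, self.baseline_doses)
        vals = [v for v, m in zip(self.live_values, mask) if m]
        return np.concatenate(vals) if vals else np.empty(0)


@dataclass
class BaselineDensity:
    """Kernel density estimate of the unperturbed covariate distribution."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    mean_log: float
    var_log: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise InvalidInputError("density must be non-negative")
        total = np.trapezoid(self.density, self.grid)
        if abs(total - 1.0) > 1e-6:
            raise InvalidInputError(f"density must integrate to 1, got {total}")

    def pdf(self, u) -> np.ndarray:
        return np.interp(np.asarray(u, dtype=float), self.grid, self.density,
                         left=0.0, right=0.0)


def estimate_baseline_density(values, bandwidth_rule="silverman",
                              min_values: int = 50,
                              grid_points: int = 512) -> BaselineDensity:
    """Gaussian KDE of log-covariate values on a padded grid.

    The grid spans [min - 3*bw, max + 3*bw] with ``grid_points`` points and
    the density is renormalized by trapezoid quadrature.  ``bandwidth_rule``
    may be "silverman", "scott", or a numeric scale factor accepted by
    :class:`scipy.stats.gaussian_kde`.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < min_values:
        raise InvalidInputError(
            f"need at least {min_values} baseline values, got {values.size}"
        )
    if np.all(values == values[0]):
        raise InvalidInputError(
            "baseline values have no spread; kernel bandwidth is degenerate"
        )
    kde = stats.gaussian_kde(values, bw_method=bandwidth_rule)
    bw = math.sqrt(float(kde.covariance[0, 0]))
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, grid_points)
    density = kde(grid)
    density = density / np.trapezoid(density, grid)
    return BaselineDensity(grid=grid, density=density, bandwidth=bw,
                           mean_log=float(values.mean()),
                           var_log=float(values.var(ddof=1)))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class _LikelihoodCache:
    """Precomputed arrays so repeated likelihood evaluations stay cheap."""

    def __init__(self, data: LiveOnlyDataset, baseline: BaselineDensity):
        pos = data.doses > 0
        if not np.all(pos):
            # dose 0 kills nothing under the model; its binomial term is
            # parameter-free and its cells carry no information about the fit
            pass
        self.log_T = np.log(np.where(data.doses > 0, data.doses, np.nan))
        self.keep = data.doses > 0
        self.N = data.n_total[self.keep]
        self.A = data.n_alive[self.keep]
        self.log_T = self.log_T[self.keep]
        live = [v for v, m in zip(data.live_values, self.keep) if m]
        self.n_live = np.array([v.size for v in live])
        self.u_live = (np.concatenate(live) if live else np.empty(0))
        self.logT_live = np.repeat(self.log_T, self.n_live)
        self.grid = baseline.grid
        self.density = baseline.density
        self.u_mean = baseline.mean_log
        p0_live = np.maximum(baseline.pdf(self.u_live), _DENSITY_FLOOR)
        self.const_logp0 = float(np.sum(np.log(p0_live)))
        self.log_binom_coef = float(np.sum(
            special.gammaln(self.N + 1) - special.gammaln(self.A + 1)
            - special.gammaln(self.N - self.A + 1)
        ))

    def __call__(self, log_ic50: float, n: float, k: float) -> float:
        du_grid = self.grid - self.u_mean
        # conditional survival on the quadrature grid, (n_doses, n_grid)
        z = n * (self.log_T[:, None] - log_ic50 - k * du_grid[None, :])
        g_grid = special.expit(-z)
        Z = np.trapezoid(g_grid * self.density[None, :], self.grid, axis=1)
        Z = np.clip(Z, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            logZ = np.log(Z)
            log1mZ = np.log1p(-Z)
        ll = self.log_binom_coef
        # binomial part; A>0 with Z=0 (or A<N with Z=1) correctly gives -inf,
        # while A=0 terms are dropped before multiplying to avoid 0 * -inf
        terms = self.A * np.where(self.A > 0, logZ, 0.0) \
            + (self.N - self.A) * np.where(self.N - self.A > 0, log1mZ, 0.0)
        ll += float(np.sum(terms))
        if self.u_live.size:
            z_live = n * (self.logT_live - log_ic50
                          - k * (self.u_live - self.u_mean))
            ll += float(np.sum(special.log_expit(-z_live)))
            ll += self.const_logp0
            ll -= float(np.sum(self.n_live * np.where(self.n_live > 0, logZ, 0.0)))
        if not np.isfinite(ll):
            return -np.inf
        return ll


def loglik_semisupervised(params: SingleCellHillParams, data: LiveOnlyDataset,
                          baseline: BaselineDensity) -> float:
    """Log likelihood of live-only data under the conditional Hill model.

    Returns -inf (never NaN) when the survival integral underflows at
    extreme parameter values, so optimizers can recover.
    """
    cache = _LikelihoodCache(data, baseline)
    if abs(math.log(params.rho_mean) - baseline.mean_log) > 1e-9:
        cache.u_mean = math.log(params.rho_mean)
        p0 = np.maximum(baseline.pdf(cache.u_live), _DENSITY_FLOOR)
        cache.const_logp0 = float(np.sum(np.log(p0)))
    return cache(params.log_ic50, params.n_rho, params.k_rho)


@dataclass
class FitResult:
    """Outcome of a semi-supervised fit with bootstrap uncertainties."""

    params: SingleCellHillParams
    loglik: float
    se: dict[str, float] = field(default_factory=dict)
    variance_explained: float = float("nan")
    n_boot: int = 0
    seed: int | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if not math.isnan(self.variance_explained):
            if not 0.0 <= self.variance_explained <= 1.0:
                raise InvalidInputError("variance_explained must lie in [0, 1]")
        if any(v < 0 for v in self.se.values() if not math.isnan(v)):
            raise InvalidInputError("standard errors must be non-negative")


class DepictiveEstimator(BaseEstimator):
    """Semi-supervised logistic (conditional Hill) model estimator.

    Maximizes the live-only likelihood over (log IC50, log n_rho, k_rho)
    with ``n_starts`` multi-starts (a seeded Latin grid over the dose range,
    n in ``n_start_bounds`` and k in ``k_start_bounds``, plus one start at
    the population Hill fit with k=0) refined by L-BFGS-B.  The reference
    density <rho> is fixed to the baseline mean.

    Attributes (after fit)
    ----------------------
    log_ic50_, n_rho_, k_rho_ : float
        Maximum-likelihood parameters.
    rho_mean_ : float
        exp(baseline mean log-covariate).
    params_ : SingleCellHillParams
    loglik_ : float
    baseline_ : BaselineDensity
    converged_ : bool
    variance_explained_ : float
        k^2 var(u) / (k^2 var(u) + pi^2/(3 n^2)).
    """

    def __init__(self, n_starts: int = 8, n_start_bounds=(0.25, 16.0),
                 k_start_bounds=(-3.0, 3.0), grid_points: int = 512,
                 bandwidth_rule="silverman", min_baseline: int = 50,
                 tol: float = 1e-8, random_state: int = 0):
        self.n_starts = n_starts
        self.n_start_bounds = n_start_bounds
        self.k_start_bounds = k_start_bounds
        self.grid_points = grid_points
        self.bandwidth_rule = bandwidth_rule
        self.min_baseline = min_baseline
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: LiveOnlyDataset, y=None, baseline: BaselineDensity | None = None,
            warm_start: SingleCellHillParams | None = None):
        data = X
        partial = (data.n_alive > 0) & (data.n_alive < data.n_total) & (data.doses > 0)
        if warm_start is None and partial.sum() < 3:
            raise NonIdentifiableError(
                "need at least 3 doses with partial killing (0 < alive < total) "
                "to identify (log IC50, n_rho, k_rho)"
            )
        if partial.sum() < 1:
            raise NonIdentifiableError("no dose with partial killing")
        if baseline is None:
            baseline = estimate_baseline_density(
                data.baseline_values(), bandwidth_rule=self.bandwidth_rule,
                min_values=self.min_baseline, grid_points=self.grid_points,
            )
        cache = _LikelihoodCache(data, baseline)

        def nll(theta):
            ll = cache(theta[0], math.exp(theta[1]), theta[2])
            # large finite penalty keeps L-BFGS-B's finite differences valid
            return -ll if np.isfinite(ll) else 1e12

        starts = self._starts(data, partial, warm_start)
        log_T = np.log(data.doses[data.doses > 0])
        span = log_T.max() - log_T.min()
        bounds = [(log_T.min() - span - 1, log_T.max() + span + 1),
                  (math.log(0.02), math.log(100.0)),
                  (2 * self.k_start_bounds[0], 2 * self.k_start_bounds[1])]
        best, best_val, best_ok = None, np.inf, False
        for theta0 in starts:
            res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                                    bounds=bounds, tol=self.tol)
            if res.fun < best_val:
                best, best_val, best_ok = res.x, res.fun, bool(res.success)
        if best is None or not np.isfinite(best_val):
            raise ConvergenceError("all optimizer starts failed")
        self.converged_ = best_ok
        self.log_ic50_ = float(best[0])
        self.n_rho_ = float(math.exp(best[1]))
        self.k_rho_ = float(best[2])
        self.rho_mean_ = float(math.exp(baseline.mean_log))
        self.loglik_ = float(-best_val)
        self.baseline_ = baseline
        self.params_ = SingleCellHillParams(
            log_ic50=self.log_ic50_, n_rho=self.n_rho_, k_rho=self.k_rho_,
            rho_mean=self.rho_mean_,
        )
        return self

    def _starts(self, data: LiveOnlyDataset, partial: np.ndarray,
                warm_start: SingleCellHillParams | None) -> list[np.ndarray]:
        if warm_start is not None:
            return [np.array([warm_start.log_ic50, math.log(warm_start.n_rho),
                              warm_start.k_rho])]
        rng = np.random.default_rng(self.random_state)
        log_T = np.log(data.doses[partial])
        lo = np.array([log_T.min(), math.log(self.n_start_bounds[0]),
                       self.k_start_bounds[0]])
        hi = np.array([log_T.max(), math.log(self.n_start_bounds[1]),
                       self.k_start_bounds[1]])
        # Latin-hypercube-style stratified starts, deterministic given seed
        m = max(self.n_starts - 1, 1)
        u = (np.stack([rng.permutation(m) for _ in range(3)], axis=1)
             + rng.random((m, 3))) / m
        starts = [lo + ui * (hi - lo) for ui in u]
        starts.append(self._hill_start(data, log_T))
        return starts

    @staticmethod
    def _hill_start(data: LiveOnlyDataset, log_T: np.ndarray) -> np.ndarray:
        from .hill import HillCurve
        try:
            est = HillCurve().fit(data.doses, data.fraction_alive)
            return np.array([math.log(est.ic50_),
                             math.log(np.clip(est.n_, 0.05, 50.0)), 0.0])
        except Exception:
            return np.array([float(np.median(log_T)), 0.0, 0.0])

    # -- post-fit conveniences ---------------------------------------------
    @property
    def variance_explained_(self) -> float:
        explained = self.k_rho_**2 * self.baseline_.var_log
        return explained / (explained + _PI2_3 / self.n_rho_**2)

    def predict_proba(self, rho, T):
        """P(alive | rho, T) under the fitted model."""
        return p_alive(rho, T, self.params_)

    def score(self, X: LiveOnlyDataset, y=None) -> float:
        """Log likelihood of a dataset under the fitted parameters."""
        return loglik_semisupervised(self.params_, X, self.baseline_)


def fit(data: LiveOnlyDataset, config: dict | None = None) -> FitResult:
    """Fit the conditional Hill model and attach bootstrap uncertainties.

    ``config`` keys (all optional): estimator keyword arguments plus
    ``n_boot`` (default 0: no bootstrap) and ``seed``.
    """
    config = dict(config or {})
    n_boot = int(config.pop("n_boot", 0))
    seed = int(config.pop("seed", 0))
    est = DepictiveEstimator(random_state=seed, **config)
    est.fit(data)
    result = FitResult(
        params=est.params_, loglik=est.loglik_,
        variance_explained=est.variance_explained_, seed=seed,
        converged=est.converged_,
    )
    if n_boot:
        result.se = bootstrap_se(data, result, B=n_boot, seed=seed,
                                 estimator=est)
        result.n_boot = n_boot
    return result


def bootstrap_se(data: LiveOnlyDataset, fitted: FitResult, B: int = 20,
                 seed: int = 0,
                 estimator: DepictiveEstimator | None = None) -> dict[str, float]:
    """Cell-level bootstrap standard errors for the fitted parameters.

    Within each dose the alive count is redrawn binomially and that many
    live covariate values are resampled with replacement; each replicate is
    refit warm-started at the point estimate.  Reproducible given ``seed``.
    """
    if B < 2:
        raise InvalidInputError("bootstrap needs B >= 2 resamples")
    if estimator is None:
        estimator = DepictiveEstimator()
        estimator.baseline_ = None
    rng = np.random.default_rng(seed)
    draws = {"log_ic50": [], "n_rho": [], "k_rho": []}
    baseline = getattr(estimator, "baseline_", None)
    for _ in range(B):
        n_alive_b, live_b = [], []
        for nj, aj, vals in zip(data.n_total, data.n_alive, data.live_values):
            a_star = int(rng.binomial(nj, aj / nj)) if nj else 0
            n_alive_b.append(a_star)
            if vals.size and a_star:
                live_b.append(rng.choice(vals, size=a_star, replace=True))
            else:
                live_b.append(np.empty(0))
        boot = LiveOnlyDataset(
            doses=data.doses, n_total=data.n_total,
            n_alive=np.asarray(n_alive_b), live_values=live_b,
            baseline_doses=data.baseline_doses, covariate=data.covariate,
        )
        est_b = DepictiveEstimator(**estimator.get_params())
        try:
            est_b.fit(boot, baseline=baseline, warm_start=fitted.params)
        except (NonIdentifiableError, ConvergenceError, InvalidInputError):
            continue
        draws["log_ic50"].append(est_b.log_ic50_)
        draws["n_rho"].append(est_b.n_rho_)
        draws["k_rho"].append(est_b.k_rho_)
    if len(draws["k_rho"]) < 2:
        raise ConvergenceError("fewer than 2 successful bootstrap refits")
    return {name: float(np.std(v, ddof=1)) for name, v in draws.items()}


def variance_explained_from_fit(fitted: FitResult,
                                baseline: BaselineDensity) -> float:
    """Share of sensitivity variance carried by the measured covariate.

    k^2 var(u) over k^2 var(u) + pi^2/(3 n_rho^2); the second term is the
    residual sensitivity variance implied by the conditional Hill slope.
    """
    explained = fitted.params.k_rho**2 * baseline.var_log
    return explained / (explained + _PI2_3 / fitted.params.n_rho**2)
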