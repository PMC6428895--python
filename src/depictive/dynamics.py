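"""Coarse-grained dynamics of TRAIL-induced apoptosis.

Two state variables on [0, 1]: c, the active initiator-caspase (IC)
fraction, and e, the active effector-caspase (EC) fraction.  Three
ingredients generate the observed behavior:

1. slow autocatalytic IC activation, driven by receptor occupancy
   a(T) = k_trail * T / (T + K_trail);
2. a quasi-steady-state Bax/Bak pore function for MOMP, whose drive is the
   effective Bax/Bak concentration at the mitochondrial surface — diluted by
   mitochondria density rho and damped by free Bcl-2:
   s = beta * c / (rho * (1 + B_f / K_bcl2)),  pore = s^h/(K_pore^h + s^h);
3. strong positive feedback from EC back onto IC activation.

    dc/dt = (a(T) + k_auto*c + k_fb*e) * (1 - c) - gamma_c * c
    de/dt = k_e * pore(c) * (1 - e) - gamma_e * e

Free Bcl-2 follows equilibrium binding with a small-molecule inhibitor
(total B_T, I_T, dissociation constant K_I).  The 1/rho dilution makes the
fixed-point structure rho-dependent: scanning rho yields monostable-high
(all cells die), bistable, and monostable-low (all survive) regions whose
boundaries are saddle-node bifurcations.

These equations and the shipped "jurkat-like" / "mda-like" parameter sets
are this package's own construction, calibrated only to qualitative targets
(three- vs two-region bifurcation structure at T=0, a biphasic IC time
course, a positive IC50-vs-rho power law, and the directions of the Bcl-2
inhibitor effects); they are not a published parameterization.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .errors import ConvergenceError, InvalidInputError, NonIdentifiableError
from .hill import DoseResponseCurve, HillFit, fit_hill

__all__ = [
    "DynamicsParams",
    "BifurcationDiagram",
    "DoseResponseGrid",
    "load_params",
    "free_bcl2",
    "pore_qss",
    "effector_qss",
    "simulate_cell",
    "fixed_points",
    "bifurcation_scan",
    "simulate_dose_response",
    "inhibitor_response",
]

_RATE_FIELDS = ("k_trail", "k_auto", "gamma_c", "k_fb", "k_e", "gamma_e", "beta")


@dataclass
class DynamicsParams:
    """Rate constants of the coarse-grained apoptosis model.

    Times in hours, TRAIL in ng/mL, caspase fractions dimensionless,
    mitochondria density rho in relative units (population mean = 1).
    """

    k_trail: float      # IC activation rate at saturating TRAIL (1/h)
    K_trail: float      # TRAIL half-saturation (ng/mL)
    k_auto: float       # IC autocatalysis rate (1/h)
    gamma_c: float      # IC deactivation rate (1/h)
    k_fb: float         # EC -> IC feedback rate (1/h)
    k_e: float          # MOMP-driven EC activation rate (1/h)
    gamma_e: float      # EC decay rate (1/h)
    beta: float         # Bax/Bak activation per unit IC (dimensionless)
    h: float            # pore cooperativity (>= 1)
    K_pore: float       # pore half-saturation (effective Bax/Bak units)
    K_bcl2: float       # free-Bcl-2 concentration halving the pore drive
    bcl2_total: float   # total Bcl-2 (concentration units)
    K_I: float          # Bcl-2:inhibitor dissociation constant
    rho: float = 1.0    # default mitochondria density (relative units)
    name: str = ""

    def __post_init__(self) -> None:
        for f_ in _RATE_FIELDS:
            if getattr(self, f_) < 0:
                raise InvalidInputError(f"{f_} must be >= 0")
        if self.h < 1:
            raise InvalidInputError("pore cooperativity h must be >= 1")
        if self.K_pore <= 0 or self.K_bcl2 <= 0 or self.K_trail <= 0:
            raise InvalidInputError("half-saturation constants must be positive")
        if self.K_I <= 0:
            raise InvalidInputError("K_I must be positive")
        if self.bcl2_total < 0:
            raise InvalidInputError("bcl2_total must be >= 0")
        if self.rho <= 0:
            raise InvalidInputError("rho must be positive")

    def drive(self, T: float) -> float:
        """Receptor-driven IC activation rate a(T) (1/h)."""
        if T < 0:
            raise InvalidInputError("TRAIL dose must be >= 0")
        return self.k_trail * T / (T + self.K_trail)

    def replace(self, **kw) -> "DynamicsParams":
        d = asdict(self)
        d.update(kw)
        return DynamicsParams(**d)

    @classmethod
    def from_yaml(cls, path) -> "DynamicsParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh)["params"])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"params": asdict(self)}, fh, sort_keys=False)


def load_params(name: str) -> DynamicsParams:
    """Load a shipped, versioned parameter set ("jurkat-like", "mda-like")."""
    fname = name.replace("-", "_") + ".yaml"
    ref = importlib.resources.files("depictive.params") / fname
    if not ref.is_file():
        raise InvalidInputError(f"no shipped parameter set named {name!r}")
    return DynamicsParams(**yaml.safe_load(ref.read_text())["params"])


def free_bcl2(bcl2_total: float, inhibitor_total: float, K_I: float) -> float:
    """Free Bcl-2 under equilibrium binding to a small-molecule inhibitor.

    Positive root of B_f^2 + (I_T - B_T + K_I) B_f - K_I B_T = 0 (mass
    conservation for both species, one complex).  Decreases monotonically
    with inhibitor dose; equals B_T at I_T = 0.
    """
    if K_I <= 0:
        raise InvalidInputError("K_I must be positive")
    if bcl2_total < 0 or inhibitor_total < 0:
        raise InvalidInputError("totals must be >= 0")
    b = inhibitor_total - bcl2_total + K_I
    # numerically stable quadratic root (b can be large either sign)
    disc = math.sqrt(b * b + 4.0 * K_I * bcl2_total)
    bf = 0.5 * (disc - b) if b < 0 else 2.0 * K_I * bcl2_total / (disc + b)
    return min(max(bf, 0.0), bcl2_total)


def pore_qss(c, rho, free_bcl2_value, params: DynamicsParams):
    """Quasi-steady-state Bax/Bak pore activity in [0, 1].

    Effective drive s = beta*c / (rho*(1 + B_f/K_bcl2)): proportional to
    active IC, diluted by mitochondria density, damped by free Bcl-2.
    """
    c = np.asarray(c, dtype=float)
    if np.any(np.asarray(rho) <= 0):
        raise InvalidInputError("rho must be positive")
    s = params.beta * np.maximum(c, 0.0) / (rho * (1.0 + free_bcl2_value / params.K_bcl2))
    sh = s ** params.h
    out = sh / (params.K_pore ** params.h + sh)
    return out if out.ndim else float(out)


def effector_qss(c, rho, free_bcl2_value, params: DynamicsParams):
    """EC fraction at its c-conditional steady state."""
    p = pore_qss(c, rho, free_bcl2_value, params)
    return params.k_e * p / (params.k_e * p + params.gamma_e)


def _rhs(t, y, params: DynamicsParams, a: float, rho: float, bf: float):
    c, e = y
    pore = pore_qss(c, rho, bf, params)
    dc = (a + params.k_auto * c + params.k_fb * e) * (1.0 - c) - params.gamma_c * c
    de = params.k_e * pore * (1.0 - e) - params.gamma_e * e
    return (dc, de)


def simulate_cell(params: DynamicsParams, T: float, t_end: float = 4.0,
                  initial=(0.0, 0.0), rho: float | None = None,
                  inhibitor: float = 0.0, n_eval: int = 400) -> pd.DataFrame:
    """Integrate one cell's (c, e) trajectory; stiff-safe LSODA.

    Returns a frame with columns t (h), c, e.  Both states remain in [0, 1]
    for any valid parameters (the vector field points inward on the
    boundary of the unit square).
    """
    if t_end <= 0:
        raise InvalidInputError("t_end must be positive")
    rho = params.rho if rho is None else rho
    bf = free_bcl2(params.bcl2_total, inhibitor, params.K_I)
    a = params.drive(T)
    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(_rhs, (0.0, t_end), list(initial), t_eval=t_eval,
                    args=(params, a, rho, bf), method="LSODA",
                    rtol=1e-7, atol=1e-9)
    if not sol.success:
        raise ConvergenceError(
            f"integrator failed: {sol.message}; last state y={sol.y[:, -1]}"
            f" at t={sol.t[-1]} (T={T}, rho={rho})"
        )
    return pd.DataFrame({"t": sol.t, "c": sol.y[0], "e": sol.y[1]})


# ---------------------------------------------------------------------------
# fixed points and bifurcation structure
# ---------------------------------------------------------------------------

def _reduced_field(c, params: DynamicsParams, a: float, rho: float, bf: float):
    """dc/dt with e at its c-conditional steady state (1-D reduction)."""
    e = effector_qss(c, rho, bf, params)
    return (a + params.k_auto * c + params.k_fb * e) * (1.0 - c) - params.gamma_c * c


def fixed_points(params: DynamicsParams, T: float, rho: float,
                 inhibitor: float = 0.0, n_grid: int = 2001,
                 tol: float = 1e-12) -> list[tuple[float, str]]:
    """All fixed points of the reduced system on c in [0, 1], with stability.

    Roots are located by dense sign-change bracketing plus Brent refinement;
    stability is the sign of the reduced field's derivative.  At least one
    fixed point always exists (the field is positive at 0 when TRAIL drive
    is present, and negative at 1).
    """
    bf = free_bcl2(params.bcl2_total, inhibitor, params.K_I)
    a = params.drive(T)
    grid = np.linspace(0.0, 1.0, n_grid)
    F = _reduced_field(grid, params, a, rho, bf)
    roots: list[float] = []
    if abs(F[0]) < tol:            # c = 0 is an exact fixed point when a = 0
        roots.append(0.0)
    from scipy.optimize import brentq
    for i in range(n_grid - 1):
        f0, f1 = F[i], F[i + 1]
        if f0 == 0.0:
            if grid[i] > 0 and (not roots or abs(grid[i] - roots[-1]) > 1e-9):
                roots.append(grid[i])
            continue
        if f0 * f1 < 0:
            r = brentq(_reduced_field, grid[i], grid[i + 1],
                       args=(params, a, rho, bf), xtol=1e-14)
            if not roots or abs(r - roots[-1]) > 1e-9:
                roots.append(r)
    out = []
    eps = 1e-7
    for r in sorted(roots):
        lo, hi = max(r - eps, 0.0), min(r + eps, 1.0)
        slope = (_reduced_field(hi, params, a, rho, bf)
                 - _reduced_field(lo, params, a, rho, bf)) / (hi - lo)
        out.append((float(r), "stable" if slope < 0 else "unstable"))
    return out


def _classify(points: list[tuple[float, str]], high_cut: float = 0.5) -> str:
    stable = [c for c, s in points if s == "stable"]
    if len(stable) >= 2:
        return "bistable"
    return "monostable_high" if stable and stable[0] >= high_cut else "monostable_low"


@dataclass
class BifurcationDiagram:
    """Fixed-point branches and region labels along a mitochondria-density scan."""

    rho_grid: np.ndarray
    branches: list[list[tuple[float, str]]]
    regions: list[str]

    def region_intervals(self) -> list[tuple[str, float, float]]:
        """Contiguous (label, rho_start, rho_end) intervals along the grid."""
        out: list[tuple[str, float, float]] = []
        for rho, label in zip(self.rho_grid, self.regions):
            if out and out[-1][0] == label:
                out[-1] = (label, out[-1][1], float(rho))
            else:
                out.append((label, float(rho), float(rho)))
        return out

    @property
    def region_sequence(self) -> list[str]:
        return [label for label, *_ in self.region_intervals()]


def bifurcation_scan(params: DynamicsParams, T: float, rho_grid,
                     inhibitor: float = 0.0) -> BifurcationDiagram:
    """Classify each density as monostable_low / bistable / monostable_high."""
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(rho_grid <= 0) or np.any(np.diff(rho_grid) <= 0):
        raise InvalidInputError("rho_grid must be positive and strictly increasing")
    branches, regions = [], []
    for rho in rho_grid:
        pts = fixed_points(params, T, float(rho), inhibitor=inhibitor)
        branches.append(pts)
        regions.append(_classify(pts))
    return BifurcationDiagram(rho_grid=rho_grid, branches=branches,
                              regions=regions)


# ---------------------------------------------------------------------------
# population dose-response simulation
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseGrid:
    """Simulated fraction-alive surface over (TRAIL dose, density) plus fits."""

    doses: np.ndarray
    rho_grid: np.ndarray
    fraction_alive: np.ndarray          # shape (n_rho, n_dose)
    hill_fits: list[HillFit | None]     # per rho; None if no transition
    powerlaw_intercept: float           # log IC50 at rho = 1
    powerlaw_exponent: float            # d log IC50 / d log rho
    population_fit: HillFit | None      # Hill fit of the rho-averaged curve
    excluded_rhos: list[float]
    seed: int = 0

    @property
    def ic50_by_rho(self) -> np.ndarray:
        return np.array([f.ic50 if f is not None else np.nan
                         for f in self.hill_fits])


def _integrate_grid(a, k_auto, k_fb, gamma_c, k_e, gamma_e, s_coef, h, K_pore,
                    t_end, dt):
    """Fixed-step RK4 for many independent cells at once.

    All arguments are broadcastable arrays over cells; s_coef is the
    per-cell pore drive per unit c (beta_i / (rho_i * (1 + B_f/K_bcl2))).
    Returns the running maximum of c, which decides the death call.
    """
    c = np.zeros_like(a)
    e = np.zeros_like(a)
    cmax = np.zeros_like(a)
    n_steps = int(round(t_end / dt))
    Kh = K_pore ** h

    def deriv(c, e):
        s = s_coef * np.maximum(c, 0.0)
        sh = s ** h
        pore = sh / (Kh + sh)
        dc = (a + k_auto * c + k_fb * e) * (1.0 - c) - gamma_c * c
        de = k_e * pore * (1.0 - e) - gamma_e * e
        return dc, de

    for _ in range(n_steps):
        dc1, de1 = deriv(c, e)
        dc2, de2 = deriv(c + 0.5 * dt * dc1, e + 0.5 * dt * de1)
        dc3, de3 = deriv(c + 0.5 * dt * dc2, e + 0.5 * dt * de2)
        dc4, de4 = deriv(c + dt * dc3, e + dt * de3)
        c = c + dt / 6.0 * (dc1 + 2 * dc2 + 2 * dc3 + dc4)
        e = e + dt / 6.0 * (de1 + 2 * de2 + 2 * de3 + de4)
        np.clip(c, 0.0, 1.0, out=c)
        np.clip(e, 0.0, 1.0, out=e)
        np.maximum(cmax, c, out=cmax)
    return cmax


def simulate_dose_response(params: DynamicsParams, doses=None, rho_grid=None,
                           cells_per_condition: int = 100, cv: float = 0.25,
                           t_end: float = 4.0, death_threshold: float = 0.5,
                           seed: int = 0, inhibitor: float = 0.0,
                           dt: float = 0.005) -> DoseResponseGrid:
    """Fraction alive over a (dose, density) grid with per-cell rate jitter.

    Defaults follow the standard simulated experiment: 100 cells per
    condition, 20 TRAIL doses, 12 mitochondria densities.  Cell-to-cell
    variability enters as lognormal (median-1) jitter with log-sd ``cv`` on
    k_trail, k_auto and beta.  A cell dies when c crosses
    ``death_threshold`` within ``t_end`` hours.  Per-density Hill fits give
    IC50(rho), which is fit to the power law log IC50 = a + k log rho;
    densities with no observable transition are excluded with a warning.
    """
    doses = np.geomspace(0.01, 100.0, 20) if doses is None \
        else np.asarray(doses, dtype=float)
    rho_grid = np.geomspace(0.25, 4.0, 12) if rho_grid is None \
        else np.asarray(rho_grid, dtype=float)
    if np.any(doses <= 0) or np.any(rho_grid <= 0):
        raise InvalidInputError("doses and rho_grid must be positive")
    rng = np.random.default_rng(seed)
    bf = free_bcl2(params.bcl2_total, inhibitor, params.K_I)
    n_rho, n_dose, n_cell = rho_grid.size, doses.size, cells_per_condition

    jitter = (np.exp(rng.normal(0.0, cv, (3, n_rho, n_dose, n_cell)))
              if cv > 0 else np.ones((3, n_rho, n_dose, n_cell)))
    k_trail = params.k_trail * jitter[0]
    k_auto = params.k_auto * jitter[1]
    beta = params.beta * jitter[2]
    T = doses[None, :, None]
    a = k_trail * T / (T + params.K_trail)
    s_coef = beta / (rho_grid[:, None, None]
                     * (1.0 + bf / params.K_bcl2))
    cmax = _integrate_grid(a, k_auto, params.k_fb, params.gamma_c,
                           params.k_e, params.gamma_e, s_coef, params.h,
                           params.K_pore, t_end, dt)
    alive = cmax < death_threshold
    frac = alive.mean(axis=2)

    hill_fits: list[HillFit | None] = []
    excluded: list[float] = []
    for i, rho in enumerate(rho_grid):
        try:
            hill_fits.append(fit_hill(DoseResponseCurve(doses, frac[i])))
        except NonIdentifiableError:
            hill_fits.append(None)
            excluded.append(float(rho))
            warnings.warn(
                f"rho={rho:.3g}: no transition across doses; excluded from "
                "the IC50(rho) power-law fit", stacklevel=2)
    ok = [i for i, f in enumerate(hill_fits) if f is not None]
    if len(ok) >= 2:
        slope, intercept = np.polyfit(np.log(rho_grid[ok]),
                                      [math.log(hill_fits[i].ic50) for i in ok], 1)
    else:
        slope, intercept = float("nan"), float("nan")
    try:
        pop_fit = fit_hill(DoseResponseCurve(doses, frac.mean(axis=0)))
    except NonIdentifiableError:
        pop_fit = None
    return DoseResponseGrid(
        doses=doses, rho_grid=rho_grid, fraction_alive=frac,
        hill_fits=hill_fits, powerlaw_intercept=float(intercept),
        powerlaw_exponent=float(slope), population_fit=pop_fit,
        excluded_rhos=excluded, seed=seed,
    )


def inhibitor_response(params: DynamicsParams, inhibitor_doses,
                       **sim_kwargs) -> pd.DataFrame:
    """Population IC50^TRAIL and density dependence along a Bcl-2 inhibitor sweep.

    Each inhibitor dose replaces total Bcl-2 by its free fraction and reruns
    the dose-response grid with identical random jitter (same seed), so the
    sweep isolates the inhibitor effect: IC50^TRAIL is monotone
    non-increasing and the rho-dependence exponent grows as pore formation
    is released from Bcl-2 inhibition.
    """
    rows = []
    for I in np.asarray(inhibitor_doses, dtype=float):
        if I < 0:
            raise InvalidInputError("inhibitor doses must be >= 0")
        grid = simulate_dose_response(params, inhibitor=float(I), **sim_kwargs)
        rows.append({
            "inhibitor": float(I),
            "free_bcl2": free_bcl2(params.bcl2_total, float(I), params.K_I),
            "ic50_trail": (grid.population_fit.ic50
                           if grid.population_fit else float("nan")),
            "powerlaw_exponent": grid.powerlaw_exponent,
            "n_excluded_rhos": len(grid.excluded_rhos),
        })
    return pd.DataFrame(rows)
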