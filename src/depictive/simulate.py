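"""Virtual single-cell populations and synthetic flow-cytometry event tables.

Each virtual cell draws independent Gaussian log-abundances for a set of
pathway components; its sensitivity kappa follows the first-order expansion
(plus an optional Gaussian intrinsic residual) and the cell survives dose T
iff kappa > log T (deterministic threshold rule — all stochasticity lives in
kappa, so the population dose response is exactly the survival function of
kappa).  A Bernoulli decision mode is also available, in which the intrinsic
residual is logistic and realized through a coin flip per (cell, dose).

A fresh cohort of ``n_cells`` is drawn per dose, emulating separate wells.
The generator also emulates flow channels: MitoTracker = rho * FSC on the
linear scale, a bimodal Annexin V channel by life/death state, and an
independent side-scatter channel usable as a negative-control covariate.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .errors import InvalidInputError
from .hill import DoseResponseCurve
from .inference import LiveOnlyDataset
from .singlecell import Component, SensitivityExpansion

__all__ = [
    "GeneratorConfig",
    "VirtualPopulation",
    "ChannelNoise",
    "benchmark_config",
    "simulate_population",
    "simulate_replicates",
    "censor_to_live_only",
    "emulate_fcm_channels",
]

_SQRT3 = math.sqrt(3.0)

#: Generating coefficients of the five-component benchmark pathway
#: (w1, w2 unobserved; x, z, q measured), with unit log-variances.
BENCHMARK_K = {"x": 0.25, "w1": 0.5, "z": 1.0, "q": 1.5, "w2": 2.0}


@dataclass
class GeneratorConfig:
    """Specification of a virtual-cell experiment.

    components : expansion terms (name, k, log_mean, sigma2)
    sigma_intrinsic : sd of the unmodeled Gaussian residual on kappa
    log_ic50 : population mean sensitivity (log ng/mL)
    doses : ng/mL; defaults to 12 log-spaced doses spanning +-3 sd of kappa
    n_cells : cells per dose (a fresh cohort is drawn for every dose)
    n_replicates : replicate experiments for helpers that iterate
    seed : master seed; replicates spawn child seeds deterministically
    decision : "threshold" (default) or "bernoulli"
    """

    components: list[Component]
    sigma_intrinsic: float = 0.0
    log_ic50: float = math.log(10.0)
    doses: np.ndarray | None = None
    n_cells: int = 10_000
    n_replicates: int = 1
    seed: int = 0
    decision: str = "threshold"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidInputError("n_cells must be >= 1")
        if self.sigma_intrinsic < 0:
            raise InvalidInputError("sigma_intrinsic must be >= 0")
        if self.decision not in ("threshold", "bernoulli"):
            raise InvalidInputError(f"unknown decision rule {self.decision!r}")
        if not self.components and self.sigma_intrinsic == 0:
            raise InvalidInputError(
                "degenerate population: no components and no intrinsic noise "
                "would make every cell identical"
            )
        if self.doses is None:
            spread = 3.0 * math.sqrt(self.kappa_variance)
            self.doses = np.exp(np.linspace(self.log_ic50 - spread,
                                            self.log_ic50 + spread, 12))
        self.doses = np.asarray(self.doses, dtype=float)
        if np.any(self.doses < 0):
            raise InvalidInputError("doses must be non-negative")

    @property
    def kappa_variance(self) -> float:
        var = sum(c.k**2 * c.sigma2 for c in self.components)
        return var + self.sigma_intrinsic**2

    @property
    def expansion(self) -> SensitivityExpansion:
        return SensitivityExpansion(
            log_ic50=self.log_ic50, components=list(self.components),
            sigma2_intrinsic=self.sigma_intrinsic**2,
        )

    def config_hash(self) -> str:
        payload = {
            "components": [vars(c).copy() for c in self.components],
            "sigma_intrinsic": self.sigma_intrinsic,
            "log_ic50": self.log_ic50,
            "doses": list(map(float, self.doses)),
            "n_cells": self.n_cells,
            "decision": self.decision,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def benchmark_config(n_cells: int = 10_000, n_replicates: int = 1,
                     seed: int = 0, **overrides) -> GeneratorConfig:
    """The five-component benchmark pathway with unit log-variances.

    Coefficients k_x=0.25, k_w1=0.5, k_z=1, k_q=1.5, k_w2=2 acting on
    independent unit-variance Gaussian log-abundances, so the variance of
    kappa is sum k_i^2 = 7.5625 and variance-explained fractions reduce to
    k_i^2 / 7.5625.
    """
    comps = [Component(name, k) for name, k in BENCHMARK_K.items()]
    return GeneratorConfig(components=comps, n_cells=n_cells,
                           n_replicates=n_replicates, seed=seed, **overrides)


@dataclass
class VirtualPopulation:
    """Long-form record of simulated cells: one row per (dose, cell).

    ``events`` columns: dose, one column per component log-abundance,
    kappa, alive (bool).
    """

    events: pd.DataFrame
    config: GeneratorConfig
    replicate_id: int = 0
    seed: int = 0

    @property
    def doses(self) -> np.ndarray:
        return self.config.doses

    def counts(self) -> pd.DataFrame:
        g = self.events.groupby("dose", sort=True)["alive"]
        out = g.agg(alive="sum", total="count").reset_index()
        out["alive"] = out["alive"].astype(int)
        return out

    def dose_response(self) -> DoseResponseCurve:
        c = self.counts()
        return DoseResponseCurve.from_counts(
            c["dose"], c["alive"], c["total"],
            replicate_id=str(self.replicate_id),
        )


def simulate_population(config: GeneratorConfig,
                        rng: np.random.Generator | None = None,
                        replicate_id: int = 0) -> VirtualPopulation:
    """Draw a virtual population; reproducible given the config seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = [c.name for c in config.components]
    frames = []
    for T in config.doses:
        logx = {
            c.name: rng.normal(c.log_mean, math.sqrt(c.sigma2), config.n_cells)
            for c in config.components
        }
        kappa = np.full(config.n_cells, config.log_ic50)
        for c in config.components:
            kappa = kappa + c.k * (logx[c.name] - c.log_mean)
        if config.decision == "threshold":
            if config.sigma_intrinsic > 0:
                kappa = kappa + rng.normal(0.0, config.sigma_intrinsic,
                                           config.n_cells)
            alive = kappa > (math.log(T) if T > 0 else -np.inf)
        else:
            # logistic intrinsic noise realized as a per-cell coin flip
            if T > 0:
                scale = config.sigma_intrinsic * _SQRT3 / math.pi
                if scale == 0:
                    p = (kappa > math.log(T)).astype(float)
                else:
                    p = special.expit((kappa - math.log(T)) / scale)
                alive = rng.random(config.n_cells) < p
            else:
                alive = np.ones(config.n_cells, dtype=bool)
        df = pd.DataFrame({name: logx[name] for name in names})
        df.insert(0, "dose", T)
        df["kappa"] = kappa
        df["alive"] = alive
        frames.append(df)
    events = pd.concat(frames, ignore_index=True)
    return VirtualPopulation(events=events, config=config,
                             replicate_id=replicate_id, seed=config.seed)


def simulate_replicates(config: GeneratorConfig,
                        n_replicates: int | None = None):
    """Yield independent replicate populations with spawned child seeds."""
    n = config.n_replicates if n_replicates is None else n_replicates
    children = np.random.SeedSequence(config.seed).spawn(n)
    for r, child in enumerate(children):
        yield simulate_population(config, rng=np.random.default_rng(child),
                                 replicate_id=r)


def censor_to_live_only(pop: VirtualPopulation, covariate: str,
                        baseline_doses: np.ndarray | None = None) -> LiveOnlyDataset:
    """Discard the covariate of dead cells, keeping exact per-dose counts.

    Mirrors the loss of the mitochondrial stain in apoptotic cells: N_j and
    A_j are retained exactly, covariate values survive only for live cells.
    """
    if covariate not in pop.events.columns:
        raise InvalidInputError(f"unknown covariate {covariate!r}")
    doses, n_total, n_alive, live_values = [], [], [], []
    for T, grp in pop.events.groupby("dose", sort=True):
        doses.append(float(T))
        n_total.append(len(grp))
        alive = grp["alive"].to_numpy()
        n_alive.append(int(alive.sum()))
        live_values.append(grp.loc[grp["alive"], covariate].to_numpy(float))
    return LiveOnlyDataset(
        doses=np.array(doses), n_total=np.array(n_total),
        n_alive=np.array(n_alive), live_values=live_values,
        baseline_doses=baseline_doses, covariate=covariate,
    )


@dataclass
class ChannelNoise:
    """Multiplicative (log-normal) measurement noise per emulated channel."""

    fsc_sd: float = 0.05
    mito_sd: float = 0.05
    ssc_sd: float = 0.25
    annexin_sd: float = 0.15
    annexin_alive: float = 100.0
    annexin_dead: float = 1000.0
    fsc_scale: float = 1e4
    ssc_scale: float = 5e3

    def zero(self) -> "ChannelNoise":
        return ChannelNoise(0.0, 0.0, 0.0, 0.0, self.annexin_alive,
                            self.annexin_dead, self.fsc_scale, self.ssc_scale)


def emulate_fcm_channels(pop: VirtualPopulation,
                         noise: ChannelNoise | None = None,
                         size_component: str = "w1",
                         density_component: str = "q",
                         seed: int | None = None) -> pd.DataFrame:
    """Map a virtual population onto FSC/SSC/MitoTracker/AnnexinV channels.

    FSC is the exponentiated size-like component (times measurement noise);
    MitoTracker = rho * FSC on the linear scale, where log rho is the
    density-like component, so log MitoTracker - log FSC = log rho exactly
    before noise.  FSC and MitoTracker are therefore positively correlated,
    and Annexin V is bimodal by life/death state.  SSC is independent of
    everything (the internal negative control).
    """
    for col in (size_component, density_component):
        if col not in pop.events.columns:
            raise InvalidInputError(f"population lacks component {col!r}")
    noise = noise or ChannelNoise()
    rng = np.random.default_rng(pop.seed + 7_654_321 if seed is None else seed)
    ev = pop.events
    m = len(ev)

    log_size = ev[size_component].to_numpy(float)
    log_rho = ev[density_component].to_numpy(float)
    fsc = noise.fsc_scale * np.exp(log_size + _noise(rng, noise.fsc_sd, m))
    mito = np.exp(log_rho) * fsc * np.exp(_noise(rng, noise.mito_sd, m))
    ssc = noise.ssc_scale * np.exp(_noise(rng, noise.ssc_sd, m, always=True))
    alive = ev["alive"].to_numpy(bool)
    annexin_mu = np.where(alive, noise.annexin_alive, noise.annexin_dead)
    annexin = annexin_mu * np.exp(_noise(rng, noise.annexin_sd, m))

    return pd.DataFrame({
        "dose": ev["dose"].to_numpy(float),
        "replicate_id": pop.replicate_id,
        "FSC": fsc, "SSC": ssc, "MitoTracker": mito, "AnnexinV": annexin,
        "state": np.where(alive, "alive", "dead"),
    })


def _noise(rng: np.random.Generator, sd: float, m: int,
           always: bool = False) -> np.ndarray:
    # consume the stream even at sd=0 only when the channel is pure noise,
    # so zeroing measurement noise does not shift other channels' draws
    if sd == 0 and not always:
        return np.zeros(m)
    return rng.normal(0.0, sd if sd > 0 else 1.0, m) * (1.0 if sd > 0 else 0.0)
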