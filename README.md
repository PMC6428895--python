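# depictive

Decomposing cell-to-cell variability in binary dose responses — with a
covariate you can only measure in the survivors.

## The problem

When an isogenic cell population is challenged with a death ligand such as
TRAIL, only a fraction of cells dies at any given dose ("fractional
killing").  This package reads the fraction-alive dose-response curve as
the cumulative distribution of single-cell sensitivities: each cell has a
log-dose death threshold κ, and the population curve

    f(T) = 1 / (1 + (T / IC50)^n)

is exactly the survival function of κ ~ Logistic(log IC50, 1/n).  The mean
sensitivity is log IC50 and its variance is π²/(3n²) — steep curves mean a
homogeneous population, shallow curves a heterogeneous one.

Expanding κ to first order in the log abundances of pathway components
x_i, κ = log IC50 + Σ k_i δlog x_i, gives a conditional (single-cell) Hill
model for a measured component ρ (here: mitochondria density, the
MitoTracker signal normalized to forward scatter):

    IC50(ρ) = IC50 · (ρ/⟨ρ⟩)^k_ρ
    n_ρ     = π / √(3 Σ_{i≠ρ} k_i² σ_i²)
    P(alive | ρ, T) = (ρ/⟨ρ⟩)^{k_ρ n_ρ} / ((ρ/⟨ρ⟩)^{k_ρ n_ρ} + (T/IC50)^{n_ρ})

so the fraction of sensitivity variance a component explains is
k_ρ²σ_ρ² / Σ_j k_j²σ_j².

The experimental twist is that apoptosis corrupts the mitochondrial stain:
ρ is observable only in *live* (Annexin-V-negative) cells.  The package's
core is a semi-supervised maximum-likelihood fit that combines the per-dose
binomial alive counts with the survivor density of the covariate
(Bayes: p(u|alive,T) ∝ P(alive|u,T)·p₀(u)), recovering (log IC50, n_ρ, k_ρ)
without ever seeing a dead cell's covariate.

Also included: a synthetic flow-cytometry generator (virtual-cell
populations with live-only censoring, used as the test substrate
throughout), population Hill fitting, gating/event-table I/O, and a
coarse-grained bistable model of TRAIL-induced apoptosis in which Bax/Bak
is diluted over the mitochondrial surface — reproducing, qualitatively, the
dependence of single-cell IC50 on mitochondria density and its modulation
by Bcl-2 inhibitors.

Intended users: quantitative cell biologists analyzing binary-outcome flow
cytometry, and modelers studying fractional killing.

## Worked example

```python
import depictive as dp

# a virtual experiment: five components shape each cell's sensitivity;
# the "q" component (k_q = 1.5) plays the role of mitochondria density
pop = dp.simulate_population(dp.benchmark_config(n_cells=10_000, seed=3))

hill = dp.fit_hill(pop.dose_response())
print(f"population Hill fit: IC50 = {hill.ic50:.2f} ng/mL, n = {hill.n:.3f}")
print(f"implied sensitivity sd: {dp.hill_to_sensitivity_sd(hill.n):.3f} (log ng/mL)")

# censor: dead cells lose their covariate, then fit semi-supervised
data = dp.censor_to_live_only(pop, "q")
res = dp.fit(data, {"n_boot": 16, "seed": 0})
print(f"k_q = {res.params.k_rho:.3f} +/- {res.se['k_rho']:.3f}")
print(f"variance explained by q: {res.variance_explained:.1%}")
```

prints

```
population Hill fit: IC50 = 10.02 ng/mL, n = 0.616
implied sensitivity sd: 2.946 (log ng/mL)
k_q = 1.476 +/- 0.026
variance explained by q: 28.6%
```

The shallow population curve (n ≈ 0.62) reflects the large total
sensitivity spread (sd ≈ 2.9 log-units).  The semi-supervised fit, seeing
only live-cell covariate values, recovers the generating coefficient
k_q = 1.5 within its bootstrap uncertainty, and attributes ≈ 29% of the
sensitivity variance to q — the generating share is k_q²/Σk_i² = 2.25/7.5625
≈ 29.8%.

A command-line interface mirrors the library:

```bash
depictive simulate --seed 1 --n-cells 10000 --out events.csv
depictive fit --events events.csv --out fit.json
depictive dynamics --params jurkat-like --mode bifurcation --out out/
depictive report --config pipeline.yaml --out out/
```

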