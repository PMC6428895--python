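# Methods

## 1. Dose response as a sensitivity distribution

The package treats a binary (live/dead) dose response as a statistical
object.  Each cell carries a sensitivity κ, the log dose at which it dies;
the population fraction alive at dose T is P(κ > log T).  If that fraction
follows a Hill curve f(T) = 1/(1+(T/IC50)^n), then κ is exactly logistic
with location log IC50 and scale 1/n, so

    E[κ] = log IC50,     Var[κ] = π² / (3 n²).

`hill_to_sensitivity_sd` / `sensitivity_sd_to_hill` are this bijection;
`fit_hill` estimates (IC50, n) by least squares on fractions (default) or
binomial maximum likelihood when counts are available (the criterion is a
modeling choice; both are exposed because published dose-response fits
rarely state theirs).  Starting values come from a deterministic log-spaced
grid over the dose range × n ∈ [0.25, 16], refined by L-BFGS-B — shallow
curves otherwise trap local optimizers.  Standard errors come from the
local curvature (finite-difference Hessian) of the objective in
(log IC50, log n), delta-methoded back to (IC50, n).  Doses of zero are
retained in the data object but excluded from log-space fitting.

Degenerate inputs are rejected explicitly: fewer than 3 distinct positive
doses, or a curve with no observed transition (all fractions > 0.95 or
< 0.05), which leaves (IC50, n) unidentifiable.

## 2. The conditional (single-cell) Hill model

Sensitivity is expanded to first order in component log abundances:
κ = log IC50 + Σ k_i (log x_i − log⟨x_i⟩) + ε.  Conditioning on one
measured component ρ gives IC50(ρ) = IC50·(ρ/⟨ρ⟩)^k_ρ and a conditional
Hill coefficient n_ρ = π/√(3·(Σ_{i≠ρ} k_i²σ_i² + σ_ε²)), combining into
P(alive|ρ,T) as a logistic survival in log T with ρ-dependent location.
The expansion is truncated at first order; interaction terms are out of
scope.  Variance explained by component i is k_i²σ_i² divided by the total
(including σ_ε²).

All arithmetic is in log-dose / log-density space, and P(alive|ρ,T) is
evaluated as expit(−n_ρ(log T − log IC50 − k_ρ δlog ρ)): the power-law
ratio form overflows for extreme ρ when the exponent k_ρ·n_ρ is large, the
log-space form cannot.

Two variance-explained conventions exist: dividing by the total variance
from the *population* Hill fit, or by k̂²σ̂² + π²/(3 n̂_ρ²) from the
conditional fit itself.  The latter is the default (`variance_explained_`,
`variance_explained_from_fit`) because it is internally consistent — the
two pieces come from the same likelihood — and cannot leave the unit
interval; the population-fit route remains available by combining
`fit_hill` with `hill_to_sensitivity_sd`.

## 3. Semi-supervised likelihood (live-only covariate)

The data structure (`LiveOnlyDataset`) is per dose j: totals N_j, alive
counts A_j, and covariate values u = log ρ for the live cells only — dead
cells carry none, because apoptosis corrupts the mitochondrial stain.

The likelihood has two parts.  With g(u, T) = P(alive|u, T) and p₀(u) the
baseline covariate density, the marginal survival at dose j is
Z_j = ∫ g(u, T_j) p₀(u) du, and

    loglik = Σ_j [ log Binom(A_j; N_j, Z_j)
                   + Σ_{i ∈ live_j} ( log g(u_ji, T_j) + log p₀(u_ji) − log Z_j ) ],

the second line being the Bayes survivor density p(u|alive,T) = g·p₀/Z.
This construction is the minimal likelihood consistent with the conditional
Hill model and the live-only censoring; it is this package's own
reconstruction of the semi-supervised logistic-regression idea, not a
transcription of a published derivation.

Choices that matter:

* **Baseline density p₀.** Gaussian KDE (Silverman bandwidth by default) on
  live cells pooled over the declared baseline doses — by default the three
  lowest, which in both the experimental design and the default generator
  kill ≲ 3% and are effectively unperturbed.  p₀ is estimated once and held
  fixed during optimization (stability; re-estimating it jointly would let
  the fit bend the reference distribution).  The reference ⟨ρ⟩ is fixed to
  the baseline mean of u.  Baseline contamination by the few dead cells at
  those doses biases k̂ down by ~1–2% at default settings — visible in the
  recovery experiments and accepted as faithful to the pooling procedure.
* **Quadrature.** Z_j by trapezoid on the 512-point KDE grid (padded ±3
  bandwidths).  Cross-checked against Monte-Carlo integration in the tests.
* **Optimization.** Maximize over (log IC50, log n_ρ, k_ρ): 8 multi-starts
  (seeded Latin-style grid over the dose range × n ∈ [0.25,16] ×
  k ∈ [−3,3], plus one start at the population Hill fit with k = 0),
  L-BFGS-B refinement, tolerance 1e-8.  Non-finite likelihoods (Z
  underflow at extreme parameters) are mapped to −∞/large-penalty, never
  NaN.  Identifiability requires ≥ 3 doses with partial killing: the dose
  axis pins n_ρ, the survivor-density shift pins k_ρ, so the two do not
  trade off (checked by recovery tests).
* **Uncertainty.** Cell-level bootstrap: within each dose A_j is redrawn
  binomially and that many live values resampled with replacement; refits
  are warm-started at the point estimate.  SEs are sds over B refits,
  reproducible given the seed.

## 4. The virtual-cell generator

`simulate_population` draws, per dose, a fresh cohort of cells (separate
wells, as in the experiment): independent Gaussian log-abundances per
component, κ from the first-order expansion plus optional Gaussian
intrinsic noise, and a deterministic threshold decision y = 1 iff
κ > log T.  The threshold rule puts all stochasticity into κ, so the
population dose response is exactly the survival function of κ — the
interpretation the statistical framework rests on.  A Bernoulli mode
(logistic intrinsic noise realized as a per-cell coin flip) is also
implemented for sensitivity analyses; threshold is the default.

The default benchmark is the five-component pathway with coefficients
k_x = 0.25, k_w1 = 0.5, k_z = 1, k_q = 1.5, k_w2 = 2, unit log-variances
(so variance-explained shares reduce to k_i²/7.5625), 10,000 cells per
dose, and log IC50 = log 10 ng/mL.  The dose grid — not fixed by the
benchmark's published description — is 12 log-spaced doses spanning
log IC50 ± 3 sd(κ), chosen so the lowest three doses are effectively
unperturbed and can serve as the pooled baseline.

Channel emulation maps a population onto FSC/SSC/MitoTracker/AnnexinV:
MitoTracker = ρ·FSC on the linear scale (so log MitoTracker − log FSC
recovers log ρ exactly at zero noise), lognormal measurement noise per
channel, a bimodal Annexin V channel by state, and an SSC channel
independent of fate (the internal negative control).  Not emulated, hence
not probed by passing tests: spectral spillover/compensation, doublets,
autofluorescence, instrument-specific transforms, and any dependence of
channel noise on state or dose.  Crucially, the generator's decision rule
is Gaussian-threshold while the fitted model assumes a logistic residual;
the recovery experiments therefore also measure robustness to that
(realistic) mismatch — the observed ~1–2% downward bias in k̂ is the price,
well inside the replicate spread.

## 5. Coarse-grained apoptosis dynamics

Two states on [0,1]: initiator-caspase activity c and effector-caspase
activity e, with

    dc/dt = (a(T) + k_auto·c + k_fb·e)(1−c) − γ_c·c,   a(T) = k_trail·T/(T+K_trail)
    de/dt = k_e·pore(c)·(1−e) − γ_e·e
    pore  = s^h/(K_pore^h + s^h),   s = β·c / (ρ·(1 + B_f/K_bcl2))

The three ingredients are slow autocatalytic IC activation, a
quasi-steady-state Bax/Bak pore (MOMP) whose drive is diluted by
mitochondria density ρ and damped by free Bcl-2, and strong EC→IC
feedback.  Free Bcl-2 under a small-molecule inhibitor is the positive
root of B_f² + (I_T − B_T + K_I)B_f − K_I·B_T = 0 (equilibrium binding
with both conservation laws).  These equations, and the shipped
`jurkat-like` / `mda-like` YAML parameter sets, are this package's own
construction calibrated to qualitative targets only: at T = 0 the
jurkat-like scan over ρ ∈ [0.25, 4] shows monostable-high → bistable →
monostable-low (three regions), the mda-like set (identical but for
five-fold higher total Bcl-2) shows bistable → monostable-low; the
single-cell c(t) trace is biphasic; IC50(ρ) has a positive power-law
exponent; Bcl-2 inhibition lowers the population IC50^TRAIL and raises the
ρ-dependence.  They are not a published parameterization and the absolute
rate values carry no biological meaning beyond those targets.

Numerics: single-cell trajectories use LSODA with rtol 1e-7 / atol 1e-9
(the vector field is smooth but can stiffen near the saddle-node).
Fixed points come from a 1-D reduction (e at its c-conditional steady
state), dense sign-change bracketing on 2001 points plus Brent refinement;
stability is the sign of the reduced field's derivative; c = 0 is handled
explicitly as an exact fixed point when a(T) = 0.  Region labels:
two stable points = bistable; one stable point = monostable_high/low split
at c = 0.5, matching the death criterion.

Population dose-response grids (default 100 cells × 20 doses × 12
densities, and the 9-dose inhibitor sweep on top — ~2×10⁵ trajectories)
use a vectorized fixed-step RK4 integrator (dt = 0.005 h) over all cells
simultaneously; it matches the LSODA reference to ~1e-3 in max c in the
tests, and the death call (c crossing 0.5 within a 4 h window, matching
the experimental time frame) is insensitive at that accuracy.  Cell-to-cell
variability enters as lognormal (median-1, log-sd `cv` = 0.25) jitter on
k_trail, k_auto and β only — a parsimonious choice sufficient for a graded
fractional response.  Densities whose curves show no transition are
excluded from the IC50(ρ) power-law fit with a warning.  Inhibitor sweeps
reuse the same seed at every inhibitor dose (common random numbers), so
monotonicity reflects the inhibitor, not resampling noise.

## 6. Gating and I/O

Event tables are CSV/TSV (`float_precision="round_trip"` on read; FCS
ingestion is not included in this build).  Gating is sequential
threshold / interval / rectangle gates declared in config, never
hard-coded; the per-dose fraction alive is the Annexin-V-negative count
over the MitoTracker-positive count, and downstream single-cell analysis
uses Annexin-V-negative cells only.  The density channel is
log ρ = log MitoTracker − log FSC, with non-positive rows excluded and
counted.  `run_pipeline` chains load/simulate → gate → density →
population Hill fit → semi-supervised fit → variance explained, tags
errors with their stage, and stamps outputs with the config hash and seed;
deterministic stages are bit-reproducible.

## 7. Scale choices and limitations

* Test-suite problem sizes are scaled to what the checks need: recovery
  tests run 20 replicates × 10,000 cells per dose (the benchmark's cohort
  size); variance-removal comparisons use 30,000 cells per dose with
  common random numbers so a sub-percent steepening is resolved without
  replication; dynamics property sweeps use 50–150 random parameter sets.
* The recovery experiments quantify bias only under the generator's
  assumptions (independent Gaussian log-abundances, threshold rule,
  perfect gating).  Real data add gating error, channel noise correlated
  with state, and non-Gaussian abundance distributions; of these, only
  channel noise and gating are emulated, and only optionally.
* The semi-supervised fit handles a single covariate (plus an internal
  control fit run separately); multi-covariate joint fits and Bayesian
  posteriors are out of scope.
* The dynamics model is deliberately coarse: no explicit Bax/Bak state,
  no receptor dynamics, no stochastic MOMP; its purpose is the
  fixed-point structure in (T, ρ), not kinetic realism.
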