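# Coarse-grained apoptosis parameter set, "mda-like".
# This package's own calibration (version 1): identical to the jurkat-like
# set except for a five-fold higher total Bcl-2, making Bax/Bak pore
# formation more susceptible to Bcl-2 inhibition.  At TRAIL = 0 the
# bifurcation scan over rho in [0.25, 4] shows only two regions
# (bistable -> monostable_low), the population IC50 is several-fold higher
# than the jurkat-like set, and a Bcl-2 inhibitor sweep lowers IC50^TRAIL
# while increasing the rho-dependence of single-cell sensitivities.
version: 1
params:
  k_trail: 3.0
  K_trail: 110.0
  k_auto: 1.05
  gamma_c: 1.0
  k_fb: 6.0
  k_e: 3.0
  gamma_e: 1.0
  beta: 1.0
  h: 6.0
  K_pore: 0.25
  K_bcl2: 0.2
  bcl2_total: 1.0
  K_I: 1.0
  rho: 1.0
  name: mda-like
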