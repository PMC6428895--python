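# Coarse-grained apoptosis parameter set, "jurkat-like".
# This package's own calibration (version 1): chosen so that, at TRAIL = 0,
# the bifurcation scan over rho in [0.25, 4] shows the three-region
# structure monostable_high -> bistable -> monostable_low, the IC-RP-style
# single-cell trace is biphasic (slow-then-fast), the simulated IC50(rho)
# power law has a positive exponent, and the population IC50 falls in the
# few-ng/mL range typical of a readily TRAIL-responsive line.
version: 1
params:
  k_trail: 3.0      # 1/h at saturating TRAIL
  K_trail: 110.0    # ng/mL
  k_auto: 1.05      # 1/h
  gamma_c: 1.0      # 1/h
  k_fb: 6.0         # 1/h
  k_e: 3.0          # 1/h
  gamma_e: 1.0      # 1/h
  beta: 1.0         # dimensionless
  h: 6.0            # pore cooperativity
  K_pore: 0.25      # effective Bax/Bak units
  K_bcl2: 0.2       # free Bcl-2 halving the pore drive
  bcl2_total: 0.2   # concentration units
  K_I: 1.0          # inhibitor dissociation constant
  rho: 1.0          # reference mitochondria density
  name: jurkat-like
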