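# Named parameter sets for the track-structure RBE_gamma-acute model.
#
# The shipped "lymphocyte-simple-exchange" set contains PLACEHOLDER values:
# they are order-of-magnitude realistic for chromosome simple exchanges in
# human peripheral blood lymphocytes referenced to acute gamma rays, but they
# are NOT the published experimental fit.  Substitute the fitted
# (sigma0, alpha_gamma, m, kappa) of the lymphocyte simple-exchange endpoint
# before using RBE-weighted dose equivalents quantitatively.
lymphocyte-simple-exchange:
  sigma0_um2: 6.0
  alpha_gamma_per_gy: 0.055
  m: 3.0
  kappa: 250.0
  endpoint: "simple exchanges, human peripheral blood lymphocytes (PLACEHOLDER values)"
  placeholder: true
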