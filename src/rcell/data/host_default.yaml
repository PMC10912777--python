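# Default E. coli host-cell parameterization.
# Units: concentrations nM, time h, protein lengths aa, M nM-aa.
# Literature anchors: total protein density M, housekeeping mass share
# phi_q, maximum elongation rate (20 aa/s), lumped gene lengths, mRNA
# turnover (~7 min half-life) and ribosome-RBS kinetics.  The remaining
# rates (nu_max, K_eps = K_nu, psi_max, tau, promoter strengths) were
# calibrated once against the empirical growth laws, the physiological
# growth-rate range (~0.25-2 1/h over sigma in [0.05, 1]) and near-optimal
# ppGpp resource allocation; see docs/methods.md.
host:
  M: 1.19e+9       # total modeled protein mass density (nM-aa)
  phi_q: 0.59      # housekeeping protein mass fraction
  eps_max: 7.2e+4  # max translation elongation rate (aa/h), = 20 aa/s
  K_eps: 3000.0    # elongation half-saturation (nM charged tRNA)
  nu_max: 4000.0   # max per-enzyme tRNA aminoacylation rate (1/h)
  K_nu: 3000.0     # aminoacylation half-saturation (nM); parity with K_eps
  psi_max: 1.0e+4  # max tRNA transcription per unit growth rate (nM)
  tau: 0.04        # ppGpp-regulation half-saturation (dimensionless)
  sigma: 0.5       # default medium nutrient quality
  c_a: 1.0         # one chromosomal copy (nM)
  alpha_a: 1.0e+5  # metabolic promoter strength (dimensionless)
  beta_a: 6.0      # mRNA degradation (1/h)
  n_a: 300.0       # lumped metabolic protein length (aa)
  k_plus_a: 60.0   # ribosome-RBS association (1/(nM h))
  k_minus_a: 60.0  # ribosome-RBS dissociation (1/h)
  c_r: 1.0
  alpha_r: 8.5e+4  # ribosomal promoter strength (alpha_r:alpha_a = 0.85)
  beta_r: 6.0
  n_r: 7459.0      # summed ribosomal protein length (aa)
  k_plus_r: 60.0
  k_minus_r: 60.0
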