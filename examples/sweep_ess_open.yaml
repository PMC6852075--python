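# Sweep specification: equilibrium cooperation surface of the open model
# (relatedness R kept as a free parameter). One output row per grid cell.
#
# mode: which computation runs per cell. One of:
#   ess_open    - open-model ESS x0*(R, lam, s, f)
#   ess_closed  - closed-model ESS x_c*(lam, k, s, f) + demographic R
#   dominance   - marginal effects dx*/dR, dx*/dlam and the dominant factor
#   routes      - direct vs via-relatedness decomposition of dx_c*/dlam
#   simulate    - individual-based runs with branching classification
mode: ess_open

# axes: parameter name -> list of values; the sweep crosses all axes.
axes:
  R: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
  lam: [0.0, 0.25, 0.5, 0.75, 1.0]
  s: [1.0]
  f: [1.0, 2.0]
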