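# Synthetic default coefficients for the linear contact-based binding score
#
#   dG_S = intercept + sum_class weight_class * count_class   [kcal/mol]
#
# Contacts are heavy-atom ligand-protein pairs within `cutoff` Angstrom,
# classified by the unordered element pair with elements mapped to
# {C, N, O, X = any other element}.
#
# These values are a synthetic stand-in chosen so that steroid-sized
# ligands in vestibule-bound poses score in the experimentally typical
# -8 to -10 kcal/mol range (K_D of order 10^2 nM at 310 K).  They are NOT
# the published coefficients of any external scoring program; substitute
# your preferred published parameter set here for production use.  The
# scoring engine assumes nothing beyond linearity in the class counts.
intercept: -4.80
cutoff: 10.5
# keys are quoted: bare NO is a YAML 1.1 boolean
weights:
  "CC": -0.013
  "CN": -0.040
  "CO": -0.047
  "CX": -0.020
  "NN": -0.053
  "NO": -0.060
  "NX": -0.033
  "OO": -0.073
  "OX": -0.040
  "XX": -0.013
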