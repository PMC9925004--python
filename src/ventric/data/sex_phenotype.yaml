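# Sex-specific ion-channel sub-unit expression multipliers applied to the
# baseline (male) ventricular myocyte model.  The female phenotype encodes
# the mRNA-expression-derived down-regulation of the repolarizing potassium
# currents (Ito, IKr, IKs, IK1) and up-regulation of the Na+/Ca2+ exchanger
# reported for phenotypically female hearts; the male phenotype is the
# identity by construction.  Values are dimensionless multipliers on the
# maximal conductances / permeabilities and are user-overridable.
male:
  g_Na: 1.0
  g_NaL: 1.0
  g_to: 1.0
  P_Ca: 1.0
  g_Kr: 1.0
  g_Ks: 1.0
  g_K1: 1.0
  g_NaCa: 1.0
  g_NaK: 1.0
female:
  g_Na: 1.0
  g_NaL: 1.0
  g_to: 0.64
  P_Ca: 1.0
  g_Kr: 0.80
  g_Ks: 0.83
  g_K1: 0.85
  g_NaCa: 1.15
  g_NaK: 1.0
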