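# Transient-sodium / delayed-rectifier-potassium gating rates for a
# hippocampal pyramidal neuron (classic Traub-Miles CA3 rate functions).
# Rates are in 1/ms, voltages in mV.  Rate kinds:
#   linoid      a * (v - th) / (1 - exp(-(v - th)/q))
#   linoid_neg  a * (th - v) / (1 - exp(-(th - v)/q))
#   expdecay    a * exp(-(v - th)/q)
#   sigmoid     a / (1 + exp(-(v - th)/q))
# The sodium current is gbar * m^3 * h * (v - E_Na), the potassium current
# gbar * n^4 * (v - E_K).  A hyperpolarizing shift moves all sodium curves
# (activation and inactivation) to more negative voltages.
name: hippocampal_pyramidal_na_k
E_Na: 50.0
E_K: -90.0
exponents: {m: 3, h: 1, n: 4}
rates:
  m_alpha: {kind: linoid,     a: 0.32,  th: -54.0, q: 4.0}
  m_beta:  {kind: linoid_neg, a: 0.28,  th: -27.0, q: 5.0}
  h_alpha: {kind: expdecay,   a: 0.128, th: -50.0, q: 18.0}
  h_beta:  {kind: sigmoid,    a: 4.0,   th: -27.0, q: 5.0}
  n_alpha: {kind: linoid,     a: 0.032, th: -52.0, q: 5.0}
  n_beta:  {kind: expdecay,   a: 0.5,   th: -57.0, q: 40.0}
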