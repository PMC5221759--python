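# Transient-sodium / delayed-rectifier-potassium kinetics for hippocampal
# CA1 pyramidal neurons (the widely used na3/kdr formulation: trap-function
# Na activation/inactivation rates with minimum time constants, and a
# Boltzmann-rate delayed rectifier with a single activation gate).
# Voltages in mV, times in ms, temperatures in degrees C.
#
# Sodium:  i = gbar * m^3 * h * (v - E_Na)
#   malpha = trap(v,  tha, Ra, qa)      trap(v,th,a,q) = a (v-th)/(1-exp(-(v-th)/q))
#   mbeta  = trap(-v, -tha, Rb, qa)
#   mtau   = max(1/(malpha+mbeta)/qt, mmin);  minf = malpha/(malpha+mbeta)
#   halpha = trap(v,  thi1, Rd, qd)
#   hbeta  = trap(-v, -thi2, Rg, qg)
#   htau   = max(1/(halpha+hbeta)/qt, hmin)
#   hinf   = 1/(1+exp((v-thinf)/qinf))
# Potassium: i = gbar * n * (v - E_K)
#   alp = exp(zeta * c * (v-vhalf)),  bet = exp(zeta * gm * c * (v-vhalf))
#   with c = 1e-3 * 9.648e4 / (8.315 * (273.16 + celsius))
#   ninf = 1/(1+alp);  ntau = max(bet/(qt_k * a0 * (1+alp)), nmin)
name: hippocampal_na3_kdr
model: na3_kdr
E_Na: 55.0
E_K: -90.0
celsius: 35.0
na:
  tha: -30.0
  qa: 7.2
  Ra: 0.4
  Rb: 0.124
  thi1: -45.0
  thi2: -45.0
  qd: 1.5
  qg: 1.5
  Rd: 0.03
  Rg: 0.01
  thinf: -59.0
  qinf: 4.0
  mmin: 0.02
  hmin: 0.5
  q10: 2.0
kdr:
  vhalf: 13.0
  zeta: -3.0
  gm: 0.7
  a0: 0.02
  nmin: 2.0
  q10: 1.0
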