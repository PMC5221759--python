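# spikelet-lab

Compartmental modelling and analysis of **somatic spikelets** — small
(< 20 mV) all-or-none spike-like depolarizations recorded at the soma of
pyramidal neurons.  The package implements a single-cell mechanism for
them: action potentials initiated at the distal axon initial segment (AIS)
that propagate down the axon but *fail to activate the soma*.  It is aimed
at computational neuroscientists who want to reproduce, probe or extend
this mechanism without a full simulator stack.

What's inside:

* **Analytic passive cable** (`spikelet_lab.passive`) — the lumped-soma
  model: a semi-infinite axon with an RC boundary.  With τ = R_mC_m,
  λ = √(R_m d_a / 4R_a) and ρ = (R_m/A_sd)/R∞, the antidromic attenuation
  of a sinusoid injected at distance *y* is
  |cosh(b₀y/λ) + (b₀/ρ)·sinh(b₀y/λ)| with b₀ = √(1+iωτ), while the
  orthodromic attenuation is only exp(Re b₀·x/λ) — a strong asymmetry
  caused by the somato-dendritic current sink.
* **Compartmental engine** (`spikelet_lab.engine`) — branched cables,
  Hodgkin–Huxley-style channels from swappable YAML rate files, implicit
  trapezoid integration on the tree (numba inner loop), voltage clamp,
  gap junctions, input resistance/capacitance measurements.
* **Model cells** (`spikelet_lab.cells`) — the reduced active cell
  (dendrite–soma–proximal AIS–distal AIS–axon, with hyperpolarized-shift
  sodium channels in the distal AIS and axon), a passive validation cell,
  axon-on-dendrite variants, frozen-inactivation manipulation, coupled
  pairs.
* **Stimuli** (`spikelet_lab.stimuli`) — the Ornstein–Uhlenbeck
  point-conductance background, pulse trains, EPSGs, waveform playback.
* **Event analysis** (`spikelet_lab.events`) — threshold and dV/dt event
  detection, spikelet / shoulder-AP / full-blown-AP classification,
  orthodromic vs antidromic direction, kink-based features, triggered
  averages, effective synaptic reversal.
* **Experiments & fixtures** (`spikelet_lab.experiments`,
  `spikelet_lab.fixtures`) — scripted desk-scale stages for every
  capability, and ground-truth synthetic traces for testing the analysis.

## Worked example

```bash
python examples/reduced_cell_step_regimes.py
```

```
 step (nA)      class  amplitude (mV)
      0.02       none               -
      0.05       none               -
      0.10   spikelet            10.8
      0.20   spikelet             7.8
      0.30      sh_AP            50.5
      1.50      sh_AP            56.3
```

Weak 50-ms somatic steps make the distal AIS fire while the soma shows only
a ~10 mV spikelet; stronger steps recruit the soma and the kink-to-peak
amplitude jumps to ~50 mV (shoulder-APs) — two well-separated amplitude
clusters, the signature of the mechanism.  The other examples print the
attenuation asymmetry (`passive_attenuation.py`), a full stochastic session
with orthodromic/antidromic statistics (`background_session.py`), detector
validation on ground-truth fixtures (`detect_synthetic_fixture.py`) and the
gap-junction alternative (`gap_junction_pair.py`).

A thin CLI mirrors the main stages:

```bash
spikelet-lab passive-attenuation --freq 300 --distance-um 50
spikelet-lab run-experiment background-session --seed 1 --duration-s 20
```

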