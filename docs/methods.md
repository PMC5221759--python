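# Methods

`spikelet-lab` implements a single-cell account of somatic spikelets in
pyramidal neurons: action potentials (APs) initiated at the distal axon
initial segment (AIS) that propagate down the axon but fail to activate the
soma, appearing there as small (< 20 mV) all-or-none depolarizations.  The
package contains three model layers (analytic passive cable, reduced active
compartmental cell, stimulation protocols), an analysis layer (event
detection, classification, feature measurement, triggered averaging), and a
synthetic-fixture layer that makes the analysis testable against exact
ground truth.

## Passive lumped-soma cable (module `passive`)

The analytic model is the classic lumped-soma configuration: a semi-infinite
passive cable (the axon, diameter `d_a`) attached at `x = 0` to a single RC
compartment representing the entire somato-dendritic membrane (area
`A_sd`).  With specific membrane resistance `R_m` (Ω·cm²), capacitance
`C_m` (µF/cm²) and axial resistivity `R_a` (Ω·cm), the derived constants are

    tau   = R_m C_m                      (membrane time constant, ms)
    lambda= sqrt(R_m d_a / (4 R_a))      (axonal length constant, cm)
    R_inf = (2/pi) d_a^(-3/2) sqrt(R_m R_a)
    rho   = (R_m / A_sd) / R_inf         (soma-to-axon resistance ratio)

At the defaults (`R_m = 1e4`, `C_m = 1`, `R_a = 150`, `d_a = 1 µm`,
`A_sd = 2e-4 cm²`) these give τ = 10 ms, λ = 0.041 cm, ρ = 0.064.  For a
sinusoidal current of radial frequency ω injected at axonal distance `y`,
with `b₀` the principal square root of `1 + iωτ`, the voltage-attenuation
ratios are

    A_axon→soma(y, ω) = |cosh(b₀ y/λ) + (β²/(b₀ ρ)) sinh(b₀ y/λ)|
    A_soma→axon(x, ω) = exp(Re(b₀) x/λ)

where `β² = 1 + iω τ_soma` is the boundary factor of the lumped soma.  By
default the soma shares the cable's membrane constants (β = b₀, recovering
the textbook `cosh + (b₀/ρ) sinh` form); the boundary capacitance and
resistance can also be set independently (`C_m_soma`, `R_m_soma`), which is
what isolates the somatic *capacitance* as the dominant high-frequency
current sink: above ~100 Hz, changing `R_m` over two decades moves the
antidromic log-attenuation by < 5%, while a decade of somatic `C_m` moves
it by ~50–60%.

The closed forms printed in the source text for ρ, R∞ and the full voltage
profile are typographically corrupted; the expressions above were re-derived
from the cable equation with the RC boundary and verified against (i) the
printed anchor values (λ = 0.041 cm, ρ = 0.064, electrotonic axon length
4.9 λ), (ii) the identity ρ = (R_m/A_sd)/R∞, and (iii) an independent
finite-difference phasor solver used as the test oracle.

## Compartmental engine (modules `engine`, `_kernels`, `channels`)

Branched cells are lists of cylindrical (optionally tapering) sections with
per-section passive constants and channel mechanisms.  Discretization uses
cylindrical lateral areas (π d L, no end caps) and half-segment axial
resistances; section attachments and gap-junction links form an undirected
graph that must be a tree (cycles are structural errors; two coupled cells
plus one junction are re-rooted into a single tree).  Default segmentation
keeps segments ≤ 10 µm in AIS/axon sections and ≤ 30 µm elsewhere.

Integration is the implicit trapezoid (Crank–Nicolson) scheme on the tree,
solved each step by ordered (Hines) elimination, with staggered exponential
gating updates — unconditionally stable on the passive subsystem and
second-order accurate (the RC-charging test measures an error ratio of 4.0
under dt halving; default dt = 0.025 ms).  Ideal voltage clamps are
implemented by row replacement, and the electrode current is reconstructed
from the discrete balance, which is what the input-capacitance measurement
(integrated clamp-transient charge / step size) uses.  The inner loop is a
numba kernel in the unit system mV/ms/nA/µS/nF.

Channel kinetics are loaded from YAML parameter files, not hard-coded.  The
shipped default is the hippocampal CA1 `na3/kdr` formulation (transient Na
with trap-function rates, m³h; delayed rectifier with a single Boltzmann
gate).  One constant was calibrated against the model's stated operating
premises: with the literal Na half-inactivation of −50 mV, the −10 mV
hyperpolarizing shift of the axonal Na channels leaves a window current
near −70 mV that exceeds the leak, and the cell paces spontaneously —
contradicting the premise that the resting potential equals the leak
reversal (−70 mV) and that events are input-driven.  The half-inactivation
is therefore set to −59 mV, inside the experimentally measured CA1 range
(about −58 to −62 mV), which yields a silent, stable rest and preserves AIS
initiation.  Alternate rate sets (e.g. the shipped Traub–Miles table) can
be swapped in through the same file format.

## Reduced cell and variants (module `cells`)

The reduced cell is: dendrite 900×6 µm — soma (40×20 µm cylinder; dendrite
at its 0 end, axon at its 1 end) — proximal AIS 30 µm — distal AIS 30 µm —
axon 1000 µm, all 1 µm diameter; uniform passive constants (C_m = 1,
R_m = 1e4, R_a = 150, E_leak = −70 mV); Na densities 0.02 S/cm²
(soma/dendrite), 0.04 (proximal AIS, axon), 0.1 (distal AIS); K densities
0.05 / 0.25 / 0.125 S/cm²; and a −10 mV shift of the Na activation *and*
inactivation curves in the distal AIS and axon.  Variants: proximal AIS
lengthened (e.g. 100 µm), the axon subtree re-rooted onto the dendrite at a
given distance, Na fast inactivation frozen (τ_h pinned to 1e5 ms at the
−70 mV steady state), and two-cell pairs coupled by an ohmic gap junction
(leak reversal and initial voltage −80 mV by convention for that
experiment).  An SWC reader is provided as the hook for reconstructed
morphologies; the reconstructed layer-V model itself is out of scope, and
all figure-style stages run on the reduced cell as a labelled surrogate.

## Stimuli (module `stimuli`)

The in-vivo-like background is the point-conductance model: excitatory and
inhibitory conductances following Ornstein–Uhlenbeck processes attached at
the soma (E_e = 0, E_i = −75 mV; means 0.01 / 0.0573 µS; SDs 0.014 /
0.02 µS; correlation times 2.728 / 10.49 ms), sampled with the exact
discretization at the solver dt.  The stimulus class keeps the source
model's unrectified convention; the *session stage* rectifies the
conductances at zero because the reduced surrogate's somatic conductance is
small enough that rare negative-total-conductance excursions destabilize
the voltage (the reference detailed cell, with its much larger somatic
load, does not have this problem).  Other protocols: rectangular steps and
sinusoids, pulse trains (0.5 nA / 2 ms / 500 ms axonal; 2 nA / 1 ms / 20 ms
dendritic; 2 nA / 15 ms presynaptic drive; 1 nA / 10 ms probe; 50-ms
steps), peak-normalized double-exponential EPSGs (0.5 / 2 ms, 0.02 µS), and
ideal voltage-clamp playback of recorded waveforms.

## Event analysis (module `events`)

Somatic events are anchored at upward crossings of −10 mV at the distal
AIS, with sub-sample linear interpolation of crossing times.  A somatic
−10 mV crossing within (−1, +5) ms of the AIS crossing makes the event an
AP (full-blown if the somatic crossing precedes or co-occurs within one
sample, shoulder-AP otherwise); otherwise it is a spikelet.  Each somatic
crossing can be claimed by one event only, and crossings within 3 ms of the
previous event's AIS peak are merged (refractory guard).  The independent
cross-check is the somatic-derivative double threshold: events crossing
20 V/s but not 100 V/s within 2 ms are spikelets, events crossing both are
APs.  Features follow the kink convention: threshold = voltage at the
maximum of the second derivative in the rising phase (Savitzky–Golay
smoothed, 5-point default), amplitude = kink to peak, plus maximum rising
slope and the least-squares slope over the 5 ms preceding the event's
alignment crossing.  Direction is orthodromic/antidromic by the relative
timing of the distal-AIS and distal-axon crossings (ties within one sample
are left unclassified).  Stimulus attribution follows the printed rules —
evoked within 2 ms of an onset, background from 10 ms after the last onset
— and the 2–10 ms gap, for which no rule is printed, is labelled ambiguous
and excluded from triggered averages.

A surrogate-specific caveat, measured in the background sessions: the
20 V/s first derivative threshold sits at this model's somatic
synaptic-noise slope floor (noise transients reach 20–30 V/s while
surrogate spikelets rise at 10–25 V/s), so below ~30 V/s the derivative
detector does not separate spikelets from synaptic transients here.  Every
derivative event above that floor, and every voltage-criterion event,
coincides with a distal-AIS AP — the zero-exception form of the central
claim.  On synthetic fixtures (whose templates have spikelet slopes of
~40–60 V/s, as in the detailed reference model) the two detectors agree on
≥ 95% of events and recover the schedule with precision = recall = 1 at
noise SD ≤ 1 mV.

## Synthetic fixtures (module `fixtures`)

Fixture waveforms are sigmoid-gated templates
`S((t−t_r)/τ_r)·(1 − S((t−t_r−sep)/τ_f))`, scaled to a requested amplitude;
peak, kink, maximum slope and crossing times all follow from the analytic
derivatives, so the ground-truth event table carries exact features.  A
fixture schedules non-overlapping spikelets and APs on top of OU background
noise in three channels (soma, distal AIS, distal axon), with direction
encoded in the AIS/axon lag.  A separate synthetic AIS-AP template
(amplitude 86 mV, half-width ≈ 0.8 ms, maximum slope ≈ 300 V/s, matching
the printed AP features of the reference detailed model) stands in for the
unavailable recorded waveform in the passive AP-attenuation stage and is
labelled synthetic.  Fixtures emulate waveform shape and stationary noise,
not recording artifacts (drift, line noise) — passing them shows the
analysis is correct, not that the detector thresholds are optimal for any
particular real recording.

## Experiment stages (module `experiments`) and problem sizes

* **Passive validation** — sinusoidal attenuation of the discretized
  soma + 2-mm-axon cell (lock-in projection over integer periods) against
  the closed form: |Δ ln A| < 0.001 at 10/300/1000 Hz; the synthetic AP
  playback attenuates within ~10% (ln units) of the 300-Hz value.
* **Somatic-step sweeps** — 50-ms steps, grid 0.025–1.5 nA in 0.025-nA
  steps; a trial with no −20 mV distal-AIS crossing is `none`, otherwise it
  is classed by its somatic events and measured kink-to-peak.  At defaults
  the regimes are ordered none → spikelet → shoulder-AP with a cluster gap
  of ~37 mV.  Suppression variants: somato-dendritic Na density (spikelet
  region shrinks monotonically, marginal by 0.05 S/cm² and ≤ 1 grid cell at
  0.08 — the exact printed cutoff depends on the original kinetics),
  soma–AIS distance → 0 (vanishes), low somatic C_m (shrinks).
* **Frozen inactivation** — with τ_h pinned, the AIS AP does not
  repolarize, the soma stays above threshold, and the spikelet class is
  empty over the whole stimulus grid.
* **Background sessions** — OU background (rectified, see above), optional
  extra protocol, default 60 s of simulated time at dt = 0.025 ms (a
  desk-scale choice; longer 100–200 s sessions only sharpen the statistics; statistics use
  hundreds to thousands of events).  The pipeline detects, classifies
  direction and provenance, measures features, cross-checks detectors and
  computes class-wise triggered averages of voltage, conductances and the
  effective synaptic reversal (g_e E_e + g_i E_i)/(g_e + g_i).  With distal
  axonal pulses, antidromic statistics are scoped to pulse-associated
  events (antidromic spikelets are, by definition, the ones evoked by the distal axonal stimulus); the
  surrogate otherwise contributes a few background-driven events that
  initiate in the distal axon.  Typical orderings: threshold AP (−23 mV) >
  orthodromic spikelet (−58 mV) > antidromic spikelet (−65 mV); pre-event
  slope 6.2 > 2.4 > ~0.5 mV/ms; antidromic pre-event excitatory-conductance
  modulation ~2% of the orthodromic one.
* **Gap-junction sweep** — junction resistance 22–82 MΩ in 5-MΩ steps
  (12–45 nS) at the soma or dendritic sites; postsynaptic amplitude
  (kink-to-peak per the printed convention, plus peak-minus-baseline, which
  stays monotone across the active-response boundary) and maximum slope per
  row, with postsynaptic-AP rows flagged.

All stages are deterministic given (configuration, seed); one run seed is
expanded into independent per-stimulus streams via `numpy` seed sequences.

## Known limitations

* The reduced cell is a surrogate for the reconstructed layer-V morphology;
  absolute rates, thresholds and slopes differ from the detailed reference
  model (e.g. spikelet rates are far higher here because the somatic
  threshold sits well above the AIS threshold at these densities).
* The exact gating equations of the cited hippocampal channel source are
  not printed; results tied to them (the precise Na-density cutoff for
  spikelet suppression) are reproduced at boundary level only.
* The analytic module covers a semi-infinite unbranched axon; finite-length
  or branched analytic solutions are out of scope (the numerical engine
  covers those cases).
* No temperature dependence, calcium dynamics or extracellular fields.
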