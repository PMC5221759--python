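"""Somatic response regimes of the reduced active cell.

Applies 50-ms somatic current steps of increasing amplitude and classifies
the somatic response: no AIS AP at all, a spikelet (the AIS fires but the
soma does not follow), or a shoulder-AP (the axonal AP triggers a somatic
AP).  The spikelet and AP amplitude clusters are separated by tens of mV.
"""

from spikelet_lab.cells import build_reduced_cell
from spikelet_lab.engine import discretize
from spikelet_lab.experiments import classify_step_trial

graph = discretize(build_reduced_cell())
print(f"{'step (nA)':>10} {'class':>10} {'amplitude (mV)':>15}")
for amp in (0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 1.0, 1.5):
    cls, amplitude = classify_step_trial(graph, amp)
    shown = f"{amplitude:.1f}" if amplitude == amplitude else "-"
    print(f"{amp:10.2f} {cls:>10} {shown:>15}")
print("\nWeak steps: the distal AIS fires but the soma shows only a ~10 mV")
print("spikelet; stronger steps recruit the soma and the kink-to-peak")
print("amplitude jumps to ~50 mV (shoulder-APs).")
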