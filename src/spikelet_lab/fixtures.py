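"""Ground-truth-labelled synthetic voltage traces for the analysis layer.

Event waveforms are differences of two sigmoids, so the peak, the kink
(maximum-curvature point), the maximum slope and threshold-crossing times
all follow from closed-form expressions of the template (evaluated on a
fine grid of the analytic function, independent of any simulation).  A
fixture is a set of soma/AIS/axon traces containing scheduled events of
known class and direction on top of Ornstein-Uhlenbeck background noise,
together with the exact event table the detector should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spikelet_lab.events import Event, EventTable
from spikelet_lab.stimuli import _ou_series
from spikelet_lab.traces import TraceSet

__all__ = ["EventTemplate", "FixtureSpec", "make_fixture", "match_events"]

_FINE = 2000  # samples per ms for closed-form truth evaluation


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class EventTemplate:
    """Sigmoid-gated spike template with closed-form derivatives.

    ``shape(t) = S((t - t_rise)/tau_rise) * (1 - S((t - t_rise - sep)/tau_fall))``
    scaled so the maximum equals ``amplitude`` (mV above baseline).  The
    rising sigmoid gates the waveform, so it is essentially zero before the
    event; all derivatives are products of sigmoid derivatives, giving
    analytic peak, kink (maximum curvature), maximum slope and crossing
    times.  ``t=0`` is the nominal event time.
    """

    amplitude: float
    tau_rise: float = 0.08  # ms
    tau_fall: float = 0.8  # ms
    sep: float = 1.2  # ms between rise and fall midpoints
    t_rise: float = 1.0  # ms after nominal event time
    support: float = 10.0  # ms

    def _raw(self, t: np.ndarray) -> np.ndarray:
        s1 = _sigmoid((t - self.t_rise) / self.tau_rise)
        s2 = _sigmoid((t - self.t_rise - self.sep) / self.tau_fall)
        return s1 * (1.0 - s2)

    def shape(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self._raw(t) / self._raw_peak() * self.amplitude

    def _fine_axis(self) -> np.ndarray:
        return np.arange(0.0, self.support, 1.0 / _FINE)

    def _raw_peak(self) -> float:
        return float(np.max(self._raw(self._fine_axis())))

    # ---- closed-form truth (analytic derivatives of the sigmoids) ----

    def _derivs(self):
        t = self._fine_axis()
        s1 = _sigmoid((t - self.t_rise) / self.tau_rise)
        s2 = _sigmoid((t - self.t_rise - self.sep) / self.tau_fall)
        scale = self.amplitude / self._raw_peak()
        d1s1 = s1 * (1 - s1) / self.tau_rise
        d1s2 = s2 * (1 - s2) / self.tau_fall
        d2s1 = d1s1 * (1 - 2 * s1) / self.tau_rise
        d2s2 = d1s2 * (1 - 2 * s2) / self.tau_fall
        v = scale * s1 * (1 - s2)
        d1 = scale * (d1s1 * (1 - s2) - s1 * d1s2)
        d2 = scale * (d2s1 * (1 - s2) - 2 * d1s1 * d1s2 - s1 * d2s2)
        return t, v, d1, d2

    def peak(self) -> tuple[float, float]:
        """(time, value) of the waveform maximum, relative to event time."""
        t, v, _, _ = self._derivs()
        i = int(np.argmax(v))
        return float(t[i]), float(v[i])

    def kink(self) -> tuple[float, float]:
        """(time, value) of maximum curvature during the rising phase."""
        t, v, _, d2 = self._derivs()
        ipeak = int(np.argmax(v))
        i = int(np.argmax(d2[: ipeak + 1]))
        return float(t[i]), float(v[i])

    def max_slope(self) -> float:
        t, v, d1, _ = self._derivs()
        ipeak = int(np.argmax(v))
        return float(np.max(d1[: ipeak + 1]))

    def crossing_time(self, level: float) -> float:
        """First time the rising waveform crosses ``level`` (mV above baseline)."""
        t, v, _, _ = self._derivs()
        ipeak = int(np.argmax(v))
        rising = v[: ipeak + 1]
        above = np.nonzero(rising >= level)[0]
        if above.size == 0:
            raise ValueError("template never reaches the requested level")
        i = int(above[0])
        if i == 0:
            return float(t[0])
        f = (level - rising[i - 1]) / (rising[i] - rising[i - 1])
        return float(t[i - 1] + f * (t[i] - t[i - 1]))


def synthetic_ais_ap_template() -> EventTemplate:
    """Synthetic stand-in for an AIS action-potential waveform.

    Built from the difference-of-sigmoids template with amplitude 86 mV,
    half-width ~0.8 ms and maximum rising slope ~340 V/s, matching the
    printed AP features of the reference biophysically detailed model.  Used
    by the passive-validation stage to measure AP-waveform attenuation when
    no recorded detailed-model waveform is available.
    """
    return EventTemplate(
        amplitude=86.0, tau_rise=0.083, tau_fall=0.35, sep=0.55,
        t_rise=3.0, support=15.0,
    )


def default_ap_template() -> EventTemplate:
    return EventTemplate(amplitude=85.0, tau_rise=0.08, tau_fall=0.8, sep=1.2)


def default_spikelet_template() -> EventTemplate:
    return EventTemplate(amplitude=13.0, tau_rise=0.08, tau_fall=1.2, sep=1.0)


@dataclass
class FixtureSpec:
    """Schedule and statistics of a synthetic fixture.

    ``schedule`` is a list of ``(time_ms, cls)`` with cls in
    {"spikelet", "sh_AP"}; ``directions`` optionally gives per-event
    "orthodromic"/"antidromic" (default all orthodromic).  Lags encode the
    somatic delay of AP events and the AIS-vs-axon timing that defines the
    direction.
    """

    T: float = 1000.0
    dt: float = 0.025
    baseline: float = -70.0
    noise_sd: float = 0.5  # mV
    noise_tau: float = 5.0  # ms
    schedule: list[tuple[float, str]] = field(default_factory=list)
    directions: list[str] | None = None
    soma_lag: float = 0.3  # ms, AIS -> soma delay for AP events
    dir_lag: float = 0.3  # ms, |AIS - axon| crossing separation
    ap_template: EventTemplate = field(default_factory=default_ap_template)
    spikelet_template: EventTemplate = field(default_factory=default_spikelet_template)
    min_separation: float = 15.0  # ms between scheduled events

    def __post_init__(self) -> None:
        times = sorted(t for t, _ in self.schedule)
        if any(b - a < self.min_separation for a, b in zip(times, times[1:])):
            raise ValueError("scheduled events overlap within the merge window")
        if self.directions is not None and len(self.directions) != len(self.schedule):
            raise ValueError("directions must match the schedule length")


def make_fixture(
    spec: FixtureSpec, seed: int = 0, thr: float = -10.0
) -> tuple[TraceSet, EventTable]:
    """Build soma/AIS/axon traces plus the exact ground-truth event table."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.T / spec.dt)) + 1
    t = np.arange(n) * spec.dt

    def noise():
        return _ou_series(0.0, spec.noise_sd, spec.noise_tau, spec.dt, n, rng)

    v_soma = spec.baseline + noise()
    v_ais = spec.baseline + noise()
    v_axon = spec.baseline + noise()

    directions = spec.directions or ["orthodromic"] * len(spec.schedule)
    truth = []
    ap, sp = spec.ap_template, spec.spikelet_template
    level = thr - spec.baseline
    ais_cross_off = ap.crossing_time(level)
    for (t_ev, cls), direction in zip(spec.schedule, directions):
        if cls not in ("spikelet", "sh_AP"):
            raise ValueError(f"unknown scheduled class {cls!r}")
        axon_lag = -spec.dir_lag if direction == "antidromic" else spec.dir_lag
        v_ais += ap.shape(t - t_ev)
        v_axon += ap.shape(t - t_ev - axon_lag)
        tmpl = ap if cls == "sh_AP" else sp
        soma_lag = spec.soma_lag if cls == "sh_AP" else 0.0
        v_soma += tmpl.shape(t - t_ev - soma_lag)
        kt, kv = tmpl.kink()
        pt, pv = tmpl.peak()
        ev = Event(
            t_ais_cross=t_ev + ais_cross_off,
            t_soma_cross=(
                t_ev + soma_lag + ap.crossing_time(level) if cls == "sh_AP" else None
            ),
            cls=cls,
            direction=direction,
            threshold_kink=spec.baseline + kv,
            amplitude=pv - kv,
            max_dvdt=tmpl.max_slope(),
            pre_slope=0.0,
        )
        truth.append(ev)

    traces = TraceSet(dt=spec.dt, meta={"seed": seed, "fixture": True})
    traces.add("V:soma:0.5", v_soma, site="soma:0.5")
    traces.add("V:distal_ais:0.5", v_ais, site="distal_ais:0.5")
    traces.add("V:axon:0.9", v_axon, site="axon:0.9")
    truth.sort(key=lambda e: e.t_ais_cross)
    return traces, EventTable(truth, meta={"ground_truth": True, "dt": spec.dt})


def match_events(
    truth: EventTable, detected: EventTable, tol_ms: float = 1.0
) -> tuple[int, int, int]:
    """Greedy time matching; returns (n_matched, n_missed, n_false)."""
    t_true = list(truth.times("ais_cross"))
    t_det = list(detected.times("ais_cross"))
    matched = 0
    for tt in t_true:
        best = None
        for i, td in enumerate(t_det):
            if abs(td - tt) <= tol_ms and (
                best is None or abs(td - tt) < abs(t_det[best] - tt)
            ):
                best = i
        if best is not None:
            matched += 1
            t_det.pop(best)
    return matched, len(t_true) - matched, len(t_det)
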