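"""Detection, classification and measurement of somatic events.

Somatic events are anchored at upward crossings of a voltage threshold
(default -10 mV) at the distal AIS.  If the soma crosses the same threshold
within a window from 1 ms before to 5 ms after the AIS crossing the event is
an AP, otherwise a spikelet.  APs whose somatic crossing precedes or
co-occurs with the AIS crossing are full-blown APs (fb_AP); the rest are
shoulder-APs (sh_AP).  A second, derivative-based detector (thresholds 20
and 100 V/s on dV/dt at the soma) serves as an independent cross-check.

Event features follow the kink convention: the event threshold is the
voltage at the maximum of the second derivative (maximum curvature) in the
rising phase, the amplitude is measured from that kink voltage to the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from spikelet_lab.traces import TraceSet

__all__ = [
    "Event",
    "EventTable",
    "MalformedEventError",
    "detect_events",
    "detect_events_dvdt",
    "classify_direction",
    "attribute_to_stimulus",
    "event_features",
    "triggered_average",
    "effective_reversal",
    "amplitude_vs_maxslope",
]


class MalformedEventError(ValueError):
    """Raised when an event has no usable local peak after threshold."""


@dataclass
class Event:
    t_ais_cross: float  # ms
    t_soma_cross: float | None = None
    cls: str = "spikelet"  # spikelet | sh_AP | fb_AP
    direction: str = "unclassified"  # orthodromic | antidromic | unclassified
    threshold_kink: float | None = None  # mV
    amplitude: float | None = None  # mV
    max_dvdt: float | None = None  # mV/ms
    pre_slope: float | None = None  # mV/ms
    provenance: str = "background"  # background | stimulus | ambiguous

    @property
    def t_ref(self) -> float:
        """Alignment reference: somatic crossing for APs, AIS for spikelets."""
        if self.cls in ("sh_AP", "fb_AP") and self.t_soma_cross is not None:
            return self.t_soma_cross
        return self.t_ais_cross


@dataclass
class EventTable:
    events: list[Event] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def of_class(self, *classes: str) -> "EventTable":
        return EventTable(
            [e for e in self.events if e.cls in classes], dict(self.meta)
        )

    def of_direction(self, direction: str) -> "EventTable":
        return EventTable(
            [e for e in self.events if e.direction == direction], dict(self.meta)
        )

    def times(self, align: str = "ais_cross") -> np.ndarray:
        if align == "ais_cross":
            return np.array([e.t_ais_cross for e in self.events])
        if align == "soma_cross":
            return np.array([e.t_ref for e in self.events])
        raise ValueError("align must be 'ais_cross' or 'soma_cross'")

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "t_ais_cross", "t_soma_cross", "cls", "direction",
            "threshold_kink", "amplitude", "max_dvdt", "pre_slope",
            "provenance",
        ]
        return pd.DataFrame(
            [{c: getattr(e, c) for c in cols} for e in self.events],
            columns=cols,
        )


def _upward_crossings(v: np.ndarray, thr: float, dt: float) -> np.ndarray:
    """Sub-sample (linearly interpolated) times of upward threshold crossings."""
    v = np.asarray(v, dtype=float)
    below = v[:-1] < thr
    above = v[1:] >= thr
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.zeros(0)
    frac = (thr - v[idx]) / (v[idx + 1] - v[idx])
    return (idx + frac) * dt


def _refractory_filter(
    times: np.ndarray,
    merge_ms: float,
    v: np.ndarray | None = None,
    dt: float | None = None,
    thr: float | None = None,
) -> np.ndarray:
    """Drop crossings within ``merge_ms`` of the previous event's peak.

    With a trace given, the guard runs from the peak of the previous event
    (maximum of ``v`` from its crossing until ``v`` falls back below
    ``thr``); without one, from the previous crossing itself.
    """
    kept: list[float] = []
    guard_end = -np.inf
    for t in times:
        if t < guard_end:
            continue
        kept.append(t)
        t_peak = t
        if v is not None:
            i = int(t / dt) + 1
            j = i
            while j < len(v) - 1 and v[j] >= thr:
                j += 1
            if j > i:
                t_peak = (i + int(np.argmax(v[i:j]))) * dt
        guard_end = t_peak + merge_ms
    return np.array(kept)


def detect_events(
    v_soma: np.ndarray,
    v_ais: np.ndarray,
    dt: float,
    thr: float = -10.0,
    window: tuple[float, float] = (-1.0, 5.0),
    merge_ms: float = 3.0,
) -> EventTable:
    """Voltage-criterion detector (threshold at AIS and soma).

    Every AIS upward crossing of ``thr`` yields one event (crossings closer
    than ``merge_ms`` to the previous event are merged as a refractory
    guard).  A somatic crossing within ``window`` ms of the AIS crossing
    makes the event an AP -- fb_AP if the somatic crossing precedes or
    co-occurs with (within one sample of) the AIS crossing, sh_AP otherwise
    -- and a spikelet if the soma never crosses inside the window.
    """
    v_soma = np.asarray(v_soma, dtype=float)
    v_ais = np.asarray(v_ais, dtype=float)
    if v_soma.shape != v_ais.shape:
        raise ValueError("soma and AIS traces must share one time base")
    t_ais = _refractory_filter(
        _upward_crossings(v_ais, thr, dt), merge_ms, v_ais, dt, thr
    )
    t_soma = list(_upward_crossings(v_soma, thr, dt))
    events = []
    for ta in t_ais:
        in_win = [
            ts for ts in t_soma if ta + window[0] <= ts <= ta + window[1]
        ]
        if in_win:
            ts = float(in_win[0])
            t_soma.remove(ts)  # a somatic crossing belongs to one event only
            cls = "fb_AP" if ts <= ta + dt else "sh_AP"
            events.append(Event(t_ais_cross=float(ta), t_soma_cross=ts, cls=cls))
        else:
            events.append(Event(t_ais_cross=float(ta), cls="spikelet"))
    return EventTable(
        events,
        meta={"thr": thr, "window": window, "merge_ms": merge_ms, "dt": dt,
              "criterion": "voltage"},
    )


def smoothed_derivative(v: np.ndarray, dt: float, window: int = 5) -> np.ndarray:
    """Savitzky-Golay first derivative (mV/ms)."""
    if len(v) < window:
        return np.gradient(np.asarray(v, dtype=float), dt)
    return savgol_filter(v, window, polyorder=2, deriv=1, delta=dt)


def detect_events_dvdt(
    v_soma: np.ndarray,
    dt: float,
    thr1: float = 20.0,
    thr2: float = 100.0,
    window: float = 2.0,
    merge_ms: float = 3.0,
    sg_window: int = 5,
) -> EventTable:
    """Double-threshold detector on the somatic voltage derivative.

    Events cross ``thr1`` (V/s = mV/ms); those that also cross ``thr2``
    within ``window`` ms are APs, the rest spikelets.  Used as an
    independent cross-check of :func:`detect_events`.
    """
    dv = smoothed_derivative(np.asarray(v_soma, dtype=float), dt, sg_window)
    t_cross = _refractory_filter(
        _upward_crossings(dv, thr1, dt), merge_ms, dv, dt, thr1
    )
    events = []
    nwin = int(round(window / dt))
    for tc in t_cross:
        i = int(tc / dt)
        peak_dv = float(np.max(dv[i : i + nwin + 1]))
        cls = "AP" if peak_dv >= thr2 else "spikelet"  # no sh/fb split here
        events.append(Event(t_ais_cross=float(tc), cls=cls, max_dvdt=peak_dv))
    return EventTable(
        events,
        meta={"thr1": thr1, "thr2": thr2, "window": window, "dt": dt,
              "criterion": "dvdt"},
    )


def classify_direction(
    event: Event,
    v_ais: np.ndarray,
    v_axon: np.ndarray,
    dt: float,
    thr: float = -10.0,
    search_ms: float = 5.0,
) -> str:
    """Orthodromic vs antidromic from AIS-vs-distal-axon crossing order.

    The AIS crossing leading the axonal crossing marks an orthodromic event;
    trailing it, antidromic.  Crossings within one sample of each other, or
    a missing axonal AP, give ``unclassified``.
    """
    t_axon = _upward_crossings(np.asarray(v_axon, dtype=float), thr, dt)
    near = t_axon[np.abs(t_axon - event.t_ais_cross) <= search_ms]
    if near.size == 0:
        direction = "unclassified"
    else:
        delta = float(near[np.argmin(np.abs(near - event.t_ais_cross))]) - event.t_ais_cross
        if abs(delta) <= dt:
            direction = "unclassified"
        elif delta > 0:
            direction = "orthodromic"
        else:
            direction = "antidromic"
    event.direction = direction
    return direction


def attribute_to_stimulus(
    events: EventTable,
    stimulus_times: np.ndarray,
    evoked_window: float = 2.0,
    background_min: float = 10.0,
) -> list[str]:
    """Label events as stimulus-evoked, background, or ambiguous.

    Within ``evoked_window`` ms after a stimulus onset -> ``stimulus``;
    ``background_min`` ms or later after the last onset (or before the first
    onset) -> ``background``; the gap in between has no rule and is labelled
    ``ambiguous`` (such events are excluded from triggered averages).
    """
    onsets = np.sort(np.asarray(stimulus_times, dtype=float))
    labels = []
    for e in events:
        t = e.t_ref
        prev = onsets[onsets <= t]
        if prev.size == 0:
            label = "background"
        else:
            delta = t - prev[-1]
            if delta < evoked_window:
                label = "stimulus"
            elif delta >= background_min:
                label = "background"
            else:
                label = "ambiguous"
        e.provenance = label
        labels.append(label)
    return labels


def event_features(
    v_soma: np.ndarray,
    dt: float,
    event: Event,
    search: tuple[float, float] = (-2.0, 6.0),
    slope_window: float = 5.0,
    sg_window: int = 5,
) -> Event:
    """Measure kink threshold, amplitude, max slope and pre-event slope.

    The threshold is the voltage at the maximum of the second derivative
    (maximum curvature) during the rising phase; the amplitude runs from
    there to the peak; ``pre_slope`` is the least-squares slope of the
    somatic voltage over ``slope_window`` ms before the event's alignment
    crossing.  Derivatives use a Savitzky-Golay smoothed estimate.  A trace
    without a local somatic peak after threshold (e.g. a pure ramp) raises
    :class:`MalformedEventError`.
    """
    v_soma = np.asarray(v_soma, dtype=float)
    t_ref = event.t_ref
    i0 = max(int(round((t_ref + search[0]) / dt)), 0)
    i1 = min(int(round((t_ref + search[1]) / dt)), len(v_soma) - 1)
    if i1 - i0 < sg_window + 2:
        raise MalformedEventError("event window lies outside the trace")
    seg = v_soma[i0 : i1 + 1]
    ipeak = int(np.argmax(seg))
    if ipeak >= len(seg) - 1 or ipeak == 0:
        raise MalformedEventError("no local somatic peak after threshold")
    dv = smoothed_derivative(seg, dt, sg_window)
    d2v = smoothed_derivative(dv, dt, sg_window)
    rising = slice(0, ipeak + 1)
    ikink = int(np.argmax(d2v[rising]))
    event.threshold_kink = float(seg[ikink])
    event.amplitude = float(seg[ipeak] - seg[ikink])
    event.max_dvdt = float(np.max(dv[rising]))
    # pre-event slope from the raw trace preceding the alignment crossing
    j1 = int(round(t_ref / dt))
    j0 = max(j1 - int(round(slope_window / dt)), 0)
    if j1 - j0 >= 2:
        tt = np.arange(j0, j1) * dt
        event.pre_slope = float(np.polyfit(tt, v_soma[j0:j1], 1)[0])
    return event


def triggered_average(
    traces: TraceSet,
    events: EventTable | np.ndarray,
    align: str = "ais_cross",
    span: tuple[float, float] = (-10.0, 10.0),
    channels: list[str] | None = None,
):
    """Event-triggered mean and SD of every channel.

    Windows extending beyond the trace are dropped and counted in the
    result's ``n_dropped``.  Returns a dict mapping channel name to
    ``(mean, sd)`` arrays plus keys ``t`` (window time axis), ``n_events``
    and ``n_dropped``.
    """
    if isinstance(events, EventTable):
        times = events.times(align)
    else:
        times = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("no events to average")
    dt = traces.dt
    k0 = int(round(span[0] / dt))
    k1 = int(round(span[1] / dt))
    channels = channels or list(traces.channels)
    n = traces.n_samples
    idx = np.round(times / dt).astype(int)
    ok = (idx + k0 >= 0) & (idx + k1 < n)
    used = idx[ok]
    if used.size == 0:
        raise ValueError("no events with complete windows")
    offsets = np.arange(k0, k1 + 1)
    out: dict = {
        "t": offsets * dt,
        "n_events": int(used.size),
        "n_dropped": int(times.size - used.size),
    }
    gather = used[:, None] + offsets[None, :]
    for name in channels:
        segs = traces[name][gather]
        out[name] = (segs.mean(axis=0), segs.std(axis=0))
    return out


def effective_reversal(
    g_e: np.ndarray, g_i: np.ndarray, E_e: float = 0.0, E_i: float = -75.0
) -> np.ndarray:
    """Conductance-weighted effective synaptic reversal potential (mV).

    ``(g_e E_e + g_i E_i) / (g_e + g_i)`` per sample; samples with
    non-positive total conductance are NaN-flagged.
    """
    g_e = np.asarray(g_e, dtype=float)
    g_i = np.asarray(g_i, dtype=float)
    tot = g_e + g_i
    with np.errstate(divide="ignore", invalid="ignore"):
        rev = (g_e * E_e + g_i * E_i) / tot
    return np.where(tot > 0, rev, np.nan)


def amplitude_vs_maxslope(events: EventTable) -> pd.DataFrame:
    """Per-event (amplitude, max slope, class) records for cluster plots."""
    rows = [
        {"amplitude": e.amplitude, "max_dvdt": e.max_dvdt, "cls": e.cls}
        for e in events
        if e.amplitude is not None and e.max_dvdt is not None
    ]
    return pd.DataFrame(rows, columns=["amplitude", "max_dvdt", "cls"])
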