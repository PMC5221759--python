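"""Stimulation protocols.

All stimulus classes expose ``resolve(graph, dt, nsteps, rng)`` returning a
list of contributions consumed by :func:`spikelet_lab.engine.integrate`:

* ``("I", comp, I_array)`` -- injected current (nA), sampled at step times;
* ``("G", comp, E_rev, g_array, record_name)`` -- point conductance (uS);
* ``("VC", comp, V_array, name)`` -- ideal voltage clamp command (mV), with
  ``nan`` marking samples where the clamp is off.

The fluctuating background is the point-conductance model: one excitatory
and one inhibitory conductance following Ornstein-Uhlenbeck processes,
attached at the soma, with synaptic current
``I = g_e(t) (E_e - V) + g_i(t) (E_i - V)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OUConductanceParams",
    "PulseTrainParams",
    "EPSGParams",
    "OUConductance",
    "CurrentStep",
    "SineCurrent",
    "PulseTrain",
    "EPSGTrain",
    "VoltageClampStep",
    "VoltageClampPlayback",
    "ou_conductance_pair",
    "epsg_waveform",
    "protocol_presets",
    "ap_waveform_playback",
]


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class OUConductanceParams:
    """Point-conductance background parameters (units: mV, uS, ms).

    Defaults are the in-vivo-like values: mean and SD of the excitatory and
    inhibitory conductances with their correlation times and reversals.
    """

    E_e: float = 0.0
    E_i: float = -75.0
    g_e0: float = 0.01
    g_i0: float = 0.0573
    std_e: float = 0.014
    std_i: float = 0.02
    tau_e: float = 2.728
    tau_i: float = 10.49

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("OU time constants must be positive")
        if self.std_e < 0 or self.std_i < 0:
            raise ValueError("OU standard deviations must be non-negative")


@dataclass(frozen=True)
class PulseTrainParams:
    amplitude: float  # nA
    width: float  # ms
    period: float  # ms

    def __post_init__(self) -> None:
        if not self.width < self.period:
            raise ValueError("pulse width must be smaller than the period")


@dataclass(frozen=True)
class EPSGParams:
    """Double-exponential synaptic conductance parameters."""

    tau_rise: float = 0.5
    tau_decay: float = 2.0
    peak: float = 0.02  # uS
    E_syn: float = 0.0  # mV
    period: float = 500.0  # ms

    def __post_init__(self) -> None:
        if not self.tau_decay > self.tau_rise > 0:
            raise ValueError("need tau_decay > tau_rise > 0")


# ---------------------------------------------------------------------------
# waveform primitives


def ou_exact_update_coefficients(tau: float, sigma: float, dt: float):
    """(decay, noise) coefficients of the exact OU discretization."""
    decay = math.exp(-dt / tau)
    noise = sigma * math.sqrt(1.0 - decay * decay)
    return decay, noise


def _ou_series(g0, sigma, tau, dt, n, rng) -> np.ndarray:
    from scipy.signal import lfilter

    decay, noise = ou_exact_update_coefficients(tau, sigma, dt)
    eps = rng.standard_normal(n - 1)
    g = np.empty(n)
    g[0] = g0
    # dev[k+1] = decay * dev[k] + noise * eps[k], dev[0] = 0
    g[1:] = g0 + lfilter([noise], [1.0, -decay], eps)
    return g


def ou_conductance_pair(
    p: OUConductanceParams,
    dt: float,
    T: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the excitatory/inhibitory OU conductance pair.

    Uses the exact discretization
    ``g(t+dt) = g0 + (g(t) - g0) e^{-dt/tau} + sigma sqrt(1 - e^{-2dt/tau}) N(0,1)``;
    excursions are *not* rectified (negative values are permitted, as in the
    source point-conductance model).  Both series start at their means.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = int(round(T / dt)) + 1
    g_e = _ou_series(p.g_e0, p.std_e, p.tau_e, dt, n, rng)
    g_i = _ou_series(p.g_i0, p.std_i, p.tau_i, dt, n, rng)
    return g_e, g_i


def epsg_time_to_peak(p: EPSGParams) -> float:
    """Closed-form time to peak of the double exponential (ms)."""
    tr, td = p.tau_rise, p.tau_decay
    return tr * td / (td - tr) * math.log(td / tr)


def epsg_waveform(p: EPSGParams, t: np.ndarray | float, onset: float = 0.0):
    """Double-exponential conductance, peak-normalized to ``p.peak`` (uS).

    The normalization factor is analytic (evaluated at the closed-form time
    to peak), not a numeric search.  Zero before ``onset``.
    """
    t = np.asarray(t, dtype=float)
    s = t - onset
    tp = epsg_time_to_peak(p)
    fmax = math.exp(-tp / p.tau_decay) - math.exp(-tp / p.tau_rise)
    shape = np.where(
        s >= 0.0,
        np.exp(-np.maximum(s, 0.0) / p.tau_decay)
        - np.exp(-np.maximum(s, 0.0) / p.tau_rise),
        0.0,
    )
    return p.peak * shape / fmax


# ---------------------------------------------------------------------------
# stimulus protocol objects


@dataclass(frozen=True)
class OUConductance:
    """Fluctuating excitatory+inhibitory point conductances at one site."""

    site: str = "soma:0.5"
    params: OUConductanceParams = field(default_factory=OUConductanceParams)
    seed: int | None = None  # None: derive from the run seed
    record: bool = True
    clip_at_zero: bool = False  # rectification off by default (source model)

    def resolve(self, graph, dt, nsteps, rng):
        if self.seed is not None:
            rng = np.random.default_rng(self.seed)
        comp = graph.site_index(self.site)
        g_e, g_i = ou_conductance_pair(self.params, dt, nsteps * dt, rng)
        if self.clip_at_zero:
            g_e = np.maximum(g_e, 0.0)
            g_i = np.maximum(g_i, 0.0)
        return [
            ("G", comp, self.params.E_e, g_e, "g_e" if self.record else None),
            ("G", comp, self.params.E_i, g_i, "g_i" if self.record else None),
        ]


@dataclass(frozen=True)
class CurrentStep:
    """Rectangular current step at one site."""

    site: str
    amplitude: float  # nA
    t_on: float = 10.0
    t_off: float = 60.0

    def resolve(self, graph, dt, nsteps, rng):
        comp = graph.site_index(self.site)
        t = np.arange(nsteps + 1) * dt
        I = np.where((t >= self.t_on) & (t < self.t_off), self.amplitude, 0.0)
        return [("I", comp, I)]


@dataclass(frozen=True)
class SineCurrent:
    """Sinusoidal current injection (used for attenuation measurements)."""

    site: str
    amplitude: float  # nA
    freq_hz: float
    t_on: float = 0.0

    def resolve(self, graph, dt, nsteps, rng):
        comp = graph.site_index(self.site)
        t = np.arange(nsteps + 1) * dt
        omega = 2.0 * math.pi * self.freq_hz * 1e-3  # rad/ms
        I = np.where(t >= self.t_on, self.amplitude * np.sin(omega * (t - self.t_on)), 0.0)
        return [("I", comp, I)]


@dataclass(frozen=True)
class PulseTrain:
    """Periodic brief current pulses."""

    site: str
    params: PulseTrainParams = field(
        default_factory=lambda: PulseTrainParams(0.5, 2.0, 500.0)
    )
    t_start: float = 10.0

    def pulse_times(self, T: float) -> np.ndarray:
        return np.arange(self.t_start, T, self.params.period)

    def resolve(self, graph, dt, nsteps, rng):
        comp = graph.site_index(self.site)
        t = np.arange(nsteps + 1) * dt
        phase = np.mod(t - self.t_start, self.params.period)
        I = np.where(
            (t >= self.t_start) & (phase < self.params.width),
            self.params.amplitude,
            0.0,
        )
        return [("I", comp, I)]


@dataclass(frozen=True)
class EPSGTrain:
    """Periodic double-exponential synaptic conductance."""

    site: str
    params: EPSGParams = field(default_factory=EPSGParams)
    t_start: float = 10.0
    record: bool = False

    def onset_times(self, T: float) -> np.ndarray:
        return np.arange(self.t_start, T, self.params.period)

    def resolve(self, graph, dt, nsteps, rng):
        comp = graph.site_index(self.site)
        t = np.arange(nsteps + 1) * dt
        g = np.zeros(nsteps + 1)
        for onset in self.onset_times(nsteps * dt):
            g += epsg_waveform(self.params, t, onset=onset)
        return [
            ("G", comp, self.params.E_syn, g, "g_syn" if self.record else None)
        ]


@dataclass(frozen=True)
class VoltageClampStep:
    """Ideal voltage clamp holding ``v_hold``, stepping to ``v_step``."""

    site: str
    v_hold: float
    v_step: float
    t_on: float
    t_off: float

    def resolve(self, graph, dt, nsteps, rng):
        comp = graph.site_index(self.site)
        t = np.arange(nsteps + 1) * dt
        V = np.where((t >= self.t_on) & (t < self.t_off), self.v_step, self.v_hold)
        return [("VC", comp, V, self.site)]


@dataclass(frozen=True)
class VoltageClampPlayback:
    """Ideal voltage clamp forcing a recorded waveform at one site.

    The clamp is active for the whole run; before ``t_start`` and after the
    waveform ends the command is padded with the waveform's first and last
    samples.  If the waveform sampling interval differs from the solver dt
    the waveform is linearly resampled (with a warning).
    """

    site: str
    waveform: np.ndarray
    dt_wave: float
    t_start: float = 10.0

    def resolve(self, graph, dt, nsteps, rng):
        comp = graph.site_index(self.site)
        wave = np.asarray(self.waveform, dtype=float)
        if not math.isclose(self.dt_wave, dt, rel_tol=1e-9):
            warnings.warn(
                f"resampling clamp waveform from dt={self.dt_wave} to dt={dt}"
            )
            t_old = np.arange(len(wave)) * self.dt_wave
            t_new = np.arange(0.0, t_old[-1] + 0.5 * dt, dt)
            wave = np.interp(t_new, t_old, wave)
        V = np.full(nsteps + 1, wave[0])
        i0 = int(round(self.t_start / dt))
        nw = min(len(wave), nsteps + 1 - i0)
        V[i0 : i0 + nw] = wave[:nw]
        if i0 + nw <= nsteps:
            V[i0 + nw :] = wave[nw - 1]
        return [("VC", comp, V, self.site)]


def ap_waveform_playback(
    waveform: np.ndarray, dt_wave: float, site: str, t_start: float = 10.0
) -> VoltageClampPlayback:
    """Voltage-clamp playback of a recorded AP waveform at ``site``."""
    return VoltageClampPlayback(
        site=site, waveform=np.asarray(waveform, dtype=float),
        dt_wave=dt_wave, t_start=t_start,
    )


def protocol_presets(site: str = "SITE") -> dict:
    """The named stimulation presets used by the experiment stages.

    ``site`` is a placeholder; use :func:`dataclasses.replace` to retarget.

    * ``single_ap_probe`` -- 1 nA for 10 ms (single-AP probe)
    * ``somatic_step``       -- 50-ms rectangular somatic step
    * ``distal_axon_pulses``     -- 0.5 nA for 2 ms every 500 ms at the distal axon
    * ``dendritic_pulses``  -- 2 nA for 1 ms every 20 ms at a proximal dendrite
    * ``s3_presynaptic``  -- 2 nA for 15 ms (gap-junction presynaptic drive)
    """
    return {
        "single_ap_probe": CurrentStep(site=site, amplitude=1.0, t_on=10.0, t_off=20.0),
        "somatic_step": CurrentStep(site=site, amplitude=0.5, t_on=10.0, t_off=60.0),
        "distal_axon_pulses": PulseTrain(site=site, params=PulseTrainParams(0.5, 2.0, 500.0)),
        "dendritic_pulses": PulseTrain(site=site, params=PulseTrainParams(2.0, 1.0, 20.0)),
        "s3_presynaptic": CurrentStep(site=site, amplitude=2.0, t_on=10.0, t_off=25.0),
    }
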