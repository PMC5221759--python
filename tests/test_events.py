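"""Event detection, classification, features and triggered averaging."""

import numpy as np
import pytest

from spikelet_lab.events import (
    Event,
    EventTable,
    MalformedEventError,
    amplitude_vs_maxslope,
    attribute_to_stimulus,
    classify_direction,
    detect_events,
    detect_events_dvdt,
    effective_reversal,
    event_features,
    triggered_average,
)
from spikelet_lab.fixtures import EventTemplate, default_ap_template
from spikelet_lab.traces import TraceSet

DT = 0.025


def trace_with_events(times, template, T=300.0, baseline=-70.0):
    t = np.arange(0.0, T, DT)
    v = np.full_like(t, baseline)
    for t0 in times:
        v += template.shape(t - t0)
    return v


AP = default_ap_template()
SP = EventTemplate(amplitude=13.0, tau_rise=0.08, tau_fall=1.2, sep=1.0)


class TestVoltageCriterion:
    def test_window_rule(self):
        """3 AIS APs; somatic companions inside the window for 2 -> 2 APs +
        1 spikelet."""
        v_ais = trace_with_events([50.0, 120.0, 190.0], AP)
        v_soma = (
            trace_with_events([50.3, 122.0], AP)
            + trace_with_events([190.0], SP)
            + 70.0  # undo the doubled baseline from summing two traces
        )
        tab = detect_events(v_soma, v_ais, DT)
        assert [e.cls for e in tab] == ["sh_AP", "sh_AP", "spikelet"]

    def test_somatic_crossing_outside_window_is_spikelet(self):
        v_ais = trace_with_events([50.0], AP)
        v_soma = trace_with_events([57.0], AP)  # +6 ms soma crossing: too late
        tab = detect_events(v_soma, v_ais, DT)
        assert len(tab) == 1
        assert tab[0].cls == "spikelet"

    def test_somatic_lead_is_full_blown(self):
        v_ais = trace_with_events([51.0], AP)
        v_soma = trace_with_events([50.0], AP)
        tab = detect_events(v_soma, v_ais, DT)
        assert tab[0].cls == "fb_AP"

    def test_flat_traces_empty(self):
        v = np.full(4000, -70.0)
        assert len(detect_events(v, v, DT)) == 0

    def test_mismatched_time_bases_rejected(self):
        with pytest.raises(ValueError):
            detect_events(np.zeros(100), np.zeros(200), DT)

    def test_subsample_interpolation(self):
        v_ais = trace_with_events([50.0], AP)
        tab = detect_events(np.full_like(v_ais, -70.0), v_ais, DT)
        t_true = 50.0 + AP.crossing_time(60.0)  # -10 mV is 60 mV above rest
        assert tab[0].t_ais_cross == pytest.approx(t_true, abs=DT)


class TestDvdtCriterion:
    def test_intermediate_slope_is_spikelet(self):
        # SP template has max slope ~40 V/s: crosses 20, not 100
        assert 20.0 < SP.max_slope() < 100.0
        v = trace_with_events([50.0], SP)
        tab = detect_events_dvdt(v, DT)
        assert [e.cls for e in tab] == ["spikelet"]

    def test_slow_event_not_detected(self):
        slow = EventTemplate(amplitude=10.0, tau_rise=1.0, tau_fall=4.0, sep=4.0)
        assert slow.max_slope() < 20.0
        v = trace_with_events([50.0], slow)
        assert len(detect_events_dvdt(v, DT)) == 0

    def test_counts_match_voltage_criterion_on_fixture(self, quiet_fixture):
        traces, truth = quiet_fixture
        vs = traces["V:soma:0.5"]
        va = traces["V:distal_ais:0.5"]
        tab_v = detect_events(vs, va, traces.dt)
        tab_d = detect_events_dvdt(vs, traces.dt)
        assert len(tab_v) == len(tab_d) == len(truth)
        binary_v = ["spikelet" if e.cls == "spikelet" else "AP" for e in tab_v]
        binary_d = [e.cls for e in tab_d]
        agree = np.mean([a == b for a, b in zip(binary_v, binary_d)])
        assert agree >= 0.95


class TestDirection:
    def make(self, lag):
        v_ais = trace_with_events([50.0], AP)
        v_axon = trace_with_events([50.0 + lag], AP)
        ev = Event(t_ais_cross=50.0 + AP.crossing_time(60.0))
        return ev, v_ais, v_axon

    def test_ais_lead_is_orthodromic(self):
        ev, va, vx = self.make(+0.3)
        assert classify_direction(ev, va, vx, DT) == "orthodromic"

    def test_axon_lead_is_antidromic(self):
        ev, va, vx = self.make(-0.3)
        assert classify_direction(ev, va, vx, DT) == "antidromic"

    def test_simultaneous_is_unclassified(self):
        ev, va, vx = self.make(0.0)
        assert classify_direction(ev, va, vx, DT) == "unclassified"

    def test_missing_axonal_ap_is_unclassified(self):
        ev, va, _ = self.make(0.0)
        flat = np.full_like(va, -70.0)
        assert classify_direction(ev, va, flat, DT) == "unclassified"


class TestProvenance:
    def test_printed_rules_and_gap(self):
        events = EventTable(
            [Event(t_ais_cross=t) for t in (101.5, 112.0, 105.0, 95.0)]
        )
        labels = attribute_to_stimulus(events, [100.0])
        assert labels == ["stimulus", "background", "ambiguous", "background"]


class TestFeatures:
    def test_template_features_match_closed_form(self):
        """Measured kink-to-peak amplitude agrees with the template truth
        within 2% (sampled finely relative to the 0.08-ms rise)."""
        dt = 0.005
        t = np.arange(0.0, 120.0, dt)
        v = -70.0 + SP.shape(t - 50.0)
        ev = Event(t_ais_cross=50.0 + SP.crossing_time(5.0))
        event_features(v, dt, ev)
        _, kink_v = SP.kink()
        _, peak_v = SP.peak()
        assert ev.amplitude == pytest.approx(peak_v - kink_v, rel=0.02)
        assert ev.max_dvdt == pytest.approx(SP.max_slope(), rel=0.05)
        # flat baseline: only the event's own foot contributes a tiny slope
        assert ev.pre_slope == pytest.approx(0.0, abs=0.2)

    def test_linear_ramp_is_malformed(self):
        v = -70.0 + 0.5 * np.arange(0.0, 100.0, DT)
        with pytest.raises(MalformedEventError):
            event_features(v, DT, Event(t_ais_cross=50.0))

    def test_scaling_about_kink_doubles_amplitude(self):
        v = trace_with_events([50.0], SP)
        ev = Event(t_ais_cross=50.0 + SP.crossing_time(5.0))
        event_features(v, DT, ev)
        v2 = ev.threshold_kink + 2.0 * (v - ev.threshold_kink)
        ev2 = Event(t_ais_cross=ev.t_ais_cross)
        event_features(v2, DT, ev2)
        assert ev2.amplitude == pytest.approx(2 * ev.amplitude, rel=0.02)


class TestTriggeredAverage:
    def make_traces(self, n=40000):
        rng = np.random.default_rng(0)
        tr = TraceSet(dt=DT)
        tr.add("x", rng.normal(5.0, 1.0, n))
        return tr

    def test_single_event_returns_the_segment(self):
        tr = self.make_traces()
        out = triggered_average(tr, np.array([500.0]), span=(-5.0, 5.0))
        i0 = int(495.0 / DT)
        seg = tr["x"][i0 : i0 + len(out["t"])]
        assert np.allclose(out["x"][0], seg)
        assert np.allclose(out["x"][1], 0.0)

    def test_identical_events_zero_sd(self):
        tr = self.make_traces()
        out = triggered_average(tr, np.array([500.0, 500.0]), span=(-5.0, 5.0))
        assert np.allclose(out["x"][1], 0.0)

    def test_random_times_average_to_stationary_mean(self):
        from spikelet_lab.stimuli import OUConductanceParams, ou_conductance_pair

        p = OUConductanceParams()
        g_e, _ = ou_conductance_pair(p, DT, 50_000.0, seed=2)
        tr = TraceSet(dt=DT)
        tr.add("g_e", g_e)
        rng = np.random.default_rng(1)
        times = rng.uniform(100.0, 49_900.0, 400)
        out = triggered_average(tr, times, span=(-5.0, 5.0))
        se = p.std_e / np.sqrt(len(times) / 2)
        assert np.all(np.abs(out["g_e"][0] - p.g_e0) < 4 * se)

    def test_incomplete_windows_dropped_and_counted(self):
        tr = self.make_traces(n=2000)
        out = triggered_average(tr, np.array([1.0, 25.0]), span=(-5.0, 5.0))
        assert out["n_events"] == 1
        assert out["n_dropped"] == 1

    def test_no_events_rejected(self):
        tr = self.make_traces()
        with pytest.raises(ValueError):
            triggered_average(tr, np.array([]))


class TestEffectiveReversal:
    def test_limits_and_mixture(self):
        assert effective_reversal(np.array([0.01]), np.array([0.0]))[0] == 0.0
        assert effective_reversal(np.array([0.01]), np.array([0.01]))[0] == pytest.approx(-37.5)
        # default background conductances: (0.01*0 + 0.0573*-75)/0.0673
        val = effective_reversal(np.array([0.01]), np.array([0.0573]))[0]
        assert val == pytest.approx(-63.86, abs=0.05)

    def test_undefined_samples_flagged(self):
        out = effective_reversal(np.array([0.0, 0.01]), np.array([0.0, 0.01]))
        assert np.isnan(out[0]) and not np.isnan(out[1])


class TestAmplitudeSlopeScatter:
    def test_two_waveform_families_separate(self):
        times_sp = [50.0 + 80 * i for i in range(5)]
        times_ap = [90.0 + 80 * i for i in range(5)]
        v_soma = (
            trace_with_events(times_sp, SP, T=600.0)
            + trace_with_events(times_ap, AP, T=600.0)
            + 70.0
        )
        v_ais = trace_with_events(sorted(times_sp + times_ap), AP, T=600.0)
        tab = detect_events(v_soma, v_ais, DT)
        for e in tab:
            event_features(v_soma, DT, e)
        df = amplitude_vs_maxslope(tab)
        sp = df[df.cls == "spikelet"]
        ap = df[df.cls != "spikelet"]
        assert len(sp) == 5 and len(ap) == 5
        assert sp.amplitude.max() < ap.amplitude.min()
        assert sp.max_dvdt.max() < ap.max_dvdt.min()

    def test_empty_table(self):
        assert amplitude_vs_maxslope(EventTable()).empty
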