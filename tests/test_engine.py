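"""Compartmental engine: discretization, integration accuracy, measurements."""

import numpy as np
import pytest

from spikelet_lab.engine import (
    Cell,
    MechanismSpec,
    SectionSpec,
    discretize,
    gap_junction_current,
    input_capacitance,
    input_resistance,
    integrate,
)
from spikelet_lab.passive import PassiveCellParams, derive_constants
from spikelet_lab.stimuli import CurrentStep, VoltageClampStep


def single_cylinder(L=40.0, d=20.0, nseg=1, **kw):
    return discretize([SectionSpec("soma", L, d, n_segments=nseg, **kw)])


class TestDiscretize:
    def test_cylindrical_lateral_area(self):
        g = single_cylinder()
        assert g.area[0] * 1e8 == pytest.approx(np.pi * 20 * 40, rel=1e-12)

    def test_series_equivalence(self):
        one = discretize([SectionSpec("a", 200.0, 2.0, n_segments=20)])
        two = discretize(
            [
                SectionSpec("a", 100.0, 2.0, n_segments=10),
                SectionSpec("b", 100.0, 2.0, n_segments=10, parent=("a", 1.0)),
            ]
        )
        r1 = input_resistance(one, "a:0.0")
        r2 = input_resistance(two, "a:0.0")
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_taper_monotone(self):
        g = discretize([SectionSpec("ais", 30.0, (1.3, 1.22), n_segments=6)])
        d = np.sqrt(g.area / (np.pi * 30e-4 / 6))
        assert np.all(np.diff(d) < 0)

    def test_cycle_rejected(self):
        secs = [
            SectionSpec("a", 50.0, 2.0, parent=("b", 0.5)),
            SectionSpec("b", 50.0, 2.0, parent=("a", 0.5)),
        ]
        with pytest.raises(ValueError):
            discretize(secs)

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="unknown section"):
            discretize([SectionSpec("a", 50.0, 2.0, parent=("zzz", 0.5))])


class TestIntegrationAccuracy:
    def test_rc_charging_matches_closed_form(self):
        g = single_cylinder()
        R = 1e4 / g.area[0] / 1e6  # MOhm
        tr = integrate(
            g, [CurrentStep("soma:0.5", 0.1, t_on=0.0, t_off=1e9)],
            dt=0.025, T=60.0, record=["soma:0.5"],
        )
        exact = -70 + 0.1 * R * (1 - np.exp(-tr.t / 10.0))
        rel = np.max(np.abs(tr["V:soma:0.5"] - exact)) / (0.1 * R)
        assert rel < 1e-3

    def test_second_order_convergence(self):
        g = single_cylinder()
        R = 1e4 / g.area[0] / 1e6
        errs = []
        for dt in (0.05, 0.025, 0.0125):
            tr = integrate(
                g, [CurrentStep("soma:0.5", 0.1, t_on=0.0, t_off=1e9)],
                dt=dt, T=50.0, record=["soma:0.5"],
            )
            exact = -70 + 0.1 * R * (1 - np.exp(-tr.t / 10.0))
            errs.append(np.max(np.abs(tr["V:soma:0.5"] - exact)))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.15)

    def test_zero_stimulus_stays_at_leak_reversal(self):
        g = discretize(
            [
                SectionSpec("a", 100.0, 2.0, E_leak=-65.0),
                SectionSpec("b", 200.0, 1.0, E_leak=-65.0, parent=("a", 1.0)),
            ]
        )
        tr = integrate(g, [], dt=0.05, T=50.0, v_init=-65.0, record=["a:0.5", "b:0.9"])
        assert np.max(np.abs(tr["V:a:0.5"] + 65.0)) < 1e-9
        assert np.max(np.abs(tr["V:b:0.9"] + 65.0)) < 1e-9

    def test_passive_linearity(self):
        g = discretize([SectionSpec("cable", 400.0, 2.0, n_segments=20)])
        kw = dict(dt=0.025, T=40.0, record=["cable:0.9"])
        s1 = CurrentStep("cable:0.1", 0.05, t_on=5.0, t_off=1e9)
        s2 = CurrentStep("cable:0.7", -0.03, t_on=15.0, t_off=25.0)
        v1 = integrate(g, [s1], **kw)["V:cable:0.9"]
        v2 = integrate(g, [s2], **kw)["V:cable:0.9"]
        v12 = integrate(g, [s1, s2], **kw)["V:cable:0.9"]
        assert np.max(np.abs(v12 - (v1 + v2 + 70.0))) < 1e-9

    def test_steady_state_charge_conservation(self):
        # at steady state the summed membrane current equals the injection
        sec = SectionSpec("cable", 300.0, 2.0, n_segments=10)
        g = discretize([sec])
        sites = [f"cable:{(k + 0.5) / 10}" for k in range(10)]
        tr = integrate(
            g, [CurrentStep("cable:0.25", 0.08, t_on=0.0, t_off=1e9)],
            dt=0.05, T=300.0, record=sites,
        )
        v_end = np.array([tr[f"V:{s}"][-1] for s in sites])
        i_membrane = np.sum(g.gL * (v_end - g.eL))
        assert i_membrane == pytest.approx(0.08, rel=1e-3)

    def test_determinism_and_seed_sensitivity(self):
        from spikelet_lab.stimuli import OUConductance

        g = single_cylinder()
        kw = dict(dt=0.05, T=200.0, record=["soma:0.5"])
        a = integrate(g, [OUConductance("soma:0.5")], seed=11, **kw)
        b = integrate(g, [OUConductance("soma:0.5")], seed=11, **kw)
        c = integrate(g, [OUConductance("soma:0.5")], seed=12, **kw)
        assert np.array_equal(a["V:soma:0.5"], b["V:soma:0.5"])
        assert not np.array_equal(a["V:soma:0.5"], c["V:soma:0.5"])

    def test_divergence_reported_with_time(self):
        # a non-finite input must surface as an integration error with the
        # first failing time, not as silent NaN output
        g = single_cylinder()
        bad = CurrentStep("soma:0.5", float("nan"), t_on=5.0, t_off=1e9)
        with pytest.raises(RuntimeError, match="at t ="):
            integrate(g, [bad], dt=0.5, T=10.0, record=["soma:0.5"])


class TestMeasurements:
    def test_isolated_cylinder_capacitance(self):
        g = single_cylinder()
        expected = 1.0 * g.area[0] * 1e6  # uF/cm^2 * cm^2 -> pF
        assert input_capacitance(g, "soma:0.5") == pytest.approx(expected, rel=0.01)

    def test_capacitance_scales_with_cm(self):
        g1 = single_cylinder()
        g2 = single_cylinder(C_m=2.0)
        assert input_capacitance(g2, "soma:0.5") == pytest.approx(
            2 * input_capacitance(g1, "soma:0.5"), rel=0.01
        )

    def test_axon_increases_input_capacitance(self):
        soma_only = single_cylinder()
        with_axon = discretize(
            [
                SectionSpec("soma", 40.0, 20.0, n_segments=1),
                SectionSpec("axon", 1000.0, 1.0, parent=("soma", 1.0)),
            ]
        )
        assert input_capacitance(with_axon, "soma:0.5") > input_capacitance(
            soma_only, "soma:0.5"
        )

    def test_sealed_end_resistance(self):
        g = single_cylinder()
        expected = 1e4 / g.area[0] / 1e6
        assert input_resistance(g, "soma:0.5") == pytest.approx(expected, rel=5e-3)
        g2 = single_cylinder(R_m=2e4)
        assert input_resistance(g2, "soma:0.5") == pytest.approx(
            2 * expected, rel=5e-3
        )

    def test_mid_axon_resistance_matches_doubly_infinite_cable(self):
        p = PassiveCellParams()
        c = derive_constants(p)
        # 4 mm cable, injection in the middle: two semi-infinite halves in
        # parallel -> R_inf / 2
        g = discretize([SectionSpec("axon", 4000.0, 1.0, n_segments=400)])
        r = input_resistance(g, "axon:0.5")
        assert r == pytest.approx(c.R_inf / 2 / 1e6, rel=0.05)

    def test_clamp_at_rest_passes_no_current(self):
        g = single_cylinder()
        tr = integrate(
            g,
            [VoltageClampStep("soma:0.5", -70.0, -70.0, t_on=0.0, t_off=1e9)],
            dt=0.025, T=20.0, record=["soma:0.5"],
        )
        assert np.max(np.abs(tr["I_clamp:soma:0.5"][1:])) < 1e-9


class TestGapJunction:
    def test_ohms_law(self):
        assert gap_junction_current(-70.0, -70.0, 50.0) == 0.0
        assert gap_junction_current(30.0, -70.0, 50.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            gap_junction_current(0.0, 0.0, -1.0)

    def test_resistance_range_maps_to_printed_conductances(self):
        r = np.arange(22.0, 82.1, 5.0)
        g_ns = 1e3 / r
        assert g_ns.max() == pytest.approx(45.45, abs=0.05)
        assert g_ns.min() == pytest.approx(12.20, abs=0.05)

    def test_two_cell_link_conserves_antisymmetry(self):
        # coupled passive cylinders: current into one equals current out of
        # the other, so the mean voltages relax toward each other
        secs = [SectionSpec("a", 40.0, 20.0, n_segments=1, E_leak=-80.0)]
        cell = Cell(
            [
                secs[0],
                SectionSpec("b", 40.0, 20.0, n_segments=1, E_leak=-60.0),
            ],
            links=[("a:0.5", "b:0.5", 100.0)],
        )
        g = discretize(cell)
        tr = integrate(g, [], dt=0.025, T=200.0, v_init=-70.0, record=["a:0.5", "b:0.5"])
        va, vb = tr["V:a:0.5"][-1], tr["V:b:0.5"][-1]
        # symmetric cells with symmetric leak offsets settle symmetrically
        assert va + vb == pytest.approx(-140.0, abs=1e-6)
        assert va < -70.0 < vb
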