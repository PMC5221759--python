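"""Closed-form lumped-soma cable analytics against independent oracles."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikelet_lab.passive import (
    PassiveCellParams,
    attenuation_axon_to_soma,
    attenuation_soma_to_axon,
    b_of_omega,
    derive_constants,
    voltage_response_profile,
)

P = PassiveCellParams()
OMEGA_300 = 2 * math.pi * 0.3  # rad/ms


def fd_cable_oracle(p, y_cm, omega0=0.0, L_cm=0.4, n=4000):
    """Finite-difference steady-state/phasor solve of the lumped-soma cable.

    Discretizes lambda^2 V'' = b^2 V on [0, L] with the soma admittance at
    x=0, a sealed far end, and a unit current source at y.  Independent of
    the closed-form solution path.
    """
    c = derive_constants(p)
    dx = L_cm / n
    x = (np.arange(n) + 0.5) * dx
    b2 = 1.0 + 1j * omega0 * c.tau
    # per-length quantities: axial conductance ga = 1/(r_a dx), membrane
    # admittance ym = (1 + i w tau)/ (r_m per length) * dx
    r_a = 4 * p.R_a / (math.pi * p.d_a**2)  # Ohm/cm
    r_m = p.R_m / (math.pi * p.d_a)  # Ohm cm
    ga = 1.0 / (r_a * dx)
    ym = b2 * dx / r_m
    y_soma = (1.0 + 1j * omega0 * p.tau_soma) * p.A_sd / p.r_m_soma
    ga0 = 1.0 / (r_a * dx / 2)
    rhs = np.zeros(n, dtype=complex)
    iy = int(y_cm / dx)
    rhs[iy] = 1.0  # unit current (A)
    diag = np.full(n, ym, dtype=complex)
    diag[1:] += ga
    diag[:-1] += ga
    # soma node eliminated: coupling from the first compartment to the
    # lumped soma admittance in series with the half-segment
    diag[0] += ga0 * y_soma / (ga0 + y_soma)
    from scipy.linalg import solve_banded

    ab = np.zeros((3, n), dtype=complex)
    ab[0, 1:] = -ga
    ab[1] = diag
    ab[2, :-1] = -ga
    v = solve_banded((1, 1), ab, rhs)
    # soma voltage from the series divider
    ga0 = 1.0 / (r_a * dx / 2)
    v_soma = v[0] * ga0 / (ga0 + y_soma)
    return x, v, v_soma


class TestDeriveConstants:
    def test_printed_defaults(self):
        c = derive_constants(P)
        assert c.tau == pytest.approx(10.0)
        assert c.lam == pytest.approx(0.041, abs=5e-4)
        assert c.rho == pytest.approx(0.064, abs=5e-4)
        assert 0.2 / c.lam == pytest.approx(4.9, abs=0.05)
        # internal consistency: rho = (R_m/A_sd) / R_inf
        assert c.rho == pytest.approx((P.R_m / P.A_sd) / c.R_inf, rel=1e-12)

    def test_scaling_laws(self):
        c = derive_constants(P)
        c2 = derive_constants(PassiveCellParams(R_m=2 * P.R_m))
        assert c2.tau == pytest.approx(2 * c.tau)
        assert c2.lam == pytest.approx(math.sqrt(2) * c.lam)
        c4 = derive_constants(PassiveCellParams(d_a=4 * P.d_a))
        assert c4.lam == pytest.approx(2 * c.lam)
        assert c4.rho == pytest.approx(8 * c.rho, rel=1e-9)

    @pytest.mark.parametrize("field", ["R_m", "C_m", "R_a", "d_a", "A_sd"])
    def test_nonpositive_rejected(self, field):
        with pytest.raises(ValueError):
            PassiveCellParams(**{field: -1.0})


class TestBOfOmega:
    def test_dc_identity(self):
        assert b_of_omega(0.0, 10.0) == pytest.approx(1.0 + 0.0j)

    def test_300hz_polar_oracle(self):
        # frozen from the independent polar-form square root:
        # r = |1 + i w tau|, b = sqrt(r) (cos(theta/2) + i sin(theta/2))
        b = b_of_omega(OMEGA_300, 10.0)
        assert b.real == pytest.approx(3.1525, abs=2e-3)
        assert b.imag == pytest.approx(2.9897, abs=2e-3)

    @given(st.floats(min_value=0.0, max_value=1e3))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_modulus_identity_and_branch(self, omega0):
        b = b_of_omega(omega0, 10.0)
        assert abs(b) ** 2 == pytest.approx(abs(1 + 1j * omega0 * 10.0), rel=1e-9)
        assert b.real >= 1.0 - 1e-12

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            b_of_omega(-1.0, 10.0)


class TestAttenuations:
    def test_zero_distance(self):
        for om in (0.0, OMEGA_300):
            assert attenuation_axon_to_soma(0.0, om, P) == pytest.approx(1.0)
            assert attenuation_soma_to_axon(0.0, om, P) == pytest.approx(1.0)

    def test_dc_axon_to_soma_vs_fd_oracle(self):
        a = attenuation_axon_to_soma(50e-4, 0.0, P)
        x, v, v_soma = fd_cable_oracle(P, 50e-4)
        iy = int(50e-4 / (0.4 / 4000))
        assert a == pytest.approx(abs(v[iy]) / abs(v_soma), rel=2e-2)
        assert a == pytest.approx(2.92, abs=0.03)

    def test_large_rho_limit(self):
        p = PassiveCellParams(A_sd=1e-9)  # rho -> infinity
        c = derive_constants(p)
        y = 50e-4
        assert attenuation_axon_to_soma(y, 0.0, p) == pytest.approx(
            math.cosh(y / c.lam), rel=1e-4
        )

    def test_soma_to_axon_closed_forms(self):
        c = derive_constants(P)
        assert attenuation_soma_to_axon(c.lam, 0.0, P) == pytest.approx(math.e)
        # 300 Hz, 50 um: exp(Re(b0) x / lambda) from the polar oracle
        assert attenuation_soma_to_axon(50e-4, OMEGA_300, P) == pytest.approx(
            1.47, abs=0.01
        )

    @given(
        y=st.floats(min_value=1e-4, max_value=0.05),
        om=st.floats(min_value=0.0, max_value=10.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_antidromic_orthodromic_asymmetry(self, y, om):
        a_in = attenuation_axon_to_soma(y, om, P)
        a_out = attenuation_soma_to_axon(y, om, P)
        assert a_in >= a_out - 1e-12  # strict asymmetry since rho < 1
        assert a_in > a_out if y > 1e-3 else True

    @given(
        y=st.floats(min_value=1e-4, max_value=0.02),
        om=st.floats(min_value=0.0, max_value=5.0),
        dom=st.floats(min_value=0.01, max_value=5.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_frequency_monotonicity(self, y, om, dom):
        assert attenuation_axon_to_soma(y, om + dom, P) >= attenuation_axon_to_soma(
            y, om, P
        ) - 1e-12
        assert attenuation_soma_to_axon(y, om + dom, P) >= attenuation_soma_to_axon(
            y, om, P
        ) - 1e-12

    def test_high_frequency_capacitance_dominance(self):
        """R_m barely matters above 100 Hz; the somatic C_m dominates."""
        y = 50e-4
        for f in (300.0, 1000.0):
            om = 2 * math.pi * f * 1e-3
            base = math.log(attenuation_axon_to_soma(y, om, P))
            lo = math.log(attenuation_axon_to_soma(y, om, PassiveCellParams(R_m=1e3)))
            hi = math.log(attenuation_axon_to_soma(y, om, PassiveCellParams(R_m=1e5)))
            rm_effect = abs(hi - lo) / base
            assert rm_effect < 0.05
            ca = math.log(
                attenuation_axon_to_soma(y, om, PassiveCellParams(C_m_soma=0.31))
            )
            cb = math.log(
                attenuation_axon_to_soma(y, om, PassiveCellParams(C_m_soma=3.1))
            )
            cm_effect = abs(cb - ca) / base
            assert cm_effect > 10 * rm_effect
        # at 300 Hz the decade of somatic C_m moves ln attenuation by > 50%
        assert (
            abs(
                math.log(attenuation_axon_to_soma(y, OMEGA_300, PassiveCellParams(C_m_soma=3.1)))
                - math.log(attenuation_axon_to_soma(y, OMEGA_300, PassiveCellParams(C_m_soma=0.31)))
            )
            / math.log(attenuation_axon_to_soma(y, OMEGA_300, P))
            > 0.5
        )


class TestVoltageProfile:
    @given(
        y=st.floats(min_value=5e-4, max_value=0.03),
        om=st.floats(min_value=0.0, max_value=10.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_branch_continuity_and_ratio(self, y, om):
        v_minus = voltage_response_profile(y * (1 - 1e-12), y, om, 1.0, P)
        v_plus = voltage_response_profile(y * (1 + 1e-12), y, om, 1.0, P)
        assert v_minus == pytest.approx(v_plus, rel=1e-6)
        v0 = voltage_response_profile(0.0, y, om, 1.0, P)
        vy = voltage_response_profile(y, y, om, 1.0, P)
        assert abs(vy / v0) == pytest.approx(
            attenuation_axon_to_soma(y, om, P), rel=1e-9
        )

    def test_dc_profile_matches_fd_oracle(self):
        y = 50e-4
        x, v, v_soma = fd_cable_oracle(P, y)
        dx = 0.4 / 4000
        # compare shapes at a few positions (normalize by the value at y)
        iy = int(y / dx)
        for frac in (0.2, 0.6, 1.5, 3.0):
            xx = frac * y
            ix = int(xx / dx)
            num = abs(v[ix]) / abs(v[iy])
            ana = abs(
                voltage_response_profile(xx, y, 0.0, 1.0, P)
                / voltage_response_profile(y, y, 0.0, 1.0, P)
            )
            assert num == pytest.approx(ana, rel=2e-2)
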