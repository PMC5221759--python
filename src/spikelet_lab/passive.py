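"""Frequency-domain analytics for a semi-infinite axon with a lumped soma.

The model is the classic lumped-soma cable: a semi-infinite passive cable
(the axon) is attached at ``x = 0`` to a single RC compartment representing
the entire somato-dendritic membrane.  Sinusoidal current of radial frequency
``omega0`` injected at axonal position ``y`` sets up a complex voltage profile
``V(x)`` whose moduli give the direction- and frequency-dependent attenuation
between axon and soma.

All lengths are in cm, times in ms, currents in nA and voltages in mV.
Specific parameters follow the conventional mixed units (``R_m`` in Ohm cm^2,
``C_m`` in uF/cm^2, ``R_a`` in Ohm cm); conversions are centralized here.

The somato-dendritic boundary may be given its own specific capacitance
(``C_m_soma``) and resistance (``R_m_soma``) independent of the cable's
global constants.  This matters for the high-frequency behaviour: the somatic
*capacitance* is the dominant current sink for fast signals travelling from
the axon to the soma, while the somatic *resistance* is nearly irrelevant
above ~100 Hz.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

__all__ = [
    "PassiveCellParams",
    "DerivedConstants",
    "derive_constants",
    "b_of_omega",
    "attenuation_axon_to_soma",
    "attenuation_soma_to_axon",
    "voltage_response_profile",
]


@dataclass(frozen=True)
class PassiveCellParams:
    """Physical constants of the lumped-soma cable model.

    Parameters
    ----------
    R_m : float
        Specific membrane resistance (Ohm cm^2).
    C_m : float
        Specific membrane capacitance (uF/cm^2).
    R_a : float
        Axial resistivity (Ohm cm).
    d_a : float
        Axon diameter (cm).
    A_sd : float
        Somato-dendritic surface area (cm^2).
    C_m_soma, R_m_soma : float or None
        Optional soma-specific membrane constants for the lumped boundary.
        ``None`` couples the boundary to the global ``C_m`` / ``R_m``.
    """

    R_m: float = 1.0e4
    C_m: float = 1.0
    R_a: float = 150.0
    d_a: float = 1.0e-4
    A_sd: float = 2.0e-4
    C_m_soma: float | None = None
    R_m_soma: float | None = None

    def __post_init__(self) -> None:
        for name in ("R_m", "C_m", "R_a", "d_a", "A_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("C_m_soma", "R_m_soma"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def c_m_soma(self) -> float:
        return self.C_m if self.C_m_soma is None else self.C_m_soma

    @property
    def r_m_soma(self) -> float:
        return self.R_m if self.R_m_soma is None else self.R_m_soma

    @property
    def tau_soma(self) -> float:
        """Boundary time constant R_sd * C_sd (ms)."""
        return self.r_m_soma * self.c_m_soma * 1e-3


@dataclass(frozen=True)
class DerivedConstants:
    """Derived cable constants.

    tau : membrane time constant (ms); lam : axonal length constant (cm);
    rho : ratio of total somato-dendritic membrane resistance to the input
    resistance of the semi-infinite axon (dimensionless); R_inf : input
    resistance of the semi-infinite cable (Ohm).
    """

    tau: float
    lam: float
    rho: float
    R_inf: float


def derive_constants(p: PassiveCellParams) -> DerivedConstants:
    """Compute tau, lambda, rho and R_inf from the physical parameters.

    tau = R_m C_m, lambda = sqrt(R_m d_a / (4 R_a)),
    R_inf = (2/pi) d_a^(-3/2) sqrt(R_m R_a), rho = (R_m / A_sd) / R_inf.
    At the default parameters this gives tau = 10 ms, lambda = 0.041 cm and
    rho = 0.064.
    """
    tau = p.R_m * p.C_m * 1e-3  # Ohm cm^2 * uF/cm^2 = us -> ms via 1e-3
    lam = math.sqrt(p.R_m * p.d_a / (4.0 * p.R_a))
    r_inf = (2.0 / math.pi) * p.d_a ** (-1.5) * math.sqrt(p.R_m * p.R_a)
    r_sd = p.r_m_soma / p.A_sd
    rho = r_sd / r_inf
    return DerivedConstants(tau=tau, lam=lam, rho=rho, R_inf=r_inf)


def b_of_omega(omega0: float, tau: float) -> complex:
    """Principal square root (positive real part) of ``1 + i omega0 tau``.

    ``omega0`` is the radial frequency in rad/ms, ``tau`` the membrane time
    constant in ms.  Computed in polar form by argument halving, so the
    principal branch is explicit.
    """
    if omega0 < 0:
        raise ValueError("omega0 must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    z = 1.0 + 1j * omega0 * tau
    r = abs(z)
    theta = cmath.phase(z)
    b = math.sqrt(r) * cmath.exp(0.5j * theta)
    assert b.real > 0
    return b


def _boundary_b2(omega0: float, p: PassiveCellParams) -> complex:
    """Squared boundary factor ``1 + i omega0 tau_soma``.

    Equals ``b(omega0)^2`` of the cable when the soma shares the global
    membrane constants; deviates when the boundary is given its own C or R.
    """
    return 1.0 + 1j * omega0 * p.tau_soma


def attenuation_axon_to_soma(
    y: float, omega0: float, p: PassiveCellParams | None = None
) -> float:
    """Antidromic (axon-to-soma) voltage attenuation |V(y)/V(0)|.

    For injection at axonal distance ``y`` (cm) the attenuation is
    ``|cosh(b0 y / lambda) + (beta^2 / (b0 rho)) sinh(b0 y / lambda)|``,
    where ``beta^2`` is the boundary factor (equal to ``b0^2`` when the soma
    shares the cable's membrane constants, reducing the expression to
    ``|cosh + (b0/rho) sinh|``).  Always >= 1 and non-decreasing in both
    ``y`` and ``omega0``.
    """
    p = p or PassiveCellParams()
    if y < 0:
        raise ValueError("y must be non-negative")
    c = derive_constants(p)
    b0 = b_of_omega(omega0, c.tau)
    beta2 = _boundary_b2(omega0, p)
    u = b0 * y / c.lam
    return abs(cmath.cosh(u) + beta2 / (b0 * c.rho) * cmath.sinh(u))


def attenuation_soma_to_axon(
    x: float, omega0: float, p: PassiveCellParams | None = None
) -> float:
    """Orthodromic (soma-to-axon) attenuation ``exp(Re(b0) x / lambda)``.

    Equal to the attenuation in a (semi-)infinite cable; independent of the
    somatic boundary.
    """
    p = p or PassiveCellParams()
    if x < 0:
        raise ValueError("x must be non-negative")
    c = derive_constants(p)
    b0 = b_of_omega(omega0, c.tau)
    return math.exp(b0.real * x / c.lam)


def voltage_response_profile(
    x: float,
    y: float,
    omega0: float,
    I0: float = 1.0,
    p: PassiveCellParams | None = None,
) -> complex:
    """Complex voltage amplitude at ``x`` for sinusoidal current at ``y``.

    ``I0`` is the current amplitude in nA; the result is in mV (R_inf is
    applied in MOhm).  The two branches (x <= y and x >= y) agree at x = y,
    and ``|V(y)/V(0)|`` equals :func:`attenuation_axon_to_soma`.
    """
    p = p or PassiveCellParams()
    if x < 0 or y < 0:
        raise ValueError("x and y must be non-negative")
    c = derive_constants(p)
    b0 = b_of_omega(omega0, c.tau)
    beta2 = _boundary_b2(omega0, p)
    r_inf_mohm = c.R_inf / 1e6
    # inner solution satisfying the lumped-RC boundary at x = 0
    coeff = (I0 * r_inf_mohm / b0) / (
        (1.0 + beta2 / (b0 * c.rho)) * cmath.exp(b0 * y / c.lam)
    )

    def inner(xx: float) -> complex:
        u = b0 * xx / c.lam
        return cmath.cosh(u) + beta2 / (b0 * c.rho) * cmath.sinh(u)

    if x <= y:
        return coeff * inner(x)
    return coeff * inner(y) * cmath.exp(-b0 * (x - y) / c.lam)
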