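"""Hodgkin-Huxley-style channel kinetics, loaded from parameter files.

Two rate-set families are supported, both specified entirely by a YAML
parameter file so the channel model can be swapped without touching code:

* ``na3_kdr`` -- the hippocampal CA1 pyramidal formulation (trap-function
  transient-Na rates with minimum time constants; Boltzmann-rate delayed
  rectifier with a single activation gate).  This is the shipped default
  (``hippocampal_na3_kdr.yaml``).
* ``alpha_beta`` -- a classic six-rate alpha/beta table (linoid /
  exponential / sigmoid rate shapes; Na m^3 h, K n^4), shipped as
  ``hippocampal_na_k.yaml`` with the Traub-Miles CA3 coefficients.

A per-compartment hyperpolarizing shift moves the sodium activation *and*
inactivation curves; the potassium gates are never shifted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["Kinetics", "load_kinetics", "default_kinetics", "RATE_KINDS"]

RATE_KINDS = {"linoid": 0, "linoid_neg": 1, "expdecay": 2, "sigmoid": 3}
_RATE_ORDER = ("m_alpha", "m_beta", "h_alpha", "h_beta", "n_alpha", "n_beta")

MODEL_ALPHA_BETA = 0
MODEL_NA3_KDR = 1

_FARADAY_OVER_R = 9.648e4 / 8.315  # K/V


def _safe_linoid(x, q):
    x = np.asarray(x, dtype=float)
    small = np.abs(x / q) < 1e-7
    denom = np.where(small, 1.0, 1.0 - np.exp(-np.where(small, 0.0, x) / q))
    return np.where(small, q + x / 2.0, x / denom)


@dataclass(frozen=True)
class Kinetics:
    """Parsed channel-kinetics set.

    ``model_id`` selects the rate family; ``params`` is the packed constant
    vector consumed by the integration kernel; ``n_exp`` is the power of the
    potassium activation gate.
    """

    name: str
    E_Na: float
    E_K: float
    model_id: int
    n_exp: int
    params: np.ndarray = field(repr=False)

    # -- python-side gate evaluation (mirrors the kernel; used for tests
    #    and initialization oracles) ------------------------------------

    def gates(self, v, v_shift_na: float = 0.0):
        """(minf, mtau, hinf, htau, ninf, ntau) at voltage ``v`` (mV)."""
        v = np.asarray(v, dtype=float)
        vna = v - v_shift_na
        p = self.params
        if self.model_id == MODEL_ALPHA_BETA:
            vals = []
            for i, vv in ((0, vna), (1, vna), (2, vna), (3, vna), (4, v), (5, v)):
                kind, a, th, q = (
                    int(p[4 * i]), p[4 * i + 1], p[4 * i + 2], p[4 * i + 3],
                )
                if kind == 0:
                    r = a * _safe_linoid(vv - th, q)
                elif kind == 1:
                    r = a * _safe_linoid(th - vv, q)
                elif kind == 2:
                    r = a * np.exp(-(vv - th) / q)
                else:
                    r = a / (1.0 + np.exp(-(vv - th) / q))
                vals.append(r)
            am, bm, ah, bh, an, bn = vals
            return (
                am / (am + bm), 1.0 / (am + bm),
                ah / (ah + bh), 1.0 / (ah + bh),
                an / (an + bn), 1.0 / (an + bn),
            )
        (tha, qa, Ra, Rb, thi1, thi2, qd, qg, Rd, Rg, thinf, qinf,
         mmin, hmin, qt_na, vhalf, zeta, gm, a0, nmin, qt_k, cfac) = p
        am = Ra * _safe_linoid(vna - tha, qa)
        bm = Rb * _safe_linoid(tha - vna, qa)
        mtau = np.maximum(1.0 / (am + bm) / qt_na, mmin)
        minf = am / (am + bm)
        ah = Rd * _safe_linoid(vna - thi1, qd)
        bh = Rg * _safe_linoid(thi2 - vna, qg)
        htau = np.maximum(1.0 / (ah + bh) / qt_na, hmin)
        hinf = 1.0 / (1.0 + np.exp((vna - thinf) / qinf))
        alp = np.exp(zeta * cfac * (v - vhalf))
        bet = np.exp(zeta * gm * cfac * (v - vhalf))
        ninf = 1.0 / (1.0 + alp)
        ntau = np.maximum(bet / (qt_k * a0 * (1.0 + alp)), nmin)
        return minf, mtau, hinf, htau, ninf, ntau

    def steady_state(self, v: float, v_shift_na: float = 0.0):
        """Steady-state (m, h, n) at voltage ``v``."""
        minf, _, hinf, _, ninf, _ = self.gates(v, v_shift_na)
        return minf, hinf, ninf


def _parse(spec: dict) -> Kinetics:
    model = spec.get("model", "alpha_beta")
    if model == "alpha_beta":
        vals = []
        for key in _RATE_ORDER:
            r = spec["rates"][key]
            vals += [float(RATE_KINDS[r["kind"]]), float(r["a"]),
                     float(r["th"]), float(r["q"])]
        n_exp = int(spec.get("exponents", {}).get("n", 4))
        return Kinetics(
            name=spec.get("name", "unnamed"),
            E_Na=float(spec["E_Na"]), E_K=float(spec["E_K"]),
            model_id=MODEL_ALPHA_BETA, n_exp=n_exp,
            params=np.array(vals, dtype=float),
        )
    if model == "na3_kdr":
        na, kdr = spec["na"], spec["kdr"]
        celsius = float(spec.get("celsius", 35.0))
        qt_na = float(na.get("q10", 2.0)) ** ((celsius - 24.0) / 10.0)
        qt_k = float(kdr.get("q10", 1.0)) ** ((celsius - 24.0) / 10.0)
        cfac = 1e-3 * _FARADAY_OVER_R / (273.16 + celsius)
        p = [na[k] for k in ("tha", "qa", "Ra", "Rb", "thi1", "thi2", "qd",
                             "qg", "Rd", "Rg", "thinf", "qinf", "mmin", "hmin")]
        p += [qt_na]
        p += [kdr[k] for k in ("vhalf", "zeta", "gm", "a0", "nmin")]
        p += [qt_k, cfac]
        return Kinetics(
            name=spec.get("name", "unnamed"),
            E_Na=float(spec["E_Na"]), E_K=float(spec["E_K"]),
            model_id=MODEL_NA3_KDR, n_exp=1,
            params=np.array(p, dtype=float),
        )
    raise ValueError(f"unknown kinetics model {model!r}")


def load_kinetics(path: str | Path | None = None) -> Kinetics:
    """Load a kinetics parameter file; ``None`` loads the shipped default."""
    if path is None:
        ref = (
            importlib.resources.files("spikelet_lab")
            / "data"
            / "hippocampal_na3_kdr.yaml"
        )
        text = ref.read_text()
    elif str(path) in ("hippocampal_na3_kdr", "hippocampal_na_k"):
        ref = importlib.resources.files("spikelet_lab") / "data" / f"{path}.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    return _parse(yaml.safe_load(text))


_DEFAULT: Kinetics | None = None


def default_kinetics() -> Kinetics:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_kinetics(None)
    return _DEFAULT
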