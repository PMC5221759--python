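"""Deterministic compartmental simulator for branched passive/active cables.

Sections (cylinders, optionally tapering) are discretized into compartments
with cylindrical lateral areas (no end caps) and axial conductances computed
from the axial resistivity.  Integration is implicit trapezoid
(Crank-Nicolson) on the tree via ordered elimination, which is
unconditionally stable on the passive subsystem and second-order accurate on
smooth problems.  Gating variables are initialized at their steady state at
``v_init`` and advanced with staggered exponential updates.

Internal units: mV, ms, nA, uS, nF, cm.  Geometry is specified in um,
specific membrane properties in the conventional mixed units (Ohm cm^2,
uF/cm^2, Ohm cm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from spikelet_lab._kernels import run_simulation
from spikelet_lab.channels import Kinetics, default_kinetics
from spikelet_lab.traces import TraceSet

__all__ = [
    "MechanismSpec",
    "SectionSpec",
    "Cell",
    "CompartmentGraph",
    "discretize",
    "integrate",
    "input_capacitance",
    "input_resistance",
    "gap_junction_current",
    "parse_site",
]

#: default max segment length (um) for AIS/axon-like vs other sections
_SEG_FINE_UM = 10.0
_SEG_COARSE_UM = 30.0


@dataclass(frozen=True)
class MechanismSpec:
    """An active conductance placed uniformly on a section.

    ``kind`` is ``transient_Na`` or ``delayed_rectifier_K``; ``gbar`` is in
    S/cm^2.  ``v_shift`` (mV) shifts the sodium activation and inactivation
    curves (negative values = hyperpolarizing shift); it is ignored for
    potassium.  ``h_tau_fixed`` pins the inactivation time constant to a
    fixed value in ms (used with a very large value to freeze fast
    inactivation at its initial steady state).
    """

    kind: str
    gbar: float
    E_rev: float | None = None
    v_shift: float = 0.0
    h_tau_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("transient_Na", "delayed_rectifier_K"):
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if self.gbar < 0:
            raise ValueError("gbar must be non-negative")


@dataclass(frozen=True)
class SectionSpec:
    """A cylindrical (optionally tapering) cable section.

    ``diam`` may be a float or a ``(d0, d1)`` pair for end-to-end taper (um).
    ``parent`` is ``(section_name, normalized_position)`` or ``None`` for the
    root.  ``n_segments=None`` picks a default so segments are <= 10 um for
    AIS/axon sections and <= 30 um elsewhere (sections whose name contains
    "ais" or "axon").
    """

    name: str
    length: float  # um
    diam: float | tuple[float, float]
    n_segments: int | None = None
    C_m: float = 1.0  # uF/cm^2
    R_m: float = 1.0e4  # Ohm cm^2
    R_a: float = 150.0  # Ohm cm
    E_leak: float = -70.0  # mV
    mechanisms: tuple[MechanismSpec, ...] = ()
    parent: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        d0, d1 = self.diams
        if self.length <= 0 or d0 <= 0 or d1 <= 0:
            raise ValueError(f"section {self.name!r}: non-positive geometry")
        if self.n_segments is not None and self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        for p in ("C_m", "R_m", "R_a"):
            if getattr(self, p) <= 0:
                raise ValueError(f"section {self.name!r}: {p} must be positive")

    @property
    def diams(self) -> tuple[float, float]:
        if isinstance(self.diam, tuple):
            return self.diam
        return (self.diam, self.diam)

    @property
    def nseg(self) -> int:
        if self.n_segments is not None:
            return self.n_segments
        lname = self.name.lower()
        target = _SEG_FINE_UM if ("ais" in lname or "axon" in lname) else _SEG_COARSE_UM
        return max(1, int(np.ceil(self.length / target)))


@dataclass
class Cell:
    """A named list of sections plus optional resistive links (gap junctions).

    ``links`` entries are ``(site_a, site_b, R_MOhm)`` with sites given as
    ``"section:pos"`` strings.
    """

    sections: list[SectionSpec]
    links: list[tuple[str, str, float]] = field(default_factory=list)
    name: str = "cell"
    meta: dict = field(default_factory=dict)

    def section(self, name: str) -> SectionSpec:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)

    def replace_section(self, name: str, **changes) -> "Cell":
        new = [replace(s, **changes) if s.name == name else s for s in self.sections]
        if not any(s.name == name for s in self.sections):
            raise KeyError(name)
        return Cell(new, list(self.links), self.name, dict(self.meta))


def parse_site(site: str) -> tuple[str, float]:
    name, _, pos = site.rpartition(":")
    if not name:
        raise ValueError(f"site {site!r} must be 'section:pos'")
    return name, float(pos)


class CompartmentGraph:
    """Discretized cell: per-compartment arrays in Hines (parent-first) order."""

    def __init__(self, kinetics: Kinetics | None = None):
        self.kinetics = kinetics or default_kinetics()
        # filled by discretize()
        self.parent: np.ndarray
        self.g_par: np.ndarray  # uS
        self.C: np.ndarray  # nF
        self.gL: np.ndarray  # uS
        self.eL: np.ndarray
        self.gNa: np.ndarray
        self.gK: np.ndarray
        self.vshift_na: np.ndarray
        self.h_tau_fixed: np.ndarray
        self.area: np.ndarray  # cm^2
        self.section_slices: dict[str, tuple[int, int]] = {}

    @property
    def n_comps(self) -> int:
        return len(self.parent)

    def site_index(self, site: str | tuple[str, float]) -> int:
        """Compartment index of the segment containing ``section:pos``."""
        name, pos = parse_site(site) if isinstance(site, str) else site
        if name not in self.section_slices:
            raise KeyError(f"unknown section {name!r}")
        start, nseg = self.section_slices[name]
        k = min(int(pos * nseg), nseg - 1)
        return start + k

    def total_capacitance_pF(self) -> float:
        return float(np.sum(self.C)) * 1e3  # nF -> pF

    def passive_copy(self) -> "CompartmentGraph":
        g = CompartmentGraph(self.kinetics)
        for attr in (
            "parent", "g_par", "C", "gL", "eL", "gNa", "gK",
            "vshift_na", "h_tau_fixed", "area",
        ):
            setattr(g, attr, getattr(self, attr).copy())
        g.section_slices = dict(self.section_slices)
        g._pos_of = self._pos_of.copy()
        g.gNa[:] = 0.0
        g.gK[:] = 0.0
        return g


def discretize(cell: Cell | list[SectionSpec]) -> CompartmentGraph:
    """Discretize a section tree (plus optional gap-junction links).

    Compartment areas are cylindrical lateral surfaces ``pi * d * L`` per
    segment; tapered sections use per-segment linearly interpolated
    diameters.  Axial conductance between adjacent compartments combines the
    two half-segment resistances.  The resulting adjacency (including links)
    must be a tree; a cycle raises a structural error.
    """
    if isinstance(cell, list):
        cell = Cell(cell)
    sections = cell.sections
    by_name = {}
    for s in sections:
        if s.name in by_name:
            raise ValueError(f"duplicate section name {s.name!r}")
        by_name[s.name] = s

    kin = default_kinetics()
    # per-compartment arrays in construction (pre-Hines) order
    comp_area, comp_C, comp_gL, comp_eL = [], [], [], []
    comp_gNa, comp_gK, comp_shift, comp_htau = [], [], [], []
    half_r = []  # MOhm, axial half-segment resistance
    slices: dict[str, tuple[int, int]] = {}
    idx = 0
    for s in sections:
        nseg = s.nseg
        slices[s.name] = (idx, nseg)
        d0, d1 = s.diams
        L_cm = s.length * 1e-4 / nseg
        gna = gk = 0.0
        shift = 0.0
        htau = np.nan
        e_na, e_k = kin.E_Na, kin.E_K
        for mech in s.mechanisms:
            if mech.kind == "transient_Na":
                gna = mech.gbar
                shift = mech.v_shift
                if mech.h_tau_fixed is not None:
                    htau = mech.h_tau_fixed
            else:
                gk = mech.gbar
        for k in range(nseg):
            frac = (k + 0.5) / nseg
            d_cm = (d0 + (d1 - d0) * frac) * 1e-4
            area = np.pi * d_cm * L_cm  # cm^2, lateral surface only
            comp_area.append(area)
            comp_C.append(s.C_m * area * 1e3)  # uF -> nF
            comp_gL.append(area / s.R_m * 1e6)  # S -> uS
            comp_eL.append(s.E_leak)
            comp_gNa.append(gna * area * 1e6)
            comp_gK.append(gk * area * 1e6)
            comp_shift.append(shift)
            comp_htau.append(htau)
            half_r.append(s.R_a * (L_cm / 2.0) / (np.pi * d_cm**2 / 4.0) / 1e6)
            idx += 1
    n = idx

    def site_comp(name: str, pos: float) -> int:
        start, nseg = slices[name]
        return start + min(int(pos * nseg), nseg - 1)

    # undirected adjacency with coupling conductances (uS)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]

    def connect(a: int, b: int, r_mohm: float) -> None:
        g = 1.0 / r_mohm
        adj[a].append((b, g))
        adj[b].append((a, g))

    for s in sections:
        start, nseg = slices[s.name]
        for k in range(nseg - 1):
            connect(start + k, start + k + 1, half_r[start + k] + half_r[start + k + 1])
        if s.parent is not None:
            pname, ppos = s.parent
            if pname not in slices:
                raise ValueError(
                    f"section {s.name!r} attaches to unknown section {pname!r}"
                )
            if not 0.0 <= ppos <= 1.0:
                raise ValueError("attachment position must be in [0, 1]")
            pc = site_comp(pname, ppos)
            connect(start, pc, half_r[start] + half_r[pc])
    for site_a, site_b, r_gj in cell.links:
        if r_gj <= 0:
            raise ValueError("gap junction resistance must be positive")
        na_, pa = parse_site(site_a)
        nb_, pb = parse_site(site_b)
        connect(site_comp(na_, pa), site_comp(nb_, pb), r_gj)

    # BFS from compartment 0 -> Hines order; cycles are structural errors
    order = np.full(n, -1, dtype=np.int64)
    parent_new = np.full(n, -1, dtype=np.int64)
    gpar_new = np.zeros(n)
    pos_of = np.full(n, -1, dtype=np.int64)  # old index -> new index
    queue = [0]
    pos_of[0] = 0
    order[0] = 0
    visited_edge_from = {0: -1}
    count = 1
    qi = 0
    while qi < len(queue):
        u = queue[qi]
        qi += 1
        for v, g in adj[u]:
            if pos_of[v] >= 0:
                if v != visited_edge_from[u]:
                    raise ValueError("section attachments form a cycle")
                continue
            pos_of[v] = count
            order[count] = v
            parent_new[count] = pos_of[u]
            gpar_new[count] = g
            visited_edge_from[v] = u
            count += 1
            queue.append(v)
    if count != n:
        raise ValueError("sections are not all connected to one tree")

    graph = CompartmentGraph()
    take = order

    def perm(values):
        return np.asarray(values, dtype=float)[take]

    graph.parent = parent_new
    graph.g_par = gpar_new
    graph.area = perm(comp_area)
    graph.C = perm(comp_C)
    graph.gL = perm(comp_gL)
    graph.eL = perm(comp_eL)
    graph.gNa = perm(comp_gNa)
    graph.gK = perm(comp_gK)
    graph.vshift_na = perm(comp_shift)
    graph.h_tau_fixed = perm(comp_htau)
    graph.section_slices = slices
    graph._pos_of = pos_of  # old->new mapping used by site_index
    return graph


# patch site_index to account for the Hines permutation
def _site_index(self: CompartmentGraph, site) -> int:
    name, pos = parse_site(site) if isinstance(site, str) else site
    if name not in self.section_slices:
        raise KeyError(f"unknown section {name!r}")
    start, nseg = self.section_slices[name]
    k = min(int(pos * nseg), nseg - 1)
    return int(self._pos_of[start + k])


CompartmentGraph.site_index = _site_index  # type: ignore[method-assign]


def integrate(
    graph: CompartmentGraph,
    stimuli: list,
    dt: float = 0.025,
    T: float = 100.0,
    v_init: float = -70.0,
    seed: int = 0,
    record: list[str] | None = None,
    record_states: list[tuple[str, str]] | None = None,
) -> TraceSet:
    """Integrate the model and return sampled traces.

    ``record`` lists ``"section:pos"`` sites whose voltage is sampled every
    ``dt`` (default: the midpoint of every section).  ``record_states``
    lists ``(site, var)`` pairs with var in {"m", "h", "n"}.  Stimuli are
    objects from :mod:`spikelet_lab.stimuli`; stochastic ones draw their
    sample paths from sub-streams spawned deterministically from ``seed``
    (identical inputs give bit-identical traces).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nsteps = int(round(T / dt))
    if record is None:
        record = [f"{name}:0.5" for name in graph.section_slices]
    rec_idx = np.array([graph.site_index(s) for s in record], dtype=np.int64)
    record_states = record_states or []
    var_code = {"m": 0, "h": 1, "n": 2}
    rs_idx = np.array(
        [graph.site_index(s) for s, _ in record_states], dtype=np.int64
    )
    rs_var = np.array([var_code[v] for _, v in record_states], dtype=np.int64)

    # resolve stimuli into dense arrays
    seeds = np.random.SeedSequence(seed).spawn(max(len(stimuli), 1))
    inj: list[tuple[int, np.ndarray]] = []
    cond: list[tuple[int, float, np.ndarray, str | None]] = []
    clamp: list[tuple[int, np.ndarray, str | None]] = []
    for k, stim in enumerate(stimuli):
        rng = np.random.default_rng(seeds[k])
        for item in stim.resolve(graph, dt, nsteps, rng):
            kind = item[0]
            if kind == "I":
                inj.append((item[1], item[2]))
            elif kind == "G":
                cond.append((item[1], item[2], item[3], item[4]))
            elif kind == "VC":
                clamp.append((item[1], item[2], item[3]))
            else:
                raise ValueError(f"unknown stimulus contribution {kind!r}")

    def pack(items, width):
        if not items:
            return (
                np.zeros(0, dtype=np.int64),
                np.zeros((0, nsteps + 1)),
            )
        idx = np.array([it[0] for it in items], dtype=np.int64)
        arr = np.vstack([it[width] for it in items]).astype(float)
        return idx, arr

    inj_comp, inj_I = pack(inj, 1)
    cond_comp = np.array([c[0] for c in cond], dtype=np.int64)
    cond_E = np.array([c[1] for c in cond], dtype=float)
    cond_g = (
        np.vstack([c[2] for c in cond]).astype(float)
        if cond
        else np.zeros((0, nsteps + 1))
    )
    clamp_comp = np.array([c[0] for c in clamp], dtype=np.int64)
    clamp_V = (
        np.vstack([c[1] for c in clamp]).astype(float)
        if clamp
        else np.zeros((0, nsteps + 1))
    )

    kin = graph.kinetics
    out_V, out_S, out_Icl, t_fail = run_simulation(
        graph.parent, graph.g_par, graph.C, graph.gL, graph.eL,
        graph.gNa, graph.gK, graph.vshift_na, graph.h_tau_fixed,
        kin.E_Na, kin.E_K,
        kin.model_id, kin.params, kin.n_exp,
        inj_comp, inj_I, cond_comp, cond_E, cond_g, clamp_comp, clamp_V,
        dt, nsteps, v_init, rec_idx, rs_idx, rs_var,
    )
    if t_fail >= 0:
        raise RuntimeError(f"integration diverged (non-finite voltage) at t = {t_fail} ms")

    traces = TraceSet(dt=dt, meta={"v_init": v_init, "seed": seed, "T": T})
    for r, site in enumerate(record):
        traces.add(f"V:{site}", out_V[r], site=site)
    for s, (site, var) in enumerate(record_states):
        traces.add(f"{var}:{site}", out_S[s], site=site)
    for k, (comp, e_rev, g_arr, name) in enumerate(cond):
        if name is not None:
            traces.add(name, g_arr)
    for k, (comp, v_arr, name) in enumerate(clamp):
        if name is not None:
            traces.add(f"I_clamp:{name}", out_Icl[k])
    return traces


def input_capacitance(
    graph: CompartmentGraph,
    site: str,
    step_mV: float = 5.0,
    t_hold: float = 50.0,
    t_step: float = 200.0,
    dt: float = 0.025,
    v_hold: float | None = None,
) -> float:
    """Input capacitance (pF) from a small prolonged voltage-clamp step.

    The clamp holds the site at rest, steps by ``step_mV`` and the
    capacitance is the integrated transient charge divided by the step
    size.  Active conductances are disabled for the measurement.  If the
    clamp current has not settled within the step a warning is issued and
    the measurement is retried with a four-fold longer step.
    """
    g = graph.passive_copy()
    v0 = float(np.mean(g.eL)) if v_hold is None else v_hold
    from spikelet_lab.stimuli import VoltageClampStep

    for duration in (t_step, 4 * t_step):
        stim = VoltageClampStep(
            site=site, v_hold=v0, v_step=v0 + step_mV, t_on=t_hold, t_off=1e18
        )
        tr = integrate(
            g, [stim], dt=dt, T=t_hold + duration, v_init=v0, record=[site]
        )
        icl = tr[f"I_clamp:{site}"]
        i_on = int(round(t_hold / dt))
        ntail = max(int(5.0 / dt), 2)
        i_ss = float(np.mean(icl[-ntail:]))
        i_prev = float(np.mean(icl[-2 * ntail : -ntail]))
        settled = abs(i_ss - i_prev) < max(1e-3 * abs(i_ss), 1e-6)
        q = float(np.trapezoid(icl[i_on - 1 :] - i_ss, dx=dt))  # nA*ms = pC
        if settled:
            return q / step_mV * 1e3  # pC/mV = nF -> pF
        warnings.warn("clamp transient not settled; retrying with longer step")
    return q / step_mV * 1e3


def input_resistance(
    graph: CompartmentGraph,
    site: str,
    dI: float = -0.01,
    T: float = 400.0,
    dt: float = 0.05,
) -> float:
    """Steady-state input resistance (MOhm) from a small current step."""
    g = graph.passive_copy()
    from spikelet_lab.stimuli import CurrentStep

    v0 = float(np.mean(g.eL))
    stim = CurrentStep(site=site, amplitude=dI, t_on=10.0, t_off=T)
    tr = integrate(g, [stim], dt=dt, T=T, v_init=v0, record=[site])
    v = tr[f"V:{site}"]
    dV = float(v[-1]) - float(v[int(round(5.0 / dt))])
    return dV / dI


def gap_junction_current(V1: float, V2: float, R_gj: float) -> float:
    """Ohmic gap-junction current (nA) injected into cell 2: (V1-V2)/R_gj."""
    if R_gj <= 0:
        raise ValueError("R_gj must be positive")
    return (V1 - V2) / R_gj
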