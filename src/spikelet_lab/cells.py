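"""Builders for the model variants.

* the reduced active cell: dendrite - soma - proximal AIS - distal AIS -
  axon, with a hyperpolarizing shift of the sodium curves in the distal AIS
  and axon (the spikelet-generating configuration);
* the passive soma + 2-mm-axon validation cell matching the analytic
  lumped-soma cable model;
* an axon-on-dendrite variant (the axon subtree re-rooted onto the
  dendrite);
* the frozen-fast-inactivation manipulation;
* two-cell gap-junction pairs.

The soma is modelled as a cylinder with the dendrite attached at its 0 end
and the axon at its 1 end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from spikelet_lab.engine import Cell, MechanismSpec, SectionSpec
from spikelet_lab.passive import PassiveCellParams

__all__ = [
    "ReducedCellParams",
    "build_reduced_cell",
    "build_passive_validation_cell",
    "build_axon_on_dendrite_cell",
    "freeze_fast_inactivation",
    "build_coupled_pair",
    "load_swc",
]


@dataclass(frozen=True)
class ReducedCellParams:
    """Geometry, passive constants and channel densities of the reduced cell.

    Lengths/diameters in um, densities in S/cm^2.  The distal AIS and axon
    sodium channels are shifted by ``na_v_shift`` mV (negative =
    hyperpolarizing) relative to the somato-dendritic and proximal-AIS
    channels.
    """

    dend_L: float = 900.0
    dend_diam: float = 6.0
    soma_L: float = 40.0
    soma_diam: float = 20.0
    prox_ais_L: float = 30.0
    distal_ais_L: float = 30.0
    axon_L: float = 1000.0
    axon_diam: float = 1.0
    C_m: float = 1.0
    C_m_soma: float | None = None  # override for the somatic compartment
    R_m: float = 1.0e4
    R_m_dend: float | None = None
    R_a: float = 150.0
    R_a_ais: float | None = None  # override for both AIS sections
    E_leak: float = -70.0
    gna_somadend: float = 0.02
    gna_prox_ais: float = 0.04
    gna_distal_ais: float = 0.1
    gna_axon: float = 0.04
    gk_somadend: float = 0.05
    gk_ais: float = 0.25
    gk_axon: float = 0.125
    na_v_shift: float = -10.0

    def __post_init__(self) -> None:
        for f in (
            "gna_somadend", "gna_prox_ais", "gna_distal_ais", "gna_axon",
            "gk_somadend", "gk_ais", "gk_axon",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.gna_distal_ais < self.gna_prox_ais:
            raise ValueError("distal AIS Na density must be >= proximal")


def _mechs(gna, gk, shift=0.0) -> tuple[MechanismSpec, ...]:
    return (
        MechanismSpec("transient_Na", gna, v_shift=shift),
        MechanismSpec("delayed_rectifier_K", gk),
    )


def build_reduced_cell(p: ReducedCellParams | None = None) -> Cell:
    """Reduced active cell; total axonal cable length 30+30+1000 = 1060 um."""
    p = p or ReducedCellParams()
    common = dict(C_m=p.C_m, R_m=p.R_m, R_a=p.R_a, E_leak=p.E_leak)
    ais_kw = dict(common)
    if p.R_a_ais is not None:
        ais_kw["R_a"] = p.R_a_ais
    soma_kw = dict(common)
    if p.C_m_soma is not None:
        soma_kw["C_m"] = p.C_m_soma
    dend_kw = dict(common)
    if p.R_m_dend is not None:
        dend_kw["R_m"] = p.R_m_dend
    sections = [
        SectionSpec(
            "soma", p.soma_L, p.soma_diam,
            mechanisms=_mechs(p.gna_somadend, p.gk_somadend), **soma_kw,
        ),
        SectionSpec(
            "dendrite", p.dend_L, p.dend_diam, parent=("soma", 0.0),
            mechanisms=_mechs(p.gna_somadend, p.gk_somadend), **dend_kw,
        ),
        SectionSpec(
            "prox_ais", p.prox_ais_L, p.axon_diam, parent=("soma", 1.0),
            mechanisms=_mechs(p.gna_prox_ais, p.gk_ais), **ais_kw,
        ),
        SectionSpec(
            "distal_ais", p.distal_ais_L, p.axon_diam, parent=("prox_ais", 1.0),
            mechanisms=_mechs(p.gna_distal_ais, p.gk_ais, p.na_v_shift), **ais_kw,
        ),
        SectionSpec(
            "axon", p.axon_L, p.axon_diam, parent=("distal_ais", 1.0),
            mechanisms=_mechs(p.gna_axon, p.gk_axon, p.na_v_shift), **common,
        ),
    ]
    return Cell(sections, name="reduced_cell", meta={"params": p})


def build_passive_validation_cell(
    p: PassiveCellParams | None = None,
    axon_L_um: float = 2000.0,
    clamp_distance_um: float = 50.0,
    E_leak: float = -70.0,
) -> Cell:
    """Lumped soma + long passive axon matching the analytic cable model.

    The soma is a single compartment whose cylindrical lateral area equals
    ``A_sd``.  The axon carries a 1-um-long clamp/recording compartment
    centred ``clamp_distance_um`` from the soma.  At the default parameters
    the axon corresponds to an electrotonic length of about 4.9 lambda.
    """
    p = p or PassiveCellParams()
    d_um = p.d_a * 1e4
    # soma cylinder with L = d and pi d L = A_sd
    soma_side = math.sqrt(p.A_sd / math.pi) * 1e4  # um
    prox_L = clamp_distance_um - 0.5
    dist_L = axon_L_um - clamp_distance_um - 0.5
    soma_kw = dict(C_m=p.c_m_soma, R_m=p.r_m_soma)
    axon_kw = dict(C_m=p.C_m, R_m=p.R_m)
    sections = [
        SectionSpec(
            "soma", soma_side, soma_side, n_segments=1, R_a=p.R_a,
            E_leak=E_leak, **soma_kw,
        ),
        SectionSpec(
            "axon_prox", prox_L, d_um, parent=("soma", 1.0), R_a=p.R_a,
            E_leak=E_leak, n_segments=max(5, int(prox_L // 5)), **axon_kw,
        ),
        SectionSpec(
            "clamp_seg", 1.0, d_um, parent=("axon_prox", 1.0), n_segments=1,
            R_a=p.R_a, E_leak=E_leak, **axon_kw,
        ),
        SectionSpec(
            "axon_dist", dist_L, d_um, parent=("clamp_seg", 1.0), R_a=p.R_a,
            E_leak=E_leak, **axon_kw,
        ),
    ]
    return Cell(sections, name="passive_validation_cell", meta={"params": p})


def build_axon_on_dendrite_cell(
    p: ReducedCellParams | None = None, attach_distance_um: float = 20.0
) -> Cell:
    """Reduced cell with the axonal subtree re-rooted onto the dendrite.

    ``attach_distance_um`` is the path distance from the soma to the AIS
    attachment point along the dendrite; 0 recovers the default topology.
    """
    p = p or ReducedCellParams()
    cell = build_reduced_cell(p)
    if attach_distance_um < 0 or attach_distance_um > p.dend_L:
        raise ValueError("attach distance must lie within the dendrite")
    if attach_distance_um == 0.0:
        return cell
    pos = attach_distance_um / p.dend_L
    sections = [
        replace(s, parent=("dendrite", pos)) if s.name == "prox_ais" else s
        for s in cell.sections
    ]
    return Cell(
        sections, name="axon_on_dendrite_cell",
        meta={"params": p, "attach_distance_um": attach_distance_um,
              "surrogate": True},
    )


def freeze_fast_inactivation(cell: Cell, at_mV: float = -70.0) -> Cell:
    """Freeze Na fast inactivation at its steady state at ``at_mV``.

    Implemented as in the source manipulation: the inactivation time
    constant is set to 1e5 ms, so ``h`` stays at its initialization value
    (initialize the run at ``v_init = at_mV``).
    """
    found = False
    sections = []
    for s in cell.sections:
        mechs = []
        for m in s.mechanisms:
            if m.kind == "transient_Na":
                found = True
                m = replace(m, h_tau_fixed=1.0e5)
            mechs.append(m)
        sections.append(replace(s, mechanisms=tuple(mechs)))
    if not found:
        raise ValueError("cell has no transient_Na mechanisms to freeze")
    meta = dict(cell.meta)
    meta["h_frozen_at_mV"] = at_mV
    return Cell(sections, list(cell.links), cell.name + "_frozen_h", meta)


def build_coupled_pair(
    cell: Cell, R_gj: float, site: str = "soma:0.5", E_leak: float | None = -80.0
) -> Cell:
    """Two identical cells coupled by an ohmic gap junction at ``site``.

    ``E_leak`` (default -80 mV, the gap-junction-experiment convention)
    overrides the leak reversal in both cells; pass ``None`` to keep the
    cells' own value.  Sections of the second cell are prefixed ``c2/``.
    """
    if R_gj <= 0:
        raise ValueError("R_gj must be positive")
    sec_name, _ = site.split(":")
    cell.section(sec_name)  # raises KeyError for unknown sites
    sections = []
    for s in cell.sections:
        if E_leak is not None:
            s = replace(s, E_leak=E_leak)
        sections.append(s)
    for s in sections[: len(cell.sections)].copy():
        parent = s.parent
        if parent is not None:
            parent = (f"c2/{parent[0]}", parent[1])
        sections.append(replace(s, name=f"c2/{s.name}", parent=parent))
    links = [(site, f"c2/{site}", R_gj)]
    return Cell(
        sections, links=links, name=cell.name + "_pair",
        meta={"R_gj_MOhm": R_gj, "gj_site": site},
    )


def load_swc(path) -> Cell:
    """Optional SWC reader mapping an SWC tree onto SectionSpecs.

    Maps SWC type codes (1 = soma, 2 = axon, 3/4 = dendrite) to one section
    per unbranched segment run with per-run mean diameter; passive constants
    and mechanisms must be attached afterwards by the caller.  This is the
    hook for plugging in a reconstructed morphology.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n, t, x, y, z, r, parent = line.split()[:7]
            rows.append((int(n), int(t), float(x), float(y), float(z),
                         float(r), int(parent)))
    if not rows:
        raise ValueError("empty SWC file")
    by_id = {r[0]: r for r in rows}
    children: dict[int, list[int]] = {}
    for r in rows:
        children.setdefault(r[6], []).append(r[0])
    type_names = {1: "soma", 2: "axon", 3: "dend", 4: "apic"}

    sections: list[SectionSpec] = []
    sec_of_node: dict[int, str] = {}
    counter: dict[str, int] = {}

    def walk(start_id: int, parent_sec: tuple[str, float] | None):
        # accumulate an unbranched run of nodes of one type
        run = [start_id]
        while True:
            kids = children.get(run[-1], [])
            if len(kids) == 1 and by_id[kids[0]][1] == by_id[run[-1]][1]:
                run.append(kids[0])
            else:
                break
        t = by_id[run[0]][1]
        base = type_names.get(t, f"type{t}")
        counter[base] = counter.get(base, 0) + 1
        name = f"{base}[{counter[base]}]"
        pts = [by_id[i] for i in run]
        length = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            length += math.dist(a[2:5], b[2:5])
        length = max(length, 1.0)
        diam = 2.0 * float(np.mean([p[5] for p in pts]))
        sections.append(
            SectionSpec(name, length, diam, parent=parent_sec)
        )
        for i in run:
            sec_of_node[i] = name
        for kid in children.get(run[-1], []):
            if kid not in sec_of_node:
                walk(kid, (name, 1.0))

    roots = children.get(-1, [])
    if not roots:
        raise ValueError("SWC file has no root node")
    walk(roots[0], None)
    return Cell(sections, name="swc_cell", meta={"source": str(path)})
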