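"""Configuration, serialization and result writing.

A run configuration is a YAML document with ``cell``, ``stimuli``, ``run``,
``analysis`` and ``output`` blocks.  All analysis defaults equal the mechanism's
conventional values (-10 mV detection thresholds, (-1, +5) ms coincidence
window, 20/100 V/s derivative thresholds with a 2-ms window, 5-ms pre-event
slope window).  Unknown keys are schema errors that name the offending key.

Results are written as an HDF5 trace container (group ``/traces``, one
dataset per channel, with dt/site attributes), a CSV event table, and a JSON
manifest recording the config hash, seed, package versions and every file
written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from spikelet_lab.cells import (
    ReducedCellParams,
    build_axon_on_dendrite_cell,
    build_coupled_pair,
    build_passive_validation_cell,
    build_reduced_cell,
    freeze_fast_inactivation,
)
from spikelet_lab.engine import Cell
from spikelet_lab.passive import PassiveCellParams
from spikelet_lab.stimuli import (
    CurrentStep,
    EPSGParams,
    EPSGTrain,
    OUConductance,
    OUConductanceParams,
    PulseTrain,
    PulseTrainParams,
    SineCurrent,
)
from spikelet_lab.traces import TraceSet

__all__ = [
    "AnalysisConfig",
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "build_cell",
    "build_stimuli",
    "write_results",
    "read_traces",
]


class ConfigError(ValueError):
    """Schema violation, naming the offending key and constraint."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Event-analysis thresholds (conventional defaults, see docs/methods.md)."""

    thr: float = -10.0  # mV, AIS and soma detection threshold
    window: tuple[float, float] = (-1.0, 5.0)  # ms, AP coincidence window
    dvdt_thr1: float = 20.0  # V/s
    dvdt_thr2: float = 100.0  # V/s
    dvdt_window: float = 2.0  # ms
    slope_window: float = 5.0  # ms
    merge_ms: float = 3.0
    evoked_window: float = 2.0  # ms
    background_min: float = 10.0  # ms


@dataclass(frozen=True)
class RunBlock:
    dt: float = 0.025
    T: float = 1000.0
    v_init: float = -70.0
    seed: int = 0
    record: tuple[str, ...] = ("soma:0.5", "distal_ais:0.5", "axon:0.95")


@dataclass
class RunConfig:
    cell: dict = field(default_factory=lambda: {"kind": "reduced"})
    stimuli: list = field(default_factory=list)
    run: RunBlock = field(default_factory=RunBlock)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cell": self.cell,
            "stimuli": self.stimuli,
            "run": dataclasses.asdict(self.run),
            "analysis": dataclasses.asdict(self.analysis),
            "output": self.output,
        }

    def config_hash(self) -> str:
        text = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    for key in block:
        if key not in allowed:
            raise ConfigError(
                f"unknown key {key!r} in {where!r}; allowed: {sorted(allowed)}"
            )


def _build_block(cls, block: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(block, fields, where)
    kwargs = dict(block)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str | Path | dict) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing blocks and keys fall back to the documented defaults; unknown
    keys raise :class:`ConfigError` naming the key.
    """
    raw = path if isinstance(path, dict) else yaml.safe_load(Path(path).read_text())
    raw = raw or {}
    _check_keys(raw, {"cell", "stimuli", "run", "analysis", "output"}, "config")
    cell = raw.get("cell", {"kind": "reduced"})
    if "kind" not in cell:
        raise ConfigError("cell block requires a 'kind' key")
    stimuli = raw.get("stimuli", [])
    for i, s in enumerate(stimuli):
        if "kind" not in s:
            raise ConfigError(f"stimuli[{i}] requires a 'kind' key")
    run = _build_block(RunBlock, raw.get("run", {}), "run")
    analysis = _build_block(AnalysisConfig, raw.get("analysis", {}), "analysis")
    return RunConfig(
        cell=cell, stimuli=stimuli, run=run, analysis=analysis,
        output=raw.get("output", {}),
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(cfg.to_dict()), sort_keys=True))


_CELL_PARAM_CLASSES = {
    "reduced": ReducedCellParams,
    "axon_on_dendrite": ReducedCellParams,
    "coupled_pair": ReducedCellParams,
    "passive_validation": PassiveCellParams,
}


def build_cell(block: dict) -> Cell:
    """Instantiate the cell described by a config ``cell`` block."""
    kind = block["kind"]
    if kind not in _CELL_PARAM_CLASSES:
        raise ConfigError(
            f"unknown cell kind {kind!r}; allowed: {sorted(_CELL_PARAM_CLASSES)}"
        )
    pcls = _CELL_PARAM_CLASSES[kind]
    params = _build_block(pcls, block.get("params", {}), f"cell.params({kind})")
    if kind == "reduced":
        cell = build_reduced_cell(params)
    elif kind == "axon_on_dendrite":
        cell = build_axon_on_dendrite_cell(
            params, block.get("attach_distance_um", 20.0)
        )
    elif kind == "coupled_pair":
        cell = build_coupled_pair(
            build_reduced_cell(params),
            R_gj=block.get("R_gj_MOhm", 50.0),
            site=block.get("gj_site", "soma:0.5"),
            E_leak=block.get("E_leak", -80.0),
        )
    else:
        cell = build_passive_validation_cell(params)
    if block.get("freeze_inactivation", False):
        cell = freeze_fast_inactivation(
            cell, at_mV=block.get("freeze_at_mV", -70.0)
        )
    return cell


_STIM_CLASSES = {
    "ou_background": (OUConductance, OUConductanceParams),
    "current_step": (CurrentStep, None),
    "sine_current": (SineCurrent, None),
    "pulse_train": (PulseTrain, PulseTrainParams),
    "epsg_train": (EPSGTrain, EPSGParams),
}


def build_stimuli(blocks: list[dict]) -> list:
    """Instantiate stimulus objects from config ``stimuli`` blocks."""
    out = []
    for i, block in enumerate(blocks):
        kind = block.get("kind")
        if kind not in _STIM_CLASSES:
            raise ConfigError(
                f"unknown stimulus kind {kind!r} in stimuli[{i}]; "
                f"allowed: {sorted(_STIM_CLASSES)}"
            )
        cls, pcls = _STIM_CLASSES[kind]
        kwargs = {k: v for k, v in block.items() if k != "kind"}
        if pcls is not None and "params" in kwargs:
            kwargs["params"] = _build_block(
                pcls, kwargs["params"], f"stimuli[{i}].params"
            )
        fields = {f.name for f in dataclasses.fields(cls)}
        _check_keys(kwargs, fields, f"stimuli[{i}]({kind})")
        out.append(cls(**kwargs))
    return out


def stimulus_to_dict(stim) -> dict:
    """Serialize a stimulus object back to its config block."""
    for kind, (cls, _) in _STIM_CLASSES.items():
        if isinstance(stim, cls):
            d = _jsonable(dataclasses.asdict(stim))
            d["kind"] = kind
            return d
    raise ValueError(f"unserializable stimulus {type(stim).__name__}")


# ---------------------------------------------------------------------------
# results


def write_traces(traces: TraceSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("traces")
        grp.attrs["dt"] = traces.dt
        for name, vals in traces.channels.items():
            ds = grp.create_dataset(name, data=vals)
            if name in traces.sites:
                ds.attrs["site"] = traces.sites[name]
        meta = f.create_group("meta")
        meta.attrs["json"] = json.dumps(_jsonable(traces.meta))


def read_traces(path: str | Path) -> TraceSet:
    with h5py.File(path, "r") as f:
        grp = f["traces"]
        out = TraceSet(dt=float(grp.attrs["dt"]))
        for name in grp:
            out.channels[name] = grp[name][...]
            if "site" in grp[name].attrs:
                out.sites[name] = str(grp[name].attrs["site"])
        out.meta = json.loads(f["meta"].attrs["json"])
    return out


def write_results(
    traces: TraceSet | None,
    events,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict:
    """Write traces (HDF5), events (CSV) and a JSON manifest; return it."""
    import spikelet_lab

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    if traces is not None:
        write_traces(traces, out / "traces.h5")
        files.append("traces.h5")
    if events is not None:
        df = events.to_dataframe() if hasattr(events, "to_dataframe") else events
        df.to_csv(out / "events.csv", index=False)
        files.append("events.csv")
    manifest = {
        "package": "spikelet-lab",
        "version": spikelet_lab.__version__,
        "numpy": np.__version__,
        "config_hash": config.config_hash() if config else None,
        "seed": (config.run.seed if config else None),
        "files": files,
    }
    if config is not None:
        save_config(config, out / "config.yaml")
        manifest["files"].append("config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
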