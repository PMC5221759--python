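"""Uniformly sampled multi-channel time series with site metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TraceSet"]


@dataclass
class TraceSet:
    """A set of uniformly sampled traces sharing one time base.

    Channels are named arrays (voltages in mV, conductances in uS, currents
    in nA, gating states dimensionless).  ``sites`` maps a channel name to
    the ``"section:position"`` string of the recording site where one
    applies.
    """

    dt: float
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    sites: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must share one length")

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return len(next(iter(self.channels.values())))

    @property
    def t(self) -> np.ndarray:
        """Time base in ms, starting at 0."""
        return np.arange(self.n_samples) * self.dt

    @property
    def duration(self) -> float:
        return max(self.n_samples - 1, 0) * self.dt

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def add(self, name: str, values: np.ndarray, site: str | None = None) -> None:
        values = np.asarray(values, dtype=float)
        if self.channels and len(values) != self.n_samples:
            raise ValueError(
                f"channel {name!r} length {len(values)} != {self.n_samples}"
            )
        self.channels[name] = values
        if site is not None:
            self.sites[name] = site

    def index_of(self, t_ms: float) -> int:
        return int(round(t_ms / self.dt))

    def window(self, t0: float, t1: float) -> "TraceSet":
        """Sub-TraceSet covering [t0, t1] ms (inclusive sample range)."""
        i0 = max(self.index_of(t0), 0)
        i1 = min(self.index_of(t1), self.n_samples - 1)
        out = TraceSet(dt=self.dt, sites=dict(self.sites), meta=dict(self.meta))
        for name, vals in self.channels.items():
            out.channels[name] = vals[i0 : i1 + 1].copy()
        out.meta["t_offset"] = i0 * self.dt + self.meta.get("t_offset", 0.0)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_ms": self.t})
        for name, vals in self.channels.items():
            df[name] = vals
        return df
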