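"""Uniformly sampled time series with a fixed 1-ms grid.

Every signal in the package -- light stimuli, cone voltages, calcium
drives, release rates, sensor traces -- is carried by :class:`Trace`.
The simulation timestep is fixed at 1 ms package-wide; times are in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The package-wide simulation timestep (ms).
DT_MS = 1.0

#: Allowed physical interpretations of a trace.
TRACE_KINDS = frozenset(
    {"luminance", "voltage_mV", "drive", "rate", "release", "fluorescence"}
)


class TraceError(ValueError):
    """Raised for malformed traces or incompatible trace operations."""


@dataclass
class Trace:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like
        Ordered samples, one per millisecond.
    kind : str
        One of :data:`TRACE_KINDS`.  Luminance traces must be binary
        (dark = 0, light = 1).
    t0 : float
        Time of the first sample (ms).
    dt : float
        Sample interval; must equal :data:`DT_MS`.
    """

    values: np.ndarray
    kind: str
    t0: float = 0.0
    dt: float = field(default=DT_MS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise TraceError("trace values must be one-dimensional")
        if self.kind not in TRACE_KINDS:
            raise TraceError(
                f"unknown trace kind {self.kind!r}; expected one of "
                f"{sorted(TRACE_KINDS)}"
            )
        if self.dt != DT_MS:
            raise TraceError(f"trace dt must be {DT_MS} ms, got {self.dt}")
        if self.kind == "luminance":
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise TraceError("luminance traces must be binary (0/1)")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration_ms(self) -> float:
        return self.dt * self.values.size

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Trace":
        """A copy carrying new samples on the same time grid."""
        return replace(self, values=np.asarray(values, float), kind=kind or self.kind)

    def shifted(self, offset_ms: float) -> "Trace":
        """The same samples translated in time by ``offset_ms``."""
        return replace(self, t0=self.t0 + offset_ms)

    # -- CSV interchange -------------------------------------------------

    def to_csv(self, path) -> None:
        """Write ``time_ms,value`` rows with a header."""
        pd.DataFrame({"time_ms": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, kind: str) -> "Trace":
        """Read a two-column ``time_ms,value`` file; 1-ms spacing enforced."""
        df = pd.read_csv(path)
        for col in ("time_ms", "value"):
            if col not in df.columns:
                raise TraceError(f"{path}: missing required column {col!r}")
        t = df["time_ms"].to_numpy(float)
        if t.size >= 2:
            steps = np.diff(t)
            if not np.allclose(steps, DT_MS, atol=1e-9):
                bad = int(np.argmax(np.abs(steps - DT_MS) > 1e-9))
                raise TraceError(
                    f"{path}: line {bad + 2}: sample spacing must be "
                    f"{DT_MS} ms, got {steps[bad]!r}"
                )
        return cls(values=df["value"].to_numpy(float), kind=kind, t0=float(t[0]) if t.size else 0.0)
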