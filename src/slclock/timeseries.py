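"""Uniformly sampled intensity traces.

:class:`TimeSeries` is the currency of the whole pipeline: simulated
oscillator output, synthetic fixtures and measured reporter traces all
travel through it.  Time is minutes from recording start, values are
arbitrary fluorescence-like units.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """A uniformly sampled intensity trace.

    Parameters
    ----------
    t : ndarray
        Sample times in minutes, strictly increasing with constant spacing.
    v : ndarray
        Intensity values (arbitrary units), finite.
    meta : dict
        Free-form provenance (cell id, rendering parameters, seeds ...).
    """

    t: np.ndarray
    v: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.v.ndim != 1:
            raise ValueError("t and v must be one-dimensional")
        if self.t.size != self.v.size:
            raise ValueError("t and v must have equal length")
        if self.t.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("t must be uniformly spaced")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("v contains non-finite values")

    @property
    def dt_sample(self) -> float:
        """Sampling interval in minutes."""
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Total span of the trace in minutes."""
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size

    @classmethod
    def from_values(cls, v, dt_sample: float, t0: float = 0.0,
                    meta: dict | None = None) -> "TimeSeries":
        """Build a trace from values and a sampling interval."""
        v = np.asarray(v, dtype=float)
        t = t0 + dt_sample * np.arange(v.size)
        return cls(t, v, meta or {})

    def copy_with(self, v=None, meta: dict | None = None) -> "TimeSeries":
        """Return a copy, optionally replacing values and/or merging metadata."""
        new_meta = dict(self.meta)
        if meta:
            new_meta.update(meta)
        return TimeSeries(self.t.copy(),
                          self.v.copy() if v is None else np.asarray(v, float),
                          new_meta)
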