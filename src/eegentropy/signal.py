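"""Basic single-channel signal container shared by all stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Signal", "as_samples"]


@dataclass
class Signal:
    """A labeled 1-D sample sequence with an optional sampling rate.

    Parameters
    ----------
    samples
        Amplitude values (arbitrary units, e.g. µV or ADC counts). Stored
        as a float64 array; must be finite.
    fs
        Sampling rate in Hz, if known.
    label
        Optional class tag (any hashable).
    meta
        Free-form provenance (file path, channel, generator seed, ...).
    """

    samples: np.ndarray
    fs: float | None = None
    label: Any = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size == 0:
            raise ValueError("Signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Signal samples must be finite reals")
        if self.fs is not None and self.fs <= 0:
            raise ValueError(f"Sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float | None:
        return None if self.fs is None else self.samples.size / self.fs


def as_samples(x: "Signal | np.ndarray | list") -> np.ndarray:
    """Coerce a Signal or array-like to a finite 1-D float64 array."""
    if isinstance(x, Signal):
        return x.samples
    arr = np.asarray(x, dtype=np.float64).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError("samples must be finite reals")
    return arr
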