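"""Multiscale extensions of ASPE: coarse-graining and time-shift families.

Two complementary scale families probe complexity beyond the native
sampling rate:

* **RCMASPE** (refined composite multiscale ASPE): at scale s the series
  is coarse-grained into s phase-shifted subsequences of non-overlapping
  window averages; their amplitude-weighted pattern distributions are
  averaged *before* taking the entropy (the "refined composite" recipe,
  which stabilizes the estimate at large scales where each subsequence is
  short).
* **TSMASPE** (time-shift multiscale ASPE): at lag k the series is
  decimated into the k interleaved subsequences (x_j, x_{j+k}, ...) and
  the ASPE values of the subsequences are averaged.

Both profiles reduce exactly to plain ASPE at scale/lag 1.
"""

from __future__ import annotations

import numpy as np

from .entropy import (
    EmbeddingConfig,
    aspe,
    entropy_from_probabilities,
    pattern_probabilities,
)
from .signal import as_samples

__all__ = [
    "MultiscaleConfig",
    "composite_coarse_grain",
    "rcmaspe",
    "time_shift_subsequences",
    "tsmaspe",
]


from dataclasses import dataclass


@dataclass(frozen=True)
class MultiscaleConfig:
    """Maximum coarse-graining scale and time-lag factor."""

    s_max: int = 10
    k_max: int = 10

    def __post_init__(self) -> None:
        if self.s_max < 1 or self.k_max < 1:
            raise ValueError("s_max and k_max must be >= 1")


def composite_coarse_grain(x, s: int, min_length: int = 2) -> list[np.ndarray]:
    """The s phase-shifted coarse-grained subsequences at scale s.

    Subsequence k (k = 1..s) has element j = mean(x_{(j-1)s+k} ... x_{js+k-1})
    (1-based indices); trailing samples that do not fill a window are
    dropped.  ``min_length`` is the shortest admissible subsequence (the
    embedding minimum of the downstream entropy).
    """
    samples = as_samples(x)
    T = samples.size
    if s < 1:
        raise ValueError(f"scale must be >= 1, got {s}")
    shortest = (T - s + 1) // s
    if shortest < min_length:
        raise ValueError(
            f"scale {s} too large for series of length {T}: shortest "
            f"coarse-grained subsequence has {shortest} < {min_length} samples"
        )
    out = []
    for k in range(s):  # k here is the 0-based phase offset
        n_win = (T - k) // s
        seg = samples[k : k + n_win * s].reshape(n_win, s)
        out.append(seg.mean(axis=1))
    return out


def rcmaspe(x, ecfg: EmbeddingConfig | None = None, s_max: int = 10) -> np.ndarray:
    """Refined composite multiscale ASPE profile for scales 1..s_max.

    At each scale the m!-bin probability vectors of the s subsequences are
    averaged element-wise and the normalized Shannon entropy of the
    average is returned.  Entry 0 (scale 1) equals plain ASPE exactly.
    """
    ecfg = ecfg or EmbeddingConfig()
    samples = as_samples(x)
    profile = np.empty(s_max, dtype=np.float64)
    for s in range(1, s_max + 1):
        subs = composite_coarse_grain(samples, s, min_length=ecfg.min_length)
        probs = np.mean([pattern_probabilities(sub, ecfg) for sub in subs], axis=0)
        profile[s - 1] = entropy_from_probabilities(probs, ecfg.m)
    return profile


def time_shift_subsequences(x, k: int, min_length: int = 2) -> list[np.ndarray]:
    """The k interleaved subsequences (x_j, x_{j+k}, x_{j+2k}, ...), j = 1..k."""
    samples = as_samples(x)
    T = samples.size
    if k < 1:
        raise ValueError(f"lag must be >= 1, got {k}")
    shortest = (T - k) // k + 1
    if shortest < min_length:
        raise ValueError(
            f"lag {k} too large for series of length {T}: shortest "
            f"time-shifted subsequence has {shortest} < {min_length} samples"
        )
    return [samples[j::k] for j in range(k)]


def tsmaspe(x, ecfg: EmbeddingConfig | None = None, k_max: int = 10) -> np.ndarray:
    """Time-shift multiscale ASPE profile for lags 1..k_max.

    Entry k-1 is the mean ASPE over the k interleaved subsequences.
    Entry 0 (lag 1) equals plain ASPE exactly.
    """
    ecfg = ecfg or EmbeddingConfig()
    samples = as_samples(x)
    profile = np.empty(k_max, dtype=np.float64)
    for k in range(1, k_max + 1):
        subs = time_shift_subsequences(samples, k, min_length=ecfg.min_length)
        profile[k - 1] = float(np.mean([aspe(sub, ecfg) for sub in subs]))
    return profile
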