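"""Amplitude-sensitive permutation entropy (ASPE).

Classical permutation entropy symbolizes a time series by the ordinal
pattern (rank order) of each delay-embedded vector and takes the Shannon
entropy of the pattern frequencies, which discards all amplitude
information.  ASPE restores amplitude sensitivity by weighting each
embedded vector's contribution to its pattern frequency with the vector's
coefficient of variation (std/|mean|), so that epochs with large relative
amplitude fluctuations — e.g. epileptic spikes — dominate the
distribution.  The entropy of the weighted distribution is normalized by
log2(m!) so the result always lies in [0, 1].

Conventions (documented because the defining expressions leave them open):

* the coefficient of variation is guarded against (near-)zero means by
  flooring the denominator at ``1e-12 * signal range`` — zero-mean vectors
  are common in EEG and the plain definition would divide by zero;
* standard deviation uses the sample (n-1) denominator by default,
  switchable via :class:`EmbeddingConfig`;
* ordinal ties are broken by the earlier original index (stable sort);
* a constant signal has zero total weight; the distribution then falls
  back to unweighted pattern frequencies, yielding entropy 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .signal import Signal, as_samples

__all__ = [
    "EmbeddingConfig",
    "PatternDistribution",
    "embed",
    "ordinal_pattern",
    "ordinal_patterns",
    "amplitude_weight",
    "amplitude_weights",
    "weighted_pattern_distribution",
    "pattern_probabilities",
    "entropy_from_probabilities",
    "aspe",
]

#: relative floor applied to |mean| in the coefficient of variation
MEAN_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding parameters.

    m : embedding dimension (>= 2, <= 10 so that m! stays exact in float64)
    tau : time delay in samples (>= 1)
    sample_std : use the n-1 (sample) denominator in the amplitude weight
    """

    m: int = 3
    tau: int = 1
    sample_std: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 2):
            raise ValueError(f"embedding dimension m must be an integer >= 2, got {self.m}")
        if self.m > 10:
            raise ValueError(f"embedding dimension m must be <= 10, got {self.m}")
        if not (isinstance(self.tau, (int, np.integer)) and self.tau >= 1):
            raise ValueError(f"time delay tau must be an integer >= 1, got {self.tau}")

    @property
    def ddof(self) -> int:
        return 1 if self.sample_std else 0

    @property
    def min_length(self) -> int:
        """Shortest series admitting at least one embedded vector."""
        return (self.m - 1) * self.tau + 1

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.m)


@dataclass
class PatternDistribution:
    """Weighted relative frequencies over the m! ordinal patterns."""

    probabilities: np.ndarray  # length m!, indexed by lexicographic pattern rank
    counts: dict  # pattern tuple -> accumulated weight
    total_weight: float
    n_vectors: int
    m: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if np.any(p < 0):
            raise ValueError("pattern probabilities must be nonnegative")
        if self.n_vectors > 0 and abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("pattern probabilities must sum to 1")
        self.probabilities = p


def embed(x, cfg: EmbeddingConfig) -> np.ndarray:
    """Delay-embed ``x`` into N = T - (m-1)*tau vectors of length m.

    Row i is (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}) in original order.
    """
    samples = as_samples(x)
    T = samples.size
    if T < cfg.min_length:
        raise ValueError(
            f"series of length {T} is too short for embedding with m={cfg.m}, "
            f"tau={cfg.tau}; at least {cfg.min_length} samples are required"
        )
    n = T - (cfg.m - 1) * cfg.tau
    cols = [samples[i * cfg.tau : i * cfg.tau + n] for i in range(cfg.m)]
    return np.stack(cols, axis=1)


def ordinal_pattern(y) -> tuple:
    """Rank pattern of one vector: indices that sort it ascending.

    Ties are broken toward the earlier original index (stable sort).
    """
    arr = np.asarray(y, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("ordinal_pattern expects a 1-D vector")
    return tuple(int(i) for i in np.argsort(arr, kind="stable"))


def ordinal_patterns(vectors: np.ndarray) -> np.ndarray:
    """Stable argsort of every row: (N, m) integer pattern matrix."""
    return np.argsort(np.asarray(vectors, dtype=np.float64), axis=1, kind="stable")


def pattern_rank(pattern) -> int:
    """Lexicographic rank of a permutation of 0..m-1 (Lehmer code)."""
    p = list(pattern)
    m = len(p)
    rank = 0
    for i in range(m - 1):
        smaller = sum(1 for j in range(i + 1, m) if p[j] < p[i])
        rank += smaller * math.factorial(m - 1 - i)
    return rank


def _pattern_ranks(patterns: np.ndarray) -> np.ndarray:
    m = patterns.shape[1]
    ranks = np.zeros(patterns.shape[0], dtype=np.int64)
    for i in range(m - 1):
        smaller = (patterns[:, i + 1 :] < patterns[:, i : i + 1]).sum(axis=1)
        ranks += smaller * math.factorial(m - 1 - i)
    return ranks


def _mean_floor(samples: np.ndarray) -> float:
    rng = float(np.ptp(samples))
    return MEAN_FLOOR_REL * (rng if rng > 0 else 1.0)


def amplitude_weights(
    vectors: np.ndarray, ddof: int = 1, mean_floor: float = MEAN_FLOOR_REL
) -> np.ndarray:
    """Coefficient-of-variation weight of each row: std / max(|mean|, floor)."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if not np.all(np.isfinite(vectors)):
        raise ValueError("embedded vectors must contain finite values")
    std = vectors.std(axis=1, ddof=ddof)
    denom = np.maximum(np.abs(vectors.mean(axis=1)), mean_floor)
    return std / denom


def amplitude_weight(y, ddof: int = 1, mean_floor: float = MEAN_FLOOR_REL) -> float:
    """Amplitude weight of a single embedded vector."""
    arr = np.asarray(y, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("amplitude weight needs a 1-D vector with >= 2 elements")
    return float(amplitude_weights(arr[None, :], ddof=ddof, mean_floor=mean_floor)[0])


def weighted_pattern_distribution(vectors: np.ndarray, weights: np.ndarray) -> PatternDistribution:
    """Accumulate ordinal-pattern weights into relative frequencies.

    If the total weight is zero (e.g. a constant signal, where every CV is
    zero) the distribution falls back to unweighted relative frequencies.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if vectors.shape[0] != weights.shape[0]:
        raise ValueError("vectors and weights must have equal counts")
    if np.any(weights < 0):
        raise ValueError("pattern weights must be nonnegative")
    m = vectors.shape[1]
    patterns = ordinal_patterns(vectors)
    ranks = _pattern_ranks(patterns)
    sums = np.bincount(ranks, weights=weights, minlength=math.factorial(m))
    # normalize by the binned sum itself so a single-pattern series gets
    # probability exactly 1 (summation order matches the numerator)
    total = float(sums.sum())
    if total > 0:
        probs = sums / total
    else:
        sums = np.bincount(ranks, minlength=math.factorial(m)).astype(np.float64)
        probs = sums / vectors.shape[0]
    counts: dict = {}
    for row, r in zip(patterns, ranks):
        counts[tuple(int(v) for v in row)] = float(sums[r])
    return PatternDistribution(
        probabilities=probs,
        counts=counts,
        total_weight=total,
        n_vectors=int(vectors.shape[0]),
        m=m,
    )


def pattern_probabilities(x, cfg: EmbeddingConfig) -> np.ndarray:
    """m!-vector of amplitude-weighted ordinal-pattern probabilities."""
    samples = as_samples(x)
    vectors = embed(samples, cfg)
    weights = amplitude_weights(vectors, ddof=cfg.ddof, mean_floor=_mean_floor(samples))
    return weighted_pattern_distribution(vectors, weights).probabilities


def entropy_from_probabilities(p: np.ndarray, m: int) -> float:
    """Normalized Shannon entropy: -sum p log2 p / log2(m!), with 0 log 0 = 0."""
    p = np.asarray(p, dtype=np.float64)
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log2(nz)))
    value = h / math.log2(math.factorial(m))
    # clip float round-off only; the mathematical range is [0, 1]
    return float(min(max(value, 0.0), 1.0)) + 0.0


def aspe(x, cfg: EmbeddingConfig | None = None) -> float:
    """Amplitude-sensitive permutation entropy of a series, in [0, 1].

    0 means a single ordinal pattern (e.g. any strictly monotone series);
    1 means all m! patterns carry equal weight (e.g. iid noise at large T).
    Invariant under positive rescaling of the input.
    """
    cfg = cfg or EmbeddingConfig()
    return entropy_from_probabilities(pattern_probabilities(x, cfg), cfg.m)
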