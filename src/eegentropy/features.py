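"""Assembly of the multi-domain entropy (MDE) feature set.

A signal is summarized by three grouped vectors, one per classifier
pathway:

* ``x_m`` — multiscale pathway: plain ASPE followed by the RCMASPE
  profile (dimension 1 + s_max, 11 by default);
* ``x_h`` — hierarchical pathway: the per-wavelet-band ASPE vector
  (dimension L + 1, 5 by default);
* ``x_t`` — time-invariant pathway: the TSMASPE profile (dimension
  k_max, 10 by default).

Every entry is an entropy in [0, 1] before standardization.  A leak-free
z-scoring standardizer (fit on training folds only) is provided because
the classifier's gating nonlinearities are scale-sensitive; it can be
switched off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .entropy import EmbeddingConfig, aspe
from .multiscale import rcmaspe, tsmaspe
from .signal import Signal, as_samples
from .wavelet import WaveletConfig, haspe_dwt

__all__ = [
    "FeatureConfig",
    "MDEFeatureVector",
    "FeatureBatch",
    "Standardizer",
    "extract_mde",
    "extract_batch",
    "stack_features",
    "write_feature_csv",
    "read_feature_csv",
]

logger = logging.getLogger(__name__)

SCALE_FLOOR = 1e-12


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the full MDE extractor (defaults: 173.61 Hz profile)."""

    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    s_max: int = 10
    k_max: int = 10
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)

    @property
    def d_m(self) -> int:
        return 1 + self.s_max

    @property
    def d_h(self) -> int:
        return self.wavelet.level + 1

    @property
    def d_t(self) -> int:
        return self.k_max

    @classmethod
    def bonn(cls) -> "FeatureConfig":
        """Profile for 4097-sample, 173.61 Hz segments (wavelet level 4)."""
        return cls()

    @classmethod
    def chbmit(cls) -> "FeatureConfig":
        """Profile for 256 Hz recordings (wavelet level 5)."""
        return cls(wavelet=WaveletConfig(level=5))


@dataclass
class MDEFeatureVector:
    """The three grouped pathway inputs extracted from one signal."""

    x_m: np.ndarray
    x_h: np.ndarray
    x_t: np.ndarray
    label: Any = None


@dataclass
class FeatureBatch:
    """Stacked pathway matrices for n samples (rows align across blocks)."""

    x_m: np.ndarray  # (n, d_m)
    x_h: np.ndarray  # (n, d_h)
    x_t: np.ndarray  # (n, d_t)
    labels: np.ndarray | None = None

    def __len__(self) -> int:
        return self.x_m.shape[0]

    def subset(self, idx) -> "FeatureBatch":
        idx = np.asarray(idx)
        labels = None if self.labels is None else self.labels[idx]
        return FeatureBatch(self.x_m[idx], self.x_h[idx], self.x_t[idx], labels)


def extract_mde(x, cfg: FeatureConfig | None = None) -> MDEFeatureVector:
    """Extract the grouped MDE feature vector of one signal.

    Deterministic for fixed input and config; invariant under positive
    rescaling of the signal (every component is).
    """
    cfg = cfg or FeatureConfig()
    samples = as_samples(x)
    label = x.label if isinstance(x, Signal) else None
    try:
        base = aspe(samples, cfg.embedding)
        multiscale = rcmaspe(samples, cfg.embedding, cfg.s_max)
    except ValueError as exc:
        raise ValueError(f"multiscale (ASPE/RCMASPE) extraction failed: {exc}") from exc
    try:
        hierarchical = haspe_dwt(samples, cfg.embedding, cfg.wavelet)
    except ValueError as exc:
        raise ValueError(f"hierarchical (wavelet-band ASPE) extraction failed: {exc}") from exc
    try:
        time_shift = tsmaspe(samples, cfg.embedding, cfg.k_max)
    except ValueError as exc:
        raise ValueError(f"time-shift (TSMASPE) extraction failed: {exc}") from exc
    return MDEFeatureVector(
        x_m=np.concatenate(([base], multiscale)),
        x_h=hierarchical,
        x_t=time_shift,
        label=label,
    )


def stack_features(vectors: Sequence[MDEFeatureVector]) -> FeatureBatch:
    if not vectors:
        raise ValueError("cannot stack an empty feature collection")
    labels = [v.label for v in vectors]
    return FeatureBatch(
        x_m=np.stack([v.x_m for v in vectors]),
        x_h=np.stack([v.x_h for v in vectors]),
        x_t=np.stack([v.x_t for v in vectors]),
        labels=None if all(l is None for l in labels) else np.asarray(labels),
    )


def extract_batch(signals: Sequence, cfg: FeatureConfig | None = None) -> FeatureBatch:
    """Extract and stack features for a collection of signals."""
    return stack_features([extract_mde(sig, cfg) for sig in signals])


@dataclass
class Standardizer:
    """Per-feature z-scoring stats, fit on training data only.

    Scales are floored at 1e-12, so a constant training column maps to
    all zeros rather than NaN.
    """

    mean_m: np.ndarray
    scale_m: np.ndarray
    mean_h: np.ndarray
    scale_h: np.ndarray
    mean_t: np.ndarray
    scale_t: np.ndarray

    @classmethod
    def fit(cls, batch: FeatureBatch) -> "Standardizer":
        if len(batch) < 2:
            raise ValueError("standardizer needs at least 2 training samples")
        stats = {}
        for name in ("m", "h", "t"):
            block = getattr(batch, f"x_{name}")
            mean = block.mean(axis=0)
            scale = block.std(axis=0, ddof=0)
            degenerate = scale <= SCALE_FLOOR
            if np.any(degenerate):
                logger.warning(
                    "%d degenerate (constant) feature column(s) in block %s; scale floored",
                    int(degenerate.sum()),
                    name,
                )
            stats[f"mean_{name}"] = mean
            stats[f"scale_{name}"] = np.maximum(scale, SCALE_FLOOR)
        return cls(**stats)

    def transform(self, batch: FeatureBatch) -> FeatureBatch:
        out = {}
        for name in ("m", "h", "t"):
            mean = getattr(self, f"mean_{name}")
            scale = getattr(self, f"scale_{name}")
            z = (getattr(batch, f"x_{name}") - mean) / scale
            # columns that were constant in training carry no signal
            z[:, scale <= SCALE_FLOOR] = 0.0
            out[f"x_{name}"] = z
        return FeatureBatch(labels=batch.labels, **out)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k).tolist()
            for k in ("mean_m", "scale_m", "mean_h", "scale_h", "mean_t", "scale_t")
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(**{k: np.asarray(v, dtype=np.float64) for k, v in d.items()})


def fit_standardizer(batch: FeatureBatch) -> Standardizer:
    return Standardizer.fit(batch)


def apply_standardizer(batch: FeatureBatch, stats: Standardizer) -> FeatureBatch:
    return stats.transform(batch)


def _column_names(d_m: int, d_h: int, d_t: int) -> list[str]:
    return (
        [f"m_{i}" for i in range(d_m)]
        + [f"h_{i}" for i in range(d_h)]
        + [f"t_{i}" for i in range(1, d_t + 1)]
    )


def write_feature_csv(path, batch: FeatureBatch) -> None:
    """Feature table: columns m_0..m_{dm-1}, h_0..h_{dh-1}, t_1..t_{dt}, label."""
    cols = _column_names(batch.x_m.shape[1], batch.x_h.shape[1], batch.x_t.shape[1])
    data = np.hstack([batch.x_m, batch.x_h, batch.x_t])
    df = pd.DataFrame(data, columns=cols)
    df["label"] = batch.labels if batch.labels is not None else ""
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_csv(path) -> FeatureBatch:
    df = pd.read_csv(path, float_precision="round_trip")
    m_cols = [c for c in df.columns if c.startswith("m_")]
    h_cols = [c for c in df.columns if c.startswith("h_")]
    t_cols = [c for c in df.columns if c.startswith("t_")]
    if not (m_cols and h_cols and t_cols):
        raise ValueError(f"{path} is not a valid feature table (missing m_/h_/t_ columns)")
    labels = None
    if "label" in df.columns and not df["label"].isna().all():
        labels = df["label"].to_numpy()
    return FeatureBatch(
        x_m=df[m_cols].to_numpy(dtype=np.float64),
        x_h=df[h_cols].to_numpy(dtype=np.float64),
        x_t=df[t_cols].to_numpy(dtype=np.float64),
        labels=labels,
    )
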