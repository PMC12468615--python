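"""Seed-deterministic generator of EEG-like signals with class structure.

The generator emulates the two regimes that matter for seizure-detection
benchmarks, without any physiological pretension:

* **background** (healthy/interictal-like): zero-mean 1/f^α colored
  noise (α ≈ 1, the standard stylized spectral fact for resting EEG) —
  broadband, disordered, high ordinal complexity;
* **ictal-like**: the same background plus a sustained ~3 Hz spike-wave
  train (a sharp spike followed by a slow wave each cycle) whose RMS is a
  configurable multiple of the background RMS — high-amplitude, rhythmic,
  low ordinal complexity.

An intermediate **interictal-like** class (background plus sparse
isolated spikes) completes a three-class preset.  Every signal derives
its own integer seed from the master seed, recorded in a manifest so the
dataset can be regenerated bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .signal import Signal

__all__ = [
    "ClassSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_background",
    "generate_ictal",
    "generate_signal",
    "generate_dataset",
    "dataset_from_manifest",
]


@dataclass(frozen=True)
class ClassSpec:
    """One signal class.

    alpha          : spectral exponent of the 1/f^α background
    rhythm_hz      : spike-wave repetition rate (0 disables the rhythm)
    rhythm_ratio   : RMS(rhythmic component) / RMS(background)
    spike_rate     : isolated-spike events per second (0 disables)
    spike_amplitude: isolated-spike peak in background-SD units
    """

    name: str
    alpha: float = 1.0
    rhythm_hz: float = 0.0
    rhythm_ratio: float = 0.0
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 4.0:
            raise ValueError(f"invalid spectral exponent alpha={self.alpha}; need 0..4")
        if self.rhythm_ratio < 0 or self.spike_rate < 0 or self.spike_amplitude < 0:
            raise ValueError("amplitude ratios and rates must be nonnegative")


BACKGROUND = ClassSpec(name="background")
INTERICTAL = ClassSpec(name="interictal", spike_rate=0.5, spike_amplitude=4.0)
ICTAL = ClassSpec(name="ictal", rhythm_hz=3.0, rhythm_ratio=2.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Dataset-level settings (defaults: 23.6 s segments at 173.61 Hz)."""

    fs: float = 173.61
    duration_s: float = 23.6
    n_per_class: int = 100
    seed: int = 0
    classes: tuple[ClassSpec, ...] = (BACKGROUND, ICTAL)

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration must be positive")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for spec in self.classes:
            if spec.rhythm_hz > self.fs / 2:
                raise ValueError(
                    f"rhythm frequency {spec.rhythm_hz} Hz exceeds Nyquist {self.fs / 2} Hz"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    @classmethod
    def two_class(cls, **kwargs) -> "SyntheticConfig":
        return cls(classes=(BACKGROUND, ICTAL), **kwargs)

    @classmethod
    def three_class(cls, **kwargs) -> "SyntheticConfig":
        return cls(classes=(BACKGROUND, INTERICTAL, ICTAL), **kwargs)


def _colored_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-SD 1/f^α noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = spec * shaping
    spec[0] = 0.0  # enforce zero mean
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _spike_wave_train(n: int, fs: float, f0: float, rng: np.random.Generator) -> np.ndarray:
    """One sharp spike plus a slow opposing wave per cycle, with mild
    cycle-to-cycle amplitude jitter; zero-mean, unit RMS."""
    t = np.arange(n) / fs
    cycle_idx = np.floor(t * f0).astype(np.int64)
    phase = t * f0 - cycle_idx
    # spike ~60 ms FWHM at 3 Hz, followed by a dominant slow half-wave:
    # the classic sharp-transient-plus-slow-wave morphology
    spike = np.exp(-0.5 * ((phase - 0.15) / 0.08) ** 2)
    wave = -0.9 * np.sin(np.pi * np.clip((phase - 0.30) / 0.65, 0.0, 1.0))
    jitter = 1.0 + 0.1 * rng.standard_normal(int(cycle_idx.max()) + 1)
    train = (spike + wave) * jitter[cycle_idx]
    train = train - train.mean()
    rms = np.sqrt(np.mean(train**2))
    return train / rms if rms > 0 else train


def _sparse_spikes(
    n: int, fs: float, rate: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Isolated biphasic transients at Poisson event times."""
    out = np.zeros(n)
    n_events = rng.poisson(rate * n / fs)
    if n_events == 0:
        return out
    centers = np.sort(rng.integers(0, n, size=n_events))
    half = max(int(0.035 * fs), 2)  # ~70 ms wide transient
    k = np.arange(-half, half + 1)
    shape = np.exp(-0.5 * (k / (half / 2.5)) ** 2) - 0.4 * np.exp(
        -0.5 * ((k - half / 2) / half) ** 2
    )
    for c in centers:
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        out[lo:hi] += amplitude * shape[lo - (c - half) : hi - (c - half)]
    return out


def generate_signal(cfg: SyntheticConfig, spec: ClassSpec, seed: int) -> Signal:
    """One signal of the given class; deterministic per (config, seed)."""
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    bg = _colored_noise(n, spec.alpha, rng)
    samples = bg.copy()
    if spec.rhythm_hz > 0 and spec.rhythm_ratio > 0:
        bg_rms = np.sqrt(np.mean(bg**2))
        samples = samples + spec.rhythm_ratio * bg_rms * _spike_wave_train(
            n, cfg.fs, spec.rhythm_hz, rng
        )
    if spec.spike_rate > 0 and spec.spike_amplitude > 0:
        samples = samples + bg.std() * _sparse_spikes(
            n, cfg.fs, spec.spike_rate, 1.0, rng
        ) * spec.spike_amplitude
    return Signal(
        samples=samples,
        fs=cfg.fs,
        label=spec.name,
        meta={"class": spec.name, "seed": int(seed)},
    )


def generate_background(cfg: SyntheticConfig, seed: int, alpha: float = 1.0) -> Signal:
    """Zero-mean 1/f^α background noise segment."""
    return generate_signal(cfg, ClassSpec(name="background", alpha=alpha), seed)


def generate_ictal(cfg: SyntheticConfig, seed: int, spec: ClassSpec = ICTAL) -> Signal:
    """Background plus a sustained spike-wave rhythm."""
    return generate_signal(cfg, spec, seed)


@dataclass
class SyntheticDataset:
    signals: list[Signal]
    labels: np.ndarray  # integer class indices, aligned with signals
    class_names: list[str]
    manifest: dict


def _build_manifest(cfg: SyntheticConfig, records: list[dict]) -> dict:
    return {
        "config": {
            "fs": cfg.fs,
            "duration_s": cfg.duration_s,
            "n_per_class": cfg.n_per_class,
            "seed": cfg.seed,
            "classes": [asdict(spec) for spec in cfg.classes],
        },
        "signals": records,
    }


def generate_dataset(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """n-per-class labeled signals in stable order (class-major).

    Per-signal seeds are drawn once from the master seed and recorded in
    the manifest, so ``dataset_from_manifest`` reproduces the dataset
    bit-identically.
    """
    cfg = cfg or SyntheticConfig()
    n_total = cfg.n_per_class * len(cfg.classes)
    sig_seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=n_total)
    signals, labels, records = [], [], []
    i = 0
    for ci, spec in enumerate(cfg.classes):
        for _ in range(cfg.n_per_class):
            seed = int(sig_seeds[i])
            signals.append(generate_signal(cfg, spec, seed))
            labels.append(ci)
            records.append({"index": i, "class": spec.name, "class_index": ci, "seed": seed})
            i += 1
    return SyntheticDataset(
        signals=signals,
        labels=np.asarray(labels),
        class_names=[spec.name for spec in cfg.classes],
        manifest=_build_manifest(cfg, records),
    )


def dataset_from_manifest(manifest: dict) -> SyntheticDataset:
    """Regenerate a dataset bit-identically from its manifest."""
    c = manifest["config"]
    cfg = SyntheticConfig(
        fs=c["fs"],
        duration_s=c["duration_s"],
        n_per_class=c["n_per_class"],
        seed=c["seed"],
        classes=tuple(ClassSpec(**spec) for spec in c["classes"]),
    )
    specs = {spec.name: spec for spec in cfg.classes}
    signals, labels = [], []
    for rec in manifest["signals"]:
        signals.append(generate_signal(cfg, specs[rec["class"]], rec["seed"]))
        labels.append(rec["class_index"])
    return SyntheticDataset(
        signals=signals,
        labels=np.asarray(labels),
        class_names=[spec.name for spec in cfg.classes],
        manifest=manifest,
    )
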