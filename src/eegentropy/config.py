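"""Run configuration: a YAML/JSON-serializable bundle of all defaults.

Defaults follow the standard operating point of the method: embedding
m=3, τ=1; maximum coarse-graining scale 10; db4 wavelet at level 4
(173.61 Hz profile) or 5 (256 Hz profile); maximum time lag 10; pathway
width 16, fusion width 32; quasi-Newton training capped at 50 iterations
and 10^6 function evaluations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifier import TrainingConfig
from .entropy import EmbeddingConfig
from .features import FeatureConfig
from .wavelet import WaveletConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a full extract→train→evaluate run."""

    # entropy / feature block
    m: int = 3
    tau: int = 1
    s_max: int = 10
    k_max: int = 10
    wavelet_basis: str = "db4"
    wavelet_level: int = 4
    sample_std: bool = True

    # classifier block
    hidden_pathway: int = 16
    hidden_fusion: int = 32
    max_iterations: int = 50
    max_function_evaluations: int = 1_000_000
    standardize: bool = True

    # cross-validation block
    n_folds: int = 10
    shuffle: bool = False

    seed: int = 0

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            embedding=EmbeddingConfig(m=self.m, tau=self.tau, sample_std=self.sample_std),
            s_max=self.s_max,
            k_max=self.k_max,
            wavelet=WaveletConfig(basis=self.wavelet_basis, level=self.wavelet_level),
        )

    def training_config(self, seed: int | None = None) -> TrainingConfig:
        return TrainingConfig(
            max_iterations=self.max_iterations,
            max_function_evaluations=self.max_function_evaluations,
            seed=self.seed if seed is None else seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown configuration field(s): {sorted(unknown)}; known: {sorted(known)}"
            )
        cfg = cls(**d)
        # construction of the sub-configs validates ranges with field paths
        try:
            cfg.feature_config()
            cfg.training_config()
        except ValueError as exc:
            raise ValueError(f"invalid configuration: {exc}") from exc
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                data = yaml.safe_load(fh)
            else:
                data = json.load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_dict(data)

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, sort_keys=True, indent=1)
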