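"""Dynamic-synapse classifier: three gated pathways with learned fusion.

The network mirrors the grouped structure of the MDE feature set instead
of flattening it.  Each pathway applies an input-dependent multiplicative
gate ("dynamic synapse") before a small fully connected compression:

* hierarchical pathway (wavelet-band entropies x_h):
  ``G_h = tanh(x_h ⊙ W_h_att)``, ``x_h' = x_h ⊙ G_h`` — frequency-band
  attention whose strength depends on the band entropies themselves;
* time-invariant pathway (time-shift entropies x_t):
  ``g_t = exp(-γ · Var(x_t))``, ``x_t' = g_t · x_t`` with learnable γ > 0
  — a scalar gain that passes stable (low-variance) lag profiles and
  suppresses erratic ones;
* multiscale pathway (ASPE + coarse-grained profile x_m):
  ``x_m' = x_m ⊙ W_m_att`` — a static learned scale mask.

Each gated vector feeds a tanh layer of width ``hidden_pathway``; the
three pathway codes are concatenated, passed through one tanh fusion
layer of width ``hidden_fusion`` and a linear layer to K logits, and
softmax yields class posteriors.  All parameters (gates included) are
trained jointly by full-batch quasi-Newton (L-BFGS) minimization of the
cross-entropy, with an analytic gradient derived by hand below; γ > 0 is
enforced by a softplus reparameterization so the search stays
unconstrained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .features import FeatureBatch

__all__ = [
    "DySCConfig",
    "TrainingConfig",
    "DySCParameters",
    "ForwardTrace",
    "gate_hierarchical",
    "gate_time_invariant",
    "gate_multiscale",
    "pathway_fuse",
    "softmax",
    "forward",
    "cross_entropy",
    "loss_and_gradient",
    "initialize_parameters",
    "train",
    "predict",
    "DynamicSynapseClassifier",
]

MODEL_FORMAT_VERSION = 1
LOG_FLOOR = 1e-15


@dataclass(frozen=True)
class DySCConfig:
    """Architecture dimensions.

    d_m/d_h/d_t : pathway input dimensions (11/5/10 under the defaults)
    n_classes   : K
    hidden_pathway : width of each per-pathway tanh layer (default 16)
    hidden_fusion  : width of the cross-pathway tanh layer (default 32)
    sample_var  : n-1 denominator in the variance gate (default True)
    """

    d_m: int
    d_h: int
    d_t: int
    n_classes: int
    hidden_pathway: int = 16
    hidden_fusion: int = 32
    sample_var: bool = True

    def __post_init__(self) -> None:
        for name in ("d_m", "d_h", "d_t", "n_classes", "hidden_pathway", "hidden_fusion"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.d_t < 2:
            raise ValueError("d_t must be >= 2 (the variance gate needs >= 2 features)")

    @property
    def var_ddof(self) -> int:
        return 1 if self.sample_var else 0


@dataclass(frozen=True)
class TrainingConfig:
    """Quasi-Newton training bounds and initialization randomness."""

    max_iterations: int = 50
    max_function_evaluations: int = 1_000_000
    seed: int = 0
    init_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.max_function_evaluations < 1:
            raise ValueError("iteration/evaluation bounds must be positive")


# ---------------------------------------------------------------------------
# parameters


_BLOCKS = (
    "w_h_att",
    "gamma_raw",
    "w_m_att",
    "W_m",
    "b_m",
    "W_h",
    "b_h",
    "W_t",
    "b_t",
    "W_f",
    "b_f",
    "W_o",
    "b_o",
)


@dataclass
class DySCParameters:
    """All learnable weights; γ = softplus(gamma_raw) > 0."""

    w_h_att: np.ndarray  # (d_h,)
    gamma_raw: float
    w_m_att: np.ndarray  # (d_m,)
    W_m: np.ndarray  # (d_m, Hp)
    b_m: np.ndarray  # (Hp,)
    W_h: np.ndarray  # (d_h, Hp)
    b_h: np.ndarray  # (Hp,)
    W_t: np.ndarray  # (d_t, Hp)
    b_t: np.ndarray  # (Hp,)
    W_f: np.ndarray  # (3*Hp, Hf)
    b_f: np.ndarray  # (Hf,)
    W_o: np.ndarray  # (Hf, K)
    b_o: np.ndarray  # (K,)

    @property
    def gamma(self) -> float:
        return float(np.logaddexp(0.0, self.gamma_raw))  # softplus

    def to_vector(self) -> np.ndarray:
        parts = []
        for name in _BLOCKS:
            v = getattr(self, name)
            parts.append(np.atleast_1d(np.asarray(v, dtype=np.float64)).ravel())
        return np.concatenate(parts)

    @classmethod
    def shapes(cls, cfg: DySCConfig) -> dict[str, tuple]:
        hp, hf, k = cfg.hidden_pathway, cfg.hidden_fusion, cfg.n_classes
        return {
            "w_h_att": (cfg.d_h,),
            "gamma_raw": (),
            "w_m_att": (cfg.d_m,),
            "W_m": (cfg.d_m, hp),
            "b_m": (hp,),
            "W_h": (cfg.d_h, hp),
            "b_h": (hp,),
            "W_t": (cfg.d_t, hp),
            "b_t": (hp,),
            "W_f": (3 * hp, hf),
            "b_f": (hf,),
            "W_o": (hf, k),
            "b_o": (k,),
        }

    @classmethod
    def from_vector(cls, vec: np.ndarray, cfg: DySCConfig) -> "DySCParameters":
        vec = np.asarray(vec, dtype=np.float64)
        fields: dict[str, Any] = {}
        pos = 0
        for name, shape in cls.shapes(cfg).items():
            size = int(np.prod(shape)) if shape else 1
            chunk = vec[pos : pos + size]
            fields[name] = float(chunk[0]) if shape == () else chunk.reshape(shape).copy()
            pos += size
        if pos != vec.size:
            raise ValueError(f"parameter vector has {vec.size} entries, expected {pos}")
        return cls(**fields)

    def check_finite(self) -> None:
        for name in _BLOCKS:
            if not np.all(np.isfinite(np.atleast_1d(getattr(self, name)))):
                raise ValueError(f"non-finite values in parameter block {name}")


def initialize_parameters(cfg: DySCConfig, tcfg: TrainingConfig) -> DySCParameters:
    """Neutral-gate initialization: attention masks start at ones (gates
    pass features through undistorted), γ starts at 1, fusion/output
    weights from a zero-mean uniform scaled by 1/sqrt(fan-in)."""
    rng = np.random.default_rng(tcfg.seed)
    shapes = DySCParameters.shapes(cfg)
    fields: dict[str, Any] = {
        "w_h_att": np.ones(cfg.d_h),
        "gamma_raw": float(np.log(np.expm1(1.0))),  # softplus^{-1}(1)
        "w_m_att": np.ones(cfg.d_m),
    }
    for name, shape in shapes.items():
        if name in fields:
            continue
        if name.startswith("b_"):
            fields[name] = np.zeros(shape)
        else:
            a = tcfg.init_scale / np.sqrt(shape[0])
            fields[name] = rng.uniform(-a, a, size=shape)
    return DySCParameters(**fields)


# ---------------------------------------------------------------------------
# forward pass


@dataclass
class ForwardTrace:
    """Every intermediate of one forward pass (batch-first arrays)."""

    G_h: np.ndarray  # (n, d_h), entries in (-1, 1)
    g_t: np.ndarray  # (n,), in (0, 1]
    var_t: np.ndarray  # (n,)
    x_m_mod: np.ndarray
    x_h_mod: np.ndarray
    x_t_mod: np.ndarray
    F_m: np.ndarray
    F_h: np.ndarray
    F_t: np.ndarray
    F_combined: np.ndarray  # (n, 3*Hp)
    H: np.ndarray  # (n, Hf) fusion hidden activations
    z: np.ndarray  # (n, K) logits
    P: np.ndarray  # (n, K) class posteriors


def gate_hierarchical(x_h: np.ndarray, w_h_att: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Attention gate: G = tanh(x ⊙ w), modulated x' = x ⊙ G."""
    x_h = np.atleast_2d(np.asarray(x_h, dtype=np.float64))
    if x_h.shape[1] != np.asarray(w_h_att).shape[0]:
        raise ValueError(
            f"hierarchical gate dimension mismatch: features {x_h.shape[1]}, "
            f"attention vector {np.asarray(w_h_att).shape[0]}"
        )
    G = np.tanh(x_h * w_h_att)
    return G, x_h * G


def gate_time_invariant(
    x_t: np.ndarray, gamma: float, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stability gate: g = exp(-γ Var(x)), x' = g·x. Returns (g, x', var)."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    x_t = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    if x_t.shape[1] < 2:
        raise ValueError("time-invariant gate needs >= 2 features per sample")
    var = x_t.var(axis=1, ddof=ddof)
    g = np.exp(-gamma * var)
    return g, g[:, None] * x_t, var


def gate_multiscale(x_m: np.ndarray, w_m_att: np.ndarray) -> np.ndarray:
    """Static learned mask: x' = x ⊙ w."""
    x_m = np.atleast_2d(np.asarray(x_m, dtype=np.float64))
    if x_m.shape[1] != np.asarray(w_m_att).shape[0]:
        raise ValueError(
            f"multiscale gate dimension mismatch: features {x_m.shape[1]}, "
            f"mask {np.asarray(w_m_att).shape[0]}"
        )
    return x_m * w_m_att


def pathway_fuse(x_mod: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pathway compression F = tanh(x' W + b)."""
    x_mod = np.atleast_2d(np.asarray(x_mod, dtype=np.float64))
    if x_mod.shape[1] != W.shape[0]:
        raise ValueError(f"fusion shape mismatch: input {x_mod.shape[1]}, weights {W.shape}")
    return np.tanh(x_mod @ W + b)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for numerical stability."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    shifted = z - z.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def forward(batch: FeatureBatch, params: DySCParameters, cfg: DySCConfig) -> ForwardTrace:
    """Full forward pass: gates → pathway fusion → cross-pathway fusion →
    linear output → softmax posteriors."""
    params.check_finite()
    for name, d in (("x_m", cfg.d_m), ("x_h", cfg.d_h), ("x_t", cfg.d_t)):
        if getattr(batch, name).shape[1] != d:
            raise ValueError(
                f"{name} has dimension {getattr(batch, name).shape[1]}, config expects {d}"
            )
    G_h, x_h_mod = gate_hierarchical(batch.x_h, params.w_h_att)
    g_t, x_t_mod, var_t = gate_time_invariant(batch.x_t, params.gamma, ddof=cfg.var_ddof)
    x_m_mod = gate_multiscale(batch.x_m, params.w_m_att)
    F_m = pathway_fuse(x_m_mod, params.W_m, params.b_m)
    F_h = pathway_fuse(x_h_mod, params.W_h, params.b_h)
    F_t = pathway_fuse(x_t_mod, params.W_t, params.b_t)
    F_combined = np.hstack([F_m, F_h, F_t])
    H = np.tanh(F_combined @ params.W_f + params.b_f)
    z = H @ params.W_o + params.b_o
    P = softmax(z)
    return ForwardTrace(
        G_h=G_h, g_t=g_t, var_t=var_t,
        x_m_mod=x_m_mod, x_h_mod=x_h_mod, x_t_mod=x_t_mod,
        F_m=F_m, F_h=F_h, F_t=F_t, F_combined=F_combined,
        H=H, z=z, P=P,
    )


# ---------------------------------------------------------------------------
# loss and analytic gradient


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-D integer array")
    if np.any((labels < 0) | (labels >= k)):
        raise ValueError(f"labels must lie in 0..{k - 1}")
    out = np.zeros((labels.size, k))
    out[np.arange(labels.size), labels] = 1.0
    return out


def cross_entropy(P: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy −(1/n) Σ_i log p_i,y_i (natural log, p floored
    at 1e−15)."""
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    Y = _one_hot(labels, P.shape[1])
    if Y.shape[0] != P.shape[0]:
        raise ValueError("batch sizes of probabilities and labels differ")
    p_true = np.maximum((P * Y).sum(axis=1), LOG_FLOOR)
    return float(-np.mean(np.log(p_true)))


def loss_and_gradient(
    vec: np.ndarray, batch: FeatureBatch, labels: np.ndarray, cfg: DySCConfig
) -> tuple[float, np.ndarray]:
    """Cross-entropy loss and its exact gradient w.r.t. every parameter.

    Backpropagates through the output/fusion layers, the three pathway
    layers, and each gate, including the chain through the softplus
    reparameterization of γ.  The loss uses the log-softmax form, which
    equals the floored cross-entropy up to the 1e−15 floor.
    """
    params = DySCParameters.from_vector(vec, cfg)
    n = len(batch)
    tr = forward(batch, params, cfg)
    Y = _one_hot(labels, cfg.n_classes)

    # stable log-softmax loss
    zs = tr.z - tr.z.max(axis=1, keepdims=True)
    log_p = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
    loss = float(-np.sum(Y * log_p) / n)
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite loss; |params|_max={np.max(np.abs(vec)):.3g}, gamma={params.gamma:.3g}"
        )

    dz = (tr.P - Y) / n  # (n, K)
    g: dict[str, Any] = {}
    g["W_o"] = tr.H.T @ dz
    g["b_o"] = dz.sum(axis=0)
    dH = dz @ params.W_o.T
    dAf = dH * (1.0 - tr.H**2)
    g["W_f"] = tr.F_combined.T @ dAf
    g["b_f"] = dAf.sum(axis=0)
    dFc = dAf @ params.W_f.T
    hp = cfg.hidden_pathway
    dF = {"m": dFc[:, :hp], "h": dFc[:, hp : 2 * hp], "t": dFc[:, 2 * hp :]}

    d_mod = {}
    for p, F, x_mod, W in (
        ("m", tr.F_m, tr.x_m_mod, params.W_m),
        ("h", tr.F_h, tr.x_h_mod, params.W_h),
        ("t", tr.F_t, tr.x_t_mod, params.W_t),
    ):
        dA = dF[p] * (1.0 - F**2)
        g[f"W_{p}"] = x_mod.T @ dA
        g[f"b_{p}"] = dA.sum(axis=0)
        d_mod[p] = dA @ W.T

    # multiscale mask: x_m' = x_m ⊙ w
    g["w_m_att"] = (d_mod["m"] * batch.x_m).sum(axis=0)

    # hierarchical gate: x_h' = x_h ⊙ tanh(x_h ⊙ w)
    dG = d_mod["h"] * batch.x_h
    dpre = dG * (1.0 - tr.G_h**2)
    g["w_h_att"] = (dpre * batch.x_h).sum(axis=0)

    # variance gate: x_t' = exp(-γ v_i) x_t, γ = softplus(gamma_raw)
    dg_t = (d_mod["t"] * batch.x_t).sum(axis=1)
    dgamma = float(np.sum(dg_t * (-tr.var_t) * tr.g_t))
    g["gamma_raw"] = dgamma * float(expit(params.gamma_raw))

    grad = DySCParameters(
        w_h_att=g["w_h_att"], gamma_raw=g["gamma_raw"], w_m_att=g["w_m_att"],
        W_m=g["W_m"], b_m=g["b_m"], W_h=g["W_h"], b_h=g["b_h"],
        W_t=g["W_t"], b_t=g["b_t"], W_f=g["W_f"], b_f=g["b_f"],
        W_o=g["W_o"], b_o=g["b_o"],
    ).to_vector()
    return loss, grad


# ---------------------------------------------------------------------------
# training / prediction


def train(
    batch: FeatureBatch,
    labels: np.ndarray,
    cfg: DySCConfig,
    tcfg: TrainingConfig | None = None,
) -> tuple[DySCParameters, Any]:
    """Full-batch quasi-Newton (L-BFGS) minimization of the cross-entropy.

    Deterministic given the seed: initialization is the only randomness.
    Returns the fitted parameters and the scipy OptimizeResult.
    """
    tcfg = tcfg or TrainingConfig()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes present")
    if len(batch) < cfg.n_classes:
        raise ValueError("need at least as many samples as classes")
    x0 = initialize_parameters(cfg, tcfg).to_vector()
    res = minimize(
        loss_and_gradient,
        x0,
        args=(batch, labels, cfg),
        method="L-BFGS-B",
        jac=True,
        options={
            "maxiter": tcfg.max_iterations,
            "maxfun": tcfg.max_function_evaluations,
        },
    )
    return DySCParameters.from_vector(res.x, cfg), res


def predict(
    batch: FeatureBatch, params: DySCParameters, cfg: DySCConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior argmax per sample; ties break toward the lower class index."""
    P = forward(batch, params, cfg).P
    return P.argmax(axis=1), P


# ---------------------------------------------------------------------------
# high-level wrapper with serialization


class DynamicSynapseClassifier:
    """Convenience wrapper bundling config, parameters and training seed."""

    def __init__(self, cfg: DySCConfig, tcfg: TrainingConfig | None = None):
        self.cfg = cfg
        self.tcfg = tcfg or TrainingConfig()
        self.params: DySCParameters | None = None
        self.optimize_result_: Any = None

    @classmethod
    def for_batch(
        cls, batch: FeatureBatch, n_classes: int, tcfg: TrainingConfig | None = None, **kwargs
    ) -> "DynamicSynapseClassifier":
        cfg = DySCConfig(
            d_m=batch.x_m.shape[1],
            d_h=batch.x_h.shape[1],
            d_t=batch.x_t.shape[1],
            n_classes=n_classes,
            **kwargs,
        )
        return cls(cfg, tcfg)

    def fit(self, batch: FeatureBatch, labels: np.ndarray) -> "DynamicSynapseClassifier":
        self.params, self.optimize_result_ = train(batch, labels, self.cfg, self.tcfg)
        return self

    def predict(self, batch: FeatureBatch) -> np.ndarray:
        self._require_fit()
        return predict(batch, self.params, self.cfg)[0]

    def predict_proba(self, batch: FeatureBatch) -> np.ndarray:
        self._require_fit()
        return predict(batch, self.params, self.cfg)[1]

    def _require_fit(self) -> None:
        if self.params is None:
            raise RuntimeError("classifier has not been fitted")

    def to_json_dict(self) -> dict:
        self._require_fit()
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "config": {
                "d_m": self.cfg.d_m, "d_h": self.cfg.d_h, "d_t": self.cfg.d_t,
                "n_classes": self.cfg.n_classes,
                "hidden_pathway": self.cfg.hidden_pathway,
                "hidden_fusion": self.cfg.hidden_fusion,
                "sample_var": self.cfg.sample_var,
            },
            "training": {
                "max_iterations": self.tcfg.max_iterations,
                "max_function_evaluations": self.tcfg.max_function_evaluations,
                "seed": self.tcfg.seed,
                "init_scale": self.tcfg.init_scale,
            },
            "parameters": {
                name: (
                    getattr(self.params, name)
                    if np.isscalar(getattr(self.params, name))
                    else getattr(self.params, name).tolist()
                )
                for name in _BLOCKS
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def from_json_dict(cls, doc: dict) -> "DynamicSynapseClassifier":
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('format_version')}")
        cfg = DySCConfig(**doc["config"])
        tcfg = TrainingConfig(**doc["training"])
        obj = cls(cfg, tcfg)
        fields = {
            name: (
                float(val) if name == "gamma_raw" else np.asarray(val, dtype=np.float64)
            )
            for name, val in doc["parameters"].items()
        }
        obj.params = DySCParameters(**fields)
        return obj

    @classmethod
    def load(cls, path) -> "DynamicSynapseClassifier":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))
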