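"""Dual-branch spectral network.

A shared 1-D residual convolutional encoder maps a preprocessed spectrum
``x in R^L`` to an embedding ``f in R^d`` (stem conv -> residual stages ->
global average pooling -> linear projection).  Two parallel heads read the
same embedding:

* a pure-substance classification head using a large-margin cosine
  formulation: at training time ``logit_k = s_cls * (cos(f, w_k) - m*[k==y])``,
  at inference ``s_cls * cos(f, w_k)``;
* a component-evidence head producing per-component evidence scores ``u_k``
  that a sigmoid converts into presence probabilities
  ``p_k = 1 / (1 + exp(-u_k))``.

The evidence head defaults to the same normalised-cosine parameterisation
(``u_k = s_evi * cos(f, v_k)``, so ``|u_k| <= s_evi``); a plain affine head is
available behind the ``evidence_head`` switch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nnet import (
    BatchNorm1d,
    Conv1d,
    GlobalAvgPool1d,
    Linear,
    MaxPool1d,
    Param,
    ReLU,
    ResidualBlock1d,
    Sequential,
)


@dataclass
class ModelConfig:
    embed_dim: int = 128
    stem: tuple[int, int, int] = (7, 2, 32)          # kernel, stride, channels
    stages: tuple[tuple[int, int], ...] = ((32, 1), (64, 1), (128, 1), (256, 1))
    stage_strides: tuple[int, ...] | None = None      # default: 2 between stages
    cosine_margin: float = 0.35
    cls_scale: float = 16.0
    evi_scale: float = 16.0
    evidence_clip: float = 6.0
    n_components: int = 3
    evidence_head: str = "cosine"                     # or "linear"
    batch_norm: bool = True
    coord_channel: bool = True
    relu_slope: float = 0.0
    input_len: int = 2048

    def __post_init__(self) -> None:
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")
        if not (0.0 <= self.cosine_margin < 1.0):
            raise ValueError("cosine_margin must lie in [0, 1)")
        if self.cls_scale <= 0 or self.evi_scale <= 0 or self.evidence_clip <= 0:
            raise ValueError("scales and clip must be positive")
        if self.n_components < 2:
            raise ValueError("need at least two components")
        if self.evidence_head not in ("cosine", "linear"):
            raise ValueError(f"unknown evidence head {self.evidence_head!r}")

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Reduced encoder for CPU-budget runs; heads and margins unchanged."""
        kw = dict(
            embed_dim=64,
            stem=(7, 2, 8),
            stages=((8, 1), (16, 1), (32, 1), (32, 1)),
        )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stem"] = list(self.stem)
        d["stages"] = [list(s) for s in self.stages]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["stem"] = tuple(d["stem"])
        d["stages"] = tuple(tuple(s) for s in d["stages"])
        if d.get("stage_strides") is not None:
            d["stage_strides"] = tuple(d["stage_strides"])
        return cls(**d)


def _normalize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norm = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero-norm vector cannot be normalised")
    return x / norm, norm


def _normalize_backward(x: np.ndarray, xhat: np.ndarray, norm: np.ndarray,
                        dxhat: np.ndarray) -> np.ndarray:
    # d/dx of x/||x||: (dxhat - xhat * <xhat, dxhat>) / ||x||
    inner = (xhat * dxhat).sum(axis=-1, keepdims=True)
    return (dxhat - xhat * inner) / norm


class CosineHead:
    """K class directions on the unit sphere with optional additive margin."""

    def __init__(self, d: int, K: int, scale: float, margin: float = 0.0,
                 rng: np.random.Generator | None = None, name: str = "head"):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.standard_normal((K, d)) * 0.1, f"{name}.w")
        self.scale, self.margin = scale, margin

    def params(self) -> list[Param]:
        return [self.w]

    def cosines(self, f: np.ndarray) -> np.ndarray:
        fhat, fnorm = _normalize_rows(f)
        what, wnorm = _normalize_rows(self.w.value)
        self._cache = (f, fhat, fnorm, what, wnorm)
        return fhat @ what.T

    def forward(self, f: np.ndarray, labels: np.ndarray | None = None) -> np.ndarray:
        cos = self.cosines(f)
        logits = cos.copy()
        if labels is not None and self.margin > 0:
            logits[np.arange(len(labels)), labels] -= self.margin
        return self.scale * logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Accumulate weight grads; return gradient w.r.t. the embedding."""
        f, fhat, fnorm, what, wnorm = self._cache
        dcos = self.scale * dlogits
        dfhat = dcos @ what
        dwhat = dcos.T @ fhat
        self.w.grad += _normalize_backward(self.w.value, what, wnorm, dwhat)
        return _normalize_backward(f, fhat, fnorm, dfhat)


class AffineEvidenceHead:
    """Plain affine evidence head: ``u = W f + b`` (unbounded scores)."""

    def __init__(self, d: int, K: int, rng: np.random.Generator | None = None,
                 name: str = "evihead"):
        self.linear = Linear(d, K, rng=rng, name=name)

    def params(self) -> list[Param]:
        return self.linear.params()

    def forward(self, f: np.ndarray) -> np.ndarray:
        return self.linear.forward(f)

    def backward(self, du: np.ndarray) -> np.ndarray:
        return self.linear.backward(du)


class DualBranchModel:
    """Shared encoder + classification branch + evidence branch."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
        k, stride, ch = config.stem
        c_in = 2 if config.coord_channel else 1
        layers: list = [
            Conv1d(c_in, ch, k, stride=stride, rng=rng, bias=not config.batch_norm,
                   name="stem"),
        ]
        if config.batch_norm:
            layers.append(BatchNorm1d(ch, name="stem.bn"))
        layers += [ReLU(config.relu_slope), MaxPool1d(3, stride=2, pad=1)]
        c_prev = ch
        strides = config.stage_strides
        if strides is None:
            strides = tuple(2 if i > 0 else 1 for i in range(len(config.stages)))
        for i, (c_out, n_blocks) in enumerate(config.stages):
            for b in range(n_blocks):
                s = strides[i] if b == 0 else 1
                layers.append(
                    ResidualBlock1d(c_prev, c_out, stride=s, rng=rng,
                                    name=f"stage{i}.{b}",
                                    batch_norm=config.batch_norm,
                                    relu_slope=config.relu_slope)
                )
                c_prev = c_out
        self.features = Sequential(layers)
        self.gap = GlobalAvgPool1d()
        self.proj = Linear(c_prev, config.embed_dim, rng=rng, name="proj")
        self.cls_head = CosineHead(config.embed_dim, config.n_components,
                                   config.cls_scale, config.cosine_margin,
                                   rng=rng, name="cls")
        if config.evidence_head == "cosine":
            self.evi_head = CosineHead(config.embed_dim, config.n_components,
                                       config.evi_scale, 0.0, rng=rng, name="evi")
        else:
            self.evi_head = AffineEvidenceHead(config.embed_dim,
                                               config.n_components, rng=rng)
        self._train_mode = True
        self.set_mode(train=False)

    # ---- plumbing -----------------------------------------------------
    def params(self) -> list[Param]:
        return (self.features.params() + self.proj.params()
                + self.cls_head.params() + self.evi_head.params())

    def set_mode(self, train: bool) -> None:
        self._train_mode = train
        self.features.set_mode(train)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, l in enumerate(self.features.layers):
            if isinstance(l, BatchNorm1d):
                state[f"running.{i}.mean"] = l.running_mean.copy()
                state[f"running.{i}.var"] = l.running_var.copy()
            if isinstance(l, ResidualBlock1d):
                for j, sub in enumerate(l._sublayers()):
                    if isinstance(sub, BatchNorm1d):
                        state[f"running.{i}.{j}.mean"] = sub.running_mean.copy()
                        state[f"running.{i}.{j}.var"] = sub.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        by_name = {p.name: p for p in self.params()}
        for name, value in state.items():
            if name.startswith("running."):
                continue
            by_name[name].value = np.array(value, dtype=np.float64)
        for i, l in enumerate(self.features.layers):
            if isinstance(l, BatchNorm1d):
                l.running_mean = np.array(state[f"running.{i}.mean"])
                l.running_var = np.array(state[f"running.{i}.var"])
            if isinstance(l, ResidualBlock1d):
                for j, sub in enumerate(l._sublayers()):
                    if isinstance(sub, BatchNorm1d):
                        sub.running_mean = np.array(state[f"running.{i}.{j}.mean"])
                        sub.running_var = np.array(state[f"running.{i}.{j}.var"])

    # ---- forward passes ----------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.config.input_len:
            raise ValueError(
                f"input length {x.shape[1]} does not match model input_len "
                f"{self.config.input_len}"
            )
        return x

    def feature_map(self, x: np.ndarray) -> np.ndarray:
        """Activations of the final convolutional stage, shape (B, C, L')."""
        x = self._check_input(x)
        if self.config.coord_channel:
            # fingerprint spectra live on an absolute wavenumber axis, so a
            # normalised coordinate channel lets band detectors be
            # position-specific despite convolutional weight sharing
            t = np.linspace(-1.0, 1.0, x.shape[1])
            coord = np.broadcast_to(t, x.shape)
            inp = np.stack([x, coord], axis=1)
        else:
            inp = x[:, None, :]
        return self.features.forward(inp)

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Embedding f = F(x), shape (B, d)."""
        a = self.feature_map(x)
        return self.proj.forward(self.gap.forward(a))

    def classify_cosine(self, f: np.ndarray, labels: np.ndarray | None = None) -> np.ndarray:
        """Class logits; with ``labels`` the target-class margin is applied."""
        return self.cls_head.forward(f, labels)

    def evidence_forward(self, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evidence scores u and probabilities p = sigmoid(u)."""
        u = self.evi_head.forward(f)
        p = 1.0 / (1.0 + np.exp(-u))
        return u, p

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Component presence probabilities for a batch of feature vectors."""
        _, p = self.evidence_forward(self.encode(x))
        return p

    def predict_class(self, x: np.ndarray) -> np.ndarray:
        """Pure-substance class indices from the classification branch."""
        logits = self.classify_cosine(self.encode(x))
        return logits.argmax(axis=1)

    # ---- checkpointing ------------------------------------------------
    def save(self, path: str | Path, extra: dict | None = None) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        sidecar = {"model_config": self.config.to_dict()}
        if extra:
            sidecar.update(extra)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DualBranchModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig.from_dict(sidecar["model_config"]))
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        model.set_mode(train=False)
        return model
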