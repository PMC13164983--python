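"""Pure-spectrum-only training of the dual-branch model.

The joint objective is

    L = L_cls + lambda_evi * L_evi + lambda_reg * L_reg

where L_cls is softmax cross-entropy on the margin-adjusted cosine logits,
L_evi is binary cross-entropy of the sigmoid evidence probabilities against
one-hot component indicators, and L_reg is a clipping penalty
``mean_k max(0, |u_k| - c)^2`` that discourages runaway evidence magnitudes.
Optimisation uses AdamW with cosine-annealed learning rate.  Mixture spectra
are barred from the gradient path by a hard guard.

Checkpoint selection is mixture-aware: tracking starts after a warm-up
(default 500 steps), only checkpoints whose pure-spectrum validation accuracy
reaches the eligibility floor (default 0.95) are considered, and among those
the one with the highest seven-category validation accuracy wins (ties go to
the latest, i.e. most annealed, step).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .inference import InferenceConfig, infer_from_proba
from .model import DualBranchModel
from .nnet import AdamW, cosine_annealing_lr
from .spectra import COMPONENTS, set_to_category


@dataclass
class TrainConfig:
    lr: float = 1e-3
    lr_min: float = 1e-5
    weight_decay: float = 1e-4
    batch_size: int = 32
    total_steps: int = 3000
    warmup_steps: int = 500
    pure_val_floor: float = 0.95
    eval_every: int = 50
    lambda_evi: float = 1.0
    lambda_reg: float = 0.01
    # random spectral erasing: occludes contiguous windows of pure training
    # spectra so evidence detectors must key on a component's own bands
    # (band presence) rather than on the absence of other components' bands
    erase_prob: float = 0.8
    erase_windows: int = 2
    erase_width: tuple[int, int] = (50, 150)
    # random amplitude scaling: presents pure band patterns at partial
    # intensity, as they appear inside mixtures after min-max normalisation
    # (down to ~0.1 for the weakest partner of a ternary mixture), so evidence
    # responses stay monotone in band amplitude
    scale_prob: float = 1.0
    scale_range: tuple[float, float] = (0.1, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_min >= self.lr:
            raise ValueError("lr_min must be < lr")
        if self.warmup_steps >= self.total_steps:
            raise ValueError("warmup_steps must be < total_steps")
        if not (0.0 < self.pure_val_floor <= 1.0):
            raise ValueError("pure_val_floor must lie in (0, 1]")

    @classmethod
    def ci(cls, **overrides) -> "TrainConfig":
        """Reduced-step profile for single-CPU runs."""
        kw = dict(total_steps=1200, eval_every=50)
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["erase_width"] = list(self.erase_width)
        d["scale_range"] = list(self.scale_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "erase_width" in d:
            d["erase_width"] = tuple(d["erase_width"])
        if "scale_range" in d:
            d["scale_range"] = tuple(d["scale_range"])
        return cls(**d)


@dataclass
class LossBreakdown:
    L_cls: float
    L_evi: float
    L_reg: float
    lambda_evi: float = 1.0
    lambda_reg: float = 0.01

    @property
    def total(self) -> float:
        return self.L_cls + self.lambda_evi * self.L_evi + self.lambda_reg * self.L_reg


@dataclass
class HistoryRecord:
    step: int
    L_cls: float
    L_evi: float
    L_reg: float
    total: float
    lr: float
    pure_val_acc: float | None = None
    seven_cat_val_acc: float | None = None
    state: dict | None = None          # parameter snapshot, eligible records only


@dataclass
class TrainHistory:
    records: list[HistoryRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FeatureDataset:
    """Preprocessed feature vectors with their category tokens."""

    X: np.ndarray
    categories: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.shape[0] != len(self.categories):
            raise ValueError("one category per row required")

    def __len__(self) -> int:
        return self.X.shape[0]

    def pure_labels(self) -> np.ndarray:
        bad = [c for c in self.categories if len(c) != 1]
        if bad:
            raise ValueError(f"mixture categories present: {sorted(set(bad))}")
        return np.array([COMPONENTS.index(c) for c in self.categories])


# ---- loss functions (value + gradient) --------------------------------

def loss_classification(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy; returns (loss, dloss/dlogits)."""
    logits = np.atleast_2d(logits)
    y = np.atleast_1d(y)
    if np.any(y < 0) or np.any(y >= logits.shape[1]):
        raise ValueError("label out of range")
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    B = len(y)
    loss = -logp[np.arange(B), y].mean()
    grad = np.exp(logp)
    grad[np.arange(B), y] -= 1.0
    return float(loss), grad / B


def loss_evidence(p: np.ndarray, z: np.ndarray,
                  eps: float = 1e-12) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of presence probabilities against indicator
    vectors; returns (loss, dloss/du) where u is the pre-sigmoid evidence."""
    p = np.atleast_2d(p)
    z = np.atleast_2d(z).astype(float)
    pc = np.clip(p, eps, 1.0 - eps)
    loss = -(z * np.log(pc) + (1.0 - z) * np.log(1.0 - pc)).mean()
    # d(BCE)/du = p - z for sigmoid outputs, averaged like the loss
    grad = (p - z) / p.size
    return float(loss), grad


def loss_regularization(u: np.ndarray, c: float) -> tuple[float, np.ndarray]:
    """Clipping penalty mean_k max(0, |u_k| - c)^2; returns (loss, dloss/du)."""
    if c <= 0:
        raise ValueError("clip threshold must be positive")
    u = np.atleast_2d(u)
    excess = np.maximum(0.0, np.abs(u) - c)
    loss = (excess**2).mean()
    grad = 2.0 * excess * np.sign(u) / u.size
    return float(loss), grad


# ---- training loop ----------------------------------------------------

def _balanced_batches(labels: np.ndarray, batch_size: int,
                      rng: np.random.Generator):
    """Endless class-balanced batch index generator.

    Each pass shuffles within class and interleaves classes round-robin so
    every batch holds a near-even class mix.
    """
    classes = np.unique(labels)
    pools = {c: np.flatnonzero(labels == c) for c in classes}
    while True:
        shuffled = {c: rng.permutation(pools[c]) for c in classes}
        longest = max(len(v) for v in shuffled.values())
        order = []
        for i in range(longest):
            for c in classes:
                pool = shuffled[c]
                order.append(pool[i % len(pool)])
        order = np.array(order)
        for start in range(0, len(order) - batch_size + 1, batch_size):
            yield order[start : start + batch_size]


def _augment_batch(xb: np.ndarray, cfg: "TrainConfig",
                   rng: np.random.Generator) -> np.ndarray:
    """Pure-spectrum-only augmentation: amplitude scaling + window erasing."""
    if cfg.erase_prob <= 0 and cfg.scale_prob <= 0:
        return xb
    xb = xb.copy()
    L = xb.shape[1]
    lo, hi = cfg.erase_width
    for i in range(xb.shape[0]):
        if cfg.scale_prob > 0 and rng.random() < cfg.scale_prob:
            xb[i] *= rng.uniform(*cfg.scale_range)
        if cfg.erase_prob > 0 and rng.random() < cfg.erase_prob:
            for _ in range(rng.integers(1, cfg.erase_windows + 1)):
                w = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, max(1, L - w)))
                xb[i, start : start + w] = 0.0
    return xb


def _one_hot(y: np.ndarray, K: int) -> np.ndarray:
    z = np.zeros((len(y), K))
    z[np.arange(len(y)), y] = 1.0
    return z


def _seven_cat_accuracy(model: DualBranchModel, data: FeatureDataset,
                        prototypes: dict, infer_cfg: InferenceConfig) -> float:
    """Recognition accuracy over all seven categories.

    Pure categories are scored by the classification branch and mixture
    categories by pair ranking plus ternary refinement, so the selection
    metric is sensitive to both capabilities of a checkpoint.
    """
    from dataclasses import replace

    cats = data.categories
    correct = 0
    pure_idx = [i for i, c in enumerate(cats) if len(c) == 1]
    mix_idx = [i for i, c in enumerate(cats) if len(c) > 1]
    if pure_idx:
        pred = model.predict_class(data.X[pure_idx])
        correct += sum(COMPONENTS[pred[j]] == cats[i]
                       for j, i in enumerate(pure_idx))
    if mix_idx:
        pairs_cfg = replace(infer_cfg, candidate_mode="pairs_only")
        p_all = model.predict_proba(data.X[mix_idx])
        for j, i in enumerate(mix_idx):
            rep = infer_from_proba(p_all[j], data.X[i], prototypes, pairs_cfg)
            correct += rep.category == cats[i]
    return correct / len(data)


def train(
    data: FeatureDataset,
    model: DualBranchModel,
    cfg: TrainConfig | None = None,
    val_pure: FeatureDataset | None = None,
    val_seven: FeatureDataset | None = None,
    prototypes: dict | None = None,
    inference_cfg: InferenceConfig | None = None,
) -> TrainHistory:
    """Optimise the joint objective on pure spectra only.

    ``val_pure`` (pure categories) and ``val_seven`` (all seven categories,
    requires ``prototypes``) enable the accuracy tracking that checkpoint
    selection needs.  Deterministic given ``cfg.seed`` and the model's
    initialisation seed.
    """
    cfg = cfg or TrainConfig()
    y = data.pure_labels()  # hard guard: raises if any mixture category present
    K = model.config.n_components
    infer_cfg = inference_cfg or InferenceConfig()
    params = model.params()
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    batches = _balanced_batches(y, cfg.batch_size, np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), 11])))
    erase_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 13]))
    history = TrainHistory()
    interval = {"cls": [], "evi": [], "reg": []}

    for step in range(1, cfg.total_steps + 1):
        idx = next(batches)
        xb, yb = data.X[idx], y[idx]
        xb = _augment_batch(xb, cfg, erase_rng)
        zb = _one_hot(yb, K)

        model.set_mode(train=True)
        a = model.feature_map(xb)
        pooled = model.gap.forward(a)
        f = model.proj.forward(pooled)
        logits = model.cls_head.forward(f, yb)
        L_cls, dlogits = loss_classification(logits, yb)
        u = model.evi_head.forward(f)
        p = 1.0 / (1.0 + np.exp(-u))
        L_evi, du_evi = loss_evidence(p, zb)
        L_reg, du_reg = loss_regularization(u, model.config.evidence_clip)

        opt.zero_grad()
        df = model.cls_head.backward(dlogits)
        df = df + model.evi_head.backward(cfg.lambda_evi * du_evi
                                          + cfg.lambda_reg * du_reg)
        da = model.gap.backward(model.proj.backward(df))
        model.features.backward(da)
        opt.lr = cosine_annealing_lr(step, cfg.total_steps, cfg.lr, cfg.lr_min)
        opt.step()

        interval["cls"].append(L_cls)
        interval["evi"].append(L_evi)
        interval["reg"].append(L_reg)

        if step % cfg.eval_every == 0 or step == cfg.total_steps:
            model.set_mode(train=False)
            bd = LossBreakdown(
                float(np.mean(interval["cls"])),
                float(np.mean(interval["evi"])),
                float(np.mean(interval["reg"])),
                cfg.lambda_evi, cfg.lambda_reg,
            )
            interval = {"cls": [], "evi": [], "reg": []}
            rec = HistoryRecord(step, bd.L_cls, bd.L_evi, bd.L_reg, bd.total,
                                lr=opt.lr)
            if val_pure is not None:
                rec.pure_val_acc = float(
                    (model.predict_class(val_pure.X) == val_pure.pure_labels()).mean()
                )
            if val_seven is not None and prototypes is not None:
                rec.seven_cat_val_acc = _seven_cat_accuracy(
                    model, val_seven, prototypes, infer_cfg)
            eligible = (
                rec.pure_val_acc is not None
                and step > cfg.warmup_steps
                and rec.pure_val_acc >= cfg.pure_val_floor
            )
            if eligible:
                rec.state = model.state_dict()
            history.records.append(rec)

    model.set_mode(train=False)
    return history


def select_checkpoint(history: TrainHistory, cfg: TrainConfig) -> HistoryRecord:
    """Mixture-aware checkpoint selection.

    Among records after the warm-up whose pure validation accuracy reaches
    the eligibility floor, pick the highest seven-category validation
    accuracy; ties go to the latest step.
    """
    if not len(history):
        raise ValueError("empty training history")
    eligible = [
        r for r in history
        if r.step > cfg.warmup_steps
        and r.pure_val_acc is not None
        and r.pure_val_acc >= cfg.pure_val_floor
    ]
    if not eligible:
        raise RuntimeError(
            "no eligible checkpoint: no evaluation after step "
            f"{cfg.warmup_steps} reached pure validation accuracy "
            f">= {cfg.pure_val_floor}; extend training or lower the floor"
        )
    best = max(eligible, key=lambda r: (r.seven_cat_val_acc
                                        if r.seven_cat_val_acc is not None else -1.0,
                                        r.step))
    return best
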