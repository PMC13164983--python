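"""End-to-end driver: simulate -> preprocess -> train -> infer -> evaluate.

A single :class:`RunConfig` nests every stage's configuration plus one global
seed, which fans out into named sub-seeds (data generation, model
initialisation, batch shuffling) so each stage is independently reproducible.
``run_pipeline`` writes every artifact (resolved config, manifest, checkpoint,
prototypes, training log, predictions, metrics) into a run directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import confusion, metrics
from .inference import InferenceConfig, build_prototypes, infer_from_proba
from .model import DualBranchModel, ModelConfig
from .preprocess import PreprocConfig, feature_axis, preprocess
from .spectra import COMPONENTS, MIXTURE_CATEGORIES, CATEGORIES
from .synthetic import GeneratorConfig, iter_dataset, default_sizes
from .trainer import FeatureDataset, TrainConfig, select_checkpoint, train

log = logging.getLogger("sersmix")


def _sub_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(tag)]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    seed: int = 0
    profile: str = "full"                    # "full" or "ci"
    generator: GeneratorConfig | None = None
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    model: ModelConfig | None = None
    train: TrainConfig | None = None
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    write_spectra: bool = False
    sizes: dict | None = None

    def __post_init__(self) -> None:
        if self.profile not in ("full", "ci"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.generator is None:
            self.generator = GeneratorConfig(seed=_sub_seed(self.seed, 1))
        if self.model is None:
            self.model = (ModelConfig() if self.profile == "full"
                          else ModelConfig.small())
        if self.train is None:
            base = TrainConfig if self.profile == "full" else TrainConfig.ci
            self.train = base(seed=_sub_seed(self.seed, 2))

    @property
    def init_seed(self) -> int:
        return _sub_seed(self.seed, 3)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "seed": self.seed,
            "profile": self.profile,
            "write_spectra": self.write_spectra,
            "sizes": self.sizes,
            "generator": self.generator.to_dict(),
            "preproc": asdict(self.preproc),
            "model": self.model.to_dict(),
            "train": self.train.to_dict(),
            "inference": asdict(self.inference),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("generator"), dict):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if isinstance(d.get("preproc"), dict):
            d["preproc"] = PreprocConfig(**d["preproc"])
        if isinstance(d.get("model"), dict):
            d["model"] = ModelConfig.from_dict(d["model"])
        if isinstance(d.get("train"), dict):
            d["train"] = TrainConfig.from_dict(d["train"])
        if isinstance(d.get("inference"), dict):
            d["inference"] = InferenceConfig(**d["inference"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def build_feature_sets(cfg: RunConfig, out_dir: Path | None = None):
    """Generate the synthetic dataset and preprocess it into feature sets.

    Returns ``{split: FeatureDataset}``; optionally writes raw spectra and the
    manifest when ``cfg.write_spectra`` and ``out_dir`` are set.
    """
    from .spectra import DatasetManifest, ManifestRecord, write_manifest, write_spectrum

    sizes = cfg.sizes or default_sizes()
    feats: dict[str, list[np.ndarray]] = {s: [] for s in ("train", "val", "test")}
    cats: dict[str, list[str]] = {s: [] for s in ("train", "val", "test")}
    records = []
    for s, category, split, i in iter_dataset(cfg.generator, sizes):
        feats[split].append(preprocess(s, cfg.preproc))
        cats[split].append(category)
        if cfg.write_spectra and out_dir is not None:
            rel = f"spectra/{split}_{category}_{i:04d}.csv"
            (out_dir / "spectra").mkdir(parents=True, exist_ok=True)
            write_spectrum(out_dir / rel, s)
            records.append(ManifestRecord(rel, category, split))
    if cfg.write_spectra and out_dir is not None:
        write_manifest(out_dir / "manifest.json", DatasetManifest(records))
    return {
        split: FeatureDataset(np.array(feats[split]), cats[split])
        for split in feats
        if feats[split]
    }


def evaluate_model(model: DualBranchModel, test: FeatureDataset,
                   prototypes: dict, infer_cfg: InferenceConfig) -> dict:
    """Pure, mixture and seven-category test evaluation of a trained model."""
    cats = np.array(test.categories)
    results: dict = {}

    pure_idx = [i for i, c in enumerate(cats) if len(c) == 1]
    if pure_idx:
        y_true = [cats[i] for i in pure_idx]
        pred_lab = model.predict_class(test.X[pure_idx])
        y_pred = [COMPONENTS[j] for j in pred_lab]
        cm = confusion(y_true, y_pred, COMPONENTS)
        rep = metrics(cm)
        results["pure"] = rep.rounded()
        results["pure"]["confusion"] = cm.counts.tolist()

    mix_idx = [i for i, c in enumerate(cats) if len(c) > 1]
    if mix_idx:
        pairs_cfg = InferenceConfig(
            tau_g=infer_cfg.tau_g, tau_rho=infer_cfg.tau_rho,
            prob_clamp=infer_cfg.prob_clamp, candidate_mode="pairs_only",
            residual_metric=infer_cfg.residual_metric)
        p_all = model.predict_proba(test.X[mix_idx])
        y_true, y_pred = [], []
        for row, i in enumerate(mix_idx):
            repn = infer_from_proba(p_all[row], test.X[i], prototypes, pairs_cfg)
            y_true.append(cats[i])
            y_pred.append(repn.category)
        cm = confusion(y_true, y_pred, MIXTURE_CATEGORIES)
        rep = metrics(cm)
        results["mixture"] = rep.rounded()
        results["mixture"]["confusion"] = cm.counts.tolist()

    if pure_idx and mix_idx:
        # pure categories scored by the classification branch, mixtures by
        # two-stage inference (same convention as checkpoint selection)
        pure_correct = np.trace(np.array(results["pure"]["confusion"]))
        mix_correct = np.trace(np.array(results["mixture"]["confusion"]))
        results["seven_category_accuracy"] = round(
            (pure_correct + mix_correct) / len(test), 4)
    return results


@dataclass
class StudyResult:
    """Everything a finished study produces, kept in memory."""

    results: dict
    history: object                 # TrainHistory
    model: DualBranchModel
    prototypes: dict
    sets: dict
    selected: object                # HistoryRecord


def run_study(cfg: RunConfig, out_dir: Path | None = None) -> StudyResult:
    """Execute simulate -> preprocess -> train -> select -> evaluate in memory."""
    stage = "simulate/preprocess"
    try:
        sets = build_feature_sets(cfg, out_dir)
        train_set = sets["train"]

        stage = "prototypes"
        by_class = {
            c: train_set.X[[i for i, cat in enumerate(train_set.categories) if cat == c]]
            for c in COMPONENTS
        }
        prototypes = build_prototypes(by_class)

        stage = "train"
        val = sets.get("val")
        val_pure = None
        if val is not None:
            pure_idx = [i for i, c in enumerate(val.categories) if len(c) == 1]
            val_pure = FeatureDataset(val.X[pure_idx],
                                      [val.categories[i] for i in pure_idx])
        model = DualBranchModel(cfg.model, seed=cfg.init_seed)
        history = train(train_set, model, cfg.train, val_pure=val_pure,
                        val_seven=val, prototypes=prototypes,
                        inference_cfg=cfg.inference)

        stage = "select_checkpoint"
        best = select_checkpoint(history, cfg.train)
        model.load_state_dict(best.state)
        log.info("selected checkpoint at step %d (pure val %.4f, 7-cat val %s)",
                 best.step, best.pure_val_acc, best.seven_cat_val_acc)

        stage = "evaluate"
        results = {"selected_step": best.step,
                   "pure_val_acc_at_selection": best.pure_val_acc,
                   "seven_cat_val_acc_at_selection": best.seven_cat_val_acc}
        if "test" in sets:
            results.update(evaluate_model(model, sets["test"], prototypes,
                                          cfg.inference))
        return StudyResult(results, history, model, prototypes, sets, best)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full study and persist all artifacts; returns metrics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out_dir / "config.yaml")
    study = run_study(cfg, out_dir)

    proto_df = pd.DataFrame({"wavenumber_cm-1": feature_axis(cfg.preproc)}
                            | {c: study.prototypes[c] for c in COMPONENTS})
    proto_df.to_csv(out_dir / "prototypes.csv", index=False, float_format="%.9g")
    with open(out_dir / "history.jsonl", "w") as fh:
        for r in study.history:
            fh.write(json.dumps({
                "step": r.step, "L_cls": r.L_cls, "L_evi": r.L_evi,
                "L_reg": r.L_reg, "total": r.total, "lr": r.lr,
                "pure_val_acc": r.pure_val_acc,
                "seven_cat_val_acc": r.seven_cat_val_acc,
            }) + "\n")
    study.model.save(out_dir / "checkpoint",
                     extra={"selected_step": study.selected.step,
                            "seed": cfg.seed,
                            "train_config": cfg.train.to_dict()})
    (out_dir / "metrics.json").write_text(json.dumps(study.results, indent=1))
    return study.results
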