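"""Experiment orchestration: preprocessing, training, and evaluation.

The protocol mirrors the standard patch-classification workflow: scan or
synthesize a dataset, draw a balanced subset, split 7:1:2 into
train/validation/test stratified by class, stain-normalize to a target
image drawn from the training split, augment the training split only,
train an SE-augmented dense network with Adam (defaults: learning rate
1e-4, batch size 32, 224x224 inputs), and report confusion-matrix metrics
plus rank-based AUC on the held-out split.  Every stage is seeded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import augment as augment_mod
from . import manifest as manifest_mod
from . import metrics as metrics_mod
from . import network as network_mod
from . import stain as stain_mod
from . import synthetic as synthetic_mod
from .nn import Adam, SGD, Tensor, cross_entropy, no_grad, softmax
from .nn.layers import BatchNorm2d

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the tuned full-scale protocol."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 10
    image_size: int = 224
    seed: int = 0
    loss: str = "cross_entropy"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")


def _prepare_images(X: np.ndarray, image_size: int) -> np.ndarray:
    """(N, H, W, 3) uint8/float -> (N, 3, S, S) float in [0, 1]."""
    X = np.asarray(X)
    if X.ndim == 3:
        X = X[None]
    if X.shape[-1] != 3:
        raise ValueError("expected channel-last RGB images (N, H, W, 3)")
    out = np.empty((X.shape[0], image_size, image_size, 3), dtype=float)
    for i, img in enumerate(X):
        img = img.astype(float)
        if img.shape[:2] != (image_size, image_size):
            img = _sk_resize(img, (image_size, image_size), order=1,
                             preserve_range=True, anti_aliasing=False)
        out[i] = img
    return (out / 255.0).transpose(0, 3, 1, 2)


def load_split_arrays(
    manifest: manifest_mod.DatasetManifest,
    split: str | None = None,
    label_key: str = "tumor_class",
) -> tuple[np.ndarray, np.ndarray]:
    """Load images (N, H, W, 3) uint8 and string labels for one split."""
    records = manifest.records if split is None else manifest.subset(split).records
    if not records:
        raise ValueError(f"no records in split {split!r}")
    X = np.stack([np.asarray(Image.open(r.path).convert("RGB")) for r in records])
    y = np.array([getattr(r, label_key) for r in records])
    return X, y


class MFSCNetClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator wrapping the SE-augmented dense network.

    Parameters mirror :class:`~mfscnet.network.ArchitectureSpec` and
    :class:`TrainConfig`.  ``fit`` accepts channel-last RGB patches
    (N, H, W, 3); images are resized bilinearly to ``image_size`` and
    scaled to [0, 1].  Training is fully seeded (weight init and batch
    order), so identically configured runs reproduce exactly.
    """

    def __init__(
        self,
        variant: str = "A",
        growth_rate: int = 32,
        block_config: tuple = (6, 12, 24, 16),
        compression: float = 0.5,
        se_reduction: int = 16,
        head_width: int | None = None,
        image_size: int = 224,
        optimizer: str = "adam",
        learning_rate: float = 1e-4,
        batch_size: int = 32,
        epochs: int = 10,
        seed: int = 0,
    ):
        self.variant = variant
        self.growth_rate = growth_rate
        self.block_config = block_config
        self.compression = compression
        self.se_reduction = se_reduction
        self.head_width = head_width
        self.image_size = image_size
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _spec(self, n_classes: int) -> network_mod.ArchitectureSpec:
        return network_mod.ArchitectureSpec(
            variant=self.variant,
            num_classes=n_classes,
            growth_rate=self.growth_rate,
            block_config=tuple(self.block_config),
            compression=self.compression,
            se_reduction=self.se_reduction,
            head_width=self.head_width,
            input_size=self.image_size,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to fit")
        spec = self._spec(len(self.classes_))
        self.model_ = network_mod.build_network(spec, seed=self.seed)
        Xp = _prepare_images(X, self.image_size)
        val = None
        if X_val is not None:
            yv = np.searchsorted(self.classes_, np.asarray(y_val))
            val = (_prepare_images(X_val, self.image_size), yv)
        self.history_ = _fit_loop(
            self.model_, Xp, y_enc,
            TrainConfig(self.optimizer, self.learning_rate, self.batch_size,
                        self.epochs, self.image_size, self.seed),
            val,
        )
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        Xp = _prepare_images(X, self.image_size)
        self.model_.eval()
        logits = []
        with no_grad():
            for start in range(0, len(Xp), self.batch_size):
                out = self.model_(Tensor(Xp[start : start + self.batch_size]))
                logits.append(out.data)
        return np.concatenate(logits)

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def recalibrate_batchnorm(model, X: np.ndarray, batch_size: int) -> None:
    """Precise-BN pass: re-estimate normalization statistics under the final
    weights as the cumulative average of batch moments over the training set.

    During training each batch is normalized by its own statistics while the
    running averages trail the moving weights; re-estimating them after the
    last update makes inference consistent with the converged model.
    """
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    model.train()
    for i, start in enumerate(range(0, len(X), batch_size)):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)  # cumulative mean of batch moments
        with no_grad():
            model(Tensor(X[start : start + batch_size]))
    for bn in bns:
        bn.momentum = 0.1


def _fit_loop(model, X, y, config: TrainConfig, val=None) -> list[dict]:
    """Seeded minibatch training; returns per-epoch history."""
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    if config.optimizer == "adam":
        opt = Adam(model.parameters(), lr=config.learning_rate)
    else:
        opt = SGD(model.parameters(), lr=config.learning_rate)
    history = []
    n = len(X)
    for epoch in range(config.epochs):
        model.train()
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = model(Tensor(X[idx]))
            loss = cross_entropy(logits, y[idx])
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((np.argmax(logits.data, axis=1) == y[idx]).sum())
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": correct / n,
        }
        if val is not None:
            Xv, yv = val
            model.eval()
            with no_grad():
                vlogits = np.concatenate([
                    model(Tensor(Xv[s : s + config.batch_size])).data
                    for s in range(0, len(Xv), config.batch_size)
                ])
            vl = -np.mean(
                np.log(softmax(vlogits)[np.arange(len(yv)), yv] + 1e-12)
            )
            entry["val_loss"] = float(vl)
            entry["val_accuracy"] = float(np.mean(np.argmax(vlogits, axis=1) == yv))
        history.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
    recalibrate_batchnorm(model, X, config.batch_size)
    return history


def train(
    model: network_mod.MFSCNet,
    manifest: manifest_mod.DatasetManifest,
    config: TrainConfig,
    label_key: str = "tumor_class",
) -> tuple[network_mod.MFSCNet, list[dict]]:
    """Train a built network on the manifest's train split (validating on
    val when present).  Labels come from ``label_key``; the label order is
    sorted-unique over the train split."""
    X, y = load_split_arrays(manifest, "train", label_key)
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) != model.spec.num_classes:
        raise ValueError(
            f"model has {model.spec.num_classes} outputs but train split has "
            f"{len(classes)} classes"
        )
    val = None
    if any(r.split == "val" for r in manifest.records):
        Xv, yv = load_split_arrays(manifest, "val", label_key)
        val = (_prepare_images(Xv, config.image_size),
               np.searchsorted(classes, yv))
    history = _fit_loop(model, _prepare_images(X, config.image_size), y_enc, config, val)
    return model, history


def evaluate(
    model: network_mod.MFSCNet,
    manifest: manifest_mod.DatasetManifest,
    split: str = "test",
    label_key: str = "tumor_class",
    image_size: int | None = None,
    batch_size: int = 32,
) -> metrics_mod.MetricsReport:
    """Deterministic forward passes over one split; full metrics report."""
    X, y = load_split_arrays(manifest, split, label_key)
    classes = sorted(set(y.tolist()))
    size = image_size or model.spec.input_size
    Xp = _prepare_images(X, size)
    model.eval()
    with no_grad():
        logits = np.concatenate([
            model(Tensor(Xp[s : s + batch_size])).data
            for s in range(0, len(Xp), batch_size)
        ])
    scores = softmax(logits)
    predicted = np.asarray(classes)[np.argmax(logits, axis=1)]
    return metrics_mod.evaluate_predictions(y, predicted, scores, classes)


def run_experiment(config: str | Path | dict) -> dict:
    """Execute the full protocol from a YAML config (or equivalent dict).

    Stages: dataset (scan or synthesize) -> balanced subsetting -> 7:1:2
    stratified split -> stain normalization (target drawn from the training
    split) -> training-split augmentation -> network build -> training ->
    test evaluation.  All artifacts (manifest CSV, stain models, model spec,
    history CSV, metrics JSON) are written to the configured output
    directory.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out_dir = Path(config.get("out_dir", "experiment"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    task = config.get("task", "binary")
    label_key = "tumor_class" if task == "binary" else "subtype"

    def stage(name):
        logger.info("stage %s", name)
        return name

    current = stage("dataset")
    try:
        if "synth" in config:
            synth_cfg = dict(config["synth"])
            per_class = int(synth_cfg.pop("per_class", 100))
            params = synthetic_mod.SynthParams(seed=seed, **synth_cfg)
            man = synthetic_mod.generate_dataset(params, per_class, out_dir / "data")
        else:
            ds = config["dataset"]
            man = manifest_mod.scan_dataset(ds["root"], ds.get("layout", "breakhis"))

        if config.get("per_class"):
            current = stage("sample_subset")
            man = manifest_mod.sample_subset(man, task, int(config["per_class"]), seed)

        current = stage("make_splits")
        ratios = tuple(config.get("ratios", (0.7, 0.1, 0.2)))
        man = manifest_mod.make_splits(man, ratios, seed, stratify_by=label_key)

        norm_cfg = config.get("normalize", {})
        if norm_cfg.get("enabled", False):
            current = stage("normalize")
            man = _normalize_stage(man, norm_cfg, out_dir / "normalized", seed)

        ops = tuple(config.get("augment_ops", ()))
        if ops:
            current = stage("augment")
            man = augment_mod.expand_training_set(man, ops, out_dir / "augmented")

        current = stage("build_network")
        net_cfg = dict(config.get("network", {}))
        train_cfg = TrainConfig(seed=seed, **config.get("train", {}))
        classes = sorted({getattr(r, label_key) for r in man.records})
        spec = network_mod.ArchitectureSpec(
            num_classes=len(classes), input_size=train_cfg.image_size, **net_cfg
        )
        model = network_mod.build_network(spec, seed=seed)

        current = stage("train")
        model, history = train(model, man, train_cfg, label_key)

        current = stage("evaluate")
        report = evaluate(model, man, "test", label_key, train_cfg.image_size)
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {current!r}: {exc}") from exc

    man.to_csv(out_dir / "manifest.csv")
    pd.DataFrame(history).to_csv(out_dir / "history.csv", index=False)
    report.to_json(out_dir / "metrics.json")
    network_mod.save_model(model, out_dir / "model")
    (out_dir / "model_spec.json").write_text(json.dumps(spec.to_dict(), indent=1))
    (out_dir / "train_config.json").write_text(json.dumps(asdict(train_cfg), indent=1))
    return {"manifest": man, "model": model, "history": history, "report": report,
            "out_dir": out_dir}


def _normalize_stage(man, norm_cfg, out_dir, seed):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train_records = [r for r in man.records if r.split == "train"]
    if not train_records:
        raise ValueError("normalization requires a train split to choose the target")
    target_path = norm_cfg.get("target") or train_records[0].path
    normalizer = stain_mod.StainNormalizer(
        od_threshold=norm_cfg.get("od_threshold", stain_mod.DEFAULT_OD_THRESHOLD),
        sparsity=norm_cfg.get("sparsity", stain_mod.DEFAULT_SPARSITY),
        seed=seed,
    )
    normalizer.fit(np.asarray(Image.open(target_path).convert("RGB")))
    normalizer.target_model_.to_json(out_dir / "target_stain_model.json")
    from dataclasses import replace

    new_records = []
    for r in man.records:
        img = np.asarray(Image.open(r.path).convert("RGB"))
        norm = normalizer.transform(img)
        path = out_dir / f"{Path(r.path).stem}__norm.png"
        Image.fromarray(norm).save(path)
        new_records.append(replace(r, path=str(path),
                                   provenance=f"normalized:{r.path}"))
    return manifest_mod.DatasetManifest(new_records, seed=man.seed,
                                        provenance=f"{man.provenance}|normalize")
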