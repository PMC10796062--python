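"""Training and validation loop wiring phantoms, preprocessing, the network,
the hybrid losses and the metric suite together.

Defaults follow the segmentation setup this package implements: Adam with
weight decay 1e-4, 55 epochs, initial learning rate 3e-4 (kept constant; no
schedule), batch size 32, softmax activation head.  The ``small`` preset
overrides epochs, batch size and model size only, for desk-scale runs.

Reproducibility: the run seed drives the case-level train/val split, batch
shuffling and weight initialization, so one seed on one device yields
identical loss curves.  The split is by case, not by slice, so adjacent
slices of one case never straddle the split.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autograd import Tensor
from .containers import SliceSample
from .layers import Adam
from .losses import LossConfig, class_to_region_probs, mixed_loss
from .metrics import MetricsReport, evaluate, iou
from .model import (
    SMALL_CONFIG,
    CLASS_TO_LABEL,
    DenseUnet,
    DenseUnetConfig,
    build_denseunet,
)
from .preprocess import labels_to_regions, load_slice_dataset


class DataError(RuntimeError):
    """Raised when the slice store is missing or empty."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 55
    lr: float = 3e-4
    batch_size: int = 32
    weight_decay: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0
    val_fraction: float = 0.2
    device: str = "cpu"
    loss: LossConfig = field(default_factory=LossConfig)
    model: DenseUnetConfig = field(default_factory=DenseUnetConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def small_preset(**overrides) -> TrainConfig:
    """Desk-scale preset: 3-scale model, 10 epochs, batch 8; other defaults kept."""
    cfg = TrainConfig(epochs=10, batch_size=8, model=SMALL_CONFIG)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


@dataclass
class RunManifest:
    """Provenance record for one training run: resolved config, split,
    per-epoch curves, and the best checkpoint."""

    config: dict
    seed: int
    run_id: str
    train_cases: list[str]
    val_cases: list[str]
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_iou_wt: float = 0.0
    checkpoint_path: str = ""

    def curves(self) -> pd.DataFrame:
        """(epoch, train_loss, val_loss, train_iou, val_iou) per epoch."""
        cols = ["epoch", "train_loss", "val_loss", "train_iou", "val_iou"]
        return pd.DataFrame(self.epochs, columns=cols)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def save_checkpoint(network: DenseUnet, path: str | Path) -> Path:
    """Write weights as ``.npz`` plus a JSON config sidecar for rebuilding."""
    path = Path(path)
    np.savez(path, **network.state_dict())
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(network.config.to_dict(), fh, indent=2)
    return path


def load_checkpoint(path: str | Path) -> DenseUnet:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not path.exists() or not sidecar.exists():
        raise IOError(f"checkpoint {path} (or its .json sidecar) not found")
    with open(sidecar) as fh:
        config = DenseUnetConfig.from_dict(json.load(fh))
    network = build_denseunet(config)
    with np.load(path) as state:
        network.load_state_dict(dict(state))
    return network


def split_cases(samples: list[SliceSample], val_fraction: float,
                seed: int) -> tuple[list[str], list[str]]:
    """Seeded case-level split; at least one case on each side."""
    cases = sorted({s.case_id for s in samples})
    rng = np.random.default_rng(seed)
    order = [cases[i] for i in rng.permutation(len(cases))]
    n_val = max(1, int(round(val_fraction * len(cases))))
    n_val = min(n_val, len(cases) - 1) if len(cases) > 1 else 0
    val = sorted(order[:n_val])
    train = sorted(order[n_val:])
    return train, val


def _batch(samples: list[SliceSample], idx: np.ndarray) -> tuple[Tensor, Tensor]:
    images = np.stack([samples[i].image for i in idx]).astype(np.float32)
    targets = np.stack([samples[i].masks.stack() for i in idx]).astype(np.float32)
    return Tensor(images), Tensor(targets)


def _wt_iou_from_probs(probs: np.ndarray, targets: np.ndarray) -> list[float]:
    """Per-sample IoU of the whole-tumor region from class probabilities."""
    pred_wt = np.argmax(probs, axis=1) >= 1  # classes 1..3 are tumor labels
    return [iou(pred_wt[i], targets[i, 0] > 0.5) for i in range(probs.shape[0])]


def _run_validation(network: DenseUnet, samples: list[SliceSample],
                    loss_cfg: LossConfig, batch_size: int) -> tuple[float, float]:
    """Mean mixed loss and mean IoU(WT) over a sample list, eval mode."""
    network.eval()
    losses, ious = [], []
    for lo in range(0, len(samples), batch_size):
        idx = np.arange(lo, min(lo + batch_size, len(samples)))
        images, targets = _batch(samples, idx)
        probs = network(images)
        regions = class_to_region_probs(probs)
        losses.append(mixed_loss(regions, targets, loss_cfg).item() * len(idx))
        ious.extend(_wt_iou_from_probs(probs.data, targets.data))
    network.train()
    return float(np.sum(losses) / len(samples)), float(np.mean(ious))


def train(config: TrainConfig, data_dir: str | Path,
          out_dir: str | Path | None = None) -> tuple[RunManifest, DenseUnet]:
    """Train a dense U-Net on a preprocessed slice store.

    Returns the run manifest (curves, split, best epoch) and the network
    carrying the best-validation-IoU weights.  With ``epochs=0`` the
    checkpoint holds the initial weights and the curves are empty.
    """
    config.loss.validate()
    samples = load_slice_dataset(data_dir)
    if not samples:
        raise DataError(f"slice store {data_dir} is empty")
    train_cases, val_cases = split_cases(samples, config.val_fraction, config.seed)
    train_samples = [s for s in samples if s.case_id in train_cases]
    val_samples = [s for s in samples if s.case_id in val_cases]
    if not train_samples:
        raise DataError("training split is empty")

    model_cfg = dataclasses.replace(config.model, seed=config.seed)
    network = build_denseunet(model_cfg)
    optimizer = Adam(
        network.parameters(), lr=config.lr, weight_decay=config.weight_decay
    )
    rng = np.random.default_rng(config.seed + 1)

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        run_id=f"run-{config.seed}-{int(time.time())}",
        train_cases=train_cases,
        val_cases=val_cases,
    )

    best_state: dict[str, np.ndarray] | None = None
    network.train()
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_samples))
        epoch_losses, epoch_ious = [], []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            images, targets = _batch(train_samples, idx)
            network.zero_grad()
            probs = network(images)
            regions = class_to_region_probs(probs)
            loss = mixed_loss(regions, targets, config.loss)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: loss={value} at epoch {epoch}"
                )
            loss.backward()
            optimizer.step()
            epoch_losses.append(value * len(idx))
            epoch_ious.extend(_wt_iou_from_probs(probs.data, targets.data))
        val_loss, val_iou = (
            _run_validation(network, val_samples, config.loss, config.batch_size)
            if val_samples
            else (float("nan"), float("nan"))
        )
        manifest.epochs.append(
            {
                "epoch": epoch,
                "train_loss": float(np.sum(epoch_losses) / len(train_samples)),
                "val_loss": val_loss,
                "train_iou": float(np.mean(epoch_ious)),
                "val_iou": val_iou,
            }
        )
        if val_samples and val_iou >= manifest.best_val_iou_wt:
            manifest.best_val_iou_wt = val_iou
            manifest.best_epoch = epoch
            best_state = {k: v.copy() for k, v in network.state_dict().items()}

    if best_state is not None:
        network.load_state_dict(best_state)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt = save_checkpoint(network, out_dir / "checkpoint_best.npz")
        manifest.checkpoint_path = str(ckpt)
        manifest.curves().to_csv(out_dir / "curves.csv", index=False)
        manifest.save(out_dir / "manifest.json")
    return manifest, network


def predict_batch(network: DenseUnet, samples: list[SliceSample],
                  batch_size: int = 32) -> list:
    """Region-mask predictions for a sample list (argmax -> labels -> masks)."""
    network.eval()
    preds = []
    for lo in range(0, len(samples), batch_size):
        idx = np.arange(lo, min(lo + batch_size, len(samples)))
        images, _ = _batch(samples, idx)
        probs = network(images).data
        class_idx = np.argmax(probs, axis=1)
        for labels in CLASS_TO_LABEL[class_idx]:
            preds.append(labels_to_regions(labels))
    return preds


def validate(checkpoint: str | Path | DenseUnet, data_dir: str | Path,
             cases: list[str] | None = None, batch_size: int = 32) -> MetricsReport:
    """Full metric report (Dice/PPV/Sensitivity/HD95/IoU per region) for a
    checkpoint over a slice store, optionally restricted to given cases."""
    network = (
        checkpoint if isinstance(checkpoint, DenseUnet) else load_checkpoint(checkpoint)
    )
    samples = load_slice_dataset(data_dir)
    if cases is not None:
        wanted = set(cases)
        samples = [s for s in samples if s.case_id in wanted]
    if not samples:
        raise DataError("no samples to evaluate")
    preds = predict_batch(network, samples, batch_size=batch_size)
    targets = [s.masks for s in samples]
    ids = [f"{s.case_id}/z{s.slice_index}" for s in samples]
    return evaluate(preds, targets, sample_ids=ids)


def run_ablation(base: TrainConfig, data_dir: str | Path,
                 mixtures: tuple[str, ...] = ("bce_tversky", "bce_dice", "bce_jaccard"),
                 ) -> pd.DataFrame:
    """Train once per loss mixture through an identical pipeline and report
    the 3-region x 4-metric table (rows: mixture, cols: region x metric)."""
    rows = {}
    for mixture in mixtures:
        cfg = dataclasses.replace(
            base, loss=dataclasses.replace(base.loss, mixture=mixture)
        )
        manifest, network = train(cfg, data_dir)
        report = validate(network, data_dir, cases=manifest.val_cases,
                          batch_size=cfg.batch_size)
        flat = {}
        for region, metrics_ in report.summary_dict().items():
            for name in ("dice", "ppv", "sensitivity", "hd95"):
                flat[f"{region}_{name}"] = metrics_[name]
        rows[mixture] = flat
    return pd.DataFrame.from_dict(rows, orient="index")
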