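"""Training and evaluation loops.

``train_steps`` is the minimal seeded loop used by tests and scaled-down
experiments; ``train_model`` drives the full config-based recipe (Dice loss,
Adam, per-epoch validation, best-checkpoint selection by validation MIOU).
"""

from __future__ import annotations

import csv
import logging
import sys
import time
from pathlib import Path

import numpy as np
from PIL import Image

from . import autodiff as ad
from .autodiff import Tensor
from .config import RunConfig
from .data import DatasetSplits, load_dataset
from .metrics import confusion_counts, dice_loss, segmentation_metrics
from .model import IrisSegNet, predict_mask, save_checkpoint
from .nn import Adam

__all__ = ["train_steps", "train_model", "evaluate_model", "predict_image",
           "TrainingDiverged"]

log = logging.getLogger("irisseg")


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


def _setup_logging(logfile=None):
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(fh)
        return fh
    return None


def train_steps(model: IrisSegNet, images: np.ndarray, masks: np.ndarray,
                steps: int, batch_size: int = 2, lr: float = 1e-3,
                seed: int = 0, log_every: int = 0):
    """Run ``steps`` Adam updates of the Dice loss; returns per-step losses.

    Batches are drawn by reshuffling the sample order every epoch with a
    generator seeded by ``seed``, so two runs with equal seeds follow
    identical trajectories.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    model.train()
    n = len(images)
    losses = []
    order = rng.permutation(n)
    cursor = 0
    for step in range(steps):
        if cursor + batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor:cursor + batch_size]
        cursor += batch_size
        xb = Tensor(images[idx])
        yb = masks[idx][:, None].astype(np.float32)
        logits = model(xb)
        loss = dice_loss(ad.sigmoid(logits), yb)
        value = float(loss.data)
        if not np.isfinite(value):
            raise TrainingDiverged(f"non-finite loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(value)
        if log_every and step % log_every == 0:
            log.info("step=%d loss=%.4f", step, value)
    return losses


def _epoch_metrics(model, images, masks, batch_size=8):
    model.eval()
    counts = []
    with ad.no_grad():
        for i in range(0, len(images), batch_size):
            logits = model(Tensor(images[i:i + batch_size]))
            preds = predict_mask(logits)[:, 0]
            for p, g in zip(preds, masks[i:i + batch_size]):
                counts.append(confusion_counts(p, g))
    model.train()
    return segmentation_metrics(counts)


def train_model(cfg: RunConfig, data: DatasetSplits | None = None):
    """Full training run per the configured recipe.

    Returns ``(model, history)``; saves ``best.npz`` (highest validation
    MIOU) and ``final.npz`` under ``cfg.checkpoint_dir``.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = _setup_logging(out_dir / "train.log")
    try:
        if data is None:
            data = load_dataset(cfg.data_dir, cfg.input_size, cfg.split,
                                cfg.seed)
        cfg.model.random_seed = cfg.seed
        model = IrisSegNet(cfg.model)
        opt = Adam(model.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        ckpt_dir = Path(cfg.checkpoint_dir)
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        n = len(data.train_images)
        history = {"train_loss": [], "val_miou": []}
        best_miou = -1.0
        log.info("training on %d images (val %d, test %d), %d epochs, "
                 "batch %d, lr %g", n, len(data.val_images),
                 len(data.test_images), cfg.epochs, cfg.batch_size,
                 cfg.learning_rate)
        for epoch in range(cfg.epochs):
            model.train()
            order = rng.permutation(n)
            epoch_losses = []
            t0 = time.time()
            limit = n - n % cfg.batch_size  # drop the ragged tail batch
            for start in range(0, limit if limit else n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = Tensor(data.train_images[idx])
                yb = data.train_masks[idx][:, None].astype(np.float32)
                loss = dice_loss(ad.sigmoid(model(xb)), yb)
                value = float(loss.data)
                if not np.isfinite(value):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch} step "
                        f"{start // cfg.batch_size}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(value)
            train_loss = float(np.mean(epoch_losses))
            history["train_loss"].append(train_loss)
            if len(data.val_images):
                report = _epoch_metrics(model, data.val_images, data.val_masks)
                history["val_miou"].append(report.miou)
                log.info("epoch=%d train_loss=%.4f val_miou=%.4f "
                         "val_f1=%.4f elapsed=%.1fs", epoch, train_loss,
                         report.miou, report.f1, time.time() - t0)
                if report.miou > best_miou:
                    best_miou = report.miou
                    save_checkpoint(ckpt_dir / "best.npz", model)
            else:
                log.info("epoch=%d train_loss=%.4f elapsed=%.1fs",
                         epoch, train_loss, time.time() - t0)
        save_checkpoint(ckpt_dir / "final.npz", model)
        if best_miou < 0:
            save_checkpoint(ckpt_dir / "best.npz", model)
        return model, history
    finally:
        if fh is not None:
            log.removeHandler(fh)
            fh.close()


def evaluate_model(model: IrisSegNet, images: np.ndarray, masks: np.ndarray,
                   out_dir=None, batch_size: int = 8, overlays: bool = False,
                   aggregate: str = "per_image"):
    """Predict every image, compute the metrics report, optionally write
    JSON/CSV reports and side-by-side overlay PNGs."""
    model.eval()
    counts, preds = [], []
    with ad.no_grad():
        for i in range(0, len(images), batch_size):
            logits = model(Tensor(images[i:i + batch_size]))
            batch_preds = predict_mask(logits)[:, 0]
            for p, g in zip(batch_preds, masks[i:i + batch_size]):
                counts.append(confusion_counts(p, g))
                preds.append(p)
    report = segmentation_metrics(counts, aggregate=aggregate)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(report.to_json())
        with open(out / "per_image.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["index", "tp", "fp", "fn", "tn",
                             "iou", "f1", "nice2"])
            for i, c in enumerate(counts):
                writer.writerow([i, c.tp, c.fp, c.fn, c.tn,
                                 f"{c.iou():.6f}", f"{c.f1():.6f}",
                                 f"{c.nice2():.6f}"])
            writer.writerow(["aggregate", "", "", "", "",
                             f"{report.miou:.6f}", f"{report.f1:.6f}",
                             f"{report.nice2:.6f}"])
        if overlays:
            for i, (img, gt, pr) in enumerate(zip(images, masks, preds)):
                panel = np.concatenate([
                    img.transpose(1, 2, 0),
                    np.repeat(gt[..., None], 3, axis=-1).astype(np.float32),
                    np.repeat(pr[..., None], 3, axis=-1).astype(np.float32),
                ], axis=1)
                Image.fromarray(
                    (np.clip(panel, 0, 1) * 255).astype(np.uint8)
                ).save(out / f"overlay_{i:04d}.png")
    return report, counts, preds


def predict_image(model: IrisSegNet, image: np.ndarray,
                  threshold: float = 0.5) -> np.ndarray:
    """Segment one preprocessed (3, S, S) image into a uint8 {0, 1} mask."""
    model.eval()
    with ad.no_grad():
        logits = model(Tensor(image[None]))
    return predict_mask(logits, threshold)[0, 0]
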