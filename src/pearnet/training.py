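"""Training loop: SGD with momentum, warmup + cosine learning-rate decay,
per-epoch train/validation loss history, and checkpointing.

The optimisation recipe follows the detector's published settings: SGD,
initial learning rate 0.01, weight decay 4.8e-4, momentum 0.937, batches
of 8 images at 640x640 for 200 epochs.  The learning rate is annealed
with a cosine schedule to a final factor of 0.1; early iterations ramp
the learning rate from zero and the momentum from 0.8 (the stock warmup).
Desk-scale runs shrink the input size, width multiple, dataset and epoch
count but keep the same recipe.
"""

from __future__ import annotations

import dataclasses
import io
import math
from pathlib import Path

import numpy as np
import yaml

from .arch import Detector, ModelConfig, build_model
from .data_io import BoundingBox, DatasetIndex, ImageRecord
from .losses import DetectionLoss
from .nn import SGD, Tensor

__all__ = ["TrainConfig", "train", "load_pretrained", "save_checkpoint",
           "load_checkpoint", "history_to_csv", "load_image"]


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 8
    epochs: int = 200
    lr0: float = 0.01
    lrf: float = 0.1              # final lr = lr0 * lrf after cosine decay
    weight_decay: float = 0.00048
    momentum: float = 0.937
    warmup_epochs: float = 3.0
    warmup_momentum: float = 0.8
    input_size: int = 640
    seed: int = 0
    augment: bool = True
    w_box: float = 0.05
    w_obj: float = 1.0
    w_cls: float = 0.5
    pretrained_weights: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if min(self.lr0, self.weight_decay, self.momentum) < 0:
            raise ValueError("optimizer hyperparameters must be non-negative")


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------


def load_image(record: ImageRecord, input_size: int) -> np.ndarray:
    """Load and letterbox-free resize an image record to input_size
    (uint8 HWC RGB).  Normalised box coordinates are unchanged by the
    plain resize."""
    from PIL import Image

    with Image.open(record.path) as im:
        im = im.convert("RGB")
        if im.size != (input_size, input_size):
            im = im.resize((input_size, input_size), Image.BILINEAR)
        return np.asarray(im)


def _to_chw(images: list[np.ndarray]) -> Tensor:
    arr = np.stack(images).astype(np.float32) / 255.0
    return Tensor(arr.transpose(0, 3, 1, 2))


def _lr_at(cfg: TrainConfig, epoch: int) -> float:
    t = epoch / max(cfg.epochs - 1, 1)
    return cfg.lr0 * ((1 - cfg.lrf) * 0.5 * (1 + math.cos(math.pi * t))
                      + cfg.lrf)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train(model: Detector, dataset: DatasetIndex, cfg: TrainConfig
          ) -> tuple[Detector, list[dict]]:
    """Train ``model`` on the dataset's train split, validating on its val
    split each epoch.

    Returns the model (restored to its best-validation weights) and the
    loss history: one dict per epoch with ``train_total``, ``train_box``,
    ``val_total``, ``val_box`` and ``lr``.  Raises ``RuntimeError`` on a
    non-finite loss.
    """
    train_recs = dataset.subset("train")
    val_recs = dataset.subset("val") or train_recs
    if not train_recs:
        raise ValueError("dataset has an empty train split")

    rng = np.random.default_rng(cfg.seed)
    loss_fn = DetectionLoss(model.cfg, cfg.w_box, cfg.w_obj, cfg.w_cls)
    decay, nodecay = [], []
    for _, p in model.named_parameters():
        (decay if p.data.ndim >= 2 else nodecay).append(p)  # wd on conv/linear weights only
    opt = SGD(decay, nodecay, lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)

    cache: dict[str, np.ndarray] = {}

    def fetch(rec: ImageRecord) -> np.ndarray:
        if rec.path not in cache:
            cache[rec.path] = load_image(rec, cfg.input_size)
        return cache[rec.path]

    n_batches = math.ceil(len(train_recs) / cfg.batch_size)
    warmup_iters = max(round(cfg.warmup_epochs * n_batches), 1)
    history: list[dict] = []
    best = (math.inf, None)
    it = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_recs))
        lr_e = _lr_at(cfg, epoch)
        tot_sum = box_sum = 0.0
        for bi in range(n_batches):
            idx = order[bi * cfg.batch_size:(bi + 1) * cfg.batch_size]
            imgs, tgts = [], []
            for j in idx:
                rec = train_recs[j]
                img, boxes = fetch(rec), rec.boxes
                if cfg.augment:
                    from .synthgen import augment as _aug
                    img, boxes = _aug(img, boxes,
                                      seed=int(rng.integers(2 ** 31)))
                imgs.append(img)
                tgts.append(boxes)
            x = _to_chw(imgs)
            raw = model(x)
            total, comps = loss_fn(raw, tgts)
            if not math.isfinite(comps["total"]):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, batch {bi}: "
                    f"loss components {comps}")
            model.zero_grad()
            total.backward()
            if it < warmup_iters:  # linear warmup of lr and momentum
                frac = (it + 1) / warmup_iters
                opt.lr = lr_e * frac
                opt.momentum = (cfg.warmup_momentum
                                + (cfg.momentum - cfg.warmup_momentum) * frac)
            else:
                opt.lr = lr_e
                opt.momentum = cfg.momentum
            opt.step()
            it += 1
            tot_sum += comps["total"] / len(idx)
            box_sum += comps["box"]
        val_total, val_box = _validation_loss(model, val_recs, loss_fn,
                                              cfg, fetch)
        history.append({
            "epoch": epoch, "lr": lr_e,
            "train_total": tot_sum / n_batches,
            "train_box": box_sum / n_batches,
            "val_total": val_total, "val_box": val_box,
        })
        if val_total < best[0]:
            best = (val_total, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def _validation_loss(model, records, loss_fn, cfg, fetch):
    model.eval()
    tot = box = 0.0
    n_batches = math.ceil(len(records) / cfg.batch_size)
    for bi in range(n_batches):
        recs = records[bi * cfg.batch_size:(bi + 1) * cfg.batch_size]
        x = _to_chw([fetch(r) for r in recs])
        raw = model(x)
        _, comps = loss_fn(raw, [r.boxes for r in recs])
        tot += comps["total"] / len(recs)
        box += comps["box"]
    return tot / n_batches, box / n_batches


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: Detector, path, epoch: int | None = None) -> None:
    sd = model.state_dict()
    meta = {"config": model.cfg.to_yaml(), "epoch": epoch}
    np.savez(path, __meta__=yaml.safe_dump(meta), **sd)


def load_checkpoint(path, model: Detector | None = None
                    ) -> tuple[Detector, int | None]:
    """Rebuild (or refill) a detector from a checkpoint file."""
    with np.load(path, allow_pickle=False) as z:
        meta = yaml.safe_load(str(z["__meta__"]))
        sd = {k: z[k] for k in z.files if k != "__meta__"}
    if model is None:
        model = build_model(ModelConfig.from_yaml(meta["config"]))
    model.load_state_dict(sd, strict=True)
    return model, meta.get("epoch")


def load_pretrained(model: Detector, path) -> tuple[list[str], list[str]]:
    """Transfer-learning hook: load every shape-compatible entry from a
    checkpoint into ``model``; mismatching or unknown entries are skipped.
    Returns (loaded, skipped) name lists."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    try:
        with np.load(p, allow_pickle=False) as z:
            sd = {k: z[k] for k in z.files if k != "__meta__"}
    except Exception as e:
        raise ValueError(f"unreadable weight file {p}: {e}") from None
    return model.load_state_dict(sd, strict=False)


def history_to_csv(history: list[dict]) -> str:
    cols = ["epoch", "lr", "train_total", "train_box", "val_total", "val_box"]
    buf = io.StringIO()
    buf.write(",".join(cols) + "\n")
    for row in history:
        buf.write(",".join(f"{row[c]:.6g}" for c in cols) + "\n")
    return buf.getvalue()
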