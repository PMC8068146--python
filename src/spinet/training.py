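"""Training loop, checkpointing, and dataset evaluation.

Training minimizes the class-weighted cross-entropy plus the auxiliary
("loss reuse") term with Adam at a base learning rate of 0.01.  All
randomness — parameter initialization, sample order, augmentation draws —
derives from the single seed in the configuration, so a rerun with the same
config reproduces the same losses.  The checkpoint with the best validation
mIoU is retained.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .config import TrainConfig, config_from_dict, config_to_dict
from .grad import Adam, Tensor
from .imagery import DatasetManifest, load_image, load_mask
from .metrics import SegMetrics, compute_metrics, confusion, total_loss
from .model import SPINet, normalize_image, predict_mask
from .synthetic import apply_pipeline


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_pa: float
    val_miou: float


@dataclass
class TrainResult:
    model: SPINet
    epochs: list
    iteration_losses: list
    best_miou: float


class NonFiniteLossError(RuntimeError):
    pass


def _load_pairs(manifest: DatasetManifest, split: str):
    pairs = []
    for e in manifest.paths(split):
        for p in (e.image, e.mask):
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest refers to missing file: {p}")
        pairs.append((load_image(e.image), load_mask(e.mask)))
    return pairs


def validate(model: SPINet, pairs) -> tuple[SegMetrics, list[SegMetrics]]:
    """Pooled metrics (one confusion matrix across all pixels) plus per-image."""
    pooled = np.zeros((3, 3), dtype=np.int64)
    per_image = []
    for img, mask in pairs:
        cm = confusion(predict_mask(model, img), mask)
        pooled += cm
        per_image.append(compute_metrics(cm))
    return compute_metrics(pooled), per_image


def fit(train_pairs, val_pairs, config: TrainConfig,
        log_stream=None, progress: bool = False) -> TrainResult:
    """Train a fresh model on in-memory (image, mask) pairs.

    `train_pairs` and `val_pairs` are sequences of (H×W×3 uint8, H×W label)
    arrays.  Returns the model restored to its best-validation-mIoU weights,
    the per-epoch records, and the raw per-iteration loss trace.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and val splits must both be nonempty")
    model = SPINet(config.model, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.base_lr)
    order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = len(train_pairs)
    records: list[EpochRecord] = []
    iter_losses: list[float] = []
    best_miou, best_state = -1.0, model.state_dict()
    epoch_iter = range(1, config.epochs + 1)
    if progress:
        from tqdm import tqdm
        epoch_iter = tqdm(epoch_iter, desc="epochs")
    for epoch in epoch_iter:
        perm = order_rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xs, ys = [], []
            for i in idx:
                img, mask = train_pairs[i]
                aug_seed = int(np.random.SeedSequence(
                    [config.seed, epoch, int(i)]).generate_state(1)[0] % (2 ** 31))
                img, mask = apply_pipeline(img, mask, config.augmentations, aug_seed)
                xs.append(normalize_image(img))
                ys.append(mask)
            x = Tensor(np.stack(xs))
            y = np.stack(ys)
            out = model.forward(x, train_mode=True)
            loss = total_loss(out.main, out.aux, y, config.class_weights, config.aux_lambda)
            lval = loss.item()
            if not np.isfinite(lval):
                raise NonFiniteLossError(
                    f"loss became non-finite at epoch {epoch}, iteration {len(iter_losses)}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            iter_losses.append(lval)
            epoch_loss += lval * len(idx)
            seen += len(idx)
        val_metrics, _ = validate(model, val_pairs)
        rec = EpochRecord(epoch=epoch, train_loss=epoch_loss / seen,
                          val_pa=val_metrics.pixel_accuracy, val_miou=val_metrics.miou)
        records.append(rec)
        if log_stream is not None:
            log_stream.write(json.dumps(asdict(rec)) + "\n")
        if val_metrics.miou > best_miou:
            best_miou = val_metrics.miou
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return TrainResult(model=model, epochs=records,
                       iteration_losses=iter_losses, best_miou=best_miou)


def train(manifest: DatasetManifest, config: TrainConfig,
          progress: bool = False) -> TrainResult:
    """Train from a dataset manifest on disk; see :func:`fit`."""
    train_pairs = _load_pairs(manifest, "train")
    val_pairs = _load_pairs(manifest, "val")
    log_dir = Path(config.log_dir)
    log_dir.mkdir(parents=True, exist_ok=True)
    with open(log_dir / "epochs.jsonl", "w") as log:
        result = fit(train_pairs, val_pairs, config, log_stream=log, progress=progress)
    ckpt_dir = Path(config.checkpoint_dir)
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    save_checkpoint(result.model, config, ckpt_dir / "best.npz")
    return result


def evaluate(manifest: DatasetManifest, model: SPINet,
             split: str = "test") -> tuple[SegMetrics, list[SegMetrics]]:
    """Run prediction over a split and pool one confusion matrix across it."""
    pairs = _load_pairs(manifest, split)
    if not pairs:
        raise ValueError(f"manifest has no '{split}' entries")
    return validate(model, pairs)


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(model: SPINet, config: TrainConfig, path) -> None:
    """Store weights plus the full config so a checkpoint is self-describing."""
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    state["config_json"] = np.frombuffer(
        json.dumps(config_to_dict(config)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> tuple[SPINet, TrainConfig]:
    with np.load(path) as data:
        config = config_from_dict(json.loads(bytes(data["config_json"]).decode()))
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model = SPINet(config.model, seed=config.seed)
    model.load_state_dict(state)
    return model, config
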