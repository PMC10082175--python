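"""Training: splits, augmentation, the optimization loop, model selection.

The protocol: the image list is randomly split 3:1:1 into train/validation/
test. Training samples are random fixed-size crops (default 256 x 256) with
random horizontal flips; the same window and flip are applied to the image
and to its precomputed full-resolution density map, so objects cut by the
crop border contribute fractional mass — the map is then sum-pooled x8 into
the learning target and thresholded into the segmentation target on the fly.
Optimization is Adam (default lr 1e-5, weight decay 1e-4, batch 16) for 600
epochs. From a configurable epoch onward every epoch is validated on full
(uncropped) images through the fused inference path; the checkpoint with the
lowest validation MAE + RMSE is the selected model, ties going to the
earliest epoch.

All randomness derives from ``TrainConfig.seed``; each epoch reseeds from
(seed, epoch), which makes runs exactly reproducible and checkpoints
resumable mid-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import PointAnnotationSet
from .evaluation import mae as _mae, rmse as _rmse
from .losses import (
    LossConfig,
    masked_structural_loss_grad,
    weighted_cross_entropy_grad,
)
from .network import Network, predict_count, save_checkpoint
from .targets import (
    ConfigError,
    DensityMap,
    GenerationConfig,
    downsample_density,
    generate_density_map,
)

__all__ = [
    "TrainConfig",
    "CheckpointRecord",
    "TrainingScene",
    "TrainResult",
    "prepare_scenes",
    "split_dataset",
    "augment",
    "select_best",
    "optimizer_from_checkpoint",
    "train",
]


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the reference protocol)."""

    crop_size: int = 256
    flip_prob: float = 0.5
    epochs: int = 600
    batch_size: int = 16
    learning_rate: float = 1e-5
    weight_decay: float = 1e-4
    validate_after_epoch: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_size % 16:
            raise ConfigError("crop_size must be divisible by 16")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


@dataclass
class CheckpointRecord:
    """Validation result of one epoch; selection score is MAE + RMSE."""

    epoch: int
    val_mae: float
    val_rmse: float

    @property
    def selection_score(self) -> float:
        return self.val_mae + self.val_rmse


@dataclass
class TrainingScene:
    """An image with its precomputed full-resolution density map."""

    image_id: str
    image: np.ndarray  # HWC uint8 (or float in [0,1])
    density: np.ndarray  # full-resolution float64 density map
    gt_count: float


@dataclass
class TrainResult:
    best: CheckpointRecord | None
    history: list[dict]
    best_params: list[np.ndarray] | None = None

    @property
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def prepare_scenes(
    scenes: list[tuple[np.ndarray, PointAnnotationSet]],
    gen_cfg: GenerationConfig | None = None,
) -> list[TrainingScene]:
    """Precompute each scene's full-resolution density map once."""
    gen_cfg = gen_cfg or GenerationConfig()
    return [
        TrainingScene(
            image_id=ann.image_id,
            image=image,
            density=generate_density_map(ann, gen_cfg).values,
            gt_count=float(ann.count),
        )
        for image, ann in scenes
    ]


def split_dataset(
    ids: list, ratios: tuple[int, int, int] = (3, 1, 1), seed: int = 0
) -> tuple[list, list, list]:
    """Random disjoint train/val/test split in the given ratio.

    Validation and test sizes are floored; the remainder goes to training.
    The shuffle is seeded and reproducible.
    """
    if len(ids) < 5:
        raise ConfigError(f"need at least 5 items to split 3:1:1, got {len(ids)}")
    total = sum(ratios)
    n = len(ids)
    n_val = n * ratios[1] // total
    n_test = n * ratios[2] // total
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    test = perm[:n_test]
    val = perm[n_test : n_test + n_val]
    trainset = perm[n_test + n_val :]
    return trainset, val, test


def augment(
    image: np.ndarray,
    density: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random crop + random horizontal flip, applied identically to both.

    Images smaller than the crop are zero-padded bottom/right first. The
    cropped density map keeps exactly the mass inside the crop window
    (fractional at borders); a flip maps column x to width-1-x.
    """
    c = cfg.crop_size
    h, w = image.shape[:2]
    if h < c or w < c:
        ph, pw = max(0, c - h), max(0, c - w)
        image = np.pad(image, [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2))
        density = np.pad(density, ((0, ph), (0, pw)))
        h, w = image.shape[:2]
    top = int(rng.integers(0, h - c + 1))
    left = int(rng.integers(0, w - c + 1))
    img_c = image[top : top + c, left : left + c]
    den_c = density[top : top + c, left : left + c]
    if rng.random() < cfg.flip_prob:
        img_c = img_c[:, ::-1]
        den_c = den_c[:, ::-1]
    return np.ascontiguousarray(img_c), np.ascontiguousarray(den_c)


def optimizer_from_checkpoint(model: Network, meta: dict, train_cfg: TrainConfig):
    """Rebuild the Adam state saved alongside a checkpoint (for resuming)."""
    from .nn import Adam

    opt = Adam(
        model.params(),
        lr=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
    )
    arrays = meta.get("_arrays", {})
    if "optimizer" in meta and arrays:
        n = len(model.params())
        opt.load_state_dict(
            {
                "t": meta["optimizer"]["t"],
                "m": [arrays[f"adam_m_{i}"] for i in range(n)],
                "v": [arrays[f"adam_v_{i}"] for i in range(n)],
            }
        )
    return opt


def select_best(records: list[CheckpointRecord]) -> CheckpointRecord:
    """Checkpoint with the lowest MAE + RMSE; ties go to the earliest epoch."""
    if not records:
        raise ConfigError("no validation records to select from")
    best = records[0]
    for r in records[1:]:
        if r.selection_score < best.selection_score:
            best = r
    return best


def _validate(net: Network, scenes: list[TrainingScene]) -> tuple[float, float]:
    preds, gts = [], []
    for sc in scenes:
        count, _, _ = predict_count(net, sc.image)
        preds.append(count)
        gts.append(sc.gt_count)
    return _mae(preds, gts), _rmse(preds, gts)


def train(
    model: Network,
    datasets: tuple[list[TrainingScene], list[TrainingScene]],
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    gen_cfg: GenerationConfig | None = None,
    log_path: str | Path | None = None,
    checkpoint_path: str | Path | None = None,
    start_epoch: int = 1,
    optimizer=None,
) -> TrainResult:
    """Run the optimization loop and return the selected checkpoint + history.

    ``datasets`` is (training scenes, validation scenes). Targets are built
    on the fly: augment -> sum-pool x8 -> threshold. Per-epoch mean loss is
    logged; once ``epoch > validate_after_epoch`` each epoch is validated
    with the fused inference path and recorded. On return the model carries
    the best checkpoint's weights (``TrainResult.best_params``); pass
    ``start_epoch``/``optimizer`` (e.g. from a saved checkpoint) to resume.
    A non-finite training loss aborts with a diagnostic.
    """
    from .nn import Adam  # local import to keep module surface tidy

    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    gen_cfg = gen_cfg or GenerationConfig()
    train_scenes, val_scenes = datasets
    if not train_scenes:
        raise ConfigError("empty training set")
    if optimizer is None:
        optimizer = Adam(
            model.params(),
            lr=train_cfg.learning_rate,
            weight_decay=train_cfg.weight_decay,
        )
    factor = gen_cfg.downsample_factor
    history: list[dict] = []
    records: list[CheckpointRecord] = []
    best: CheckpointRecord | None = None
    best_params: list[np.ndarray] | None = None

    for epoch in range(start_epoch, train_cfg.epochs + 1):
        rng = np.random.default_rng([train_cfg.seed, epoch])
        order = rng.permutation(len(train_scenes))
        epoch_losses = []
        for b0 in range(0, len(order), train_cfg.batch_size):
            idxs = order[b0 : b0 + train_cfg.batch_size]
            imgs, dtargets, sgts = [], [], []
            for i in idxs:
                sc = train_scenes[i]
                img_c, den_c = augment(sc.image, sc.density, train_cfg, rng)
                dt = downsample_density(DensityMap(den_c), factor).values
                imgs.append(model.normalize(img_c))
                dtargets.append(dt)
                sgts.append((dt > gen_cfg.seg_epsilon).astype(np.float64))
            x = np.stack(imgs)
            dens, seg = model.forward_batch(x, train=True)
            nb = len(idxs)
            g_dens = np.zeros_like(dens, dtype=np.float64)
            g_seg = np.zeros_like(seg, dtype=np.float64)
            batch_loss = 0.0
            for j in range(nb):
                sl, g_sl = masked_structural_loss_grad(
                    dens[j, 0].astype(np.float64), dtargets[j], sgts[j], loss_cfg
                )
                ce, g_ce = weighted_cross_entropy_grad(
                    seg[j, 0].astype(np.float64), sgts[j], loss_cfg
                )
                batch_loss += sl + loss_cfg.lambda_seg * ce
                g_dens[j, 0] = g_sl / nb
                g_seg[j, 0] = loss_cfg.lambda_seg * g_ce / nb
            batch_loss /= nb
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            model.backward_batch(g_dens, g_seg)
            optimizer.step()
            optimizer.zero_grad()
            epoch_losses.append(batch_loss)

        entry: dict = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if epoch > train_cfg.validate_after_epoch and val_scenes:
            vmae, vrmse = _validate(model, val_scenes)
            rec = CheckpointRecord(epoch=epoch, val_mae=vmae, val_rmse=vrmse)
            records.append(rec)
            entry.update(val_mae=vmae, val_rmse=vrmse, selection_score=rec.selection_score)
            if best is None or rec.selection_score < best.selection_score:
                best = rec
                best_params = [p.value.copy() for p in model.params()]
        history.append(entry)
        if checkpoint_path is not None:
            save_checkpoint(
                checkpoint_path, model, optimizer, extra={"epoch": epoch}
            )

    if best_params is not None:
        for p, v in zip(model.params(), best_params):
            p.value = v.copy()
    if log_path is not None:
        pd.DataFrame(history).to_csv(log_path, index=False)
    return TrainResult(best=best, history=history, best_params=best_params)
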