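"""Training loop (Dice loss, IoU validation, Adam) and tiled inference."""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from ..volume_io import Volume3D
from . import nn
from .unet import UNet3D

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization protocol: Dice loss, IoU validation, Adam at lr 1e-4.

    ``epochs`` defaults to a desk-scale 50; pass 500 to reproduce the
    full-scale protocol.  ``subvolume_edge``/``subvolumes_per_paw`` describe
    the tile extraction feeding this loop.
    """

    epochs: int = 50
    lr: float = 1e-4
    val_fraction: float = 0.25
    seed: int = 0
    patches_per_epoch: int = 4
    patch: int | None = None  # None = NetConfig.patch
    fg_patch_fraction: float = 0.5  # fraction of patches forced to contain joint voxels
    subvolume_edge: int = 200
    subvolumes_per_paw: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.lr < 0:
            raise ValueError(f"lr must be >= 0, got {self.lr}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TileSpec:
    """Non-overlapping tiled inference geometry (default 352^3 tiles)."""

    tile_edge: int = 352
    overlap: int = 0
    pad_mode: str = "edge"

    def __post_init__(self) -> None:
        if not self.tile_edge > self.overlap >= 0:
            raise ValueError(f"need tile_edge > overlap >= 0, got {self.tile_edge}/{self.overlap}")


@dataclass
class JointPrediction:
    """Probability volume plus its binarization."""

    probability: np.ndarray
    mask: np.ndarray
    threshold: float = 0.5


def _sample_patch(
    rng: np.random.Generator,
    image: np.ndarray,
    mask: np.ndarray,
    patch: int,
    force_fg: bool,
) -> tuple[np.ndarray, np.ndarray]:
    shape = image.shape
    pad = [(0, max(patch - s, 0)) for s in shape]
    if any(p[1] for p in pad):
        image = np.pad(image, pad, mode="edge")
        mask = np.pad(mask, pad, mode="constant")
        shape = image.shape
    max_origin = [s - patch for s in shape]
    if force_fg and mask.any():
        # center the patch near a random joint voxel
        coords = np.argwhere(mask)
        c = coords[rng.integers(len(coords))]
        origin = [int(np.clip(c[i] - patch // 2, 0, max_origin[i])) for i in range(3)]
    else:
        origin = [int(rng.integers(m + 1)) for m in max_origin]
    sl = tuple(slice(o, o + patch) for o in origin)
    return image[sl], mask[sl]


def validation_iou(model: UNet3D, tiles, threshold: float = 0.5) -> float:
    """Mean IoU of binarized predictions over validation tiles."""
    scores = []
    for image, mask in tiles:
        prob = model.predict(model.normalize(image))[0]
        scores.append(nn.iou(prob >= threshold, mask))
    return float(np.mean(scores)) if scores else float("nan")


def train(
    model: UNet3D,
    train_tiles: list[tuple[np.ndarray, np.ndarray]],
    val_tiles: list[tuple[np.ndarray, np.ndarray]] | None,
    cfg: TrainConfig | None = None,
) -> tuple[UNet3D, pd.DataFrame]:
    """Optimize the Dice loss over random patches; keep the best-IoU weights.

    Patches of ``cfg.patch`` (default: the net's training patch) are drawn
    from the tiles each epoch, half forced to contain at least one joint
    voxel.  History has one row per epoch (mean train Dice loss, validation
    IoU); the returned model carries the best-validation-IoU weights (the
    final weights when there is no validation set).
    """
    cfg = cfg or TrainConfig()
    if not train_tiles:
        raise ValueError("empty training set")
    if all(not np.asarray(m).any() for _, m in train_tiles):
        logger.warning("all training tiles have empty joint masks; Dice guarded by smoothing")
    rng = np.random.default_rng(cfg.seed)
    patch = cfg.patch or model.cfg.patch
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    rows = []
    best_iou = -np.inf
    best_state = None
    for epoch in range(cfg.epochs):
        losses = []
        for k in range(cfg.patches_per_epoch):
            ti = int(rng.integers(len(train_tiles)))
            image, mask = train_tiles[ti]
            force_fg = rng.random() < cfg.fg_patch_fraction
            img_p, msk_p = _sample_patch(rng, np.asarray(image), np.asarray(mask), patch, force_fg)
            pred = model.forward(model.normalize(img_p))
            loss = nn.dice_loss(pred, msk_p[None])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "train_dice_loss": float(np.mean(losses))}
        if val_tiles:
            row["val_iou"] = validation_iou(model, val_tiles)
            if row["val_iou"] >= best_iou:
                best_iou = row["val_iou"]
                best_state = model.state_dict()
        rows.append(row)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, pd.DataFrame(rows)


def predict_tiled(
    model: UNet3D,
    volume: Volume3D | np.ndarray,
    tiles: TileSpec | None = None,
    threshold: float = 0.5,
) -> JointPrediction:
    """Tile the volume, run per-tile forward passes, stitch, binarize.

    Tiles are edge-padded up to ``tile_edge`` (padding cropped from the
    output), so output shape equals input shape.  The tile edge must be
    divisible by the net's downsampling factor.
    """
    tiles = tiles or TileSpec()
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume)
    factor = 2 ** (model.cfg.depth - 1)
    if tiles.tile_edge % factor != 0:
        raise ValueError(
            f"tile_edge {tiles.tile_edge} not divisible by the net's downsampling factor {factor}"
        )
    edge = tiles.tile_edge
    step = edge - tiles.overlap
    shape = data.shape
    prob = np.zeros(shape, dtype=np.float32)
    weight = np.zeros(shape, dtype=np.float32)
    starts = [list(range(0, s, step)) if s > 0 else [0] for s in shape]
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = tuple(
                    slice(o, min(o + edge, s)) for o, s in zip((z0, y0, x0), shape)
                )
                block = data[sl]
                pad = [(0, edge - (b.stop - b.start)) for b in sl]
                if any(p[1] for p in pad):
                    block = np.pad(block, pad, mode=tiles.pad_mode)
                out = model.predict(model.normalize(block))[0]
                crop = tuple(slice(0, b.stop - b.start) for b in sl)
                prob[sl] += out[crop]
                weight[sl] += 1.0
    prob /= np.maximum(weight, 1.0)
    return JointPrediction(probability=prob, mask=prob >= threshold, threshold=threshold)
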