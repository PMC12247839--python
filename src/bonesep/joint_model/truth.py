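"""Ground-truth joint derivation and training-tile extraction.

The learned target is the peri-articular negative space: the region where
cube dilations of two *different* bone labels meet, grown again by the same
dilation size for thickness and lateral extent.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from ..volume_io import LabelVolume, Volume3D

logger = logging.getLogger(__name__)


def _cube(radius: int) -> np.ndarray:
    return np.ones((2 * radius + 1,) * 3, dtype=bool)


def derive_joint_truth(
    labels: LabelVolume | np.ndarray,
    dilation_size: int = 5,
    include_bone_boundary: bool = True,
) -> np.ndarray:
    """Binary joint mask from a bone label map.

    Interface voxels are those where cube dilations (half-size
    ``dilation_size``) of at least two distinct labels intersect, restricted
    to background plus (optionally) the one-voxel bone boundary; the
    returned mask is that interface dilated by ``dilation_size`` again.
    Fewer than two labels yields an empty mask with a logged warning.
    """
    arr = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    ids = np.unique(arr)
    ids = ids[ids != 0]
    if len(ids) < 2:
        logger.warning("derive_joint_truth: fewer than 2 labels; returning empty mask")
        return np.zeros(arr.shape, dtype=bool)
    cube = _cube(dilation_size)
    coverage = np.zeros(arr.shape, dtype=np.uint16)
    for i in ids:
        coverage += ndimage.binary_dilation(arr == i, structure=cube).astype(np.uint16)
    interface = coverage >= 2
    background = arr == 0
    if include_bone_boundary:
        boundary = (arr > 0) & ndimage.binary_dilation(background, structure=_cube(1))
        interface &= background | boundary
    else:
        interface &= background
    return ndimage.binary_dilation(interface, structure=cube)


def _box_slices(center: tuple[int, ...], edge: int, shape: tuple[int, ...]):
    """edge^3 box around center, shifted to stay inside the (padded) shape."""
    slices = []
    for c, s in zip(center, shape):
        start = int(np.clip(c - edge // 2, 0, max(s - edge, 0)))
        slices.append(slice(start, start + edge))
    return tuple(slices)


def extract_training_tiles(
    volume: Volume3D,
    joint_truth: np.ndarray,
    n_tiles: int = 3,
    edge: int = 200,
    foreground_hu: float = 2500.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut ``n_tiles`` aligned (image, mask) tiles of ``edge``^3 voxels.

    Placement mirrors the even positioning over the bone cluster, the digit
    tips and background: the first tile is centred on the densest-foreground
    region, the second on the foreground voxel farthest from the foreground
    centroid (digit tips), the third on the emptiest region; further tiles
    cycle through jittered repeats of the three placements.  Volumes smaller
    than ``edge`` are edge-padded.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    mask = np.asarray(joint_truth, dtype=bool)
    if data.shape != mask.shape:
        raise ValueError("volume / joint truth shape mismatch")
    pad = [(0, max(edge - s, 0)) for s in data.shape]
    if any(p[1] for p in pad):
        data = np.pad(data, pad, mode="edge")
        mask = np.pad(mask, pad, mode="constant")
    fg = data >= foreground_hu

    # density of foreground within an edge^3 window, evaluated at box centers
    density = ndimage.uniform_filter(fg.astype(np.float32), size=min(edge, min(data.shape)))
    dense_center = np.unravel_index(np.argmax(density), density.shape)
    empty_center = np.unravel_index(np.argmin(density), density.shape)

    if fg.any():
        coords = np.argwhere(fg)
        centroid = coords.mean(axis=0)
        far = coords[np.argmax(((coords - centroid) ** 2).sum(axis=1))]
        tip_center = tuple(int(v) for v in far)
    else:
        tip_center = tuple(s // 2 for s in data.shape)

    centers = [tuple(int(v) for v in dense_center), tip_center, tuple(int(v) for v in empty_center)]
    tiles = []
    for k in range(n_tiles):
        c = centers[k % 3]
        if k >= 3:  # jitter repeats deterministically
            shift = 7 * (k // 3)
            c = tuple(v + shift for v in c)
        sl = _box_slices(c, edge, data.shape)
        tiles.append((data[sl].copy(), mask[sl].copy()))
    return tiles


def split_validation(tiles: list, fraction: float = 0.25, seed: int = 0) -> tuple[list, list]:
    """Deterministic random split; |validation| = round(fraction * n)."""
    if len(tiles) < 4:
        raise ValueError(f"need >= 4 tiles to split, got {len(tiles)}")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tiles))
    n_val = int(round(fraction * len(tiles)))
    val_idx = set(order[:n_val].tolist())
    train = [t for i, t in enumerate(tiles) if i not in val_idx]
    val = [t for i, t in enumerate(tiles) if i in val_idx]
    return train, val
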