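"""Synthetic multi-bone micro-CT phantoms with exact ground-truth labels.

A phantom emulates a rodent paw at 17.5 µm isotropic resolution: chains of
capsule-shaped "digit" bones plus a packed cluster of ellipsoidal
"tarsal/carpal" bodies, every pair of adjacent bones separated by a thin
dark joint gap.  Pathology operators bridge a gap (fusion) or carve a bone
surface-first (erosion, up to complete deletion), so downstream error
classes (over-connected / missing) have controllable ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume_io import BoneTable, LabelVolume, Volume3D

MAX_BONES = 33  # murine paw scope: 30-33 bones


class PhantomGeometryError(RuntimeError):
    """Raised when the requested layout does not fit in the grid."""


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic multi-bone volume.

    Distances (``gap_width``, ``blur_sigma``, ``spacing``) are micrometres;
    intensities are HU.  Defaults sit inside the pipeline's 2500-20000 HU
    bone window with 2-voxel joint gaps at 17.5 µm spacing.
    """

    n_digits: int = 5
    bones_per_digit: int = 3
    cluster_bones: int = 7
    gap_width: float = 35.0
    bone_intensity: float = 8000.0
    background_intensity: float = 0.0
    blur_sigma: float = 8.0
    noise_sd: float = 300.0
    fusion_pairs: list[tuple[int, int]] = field(default_factory=list)
    erosion_fraction: dict[int, float] = field(default_factory=dict)
    missing_bones: list[int] = field(default_factory=list)
    seed: int = 0
    shape: tuple[int, int, int] = (40, 104, 84)
    spacing: float = 17.5
    digit_bone_radius: float = 4.6  # voxels
    digit_bone_length: float = 14.0  # voxels
    cluster_semiaxis: tuple[float, float] = (5.0, 6.2)  # min/max, voxels

    def __post_init__(self) -> None:
        if self.gap_width <= 0:
            raise ValueError("gap_width must be > 0")
        if not (self.bone_intensity > 2500.0 > self.background_intensity >= 0.0):
            raise ValueError(
                "require bone_intensity > 2500 HU > background_intensity >= 0, got "
                f"{self.bone_intensity} / {self.background_intensity}"
            )
        if self.total_bones > MAX_BONES:
            raise ValueError(f"total bones {self.total_bones} exceeds {MAX_BONES}")
        if self.total_bones < 1:
            raise ValueError("phantom needs at least one bone")

    @property
    def total_bones(self) -> int:
        return self.n_digits * self.bones_per_digit + self.cluster_bones

    @property
    def gap_vox(self) -> int:
        return max(1, math.ceil(self.gap_width / self.spacing))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fusion_pairs"] = [list(p) for p in self.fusion_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["fusion_pairs"] = [tuple(p) for p in d.get("fusion_pairs", [])]
        d["erosion_fraction"] = {int(k): float(v) for k, v in d.get("erosion_fraction", {}).items()}
        d["shape"] = tuple(d.get("shape", (40, 104, 84)))
        d["cluster_semiaxis"] = tuple(d.get("cluster_semiaxis", (5.0, 6.2)))
        return cls(**d)


@dataclass
class PhantomOutput:
    """A realized phantom: image volume, exact truth labels and bone table."""

    volume: Volume3D
    truth: LabelVolume
    table: BoneTable
    spec: PhantomSpec
    adjacency: list[tuple[int, int]] = field(default_factory=list)


def _capsule_mask(shape, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0-p1 (all in voxel units)."""
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    p = np.stack([zz, yy, xx], axis=-1)
    a = np.asarray(p0, dtype=np.float64)
    b = np.asarray(p1, dtype=np.float64)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        d2 = ((p - a) ** 2).sum(-1)
    else:
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        d2 = ((p - (a + t[..., None] * ab)) ** 2).sum(-1)
    return d2 <= radius * radius


def _ellipsoid_mask(shape, center, semiaxes, rotation) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    p = np.stack([zz, yy, xx], axis=-1) - np.asarray(center, dtype=np.float64)
    local = p @ rotation  # rotate into the ellipsoid frame
    q = (local / np.asarray(semiaxes)) ** 2
    return q.sum(-1) <= 1.0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    return q * np.sign(np.diag(r))


def _ball(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    zz, yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1, -radius : radius + 1]
    return zz * zz + yy * yy + xx * xx <= radius * radius


def _layout(spec: PhantomSpec, rng: np.random.Generator):
    """Place bone primitives; returns per-bone (id, name, compartment, mask fn args)."""
    gap = spec.gap_vox
    r = spec.digit_bone_radius
    length = spec.digit_bone_length
    margin = 2
    zc = spec.shape[0] / 2.0

    bones = []  # (label_id, name, compartment, kind, params)
    label = 0

    # cluster: ellipsoids on a 2-row grid at the proximal (low-y) end
    if spec.cluster_bones:
        smin, smax = spec.cluster_semiaxis
        pitch = 2 * smax + gap + 1
        per_row = math.ceil(spec.cluster_bones / 2)
        for i in range(spec.cluster_bones):
            row, col = divmod(i, per_row)
            label += 1
            cy = margin + smax + row * pitch
            cx = margin + smax + col * pitch
            axes = rng.uniform(smin, smax, size=3)
            rot = _random_rotation(rng)
            bones.append((label, f"C{label}", "tarsal/carpal", "ellipsoid",
                          ((zc, cy, cx), axes, rot)))
        cluster_y_end = margin + smax + pitch + smax
    else:
        cluster_y_end = margin

    # digits: chains of capsules along +y, one chain per x offset
    comp_cycle = ["metatarsal/metacarpal", "proximal_phalanx", "distal_phalanx"]
    digit_pitch = 2 * r + gap + 2
    y0 = cluster_y_end + gap + 2
    for d in range(spec.n_digits):
        cx = margin + r + d * digit_pitch
        y = y0
        for b in range(spec.bones_per_digit):
            label += 1
            comp = comp_cycle[b] if b < 3 else "other"
            p0 = (zc, y + r, cx)
            p1 = (zc, y + length - r, cx)
            bones.append((label, f"D{d + 1}B{b + 1}", comp, "capsule", (p0, p1, r)))
            y += length + gap
    return bones


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Rasterize, shade, blur and noise a phantom per its spec.

    Deterministic for a fixed ``spec.seed``.  Raises
    :class:`PhantomGeometryError` naming the first bone whose placement
    would violate the inter-bone gap or fall outside the grid.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    truth = np.zeros(shape, dtype=np.int32)
    gap = spec.gap_vox
    sep_ball = _ball(gap)

    bones = _layout(spec, rng)
    entries = []
    occupied_dilated = np.zeros(shape, dtype=bool)
    masks: dict[int, np.ndarray] = {}
    for label, name, comp, kind, params in bones:
        if kind == "capsule":
            mask = _capsule_mask(shape, *params)
        else:
            mask = _ellipsoid_mask(shape, *params)
        if not mask.any():
            raise PhantomGeometryError(f"bone {name} (id {label}) falls outside the grid")
        edge = np.zeros(shape, dtype=bool)
        edge[0], edge[-1] = True, True
        edge[:, 0], edge[:, -1] = True, True
        edge[:, :, 0], edge[:, :, -1] = True, True
        if (mask & edge).any():
            raise PhantomGeometryError(f"bone {name} (id {label}) touches the grid boundary")
        if (mask & occupied_dilated).any():
            raise PhantomGeometryError(
                f"bone {name} (id {label}) collides with an earlier bone "
                f"(separation < {gap} voxels)"
            )
        truth[mask] = label
        masks[label] = mask
        occupied_dilated |= ndimage.binary_dilation(mask, structure=sep_ball)
        entries.append((label, name, comp))

    # adjacency: pairs whose gap is exactly the layout gap
    adjacency = []
    labels_present = sorted(masks)
    touch_ball = _ball(gap + 1)
    dilated = {l: ndimage.binary_dilation(masks[l], structure=touch_ball) for l in labels_present}
    for i, a in enumerate(labels_present):
        for b in labels_present[i + 1 :]:
            if (dilated[a] & masks[b]).any():
                adjacency.append((a, b))

    image = np.full(shape, spec.background_intensity, dtype=np.float64)
    image[truth > 0] = spec.bone_intensity

    out = PhantomOutput(
        volume=Volume3D(image, spacing=(spec.spacing,) * 3),
        truth=LabelVolume(truth, spacing=(spec.spacing,) * 3),
        table=BoneTable(entries),
        spec=spec,
        adjacency=adjacency,
    )

    for pair in spec.fusion_pairs:
        out = apply_fusion(out, tuple(pair), _finalize=False)
    for bone_id, frac in sorted(spec.erosion_fraction.items()):
        out = apply_erosion(out, bone_id, frac, _finalize=False)
    for bone_id in spec.missing_bones:
        out = apply_erosion(out, bone_id, 1.0, _finalize=False)

    return _finalize(out, rng)


def _finalize(out: PhantomOutput, rng: np.random.Generator) -> PhantomOutput:
    spec = out.spec
    image = out.volume.data.astype(np.float64)
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.blur_sigma / spec.spacing)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return replace_volume(out, image)


def replace_volume(out: PhantomOutput, image: np.ndarray) -> PhantomOutput:
    return PhantomOutput(
        volume=Volume3D(image, spacing=out.volume.spacing, origin=out.volume.origin),
        truth=out.truth,
        table=out.table,
        spec=out.spec,
        adjacency=out.adjacency,
    )


def apply_fusion(out: PhantomOutput, pair: tuple[int, int], _finalize: bool = True) -> PhantomOutput:
    """Fill the joint gap between an adjacent pair at bone intensity.

    The bridge is wide (the full inter-bone contact region, reaching around
    the joint), emulating pathologic fusion where the joint space no longer
    exists.  Truth labels stay distinct: fusion is an image-level pathology,
    so a downstream merge of the pair is countable as an over-connection
    error.
    """
    a, b = int(pair[0]), int(pair[1])
    pairs = {tuple(sorted(p)) for p in out.adjacency}
    if tuple(sorted((a, b))) not in pairs:
        raise ValueError(f"bones {a} and {b} are not adjacent in the layout")
    gap = out.spec.gap_vox
    ball = _ball(gap + 3)
    mask_a = out.truth.labels == a
    mask_b = out.truth.labels == b
    bridge = (
        ndimage.binary_dilation(mask_a, structure=ball)
        & ndimage.binary_dilation(mask_b, structure=ball)
        & (out.truth.labels == 0)
    )
    image = out.volume.data.copy()
    image[bridge] = out.spec.bone_intensity
    return replace_volume(out, image)


def apply_erosion(
    out: PhantomOutput, bone_id: int, fraction: float, _finalize: bool = True
) -> PhantomOutput:
    """Carve ``fraction`` of a bone's voxels, surface first, in image and truth."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    bone_id = int(bone_id)
    mask = out.truth.labels == bone_id
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"unknown bone id {bone_id}")
    if fraction == 0.0:
        return out
    n_remove = int(round(fraction * n))
    # surface-first: remove in increasing order of depth (EDT inside the bone)
    depth = ndimage.distance_transform_edt(mask)
    flat_idx = np.flatnonzero(mask.ravel())
    order = np.lexsort((flat_idx, depth.ravel()[flat_idx]))
    removed = flat_idx[order[:n_remove]]
    truth = out.truth.labels.copy()
    image = out.volume.data.copy()
    truth.ravel()[removed] = 0
    image.ravel()[removed] = out.spec.background_intensity
    return PhantomOutput(
        volume=Volume3D(image, spacing=out.volume.spacing, origin=out.volume.origin),
        truth=LabelVolume(truth, spacing=out.truth.spacing, origin=out.truth.origin),
        table=out.table,
        spec=out.spec,
        adjacency=out.adjacency,
    )
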