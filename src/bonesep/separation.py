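"""Marker generation and marker-based watershed separation of bones.

Markers are the connected components of (bone mask minus joint mask); the
watershed floods the bone mask from those markers over a topography
(negated distance-to-background by default), so each bone-mask voxel ends
in exactly one marker basin.  The flood is a stratified priority flood:
voxels are claimed in increasing (topography value, marker id) order, which
makes the result independent of within-stratum processing order and lets an
exhaustive reference implementation reproduce it voxel-for-voxel.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit
from scipy import ndimage

from . import enhancement as enh
from .volume_io import LabelVolume, Volume3D, window_mask

Topography = Literal["distance", "intensity"]


class PipelineError(RuntimeError):
    pass


@dataclass
class MarkerSet:
    """Disjoint seed components inside the bone mask, one positive id each."""

    markers: np.ndarray

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers)
        if self.markers.ndim != 3 or not np.issubdtype(self.markers.dtype, np.integer):
            raise ValueError("markers must be a 3D integer array")

    def ids(self) -> np.ndarray:
        ids = np.unique(self.markers)
        return ids[ids != 0]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def make_markers(
    bone_mask: np.ndarray,
    joint: np.ndarray,
    min_voxels: int = 27,
    connectivity: int = 26,
) -> MarkerSet:
    """Label components of ``bone_mask & ~joint``, dropping dust components.

    Components smaller than ``min_voxels`` are discarded; survivors are
    renumbered 1..n in scan order.  Raises :class:`PipelineError` when no
    seed survives (inspect the HU threshold and the joint mask).
    """
    bone_mask = np.asarray(bone_mask, dtype=bool)
    if not bone_mask.any():
        raise PipelineError("bone mask is empty")
    seeds = bone_mask & ~np.asarray(joint, dtype=bool)
    lab, n = ndimage.label(seeds, structure=_structure(connectivity))
    if n:
        counts = np.bincount(lab.ravel(), minlength=n + 1)
        keep = np.flatnonzero(counts[1:] >= min_voxels) + 1
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
        lab = remap[lab]
        n = len(keep)
    if n == 0:
        raise PipelineError(
            "no marker component survived; joint mask may cover all bones or "
            "min_voxels may be too large — inspect thresholds"
        )
    return MarkerSet(lab.astype(np.int32))


def _neighbor_offsets(shape: tuple[int, int, int], connectivity: int) -> np.ndarray:
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offs.append((dz, dy, dx))
    return np.array(offs, dtype=np.int64)


@njit(cache=True)
def _priority_flood(topo, mask, labels, offsets, nz, ny, nx):  # pragma: no cover
    """Level-synchronous priority flood.

    Heap entries are (flood value, round, marker id, voxel); the round
    counter increments along a wave within one flood level and resets when
    the level rises, so at a tied level every basin grows one voxel layer
    per round (plateaus are shared fairly instead of being swept by the
    first marker).  A voxel contested at the same (value, round) goes to
    the lower marker id.
    """
    n = topo.size
    cap = 1024
    hv = np.empty(cap, dtype=np.float64)  # flood value
    hr = np.empty(cap, dtype=np.int64)  # round within the level
    hm = np.empty(cap, dtype=np.int64)  # marker id
    hp = np.empty(cap, dtype=np.int64)  # flat voxel index
    size = 0

    for i in range(n):
        if labels[i] > 0:
            # initial seeds: level = own topography, round -1 (markers are
            # labeled before immersion starts, so their first expansion layer
            # is a round-0 peer of waves arriving from deeper levels)
            if size == cap:
                cap *= 2
                hv2 = np.empty(cap, dtype=np.float64)
                hr2 = np.empty(cap, dtype=np.int64)
                hm2 = np.empty(cap, dtype=np.int64)
                hp2 = np.empty(cap, dtype=np.int64)
                hv2[:size] = hv; hr2[:size] = hr; hm2[:size] = hm; hp2[:size] = hp
                hv, hr, hm, hp = hv2, hr2, hm2, hp2
            hv[size] = topo[i]; hr[size] = -1; hm[size] = labels[i]; hp[size] = i
            size += 1
            j = size - 1
            while j > 0:
                pa = (j - 1) // 2
                if (hv[j], hr[j], hm[j]) < (hv[pa], hr[pa], hm[pa]):
                    hv[j], hv[pa] = hv[pa], hv[j]
                    hr[j], hr[pa] = hr[pa], hr[j]
                    hm[j], hm[pa] = hm[pa], hm[j]
                    hp[j], hp[pa] = hp[pa], hp[j]
                    j = pa
                else:
                    break

    expanded = np.zeros(n, dtype=np.uint8)
    n_off = offsets.shape[0]
    while size > 0:
        v = hv[0]; r = hr[0]; m = hm[0]; p = hp[0]
        size -= 1
        hv[0] = hv[size]; hr[0] = hr[size]; hm[0] = hm[size]; hp[0] = hp[size]
        j = 0
        while True:
            l = 2 * j + 1
            rt = 2 * j + 2
            s = j
            if l < size and (hv[l], hr[l], hm[l]) < (hv[s], hr[s], hm[s]):
                s = l
            if rt < size and (hv[rt], hr[rt], hm[rt]) < (hv[s], hr[s], hm[s]):
                s = rt
            if s == j:
                break
            hv[j], hv[s] = hv[s], hv[j]
            hr[j], hr[s] = hr[s], hr[j]
            hm[j], hm[s] = hm[s], hm[j]
            hp[j], hp[s] = hp[s], hp[j]
            j = s

        if labels[p] == 0:
            labels[p] = m
        elif labels[p] != m or expanded[p] == 1:
            continue  # duplicate entry: already claimed (and possibly expanded)
        expanded[p] = 1
        pz = p // (ny * nx)
        py = (p % (ny * nx)) // nx
        px = p % nx
        for k in range(n_off):
            qz = pz + offsets[k, 0]
            qy = py + offsets[k, 1]
            qx = px + offsets[k, 2]
            if qz < 0 or qz >= nz or qy < 0 or qy >= ny or qx < 0 or qx >= nx:
                continue
            q = (qz * ny + qy) * nx + qx
            if mask[q] == 0 or labels[q] != 0:
                continue
            nv = topo[q] if topo[q] > v else v
            nr = r + 1 if nv == v else 0
            if size == cap:
                cap *= 2
                hv2 = np.empty(cap, dtype=np.float64)
                hr2 = np.empty(cap, dtype=np.int64)
                hm2 = np.empty(cap, dtype=np.int64)
                hp2 = np.empty(cap, dtype=np.int64)
                hv2[:size] = hv; hr2[:size] = hr; hm2[:size] = hm; hp2[:size] = hp
                hv, hr, hm, hp = hv2, hr2, hm2, hp2
            hv[size] = nv; hr[size] = nr; hm[size] = m; hp[size] = q
            size += 1
            j = size - 1
            while j > 0:
                pa = (j - 1) // 2
                if (hv[j], hr[j], hm[j]) < (hv[pa], hr[pa], hm[pa]):
                    hv[j], hv[pa] = hv[pa], hv[j]
                    hr[j], hr[pa] = hr[pa], hr[j]
                    hm[j], hm[pa] = hm[pa], hm[j]
                    hp[j], hp[pa] = hp[pa], hp[j]
                    j = pa
                else:
                    break
    return labels


def watershed_topography(
    volume: Volume3D | np.ndarray | None,
    bone_mask: np.ndarray,
    kind: Topography = "distance",
) -> np.ndarray:
    """Topography flooded by the watershed (lower = flooded earlier)."""
    bone_mask = np.asarray(bone_mask, dtype=bool)
    if kind == "distance":
        return -ndimage.distance_transform_edt(bone_mask)
    if kind == "intensity":
        if volume is None:
            raise ValueError("intensity topography needs the source volume")
        data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume, float)
        return -data.astype(np.float64)
    raise ValueError(f"unknown topography {kind!r}")


def watershed_separate(
    volume: Volume3D | np.ndarray | None,
    bone_mask: np.ndarray,
    markers: MarkerSet,
    topography: Topography = "distance",
    connectivity: int = 26,
) -> LabelVolume:
    """Flood ``bone_mask`` from ``markers`` over the chosen topography.

    Every bone-mask voxel connected to a marker gets that marker's id;
    at equal flood level the lower marker id wins.  Mask voxels not
    connected to any marker stay 0.
    """
    bone_mask = np.asarray(bone_mask, dtype=bool)
    marr = markers.markers
    if marr.shape != bone_mask.shape:
        raise ValueError("marker / mask shape mismatch")
    if ((marr > 0) & ~bone_mask).any():
        raise ValueError("markers must lie inside the bone mask")
    topo = watershed_topography(volume, bone_mask, topography)
    work = np.where(bone_mask, marr.astype(np.int64), 0)
    offsets = _neighbor_offsets(bone_mask.shape, connectivity)
    nz, ny, nx = bone_mask.shape
    out = _priority_flood(
        np.ascontiguousarray(topo.ravel()),
        np.ascontiguousarray(bone_mask.ravel().astype(np.uint8)),
        np.ascontiguousarray(work.ravel()),
        offsets,
        nz,
        ny,
        nx,
    )
    spacing = volume.spacing if isinstance(volume, Volume3D) else (1.0, 1.0, 1.0)
    return LabelVolume(out.reshape(bone_mask.shape).astype(np.int32), spacing=spacing)


@dataclass
class RunLog:
    """Per-stage bookkeeping of one pipeline run."""

    stages: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def add(self, name: str, t0: float, **counts) -> None:
        self.stages.append({"stage": name, "seconds": time.perf_counter() - t0, **counts})

    def to_dict(self) -> dict:
        return {"params": self.params, "stages": self.stages}


def run_pipeline(
    volume: Volume3D,
    config=None,
    model=None,
) -> tuple[LabelVolume, np.ndarray, RunLog]:
    """HU window -> enhancement chain (+ optional DL) -> markers -> watershed.

    ``config`` is a :class:`bonesep.config.PipelineConfig` (defaults used
    when omitted); ``model`` an optional trained joint predictor whose tiled
    probability output joins the response union.  Returns the label volume,
    the boolean joint mask, and a run log with per-stage voxel counts.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    log = RunLog(params=cfg.to_dict())

    t0 = time.perf_counter()
    bone_mask = window_mask(volume, cfg.hu_window[0], cfg.hu_window[1])
    log.add("window_mask", t0, voxels=int(bone_mask.sum()))

    t0 = time.perf_counter()
    bth = enh.black_top_hat(volume, radius=cfg.bth_radius)
    log.add("black_top_hat", t0, nonzero=int((bth.data > 0).sum()))

    t0 = time.perf_counter()
    sef = enh.sheetness(volume, scales=cfg.sheet_scales)
    log.add("sheetness", t0, nonzero=int((sef.data > 0).sum()))

    mef = None
    if cfg.voting_enabled:
        t0 = time.perf_counter()
        mef = enh.tensor_voting(sef, sigma_v=cfg.voting_sigma, threshold=cfg.voting_threshold)
        log.add("tensor_voting", t0, nonzero=int((mef.data > 0).sum()))

    dl_prob = None
    if model is not None:
        from .joint_model import predict_tiled, TileSpec

        t0 = time.perf_counter()
        tiles = TileSpec(tile_edge=cfg.tile_edge, overlap=cfg.tile_overlap)
        dl_prob = predict_tiled(model, volume, tiles).probability
        log.add("dl_prediction", t0, supra=int((dl_prob > 0.5).sum()))

    t0 = time.perf_counter()
    joint = enh.combine_responses(
        bth,
        sef,
        mef,
        dl_prob=dl_prob,
        thresholds=cfg.thresholds,
        half_kernel=cfg.dilation_half_kernel,
        dilation_shape=cfg.dilation_shape,
    )
    log.add("combine_responses", t0, joint_voxels=int(joint.sum()))

    t0 = time.perf_counter()
    try:
        markers = make_markers(
            bone_mask, joint, min_voxels=cfg.marker_min_voxels, connectivity=cfg.connectivity
        )
    except PipelineError as exc:
        raise PipelineError(f"make_markers: {exc}") from exc
    log.add("make_markers", t0, n_markers=int(len(markers.ids())))

    t0 = time.perf_counter()
    labels = watershed_separate(
        volume, bone_mask, markers, topography=cfg.topography, connectivity=cfg.connectivity
    )
    log.add("watershed", t0, n_labels=int(len(labels.ids())))
    return labels, joint, log
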