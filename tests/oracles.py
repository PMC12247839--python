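"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library calls and algorithms used by the
package (no scipy morphology, no heap flood): exhaustive window scans,
explicit Chebyshev distances, and vectorized fixpoint iteration.
"""

from __future__ import annotations

import numpy as np


def brute_closing_minus_image(volume: np.ndarray, radius: int) -> np.ndarray:
    """Black top-hat by exhaustive min/max over cubic windows (edge-clamped)."""
    v = np.asarray(volume, dtype=np.float64)
    nz, ny, nx = v.shape
    dil = np.empty_like(v)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                w = v[
                    max(z - radius, 0) : z + radius + 1,
                    max(y - radius, 0) : y + radius + 1,
                    max(x - radius, 0) : x + radius + 1,
                ]
                dil[z, y, x] = w.max()
    clo = np.empty_like(v)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                w = dil[
                    max(z - radius, 0) : z + radius + 1,
                    max(y - radius, 0) : y + radius + 1,
                    max(x - radius, 0) : x + radius + 1,
                ]
                clo[z, y, x] = w.min()
    return clo - v


def _neighbor_shifts(connectivity: int):
    shifts = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                shifts.append((dz, dy, dx))
    return shifts


def _shifted(arr: np.ndarray, shift, fill):
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(shift):
        if s > 0:
            src[ax] = slice(0, arr.shape[ax] - s)
            dst[ax] = slice(s, None)
        elif s < 0:
            src[ax] = slice(-s, None)
            dst[ax] = slice(0, arr.shape[ax] + s)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def stratified_watershed(
    topo: np.ndarray, mask: np.ndarray, markers: np.ndarray, connectivity: int = 26
) -> np.ndarray:
    """Watershed by explicit level-synchronous flooding (no heap).

    Each iteration finds the globally minimal flood value over all frontier
    voxels (the flood value of a frontier voxel via a labeled neighbor is
    ``max(neighbor reach, topo(voxel))``) and claims *every* frontier voxel
    achieving it simultaneously — one BFS layer per iteration, so tied
    levels are shared fairly between basins.  A voxel reachable from
    several basins in the same layer goes to the lowest marker id.
    """
    topo = np.asarray(topo, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    labels = np.where(mask, markers, 0).astype(np.int64)
    reach = np.where(labels > 0, topo, np.inf)
    shifts = _neighbor_shifts(connectivity)
    big = np.inf
    while True:
        cand_val = np.full(topo.shape, big)
        cand_mark = np.full(topo.shape, np.iinfo(np.int64).max, dtype=np.int64)
        frontier = mask & (labels == 0)
        if not frontier.any():
            break
        for sh in shifts:
            nb_lab = _shifted(labels, sh, 0)
            nb_reach = _shifted(reach, sh, big)
            ok = frontier & (nb_lab > 0)
            val = np.maximum(nb_reach, topo)
            better = ok & (
                (val < cand_val) | ((val == cand_val) & (nb_lab < cand_mark))
            )
            cand_val[better] = val[better]
            cand_mark[better] = nb_lab[better]
        if not np.isfinite(cand_val).any():
            break  # remaining mask voxels unreachable from any marker
        vmin = cand_val.min()
        claim = cand_val == vmin
        labels[claim] = cand_mark[claim]
        reach[claim] = vmin
    return labels


def chebyshev_dilation(mask: np.ndarray, size: int) -> np.ndarray:
    """Voxels within Chebyshev distance ``size`` of the mask.

    Point-by-point: every set voxel stamps its (2*size+1)^3 cube, clipped at
    the grid boundary — the definition itself, no morphology library.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for z, y, x in np.argwhere(mask):
        out[
            max(z - size, 0) : z + size + 1,
            max(y - size, 0) : y + size + 1,
            max(x - size, 0) : x + size + 1,
        ] = True
    return out


def joint_truth_reference(
    labels: np.ndarray, size: int, include_bone_boundary: bool = True
) -> np.ndarray:
    """Double-dilation-intersection joint truth via explicit Chebyshev math."""
    labels = np.asarray(labels)
    ids = [i for i in np.unique(labels) if i != 0]
    if len(ids) < 2:
        return np.zeros(labels.shape, dtype=bool)
    dilated = [chebyshev_dilation(labels == i, size) for i in ids]
    coverage = np.sum(dilated, axis=0)
    interface = coverage >= 2
    background = labels == 0
    if include_bone_boundary:
        near_bg = chebyshev_dilation(background, 1)
        interface &= background | ((labels > 0) & near_bg)
    else:
        interface &= background
    return chebyshev_dilation(interface, size)


def classify_reference(
    pred: np.ndarray, truth: np.ndarray, overlap_min: float = 0.5
) -> dict[int, str]:
    """Outcome per truth id by exhaustive pairwise overlap enumeration."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    truth_ids = [i for i in np.unique(truth) if i != 0]
    outcomes = {}
    matches = {}
    for ti in truth_ids:
        tmask = truth == ti
        cands = []
        for pi in np.unique(pred[tmask]):
            if pi == 0:
                continue
            if ((pred == pi) & tmask).sum() >= overlap_min * tmask.sum():
                cands.append(int(pi))
        matches[int(ti)] = cands
    for ti in truth_ids:
        cands = matches[int(ti)]
        if not cands:
            outcomes[int(ti)] = "missing"
        elif len(cands) >= 2:
            outcomes[int(ti)] = "over_split"
        elif any(cands[0] in matches[int(tj)] for tj in truth_ids if tj != ti):
            outcomes[int(ti)] = "over_connected"
        else:
            outcomes[int(ti)] = "correct"
    return outcomes


def stick_vote_sum(
    token_positions: np.ndarray,
    token_normals: np.ndarray,
    token_weights: np.ndarray,
    at: tuple[int, int, int],
    sigma_v: float,
) -> np.ndarray:
    """Accumulated vote tensor at one voxel by direct summation over tokens."""
    acc = np.zeros((3, 3))
    q = np.asarray(at, dtype=np.float64)
    c = -16.0 * np.log(0.1) * (sigma_v - 1.0) / np.pi**2
    for p, n, w in zip(token_positions, token_normals, token_weights):
        v = q - np.asarray(p, dtype=np.float64)
        l = np.linalg.norm(v)
        if l == 0:
            acc += w * np.outer(n, n)
            continue
        if l > 3 * sigma_v:
            continue
        vhat = v / l
        cos_phi = float(np.clip(vhat @ n, -1, 1))
        theta = abs(np.pi / 2 - np.arccos(abs(cos_phi)))
        if theta > np.pi / 4:
            continue
        sin_t = np.sin(theta)
        s = l * theta / sin_t if sin_t > 1e-12 else l
        kappa = 2 * sin_t / l
        df = np.exp(-(s**2 + c * kappa**2) / sigma_v**2)
        n_rot = 2 * cos_phi * vhat - n
        n_rot /= max(np.linalg.norm(n_rot), 1e-12)
        acc += w * df * np.outer(n_rot, n_rot)
    return acc
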