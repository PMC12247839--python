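"""Classical joint-space enhancement chain.

Four stages highlight the thin dark gaps between bright bones:

* :func:`black_top_hat` — grayscale closing minus the image; responds to
  dark structures narrower than the structuring element.
* :func:`sheetness` — multi-scale Hessian eigenvalue filter selecting
  dark plate-like structures (one dominant positive eigenvalue).
* :func:`tensor_voting` — stick tensor voting that reinforces surface
  continuity and bridges small holes in the sheet response.
* :func:`dilate_mask` / :func:`combine_responses` — binarize each response,
  union, and grow by a half-kernel-2 dilation into the final joint mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .volume_io import Volume3D

Provenance = Literal["bth", "sheetness", "voting"]


@dataclass
class ResponseVolume:
    """Non-negative scalar response of one enhancement stage."""

    data: np.ndarray
    provenance: Provenance

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("response must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("response values must be finite")
        if self.data.min(initial=0.0) < 0:
            raise ValueError("response values must be >= 0")


def _as_array(volume) -> np.ndarray:
    if isinstance(volume, Volume3D):
        return np.asarray(volume.data, dtype=np.float64)
    return np.asarray(volume, dtype=np.float64)


def black_top_hat(volume: Volume3D | np.ndarray, radius: int = 3) -> ResponseVolume:
    """Grayscale closing minus image with a cubic element of half-size ``radius``."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    data = _as_array(volume)
    size = 2 * radius + 1
    closed = ndimage.grey_closing(data, size=(size, size, size), mode="nearest")
    return ResponseVolume(closed - data, "bth")


def _hessian_eigvals(data: np.ndarray, sigma: float) -> np.ndarray:
    """Eigenvalues of the gamma-normalized Gaussian Hessian, shape (..., 3)."""
    h = np.empty(data.shape + (3, 3))
    axes = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))
    smoothed = {}
    for i, j in axes:
        order = [0, 0, 0]
        order[i] += 1
        order[j] += 1
        d = ndimage.gaussian_filter(data, sigma=sigma, order=order, mode="nearest")
        smoothed[(i, j)] = d * sigma**2  # gamma normalization (gamma = 2)
    for i in range(3):
        for j in range(3):
            h[..., i, j] = smoothed[(min(i, j), max(i, j))]
    return np.linalg.eigvalsh(h)


def sheetness(
    volume: Volume3D | np.ndarray,
    scales: Sequence[float] = (1.0, 1.5, 2.0),
    alpha: float = 0.5,
    beta: float = 0.5,
) -> ResponseVolume:
    """Multi-scale dark-sheet enhancement.

    Per scale, the Gaussian Hessian is classified by its eigenvalue
    signature: a dark plate in bright surround has one dominant positive
    eigenvalue and two near-zero ones.  A Frangi-style geometric score
    (plate-vs-tube and plate-vs-blob ratios, gates ``alpha``/``beta``) is
    damped by a structureness term with half-max-Frobenius cutoff; the
    output is the voxelwise maximum over scales.
    """
    scales = list(scales)
    if not scales or any(s <= 0 for s in scales):
        raise ValueError(f"scales must be non-empty and positive, got {scales}")
    data = _as_array(volume)
    # remove the DC component: the truncated discrete derivative kernels do
    # not sum exactly to zero, so a raw intensity offset would leak into the
    # Hessian and break shift invariance
    data = data - data.mean()
    best = np.zeros_like(data)
    for sigma in scales:
        ev = _hessian_eigvals(data, sigma)
        # sort by |eigenvalue|: |l1| <= |l2| <= |l3|
        order = np.argsort(np.abs(ev), axis=-1)
        ev = np.take_along_axis(ev, order, axis=-1)
        l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
        a3 = np.abs(l3)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_tube = np.where(a3 > 0, np.abs(l2) / a3, 0.0)  # 0 for plates, 1 for tubes
            r_blob = np.where(a3 > 0, np.abs(l1) / a3, 0.0)
        structureness = np.sqrt((ev**2).sum(-1))
        c = structureness.max() / 2.0
        score = np.exp(-(r_tube**2) / (2 * alpha**2)) * np.exp(-(r_blob**2) / (2 * beta**2))
        if c > 0:
            score = score * (1.0 - np.exp(-(structureness**2) / (2 * c**2)))
        score = np.where(l3 > 0, score, 0.0)  # dark-selective polarity
        np.maximum(best, score, out=best)
    return ResponseVolume(best, "sheetness")


# ---------------------------------------------------------------------------
# tensor voting

#: 13 unique axis directions of the cubic lattice (unit vectors, half-space).
_CUBE_DIRECTIONS = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.float64,
)
_CUBE_DIRECTIONS /= np.linalg.norm(_CUBE_DIRECTIONS, axis=1, keepdims=True)


def stick_vote_kernel(normal: np.ndarray, sigma_v: float, radius: int) -> np.ndarray:
    """Dense stick-vote tensor kernel for a token with unit ``normal`` at the origin.

    Returns an array of shape ``(2r+1, 2r+1, 2r+1, 3, 3)``; entry at offset
    ``v`` is ``DF(s, kappa) * n' n'^T`` with the classical decay
    ``DF = exp(-(s^2 + c kappa^2) / sigma_v^2)``, arc length
    ``s = l * theta / sin(theta)``, curvature ``kappa = 2 sin(theta) / l``,
    and the votes cut off beyond 45 degrees from the token's plane.
    """
    n = np.asarray(normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    size = 2 * radius + 1
    grid = np.stack(
        np.meshgrid(*([np.arange(-radius, radius + 1)] * 3), indexing="ij"), axis=-1
    ).astype(np.float64)
    l = np.linalg.norm(grid, axis=-1)
    out = np.zeros((size, size, size, 3, 3))
    # token at origin votes on itself with its own orientation
    out[radius, radius, radius] = np.outer(n, n)
    nz = l > 0
    v = np.zeros_like(grid)
    v[nz] = grid[nz] / l[nz, None]
    cos_phi = np.clip(v @ n, -1.0, 1.0)  # angle to the normal
    theta = np.abs(np.pi / 2 - np.arccos(np.abs(cos_phi)))  # angle to the plane
    with np.errstate(divide="ignore", invalid="ignore"):
        sin_t = np.sin(theta)
        s = np.where(sin_t > 1e-12, l * theta / np.maximum(sin_t, 1e-12), l)
        kappa = np.where(l > 0, 2.0 * sin_t / np.maximum(l, 1e-12), 0.0)
    c = -16.0 * np.log(0.1) * (sigma_v - 1.0) / (np.pi**2)
    df = np.exp(-(s**2 + c * kappa**2) / sigma_v**2)
    df = np.where(nz & (theta <= np.pi / 4) & (l <= 3 * sigma_v), df, 0.0)
    # received stick orientation: normal rotated by 2*theta in the (v, n) plane
    n_rot = 2.0 * cos_phi[..., None] * v - n
    norm = np.linalg.norm(n_rot, axis=-1, keepdims=True)
    n_rot = np.where(norm > 0, n_rot / np.maximum(norm, 1e-12), 0.0)
    outer = n_rot[..., :, None] * n_rot[..., None, :]
    out[nz] = (df[..., None, None] * outer)[nz]
    out[radius, radius, radius] = np.outer(n, n)
    return out


def _token_normals(saliency: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Per-voxel plate normal from the structure tensor of the saliency map."""
    grads = np.gradient(ndimage.gaussian_filter(saliency, sigma, mode="nearest"))
    st = np.empty(saliency.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            st[..., i, j] = ndimage.gaussian_filter(grads[i] * grads[j], 1.5, mode="nearest")
    _, vecs = np.linalg.eigh(st)
    return vecs[..., -1]  # eigenvector of the largest eigenvalue


def tensor_voting(
    saliency: ResponseVolume | np.ndarray,
    sigma_v: float = 4.0,
    threshold: float | None = None,
) -> ResponseVolume:
    """Stick tensor voting on a sparse token field; returns plate saliency.

    Voxels above ``threshold`` (Otsu of nonzero values when ``None``) become
    tokens whose plate normal is estimated from the structure tensor of the
    input.  Normals are binned to the 13 cubic axis directions and votes are
    cast by convolving each bin's weight field with its dense stick kernel.
    Output is the eigen-gap ``lambda1 - lambda2`` of the accumulated tensor.
    """
    if sigma_v <= 0:
        raise ValueError(f"sigma_v must be > 0, got {sigma_v}")
    data = saliency.data if isinstance(saliency, ResponseVolume) else np.asarray(saliency, float)
    if threshold is None:
        nonzero = data[data > 0]
        threshold = float(threshold_otsu(nonzero)) if nonzero.size >= 2 else np.inf
    tokens = data > threshold
    if not tokens.any():
        return ResponseVolume(np.zeros_like(data), "voting")

    normals = _token_normals(data)
    radius = int(np.ceil(3 * sigma_v))
    # bin token normals to the nearest cubic direction (|dot| max; lowest index wins ties)
    dots = np.abs(normals[tokens] @ _CUBE_DIRECTIONS.T)
    bins = np.argmax(dots, axis=1)
    weights = data[tokens]
    tok_idx = np.argwhere(tokens)

    acc = np.zeros(data.shape + (3, 3))
    for b in range(len(_CUBE_DIRECTIONS)):
        sel = bins == b
        if not sel.any():
            continue
        field = np.zeros_like(data)
        field[tuple(tok_idx[sel].T)] = weights[sel]
        kernel = stick_vote_kernel(_CUBE_DIRECTIONS[b], sigma_v, radius)
        for i in range(3):
            for j in range(i, 3):
                comp = signal.fftconvolve(field, kernel[..., i, j], mode="same")
                acc[..., i, j] += comp
                if i != j:
                    acc[..., j, i] += comp
    ev = np.linalg.eigvalsh(acc)
    out = np.clip(ev[..., 2] - ev[..., 1], 0.0, None)
    out[np.abs(out) < 1e-9 * max(out.max(), 1.0)] = 0.0
    return ResponseVolume(out, "voting")


def dilate_mask(mask: np.ndarray, half_kernel: int = 2, shape: str = "cube") -> np.ndarray:
    """Binary dilation by a cube (default) or ball of half-size ``half_kernel``."""
    if half_kernel < 0:
        raise ValueError(f"half_kernel must be >= 0, got {half_kernel}")
    mask = np.asarray(mask, dtype=bool)
    if half_kernel == 0:
        return mask.copy()
    size = 2 * half_kernel + 1
    if shape == "cube":
        structure = np.ones((size, size, size), dtype=bool)
    elif shape == "ball":
        zz, yy, xx = np.mgrid[-half_kernel:half_kernel + 1,
                              -half_kernel:half_kernel + 1,
                              -half_kernel:half_kernel + 1]
        structure = zz**2 + yy**2 + xx**2 <= half_kernel**2
    else:
        raise ValueError(f"unknown structuring element shape {shape!r}")
    return ndimage.binary_dilation(mask, structure=structure)


def _binarize(response: ResponseVolume | np.ndarray | None, threshold: float | None):
    if response is None:
        return None
    data = response.data if isinstance(response, ResponseVolume) else np.asarray(response, float)
    if threshold is None:
        nonzero = data[data > 0]
        if nonzero.size < 2 or np.ptp(nonzero) == 0:
            return data > 0
        threshold = float(threshold_otsu(nonzero))
    return data > threshold


def combine_responses(
    bth: ResponseVolume | None = None,
    sef: ResponseVolume | None = None,
    mef: ResponseVolume | None = None,
    dl_prob: np.ndarray | None = None,
    thresholds: dict[str, float | None] | None = None,
    half_kernel: int = 2,
    dilation_shape: str = "cube",
) -> np.ndarray:
    """Binarize each available response, union them, dilate by ``half_kernel``.

    ``thresholds`` maps source names (``bth``/``sef``/``mef``/``dl``) to
    binarization levels; missing entries default to per-volume Otsu on
    nonzero values (``dl`` defaults to 0.5).  Returns the boolean joint mask.
    """
    thresholds = thresholds or {}
    sources = {
        "bth": _binarize(bth, thresholds.get("bth")),
        "sef": _binarize(sef, thresholds.get("sef")),
        "mef": _binarize(mef, thresholds.get("mef")),
    }
    if dl_prob is not None:
        sources["dl"] = np.asarray(dl_prob) > thresholds.get("dl", 0.5)
    available = [m for m in sources.values() if m is not None]
    if not available:
        raise ValueError("no responses supplied")
    shapes = {m.shape for m in available}
    if len(shapes) != 1:
        raise ValueError(f"response shape mismatch: {sorted(shapes)}")
    union = np.zeros(available[0].shape, dtype=bool)
    for m in available:
        union |= m
    return dilate_mask(union, half_kernel=half_kernel, shape=dilation_shape)
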