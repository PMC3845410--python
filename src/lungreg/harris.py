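"""3D Harris-style tissue-feature detection.

Vessel bifurcations, vascular endpoints and tissue boundary corners are
locations where the local autocorrelation of the image rises steeply in every
direction, i.e. where all three eigenvalues of the Gaussian-windowed
structure tensor

    M(p) = sum_q  W(q - p) * g(q) g(q)^T,      g = (Ix, Iy, Iz)

are large.  The detector response used here is the smallest eigenvalue
lambda3 (Shi-Tomasi style), which directly operationalises "all three
eigenvalues large"; the classical Harris ``det - k * trace^3`` variant is
available via ``method="harris"``.

The window W is an unnormalised truncated Gaussian (weight sum, not weighted
mean), separable per axis, radius ``ceil(3*sigma)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Volume

__all__ = [
    "KeyPoint",
    "gradients",
    "gauss_window_1d",
    "structure_tensor",
    "harris_response",
    "select_keypoints",
    "detect_keypoints",
    "keypoints_to_csv",
]


@dataclass
class KeyPoint:
    """A detected feature point.

    eigenvalues are sorted descending (l1 >= l2 >= l3); response is l3.
    """

    voxel_index: tuple[int, int, int]
    world_mm: np.ndarray
    eigenvalues: tuple[float, float, float]
    response: float


def gradients(vol: Volume | np.ndarray, gradient_sigma: float = 1.0):
    """Gaussian-derivative intensity gradients (Ix, Iy, Iz), per-voxel units.

    The gradient of a linear ramp a*x + b*y + c*z is (a, b, c) at interior
    voxels regardless of sigma.
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if data.ndim != 3 or min(data.shape) < 3:
        raise ValueError(f"need a 3D volume with every axis >= 3, got shape {data.shape}")
    if gradient_sigma <= 0:
        raise ValueError("gradient_sigma must be positive")
    data = data.astype(np.float64, copy=False)
    r = max(1, int(np.ceil(4.0 * gradient_sigma)))
    t = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(t**2) / (2.0 * gradient_sigma**2))
    smooth = g / g.sum()
    # normalised so a linear ramp differentiates exactly despite truncation
    deriv = t * g / np.sum(t**2 * g)
    out = []
    for ax in range(3):
        a = data
        for other in range(3):
            a = ndimage.correlate1d(a, deriv if other == ax else smooth, axis=other, mode="nearest")
        out.append(a)
    return tuple(out)


def gauss_window_1d(sigma: float) -> np.ndarray:
    """Unnormalised 1D Gaussian window, truncated at radius ceil(3*sigma)."""
    r = int(np.ceil(3.0 * sigma))
    t = np.arange(-r, r + 1, dtype=float)
    return np.exp(-(t**2) / (2.0 * sigma**2))


def structure_tensor(gx, gy, gz, window_sigma: float = 1.5, mode: str = "nearest") -> np.ndarray:
    """Per-voxel 3x3 structure tensor, shape (*vol.shape, 3, 3).

    Each entry is the Gaussian-window-weighted local SUM of the corresponding
    gradient product (e.g. sum W * Ix * Iy), with separable product weights
    W(dx,dy,dz) = w(dx) w(dy) w(dz).  Symmetric positive semi-definite up to
    rounding.
    """
    if window_sigma <= 0:
        raise ValueError("window_sigma must be positive")
    gx, gy, gz = (np.asarray(g, dtype=np.float64) for g in (gx, gy, gz))
    if not (gx.shape == gy.shape == gz.shape):
        raise ValueError("gradient grids must share a shape")
    w = gauss_window_1d(window_sigma)

    def smooth(a):
        for ax in range(3):
            a = ndimage.correlate1d(a, w, axis=ax, mode=mode)
        return a

    out = np.empty(gx.shape + (3, 3), dtype=np.float64)
    prods = {
        (0, 0): gx * gx, (0, 1): gx * gy, (0, 2): gx * gz,
        (1, 1): gy * gy, (1, 2): gy * gz, (2, 2): gz * gz,
    }
    for (i, j), p in prods.items():
        s = smooth(p)
        out[..., i, j] = s
        out[..., j, i] = s
    return out


def harris_response(stf: np.ndarray, method: str = "min_eig", k: float = 0.05) -> np.ndarray:
    """Corner response grid from a structure tensor field.

    ``min_eig``: smallest eigenvalue lambda3 (default).  ``harris``:
    det(M) - k * trace(M)^3.
    """
    if stf.ndim != 5 or stf.shape[-2:] != (3, 3):
        raise ValueError(f"expected tensor field of shape (..., 3, 3), got {stf.shape}")
    if method == "min_eig":
        return np.linalg.eigvalsh(stf)[..., 0]
    if method == "harris":
        tr = np.trace(stf, axis1=-2, axis2=-1)
        return np.linalg.det(stf) - k * tr**3
    raise ValueError(f"unknown response method {method!r}")


def _tensor_eigvals_at(stf: np.ndarray, idx: np.ndarray) -> np.ndarray:
    mats = stf[idx[:, 0], idx[:, 1], idx[:, 2]]
    return np.linalg.eigvalsh(mats)[:, ::-1]  # descending


def select_keypoints(
    response: np.ndarray,
    vol: Volume,
    mask: np.ndarray | None = None,
    response_threshold: float = 0.0,
    min_distance_mm: float = 5.0,
    max_points: int | None = None,
    border: int = 0,
    stf: np.ndarray | None = None,
) -> list[KeyPoint]:
    """Greedy spatially spread selection of response maxima.

    Candidates are 26-neighbourhood local maxima with response >= threshold,
    inside ``mask`` and at least ``border`` voxels from every face.  They are
    visited in descending response order (ties broken lexicographically by
    voxel index) and accepted greedily if farther than ``min_distance_mm``
    (world mm) from every already accepted point.
    """
    if min_distance_mm < 0:
        raise ValueError("min_distance_mm must be >= 0")
    if mask is not None and mask.shape != response.shape:
        raise ValueError("mask shape must match response shape")

    localmax = response >= ndimage.maximum_filter(response, size=3, mode="constant", cval=-np.inf)
    cand = localmax & (response >= response_threshold)
    if mask is not None:
        cand &= mask
    if border > 0:
        edge = np.ones(response.shape, dtype=bool)
        edge[border:-border or None, border:-border or None, border:-border or None] = False
        cand &= ~edge
    idx = np.argwhere(cand)
    if idx.size == 0:
        return []
    resp = response[idx[:, 0], idx[:, 1], idx[:, 2]]
    # descending response, lexicographic voxel-index tie-break
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -resp))
    idx, resp = idx[order], resp[order]
    world = vol.voxel_to_world(idx)

    accepted: list[int] = []
    acc_pts = np.empty((0, 3))
    for i in range(len(idx)):
        if acc_pts.size and np.min(np.linalg.norm(acc_pts - world[i], axis=1)) <= min_distance_mm:
            continue
        accepted.append(i)
        acc_pts = np.vstack([acc_pts, world[i]])
        if max_points is not None and len(accepted) >= max_points:
            break

    sel = np.asarray(accepted, dtype=int)
    eig = (
        _tensor_eigvals_at(stf, idx[sel])
        if stf is not None
        else np.column_stack([resp[sel]] * 3)
    )
    return [
        KeyPoint(tuple(int(v) for v in idx[i]), world[i], tuple(float(e) for e in eig[j]), float(resp[i]))
        for j, i in enumerate(sel)
    ]


def detect_keypoints(
    vol: Volume,
    mask: np.ndarray | None = None,
    gradient_sigma: float = 1.0,
    window_sigma: float = 1.5,
    response_threshold: float | None = None,
    rel_threshold: float = 0.05,
    min_distance_mm: float = 5.0,
    max_points: int | None = 2000,
    border: int | None = None,
    method: str = "min_eig",
):
    """Full detection pass: gradients -> structure tensor -> response -> selection.

    If ``response_threshold`` is None it is set to ``rel_threshold`` times the
    maximum response inside the mask.  ``border`` defaults to the filter
    support plus the descriptor half-window (9 voxels) so detected points
    always admit a descriptor.

    Returns (keypoints, response_grid).
    """
    gx, gy, gz = gradients(vol, gradient_sigma)
    stf = structure_tensor(gx, gy, gz, window_sigma)
    response = harris_response(stf, method=method)
    if border is None:
        border = max(int(np.ceil(3 * window_sigma)) + int(np.ceil(3 * gradient_sigma)), 9)
    if response_threshold is None:
        r = response if mask is None else np.where(mask, response, -np.inf)
        peak = float(np.max(r)) if np.isfinite(r).any() else 0.0
        response_threshold = rel_threshold * max(peak, 0.0)
    kps = select_keypoints(
        response, vol, mask=mask, response_threshold=response_threshold,
        min_distance_mm=min_distance_mm, max_points=max_points, border=border, stf=stf,
    )
    return kps, response


def keypoints_to_csv(kps: list[KeyPoint], path) -> None:
    """Export keypoints as CSV: index, x/y/z mm, eigenvalues, response."""
    lines = ["index,x_mm,y_mm,z_mm,lambda1,lambda2,lambda3,response"]
    for i, kp in enumerate(kps):
        x, y, z = kp.world_mm
        l1, l2, l3 = kp.eigenvalues
        lines.append(f"{i},{x:.6f},{y:.6f},{z:.6f},{l1:.6g},{l2:.6g},{l3:.6g},{kp.response:.6g}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
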