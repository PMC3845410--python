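"""Thin-plate-spline (Bookstein) fitting and volume warping.

The 3D TPS maps a point p to

    f(p) = a0 + A p + sum_i w_i U(|p - c_i|),      U(r) = r,

with U the 3D biharmonic kernel (not the 2D r^2 log r), the c_i the source
control points, and the weights W subject to the orthogonality side
conditions sum_i w_i = 0 and sum_i w_i c_i^T = 0 per output axis.  With
regularisation lambda = 0 the spline interpolates the control points
exactly; lambda > 0 trades exactness for smoothness (useful with noisy
landmarks).

Direction convention: for registration, control points are taken in
TARGET space mapping to TEMPLATE space, so backward warping of the template
onto the target grid needs no field inversion (see ``warp_volume``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .volume_io import Volume

__all__ = ["TPSModel", "fit_tps", "apply_tps", "warp_volume", "save_tps", "load_tps"]


@dataclass
class TPSModel:
    """Fitted spline: N control points (mm), 3x4 affine block, Nx3 weights."""

    control_points: np.ndarray  # (N, 3) source points, mm
    affine: np.ndarray  # (3, 4): [A | t] acting as A p + t
    weights: np.ndarray  # (N, 3) nonaffine coefficients
    lam: float = 0.0

    @property
    def n_points(self) -> int:
        return self.control_points.shape[0]


def fit_tps(source: np.ndarray, target: np.ndarray, lam: float = 0.0) -> TPSModel:
    """Fit a 3D TPS taking ``source`` points onto ``target`` points.

    Solves the standard bordered linear system

        [ K + lam*I   P ] [ W ]   [ T ]
        [    P^T      0 ] [ A ] = [ 0 ]

    with K_ij = U(|s_i - s_j|) and P = [1 | s].  Requires N >= 4
    non-coplanar source points (P must have full column rank 4), else the
    system is singular and a ``ValueError`` names the degeneracy.
    """
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    n = source.shape[0]
    if target.shape[0] != n:
        raise ValueError(f"source ({n}) and target ({target.shape[0]}) point counts differ")
    if n < 4:
        raise ValueError(f"TPS needs at least 4 control points, got {n}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")

    P = np.hstack([np.ones((n, 1)), source])  # (n, 4)
    if np.linalg.matrix_rank(P, tol=1e-8 * max(1.0, np.abs(source).max())) < 4:
        raise ValueError("degenerate control-point configuration: source points are coplanar or coincident")

    K = cdist(source, source)  # U(r) = r
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K + lam * np.eye(n)
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = target
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular TPS system (degenerate control points): {exc}") from exc
    W = sol[:n]  # (n, 3)
    coef = sol[n:]  # (4, 3): row 0 translation, rows 1:4 linear part
    affine = np.zeros((3, 4))
    affine[:, :3] = coef[1:].T
    affine[:, 3] = coef[0]
    return TPSModel(source.copy(), affine, W, lam=lam)


def apply_tps(model: TPSModel, points: np.ndarray, chunk: int = 65536) -> np.ndarray:
    """Evaluate the spline at (..., 3) mm points (chunked for dense grids)."""
    pts = np.asarray(points, dtype=float)
    flat = pts.reshape(-1, 3)
    out = np.empty_like(flat)
    A, t = model.affine[:, :3], model.affine[:, 3]
    for s in range(0, flat.shape[0], chunk):
        block = flat[s : s + chunk]
        U = cdist(block, model.control_points)
        out[s : s + chunk] = block @ A.T + t + U @ model.weights
    return out.reshape(pts.shape)


def identity_tps(anchor: np.ndarray | None = None) -> TPSModel:
    """An identity spline (useful as a no-op baseline)."""
    pts = np.zeros((0, 3)) if anchor is None else np.asarray(anchor, float).reshape(-1, 3)
    affine = np.hstack([np.eye(3), np.zeros((3, 1))])
    return TPSModel(pts, affine, np.zeros((pts.shape[0], 3)))


def warp_volume(
    template: Volume,
    model: TPSModel,
    reference: Volume,
    fill: float | None = None,
    order: int = 1,
) -> Volume:
    """Backward-warp the template onto the reference grid.

    For every output voxel at world position p (on the reference grid) the
    template is sampled at f(p) with trilinear interpolation; samples
    falling outside the template get ``fill`` (default: the template's
    minimum intensity, i.e. air).
    """
    if fill is None:
        fill = float(template.data.min())
    idx = np.stack(
        np.meshgrid(*(np.arange(s) for s in reference.shape), indexing="ij"), axis=-1
    ).astype(float)
    world = reference.voxel_to_world(idx)
    mapped = apply_tps(model, world.reshape(-1, 3))
    vox = template.world_to_voxel(mapped)  # (N, 3) continuous template voxels
    # sample with edge replication, then fill voxels that map genuinely
    # outside; the epsilon keeps boundary voxels of an identity map exact
    eps = 1e-6
    limit = np.asarray(template.shape, float) - 1
    outside = np.any((vox < -eps) | (vox > limit + eps), axis=1)
    data = ndimage.map_coordinates(template.data.astype(float), vox.T, order=order, mode="nearest")
    data[outside] = fill
    return Volume(data.reshape(reference.shape), reference.spacing.copy(), reference.origin.copy())


def save_tps(model: TPSModel, path) -> None:
    """Serialise a fitted model to JSON text."""
    obj = {
        "kernel": "U(r)=r",
        "lambda": model.lam,
        "control_points": model.control_points.tolist(),
        "affine": model.affine.tolist(),
        "weights": model.weights.tolist(),
    }
    Path(path).write_text(json.dumps(obj) + "\n")


def load_tps(path) -> TPSModel:
    obj = json.loads(Path(path).read_text())
    return TPSModel(
        np.asarray(obj["control_points"], float).reshape(-1, 3),
        np.asarray(obj["affine"], float).reshape(3, 4),
        np.asarray(obj["weights"], float).reshape(-1, 3),
        lam=float(obj.get("lambda", 0.0)),
    )
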