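"""3D SIFT orientation-histogram descriptor (2048 components).

Each keypoint is described by the gradient orientation distribution in the
16x16x16 voxel cube around it: the cube splits into 4x4x4 subregions of
4x4x4 voxels, and each subregion accumulates an 8 azimuth x 4 elevation
histogram of 45-degree bins, weighted by gradient magnitude and an isotropic
spatial Gaussian. 64 subregions x 32 bins = 2048 components, L2-normalised.

Layout: component index = ((sx*4 + sy)*4 + sz) * 32 + az_bin * 4 + el_bin,
with (sx, sy, sz) the subregion grid coordinate. The 16-voxel window spans
keypoint offset -8 ... +7 per axis (an even window has no centre voxel).

No dominant-orientation assignment: respiratory motion is locally close to
a translation, so the descriptor frame is the image axis frame. Hard bin
assignment by default; trilinear soft-binning over orientation is available
via ``soft=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harris import KeyPoint, gradients
from .volume_io import Volume

__all__ = [
    "DESCRIPTOR_SIZE",
    "Descriptor",
    "spherical_gradient",
    "build_descriptor",
    "build_descriptors",
    "descriptor_distance",
]

DESCRIPTOR_SIZE = 2048  # 4^3 subregions * 8 azimuth * 4 elevation bins
_HALF = 8  # window spans voxel offsets -8 ... +7


@dataclass
class Descriptor:
    values: np.ndarray
    keypoint: KeyPoint | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.values.size != DESCRIPTOR_SIZE:
            raise ValueError(f"descriptor must have {DESCRIPTOR_SIZE} components, got {self.values.size}")


def spherical_gradient(g):
    """(magnitude, azimuth_deg, elevation_deg) of gradient vectors.

    Azimuth in [0, 360) measured in the x-y plane from +x; elevation in
    [-90, 90] toward +z. A zero gradient returns (0, 0, 0) and contributes
    nothing to any histogram. Vectorised over a trailing axis of size 3.
    """
    g = np.asarray(g, dtype=float)
    gx, gy, gz = g[..., 0], g[..., 1], g[..., 2]
    mag = np.sqrt(gx**2 + gy**2 + gz**2)
    az = np.degrees(np.arctan2(gy, gx)) % 360.0
    el = np.degrees(np.arctan2(gz, np.hypot(gx, gy)))
    zero = mag == 0
    az = np.where(zero, 0.0, az)
    el = np.where(zero, 0.0, el)
    return mag, az, el


def _window_weights(weight_sigma: float) -> np.ndarray:
    off = np.arange(-_HALF, _HALF)
    dx, dy, dz = np.meshgrid(off, off, off, indexing="ij")
    return np.exp(-(dx**2 + dy**2 + dz**2) / (2.0 * weight_sigma**2))


def _bin_indices(az: np.ndarray, el: np.ndarray):
    """Hard 45-degree binning: right-open intervals, elevation +90 -> top bin."""
    az_bin = np.floor(az / 45.0).astype(int) % 8
    el_bin = np.clip(np.floor((el + 90.0) / 45.0).astype(int), 0, 3)
    return az_bin, el_bin


def _histogram(mag_w, az, el, sub_flat, soft: bool):
    if not soft:
        az_bin, el_bin = _bin_indices(az, el)
        comp = sub_flat * 32 + az_bin * 4 + el_bin
        return np.bincount(comp.ravel(), weights=mag_w.ravel(), minlength=DESCRIPTOR_SIZE)
    # soft: bilinear split over the two nearest azimuth and elevation bins
    hist = np.zeros(DESCRIPTOR_SIZE)
    az_pos = az / 45.0 - 0.5
    el_pos = np.clip((el + 90.0) / 45.0 - 0.5, 0.0, 3.0)
    a0 = np.floor(az_pos).astype(int)
    e0 = np.floor(el_pos).astype(int)
    fa, fe = az_pos - a0, el_pos - e0
    for da, wa in ((0, 1 - fa), (1, fa)):
        for de, we in ((0, 1 - fe), (1, fe)):
            ab = (a0 + da) % 8
            eb = np.clip(e0 + de, 0, 3)
            comp = sub_flat * 32 + ab * 4 + eb
            hist += np.bincount(comp.ravel(), weights=(mag_w * wa * we).ravel(), minlength=DESCRIPTOR_SIZE)
    return hist


def _descriptor_from_grads(gx, gy, gz, voxel, weights, soft, normalize=True):
    x, y, z = voxel
    sl = tuple(slice(c - _HALF, c + _HALF) for c in (x, y, z))
    g = np.stack([gx[sl], gy[sl], gz[sl]], axis=-1)
    mag, az, el = spherical_gradient(g)
    off = np.arange(16) // 4
    sx, sy, sz = np.meshgrid(off, off, off, indexing="ij")
    sub_flat = (sx * 4 + sy) * 4 + sz
    hist = _histogram(mag * weights, az, el, sub_flat, soft)
    if normalize:
        n = np.linalg.norm(hist)
        if n > 0:
            hist = hist / n
    return hist


def build_descriptors(
    vol: Volume,
    keypoints: list[KeyPoint],
    gradient_sigma: float = 1.0,
    weight_sigma: float = 8.0,
    border: str = "reject",
    soft: bool = False,
):
    """Descriptors for many keypoints; gradients are computed once.

    Returns ``(matrix, kept_indices)`` where matrix is (n_kept, 2048) and
    kept_indices maps its rows back into ``keypoints``. Under the default
    ``border="reject"`` policy, keypoints whose 16^3 window leaves the volume
    are dropped; ``border="zero-pad"`` keeps them by zero-padding gradients.
    """
    if border not in ("reject", "zero-pad"):
        raise ValueError(f"unknown border policy {border!r}")
    gx, gy, gz = gradients(vol, gradient_sigma)
    pad = 0
    if border == "zero-pad":
        pad = _HALF
        gx, gy, gz = (np.pad(g, pad) for g in (gx, gy, gz))
    weights = _window_weights(weight_sigma)
    shape = np.asarray(vol.shape)
    rows, kept = [], []
    for i, kp in enumerate(keypoints):
        v = np.asarray(kp.voxel_index)
        if border == "reject" and (np.any(v - _HALF < 0) or np.any(v + _HALF - 1 >= shape)):
            continue
        rows.append(_descriptor_from_grads(gx, gy, gz, v + pad, weights, soft))
        kept.append(i)
    mat = np.asarray(rows).reshape(len(rows), DESCRIPTOR_SIZE) if rows else np.empty((0, DESCRIPTOR_SIZE))
    return mat, kept


def build_descriptor(
    vol: Volume,
    kp: KeyPoint,
    gradient_sigma: float = 1.0,
    weight_sigma: float = 8.0,
    border: str = "reject",
    soft: bool = False,
) -> Descriptor:
    """Descriptor for a single keypoint (see module docstring for layout)."""
    mat, kept = build_descriptors(vol, [kp], gradient_sigma, weight_sigma, border, soft)
    if not kept:
        raise ValueError(
            f"keypoint at voxel {kp.voxel_index} is too close to the border for a "
            f"16^3 descriptor window (policy 'reject')"
        )
    return Descriptor(mat[0], keypoint=kp)


def descriptor_distance(a, b) -> float:
    """Euclidean (l2) distance between two descriptors."""
    av = a.values if isinstance(a, Descriptor) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, Descriptor) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"descriptor length mismatch: {av.shape} vs {bv.shape}")
    return float(np.linalg.norm(av - bv))
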