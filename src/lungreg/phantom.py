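"""Ground-truth lung phantoms: vessel trees, bifurcations, known deformation.

The phantom emulates the features the detector is built for: a dark
ellipsoidal "lung" embedded in brighter body tissue, containing a bright
branching vessel tree whose bifurcations are the ground-truth landmarks.
A second respiratory "phase" is produced by resampling the template through
a known smooth displacement field (global translation plus compact Gaussian
bumps, dominant along z to mimic diaphragm-driven superior-inferior motion),
so every pipeline stage can be scored against exact correspondences.

What it does NOT emulate: airway/lobe anatomy, CT noise texture
(noise is additive white Gaussian), intensity drift between phases, or
sliding motion at the pleura.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .harris import KeyPoint
from .volume_io import Volume

__all__ = ["GaussianBump", "DeformationField", "PhantomSpec", "make_phantom", "plant_decoys"]


@dataclass
class GaussianBump:
    center_mm: tuple[float, float, float]
    amplitude_mm: tuple[float, float, float]
    sigma_mm: float


@dataclass
class DeformationField:
    """u(x) = translation + sum of Gaussian bumps; maps target -> template
    as a displacement: template_position(x) = x + u(x)."""

    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bumps: list[GaussianBump] = field(default_factory=list)

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        u = np.broadcast_to(np.asarray(self.translation_mm, float), pts.shape).copy()
        for b in self.bumps:
            r2 = np.sum((pts - np.asarray(b.center_mm)) ** 2, axis=-1, keepdims=True)
            u = u + np.asarray(b.amplitude_mm) * np.exp(-r2 / (2.0 * b.sigma_mm**2))
        return u

    def map_target_to_template(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) + self.displacement(pts)

    def map_template_to_target(self, pts: np.ndarray, tol: float = 1e-9, max_iter: int = 100) -> np.ndarray:
        """Invert x + u(x) = q by fixed-point iteration (small displacements)."""
        q = np.asarray(pts, dtype=float)
        x = q - self.displacement(q)
        for _ in range(max_iter):
            x_new = q - self.displacement(x)
            if np.max(np.abs(x_new - x)) < tol:
                return x_new
            x = x_new
        return x

    def max_displacement(self, pts: np.ndarray) -> float:
        return float(np.max(np.linalg.norm(self.displacement(pts), axis=-1)))


def _default_deformation(extent: np.ndarray) -> DeformationField:
    f = lambda fx, fy, fz: tuple(np.array([fx, fy, fz]) * extent)
    return DeformationField(
        translation_mm=np.array([0.5, 0.8, 2.0]),
        bumps=[
            GaussianBump(f(0.45, 0.50, 0.70), (1.0, 1.5, 6.0), 0.22 * float(extent.mean())),
            GaussianBump(f(0.62, 0.42, 0.42), (-1.5, 1.0, 3.0), 0.18 * float(extent.mean())),
        ],
    )


# Default vessel tree in fractional volume coordinates: a trunk entering the
# lung from the top, two generations of branching.  Nodes with degree >= 3
# are the ground-truth bifurcations.
_TREE_NODES = {
    "e0": (0.50, 0.50, 0.20),
    "b1": (0.50, 0.48, 0.38),
    "b2": (0.36, 0.40, 0.54),
    "b3": (0.64, 0.56, 0.56),
    "t2": (0.42, 0.54, 0.72),
    "t4": (0.58, 0.40, 0.72),
    "u1": (0.24, 0.26, 0.72),
    "u2": (0.34, 0.50, 0.68),
    "u3": (0.78, 0.70, 0.74),
    "u4": (0.68, 0.58, 0.80),
    "v1": (0.34, 0.58, 0.80),
    "v2": (0.48, 0.62, 0.82),
    "v3": (0.52, 0.30, 0.80),
    "v4": (0.66, 0.44, 0.82),
}
_TREE_EDGES = [
    ("e0", "b1"),
    ("b1", "b2"), ("b1", "b3"),
    ("b2", "u1"), ("b2", "u2"), ("b2", "t2"),
    ("b3", "u3"), ("b3", "u4"), ("b3", "t4"),
    ("t2", "v1"), ("t2", "v2"),
    ("t4", "v3"), ("t4", "v4"),
]
_BIFURCATIONS = ["b1", "b2", "b3", "t2", "t4"]


@dataclass
class PhantomSpec:
    """Stated world of the synthetic test case.

    Intensities are CT-like arbitrary units: dark lung (100) against
    brighter body tissue (600), with bright-in-lung vessels (500).  The
    default grid is 96^3 at 1 mm isotropic; default deformation peaks near
    8-9 mm, dominated by the z (superior-inferior) axis.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lung_intensity: float = 100.0
    body_intensity: float = 600.0
    vessel_intensity: float = 500.0
    vessel_radius_mm: float = 2.0
    junction_bulge_factor: float = 1.5  # junction thickening, anchors the corner at the node
    smooth_sigma_vox: float = 0.8
    deformation: DeformationField | None = None  # None -> default field
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.vessel_intensity > self.lung_intensity:
            raise ValueError("vessel_intensity must exceed lung_intensity (vessels are bright against lung)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _world_grid(spec: PhantomSpec) -> np.ndarray:
    axes = [spec.origin[a] + np.arange(spec.shape[a]) * spec.spacing[a] for a in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _segment_distance(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    d = p1 - p0
    t = np.clip(np.einsum("...k,k->...", pts - p0, d) / (d @ d), 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(pts - proj, axis=-1)


def _paint_near(mask, spec, world, corners_mm, radius_mm, predicate):
    """Set mask voxels where predicate(local world grid) within the bounding
    box of ``corners_mm`` padded by ``radius_mm`` (avoids full-grid scans)."""
    origin = np.asarray(spec.origin)
    spacing = np.asarray(spec.spacing)
    lo_mm = np.min(corners_mm, axis=0) - radius_mm - spacing
    hi_mm = np.max(corners_mm, axis=0) + radius_mm + spacing
    lo = np.maximum(0, np.floor((lo_mm - origin) / spacing).astype(int))
    hi = np.minimum(np.asarray(spec.shape), np.ceil((hi_mm - origin) / spacing).astype(int) + 1)
    sl = tuple(slice(lo[a], hi[a]) for a in range(3))
    mask[sl] |= predicate(world[sl])


def _render_template(spec: PhantomSpec, world: np.ndarray):
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    center = np.asarray(spec.origin) + extent / 2.0
    semi = 0.40 * extent
    lung = np.sum(((world - center) / semi) ** 2, axis=-1) <= 1.0

    nodes = {k: np.asarray(spec.origin) + np.asarray(v) * extent for k, v in _TREE_NODES.items()}
    vessel = np.zeros(spec.shape, dtype=bool)
    r = spec.vessel_radius_mm
    for a, b in _TREE_EDGES:
        pa, pb = nodes[a], nodes[b]
        _paint_near(vessel, spec, world, np.array([pa, pb]), r, lambda w: _segment_distance(w, pa, pb) <= r)
    # thickened junctions: a bulge at every interior tree node keeps the
    # corner response centred on the ground-truth bifurcation coordinate
    rb = spec.junction_bulge_factor * r
    degree = {k: 0 for k in nodes}
    for a, b in _TREE_EDGES:
        degree[a] += 1
        degree[b] += 1
    for k, n in nodes.items():
        if degree[k] >= 3:
            _paint_near(vessel, spec, world, n[None, :], rb, lambda w: np.linalg.norm(w - n, axis=-1) <= rb)
    data = np.full(spec.shape, spec.body_intensity, dtype=float)
    data[lung] = spec.lung_intensity
    data[vessel & lung] = spec.vessel_intensity
    if spec.smooth_sigma_vox > 0:
        data = ndimage.gaussian_filter(data, spec.smooth_sigma_vox, mode="nearest")
    bifurcations = np.array([nodes[k] for k in _BIFURCATIONS])
    return data, lung, bifurcations


def make_phantom(spec: PhantomSpec | None = None):
    """Build (template, target, template_landmarks, target_landmarks).

    The target phase satisfies target(x) = template(x + u(x)) by trilinear
    resampling, u being the spec's displacement field (target -> template
    direction, so no inversion is needed for rendering).  Landmarks are the
    vessel bifurcations: their template positions are exact tree nodes; their
    target positions solve x + u(x) = node by fixed-point iteration.  Noise
    (seeded) is added independently to both phases.
    """
    spec = spec or PhantomSpec()
    world = _world_grid(spec)
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    deform = spec.deformation if spec.deformation is not None else _default_deformation(extent)
    maxdisp = deform.max_displacement(world[::4, ::4, ::4].reshape(-1, 3))
    if maxdisp > 0.25 * float(extent.min()):
        raise ValueError(
            f"deformation too large for the grid: max displacement {maxdisp:.1f} mm "
            f"exceeds 25% of the {extent.min():.0f} mm extent"
        )

    data, lung, bif_template = _render_template(spec, world)
    template = Volume(data, np.asarray(spec.spacing, float), np.asarray(spec.origin, float))

    src = deform.map_target_to_template(world.reshape(-1, 3))
    vox = template.world_to_voxel(src).T
    tdata = ndimage.map_coordinates(data, vox, order=1, mode="nearest").reshape(spec.shape)
    target = Volume(tdata, template.spacing.copy(), template.origin.copy())

    bif_target = deform.map_template_to_target(bif_template)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        template.data = template.data + rng.normal(0.0, spec.noise_sigma, spec.shape)
        target.data = target.data + rng.normal(0.0, spec.noise_sigma, spec.shape)

    return template, target, bif_template, bif_target


def lung_mask(spec: PhantomSpec | None = None) -> np.ndarray:
    """The exact ellipsoidal lung mask of the spec (pre-smoothing geometry)."""
    spec = spec or PhantomSpec()
    world = _world_grid(spec)
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    center = np.asarray(spec.origin) + extent / 2.0
    return np.sum(((world - center) / (0.40 * extent)) ** 2, axis=-1) <= 1.0


def plant_decoys(keypoints: list[KeyPoint], n_decoys: int, vol: Volume, mask: np.ndarray, seed: int = 0):
    """Append ``n_decoys`` random in-mask keypoints; returns (list, is_decoy).

    The boolean tags let precision/recall of the matching cascade be scored
    exactly: any retained pair touching a decoy is a known false match.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    out = list(keypoints)
    tags = [False] * len(keypoints)
    if n_decoys == 0:
        return out, tags
    rng = np.random.default_rng(seed)
    idx = np.argwhere(mask)
    pick = idx[rng.choice(idx.shape[0], size=n_decoys, replace=False)]
    for v in pick:
        out.append(KeyPoint(tuple(int(c) for c in v), vol.voxel_to_world(v), (0.0, 0.0, 0.0), 0.0))
        tags.append(True)
    return out, tags
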