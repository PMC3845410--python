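"""Volume and landmark I/O, isotropic resampling, intensity masking.

Conventions
-----------
* Volumes are stored with axis order ``(x, y, z)``, x fastest-varying on disk.
* Voxel indices are 0-based.  World coordinates are millimetres:
  ``world = origin + index * spacing``.  All keypoints, landmarks and spline
  models downstream operate in world mm so anisotropic spacing never leaks
  past this module.
* Supported volume formats: MetaImage (``.mha``/``.mhd``) and NIfTI
  (``.nii``/``.nii.gz``).  Landmarks are plain text, one ``x, y, z`` mm
  triple per line, ``#`` comments allowed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "threshold_mask",
    "read_landmarks",
    "write_landmarks",
]


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and origin in mm.

    ``data[ix, iy, iz]`` is the intensity at world position
    ``origin + (ix, iy, iz) * spacing``.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {tuple(self.spacing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, idx) -> np.ndarray:
        """World mm coordinates of voxel indices (broadcasts over (..., 3))."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_voxel(self, pts) -> np.ndarray:
        """Continuous voxel coordinates of world-mm points (inverse of above)."""
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def extent_mm(self) -> np.ndarray:
        """Physical extent per axis (voxel-as-cell convention: shape*spacing)."""
        return np.asarray(self.shape) * self.spacing


@dataclass
class LandmarkSet:
    """An ordered list of world-mm points, optionally labelled."""

    points: np.ndarray
    labels: list | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# MetaImage (.mha / .mhd)
# ---------------------------------------------------------------------------

_MET_DTYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_DTYPE_MET = {np.dtype(v): k for k, v in _MET_DTYPES.items()}


def _read_metaimage(path: Path) -> Volume:
    raw = path.read_bytes()
    # Header is ASCII lines "Key = value" terminated by the ElementDataFile line.
    header: dict[str, str] = {}
    pos = 0
    while True:
        nl = raw.find(b"\n", pos)
        if nl < 0:
            raise ValueError(f"{path}: truncated MetaImage header (no ElementDataFile)")
        line = raw[pos:nl].decode("ascii", errors="replace").strip()
        pos = nl + 1
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed MetaImage header line {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        header[key] = val
        if key == "ElementDataFile":
            break

    for req in ("DimSize", "ElementType", "ElementDataFile"):
        if req not in header:
            raise ValueError(f"{path}: MetaImage header missing field {req}")
    if header.get("CompressedData", "False").lower() == "true":
        raise ValueError(f"{path}: compressed MetaImage data is not supported")
    ndims = int(header.get("NDims", "3"))
    if ndims != 3:
        raise ValueError(f"{path}: NDims={ndims}, only 3D volumes supported")

    dims = [int(t) for t in header["DimSize"].split()]
    if len(dims) != 3:
        raise ValueError(f"{path}: DimSize must have 3 entries, got {header['DimSize']!r}")
    etype = header["ElementType"]
    if etype not in _MET_DTYPES:
        raise ValueError(f"{path}: unsupported ElementType {etype}")
    dtype = np.dtype(_MET_DTYPES[etype])
    if header.get("ElementByteOrderMSB", "False").lower() == "true" or (
        header.get("BinaryDataByteOrderMSB", "False").lower() == "true"
    ):
        dtype = dtype.newbyteorder(">")

    spacing = header.get("ElementSpacing", header.get("ElementSize", "1 1 1"))
    spacing = np.array([float(t) for t in spacing.split()])
    origin = np.array([float(t) for t in header.get("Offset", "0 0 0").split()])

    datafile = header["ElementDataFile"]
    if datafile == "LOCAL":
        buf = raw[pos:]
    else:
        buf = (path.parent / datafile).read_bytes()
    n = dims[0] * dims[1] * dims[2]
    arr = np.frombuffer(buf, dtype=dtype, count=n)
    if arr.size < n:
        raise ValueError(f"{path}: data has {arr.size} elements, expected {n}")
    # On-disk order is x fastest -> reshape (z, y, x) then transpose to (x, y, z).
    data = arr.reshape(dims[2], dims[1], dims[0]).transpose(2, 1, 0)
    return Volume(data.astype(np.float64, copy=True), spacing, origin)


def _write_metaimage(vol: Volume, path: Path, dtype=np.float32) -> None:
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_MET:
        raise ValueError(f"unsupported MetaImage dtype {dtype}")
    mhd = path.suffix == ".mhd"
    datafile = path.with_suffix(".raw").name if mhd else "LOCAL"
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {vol.shape[0]} {vol.shape[1]} {vol.shape[2]}\n"
        f"ElementSpacing = {vol.spacing[0]:.10g} {vol.spacing[1]:.10g} {vol.spacing[2]:.10g}\n"
        f"Offset = {vol.origin[0]:.10g} {vol.origin[1]:.10g} {vol.origin[2]:.10g}\n"
        f"ElementType = {_DTYPE_MET[dtype]}\n"
        f"ElementDataFile = {datafile}\n"
    )
    payload = np.ascontiguousarray(vol.data.transpose(2, 1, 0).astype(dtype)).tobytes()
    if mhd:
        path.write_text(header)
        (path.parent / datafile).write_bytes(payload)
    else:
        path.write_bytes(header.encode("ascii") + payload)


# ---------------------------------------------------------------------------
# NIfTI (.nii / .nii.gz) via nibabel
# ---------------------------------------------------------------------------


def _read_nifti(path: Path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI volume, got shape {data.shape}")
    affine = img.affine
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(affine[:3, 3], dtype=float)
    return Volume(data, spacing, origin)


def _write_nifti(vol: Volume, path: Path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------


def _fmt(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".mha", ".mhd")):
        return "meta"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise ValueError(f"{path}: unsupported volume format (use .mha/.mhd/.nii/.nii.gz)")


def read_volume(path) -> Volume:
    """Read a MetaImage or NIfTI volume; spacing/origin come from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    return _read_metaimage(path) if _fmt(path) == "meta" else _read_nifti(path)


def write_volume(vol: Volume, path, dtype=np.float32) -> None:
    """Write a volume; format chosen from the file suffix."""
    path = Path(path)
    if _fmt(path) == "meta":
        _write_metaimage(vol, path, dtype=dtype)
    else:
        _write_nifti(vol, path)


def resample_isotropic(vol: Volume, target_spacing: float | None = None, order: int = 1) -> Volume:
    """Resample to isotropic spacing by trilinear interpolation.

    Defaults to the maximum input spacing (downsampling the finer axes to the
    coarsest, the cheap direction for CT slabs with thick slices).  Output
    shape preserves the physical extent ``shape * spacing`` to within one
    voxel.  ``order=0`` gives nearest-neighbour (for masks).
    """
    if target_spacing is None:
        target_spacing = float(np.max(vol.spacing))
    if target_spacing <= 0:
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")
    new_shape = np.maximum(1, np.floor(vol.extent_mm() / target_spacing + 0.5).astype(int))
    if tuple(new_shape) == vol.shape and np.allclose(vol.spacing, target_spacing):
        return Volume(vol.data.copy(), np.full(3, float(target_spacing)), vol.origin.copy())
    # Output voxel i sits at world origin + i*target -> template voxel i*target/spacing.
    scale = target_spacing / vol.spacing
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(new_shape, scale)), indexing="ij")
    data = ndimage.map_coordinates(vol.data.astype(float), np.stack(grids), order=order, mode="nearest")
    return Volume(data, np.full(3, float(target_spacing)), vol.origin.copy())


def threshold_mask(vol: Volume, lo: float, hi: float) -> np.ndarray:
    """Boolean mask, true exactly where ``lo <= intensity <= hi``.

    A coarse stand-in for lung segmentation: a single intensity band keeps
    the low-intensity lung interior (and its bright vessels if ``hi`` is set
    above the vessel intensity) while discarding surrounding body tissue.
    """
    if lo > hi:
        raise ValueError(f"threshold lo ({lo}) must not exceed hi ({hi})")
    return (vol.data >= lo) & (vol.data <= hi)


# ---------------------------------------------------------------------------
# Landmark text files
# ---------------------------------------------------------------------------


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark text file: one ``x, y, z`` mm triple per line.

    Blank lines and ``#`` comments are skipped.  Commas or whitespace
    separate the coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    opener = gzip.open if path.name.endswith(".gz") else open
    pts = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [t for t in line.replace(",", " ").split() if t]
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 coordinates, got {line!r}")
            try:
                pts.append([float(t) for t in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate in {line!r}") from exc
    return LandmarkSet(np.asarray(pts, dtype=float).reshape(-1, 3))


def write_landmarks(ls: LandmarkSet, path) -> None:
    """Write landmarks as text, 6 decimal places (round-trip stable)."""
    lines = [f"{p[0]:.6f}, {p[1]:.6f}, {p[2]:.6f}" for p in ls.points]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
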