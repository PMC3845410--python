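"""Registration quality metrics: SSD, intensity correlation, landmark errors.

SSD here is the MEAN of squared per-voxel intensity differences (a sum
convention would make values depend on grid size; comparisons are always
internal, before vs after registration, so the convention only needs to be
fixed and stated).  Landmark errors follow the target-minus-registered
convention with per-axis mean absolute deviation (MAD) and standard
deviation (SD, N-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import LandmarkSet, Volume

__all__ = ["LandmarkErrorSummary", "RegistrationMetrics", "ssd", "intensity_cc", "landmark_errors"]


def _check_geometry(a: Volume, b: Volume) -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise ValueError(
            f"volume geometries differ: shape {a.shape} vs {b.shape}, "
            f"spacing {tuple(a.spacing)} vs {tuple(b.spacing)}"
        )


def ssd(a: Volume, b: Volume, mask: np.ndarray | None = None) -> float:
    """Mean squared intensity difference over the (masked) voxels."""
    _check_geometry(a, b)
    diff = a.data.astype(float) - b.data.astype(float)
    if mask is not None:
        if mask.shape != a.shape:
            raise ValueError("mask shape must match volume shape")
        diff = diff[mask]
    return float(np.mean(diff**2))


def intensity_cc(a: Volume, b: Volume, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of voxel intensities over the (masked) region."""
    _check_geometry(a, b)
    x = a.data.astype(float)
    y = b.data.astype(float)
    if mask is not None:
        if mask.shape != a.shape:
            raise ValueError("mask shape must match volume shape")
        x, y = x[mask], y[mask]
    x, y = x.ravel(), y.ravel()
    x = x - x.mean()
    y = y - y.mean()
    den = np.sqrt((x @ x) * (y @ y))
    if den == 0.0:
        raise ValueError("intensity correlation undefined: zero variance in an input")
    return float(np.clip((x @ y) / den, -1.0, 1.0))


@dataclass
class LandmarkErrorSummary:
    deltas: np.ndarray  # (N, 3), target - registered, mm
    mad: np.ndarray  # (3,) mean |delta| per axis
    sd: np.ndarray  # (3,) std of delta per axis (ddof=1; 0 for N=1)

    @property
    def mean_norm(self) -> float:
        """Mean Euclidean error over points, mm."""
        return float(np.mean(np.linalg.norm(self.deltas, axis=1)))


def landmark_errors(registered: LandmarkSet, target: LandmarkSet) -> LandmarkErrorSummary:
    """Per-point error vectors (target - registered) with MAD/SD summaries."""
    if len(registered) != len(target):
        raise ValueError(f"landmark counts differ: {len(registered)} vs {len(target)}")
    deltas = target.points - registered.points
    mad = np.mean(np.abs(deltas), axis=0)
    sd = np.std(deltas, axis=0, ddof=1) if len(registered) > 1 else np.zeros(3)
    return LandmarkErrorSummary(deltas, mad, sd)


@dataclass
class RegistrationMetrics:
    """Before/after similarity plus optional landmark summary."""

    ssd_before: float
    ssd_after: float
    cc_before: float
    cc_after: float
    landmarks_before: LandmarkErrorSummary | None = None
    landmarks_after: LandmarkErrorSummary | None = None

    def as_dict(self) -> dict:
        out = {
            "ssd_before": self.ssd_before,
            "ssd_after": self.ssd_after,
            "cc_before": self.cc_before,
            "cc_after": self.cc_after,
        }
        for tag, lm in (("before", self.landmarks_before), ("after", self.landmarks_after)):
            if lm is not None:
                out[f"landmark_mad_{tag}_mm"] = lm.mad.tolist()
                out[f"landmark_sd_{tag}_mm"] = lm.sd.tolist()
                out[f"landmark_mean_error_{tag}_mm"] = lm.mean_norm
        return out
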