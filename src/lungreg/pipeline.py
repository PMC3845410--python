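"""End-to-end registration: detect, describe, match, fit TPS, warp, score.

This module is the library-level orchestration the CLI and the test suite
both call.  The flow is:

    resample both volumes to isotropic spacing
      -> optional intensity-band lung mask
      -> Harris tissue-feature detection in each volume
      -> 3D SIFT descriptors
      -> match-verification cascade (ratio / symmetry / CC / structure)
      -> TPS fitted with TARGET keypoints as sources mapping to TEMPLATE
         keypoints, so warping the template onto the target grid is a
         direct backward resample
      -> before/after SSD and intensity-CC (and landmark errors if given)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import harris, matching, metrics, sift3d, tps
from .volume_io import LandmarkSet, Volume, resample_isotropic, threshold_mask, write_volume

__all__ = ["PipelineConfig", "RegistrationResult", "register"]

log = logging.getLogger("lungreg")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline with its default.

    tau = 0.8 and d_voxels = 5 follow the published cascade; the remaining
    defaults are this package's own choices (see docs/methods.md).
    """

    iso_spacing: float | None = None  # None -> max input spacing
    mask_lo: float | None = None  # no mask unless both bounds given
    mask_hi: float | None = None
    gradient_sigma: float = 1.0
    window_sigma: float = 1.5
    response_method: str = "min_eig"
    response_threshold: float | None = None  # absolute; None -> relative
    rel_threshold: float = 0.05
    min_distance_mm: float = 5.0
    max_points: int = 800
    weight_sigma: float = 8.0
    descriptor_border: str = "reject"
    soft_binning: bool = False
    tau: float = 0.8
    cc_threshold: float = 0.7
    d_voxels: int = 5
    K_neighbors: int = 8
    consensus_threshold: int | None = None  # None -> K // 2
    tps_lambda: float = 0.0
    seed: int = 0

    def match_config(self) -> matching.MatchConfig:
        return matching.MatchConfig(
            tau=self.tau,
            cc_threshold=self.cc_threshold,
            d_voxels=self.d_voxels,
            K_neighbors=self.K_neighbors,
            consensus_threshold=self.consensus_threshold,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key=value text config; '#' comments allowed."""
        cfg = cls()
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            setattr(cfg, key, _coerce(val, getattr(cfg, key)))
        return cfg


def _coerce(text: str, current):
    if text.lower() in ("none", ""):
        return None
    if isinstance(current, bool):
        return text.lower() in ("1", "true", "yes")
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


@dataclass
class RegistrationResult:
    template_iso: Volume
    target_iso: Volume
    warped: Volume
    keypoints_template: list[harris.KeyPoint]
    keypoints_target: list[harris.KeyPoint]
    pairs: list[matching.MatchPair]
    retained: list[matching.MatchPair]
    report: matching.MatchReport
    model: tps.TPSModel | None
    metrics: metrics.RegistrationMetrics
    config: PipelineConfig

    def save(self, out_dir, write_warped: bool = True) -> None:
        """Write the standard artifact set to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if write_warped:
            write_volume(self.warped, out / "warped.mha")
        matching.matches_to_csv(self.pairs, self.keypoints_template, self.keypoints_target, out / "matches.csv")
        matching.report_to_json(self.report, out / "match_report.json")
        harris.keypoints_to_csv(self.keypoints_template, out / "keypoints_template.csv")
        harris.keypoints_to_csv(self.keypoints_target, out / "keypoints_target.csv")
        if self.model is not None:
            tps.save_tps(self.model, out / "tps_model.json")
        (out / "metrics.json").write_text(json.dumps(self.metrics.as_dict(), indent=2) + "\n")
        (out / "config.json").write_text(json.dumps(self.config.as_dict(), indent=2) + "\n")


def _detect_and_describe(vol: Volume, mask, cfg: PipelineConfig, tag: str):
    kps, _ = harris.detect_keypoints(
        vol,
        mask=mask,
        gradient_sigma=cfg.gradient_sigma,
        window_sigma=cfg.window_sigma,
        response_threshold=cfg.response_threshold,
        rel_threshold=cfg.rel_threshold,
        min_distance_mm=cfg.min_distance_mm,
        max_points=cfg.max_points,
        method=cfg.response_method,
    )
    desc, kept = sift3d.build_descriptors(
        vol, kps, cfg.gradient_sigma, cfg.weight_sigma, cfg.descriptor_border, cfg.soft_binning
    )
    kps = [kps[i] for i in kept]
    log.info("%s: %d keypoints described", tag, len(kps))
    return kps, desc


def register(
    template: Volume,
    target: Volume,
    config: PipelineConfig | None = None,
    landmarks_template: LandmarkSet | None = None,
    landmarks_target: LandmarkSet | None = None,
) -> RegistrationResult:
    """Run the full feature-based registration of template onto target.

    Landmark evaluation (optional) is done in template space: a target-space
    landmark x is mapped through the fitted spline f (target -> template)
    and compared with its paired template landmark q.  Before registration
    the error of the pair is |x - q| (identity map); after, |f(x) - q|.
    """
    cfg = config or PipelineConfig()
    t_iso = resample_isotropic(template, cfg.iso_spacing)
    g_iso = resample_isotropic(target, cfg.iso_spacing if cfg.iso_spacing is not None else float(np.max(template.spacing)))

    mask_t = mask_g = None
    if cfg.mask_lo is not None and cfg.mask_hi is not None:
        mask_t = threshold_mask(t_iso, cfg.mask_lo, cfg.mask_hi)
        mask_g = threshold_mask(g_iso, cfg.mask_lo, cfg.mask_hi)

    kp_t, desc_t = _detect_and_describe(t_iso, mask_t, cfg, "template")
    kp_g, desc_g = _detect_and_describe(g_iso, mask_g, cfg, "target")

    retained, pairs, report = matching.match_pipeline(
        t_iso, g_iso, kp_t, kp_g, desc_t, desc_g, cfg.match_config()
    )
    log.info("match report: %s", report.as_dict())

    model = None
    warped = t_iso
    if len(retained) >= 4:
        src = np.array([kp_g[m.target_idx].world_mm for m in retained])
        dst = np.array([kp_t[m.template_idx].world_mm for m in retained])
        try:
            model = tps.fit_tps(src, dst, lam=cfg.tps_lambda)
            warped = tps.warp_volume(t_iso, model, g_iso)
        except ValueError as exc:
            log.warning("TPS fit failed (%s); falling back to identity", exc)
            model = None
    if model is None:
        log.warning("too few retained matches (%d) for TPS; identity warp", len(retained))
        warped = tps.warp_volume(t_iso, tps.identity_tps(), g_iso)

    # similarity is scored over the target-grid mask when one is configured:
    # outside the lung the TPS extrapolates beyond its control hull and the
    # uniform body carries no registration signal
    same_grid = t_iso.shape == g_iso.shape
    m = metrics.RegistrationMetrics(
        ssd_before=metrics.ssd(t_iso, g_iso, mask_g) if same_grid else float("nan"),
        ssd_after=metrics.ssd(warped, g_iso, mask_g),
        cc_before=metrics.intensity_cc(t_iso, g_iso, mask_g) if same_grid else float("nan"),
        cc_after=metrics.intensity_cc(warped, g_iso, mask_g),
    )
    if landmarks_template is not None and landmarks_target is not None:
        m.landmarks_before = metrics.landmark_errors(landmarks_target, landmarks_template)
        if model is not None:
            mapped = tps.apply_tps(model, landmarks_target.points)
            m.landmarks_after = metrics.landmark_errors(LandmarkSet(mapped), landmarks_template)
        else:
            m.landmarks_after = m.landmarks_before

    return RegistrationResult(
        template_iso=t_iso,
        target_iso=g_iso,
        warped=warped,
        keypoints_template=kp_t,
        keypoints_target=kp_g,
        pairs=pairs,
        retained=retained,
        report=report,
        model=model,
        metrics=m,
        config=cfg,
    )
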