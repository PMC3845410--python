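"""Feature matching and mismatch removal.

Four-stage verification cascade:

1. **Ratio test** — nearest/second-nearest descriptor distance ratio below
   tau (default 0.8) accepts a tentative match.
2. **Symmetry** — matching is run in both directions; a pair survives only
   if it is mutual.
3. **Patch cross-correlation** — the Gaussian-weighted Pearson correlation
   of the intensity patches (half-width d voxels, default 5) around the two
   endpoints must exceed a threshold.
4. **Structural invariance** — the relative positions of lung structures
   change little between respiratory phases, so a true pair's nearest
   matched neighbours in the template must correspond to the nearest matched
   neighbours of its partner in the target.  Pairs whose neighbourhoods
   disagree are removed by consensus count.

Stage counts are reported so that
``candidates = removed_by_cc + removed_by_structure + retained`` always
holds ("candidates" = pairs entering the verification stages, i.e. after
the symmetric ratio matching).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .harris import KeyPoint
from .volume_io import Volume

__all__ = [
    "MatchPair",
    "MatchReport",
    "MatchConfig",
    "ratio_match",
    "symmetric_filter",
    "patch_cc",
    "cc_filter",
    "structural_invariance_filter",
    "match_pipeline",
    "matches_to_csv",
]

STATUS_ORDER = ("candidate", "removed_by_cc", "removed_by_structure", "retained")


@dataclass
class MatchPair:
    template_idx: int
    target_idx: int
    d1: float
    d2: float
    ratio: float
    cc: float | None = None
    status: str = "candidate"


@dataclass
class MatchReport:
    candidates: int = 0
    removed_by_cc: int = 0
    removed_by_structure: int = 0
    retained: int = 0

    def as_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "removed_by_cc": self.removed_by_cc,
            "removed_by_structure": self.removed_by_structure,
            "retained": self.retained,
        }

    def check_conservation(self) -> bool:
        return self.candidates == self.removed_by_cc + self.removed_by_structure + self.retained


@dataclass
class MatchConfig:
    """Tunables of the cascade; tau and d_voxels follow the published values."""

    tau: float = 0.8
    cc_threshold: float = 0.7
    d_voxels: int = 5
    cc_sigma: float | None = None  # default d/2
    K_neighbors: int = 8
    consensus_threshold: int | None = None  # default K // 2
    spherical_patch: bool = False
    iterative_structural: bool = False


def ratio_match(descA: np.ndarray, descB: np.ndarray, tau: float = 0.8) -> list[MatchPair]:
    """Lowe ratio-test matching from descriptor set A into set B.

    For each row of A the best (d1) and second-best (d2) l2 neighbours in B
    are found; the pair is emitted iff d1/d2 < tau.  With fewer than two
    descriptors in B no ratio exists and nothing is emitted; duplicate
    descriptors (d2 = 0) are rejected as ambiguous.
    """
    if not (0 < tau <= 1):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    descA = np.atleast_2d(np.asarray(descA, dtype=float))
    descB = np.atleast_2d(np.asarray(descB, dtype=float))
    if descA.size == 0 or descB.shape[0] < 2:
        return []
    d = cdist(descA, descB)
    part = np.argpartition(d, 1, axis=1)[:, :2]
    out = []
    for i in range(descA.shape[0]):
        j0, j1 = part[i]
        if d[i, j0] > d[i, j1]:
            j0, j1 = j1, j0
        d1, d2 = float(d[i, j0]), float(d[i, j1])
        if d2 == 0.0:
            continue  # duplicate descriptors: ratio undefined, ambiguous
        r = d1 / d2
        if r < tau:
            out.append(MatchPair(i, int(j0), d1, d2, r))
    return out


def symmetric_filter(matchesAB: list[MatchPair], matchesBA: list[MatchPair]) -> list[MatchPair]:
    """Keep (i, j) iff i->j was matched A->B and j->i was matched B->A."""
    back = {(m.template_idx, m.target_idx) for m in matchesBA}
    return [m for m in matchesAB if (m.target_idx, m.template_idx) in back]


def _patch(vol: Volume, center, lo_off, hi_off) -> np.ndarray:
    c = np.asarray(center, dtype=int)
    sl = tuple(slice(c[a] + lo_off[a], c[a] + hi_off[a] + 1) for a in range(3))
    return vol.data[sl]


def patch_cc(
    vA: Volume,
    pA: KeyPoint | tuple,
    vB: Volume,
    pB: KeyPoint | tuple,
    d_voxels: int = 5,
    sigma: float | None = None,
    spherical: bool = False,
) -> float:
    """Gaussian-weighted Pearson correlation of two cubic intensity patches.

    The patch is all voxels within Chebyshev distance ``d_voxels`` of the
    keypoint (a (2d+1)^3 cube; ``spherical=True`` restricts to Euclidean
    distance <= d). Weights are an isotropic Gaussian with
    ``sigma = d/2`` by default, applied symmetrically to the mean-removed
    intensities of both patches. Patches are cropped to the offsets valid in
    both volumes; a zero-variance patch yields 0 (no evidence of similarity).
    """
    if d_voxels < 1:
        raise ValueError("d_voxels must be >= 1")
    if sigma is None:
        sigma = d_voxels / 2.0
    cA = np.asarray(pA.voxel_index if isinstance(pA, KeyPoint) else pA, dtype=int)
    cB = np.asarray(pB.voxel_index if isinstance(pB, KeyPoint) else pB, dtype=int)
    shA, shB = np.asarray(vA.shape), np.asarray(vB.shape)
    lo = np.maximum(-d_voxels, np.maximum(-cA, -cB))
    hi = np.minimum(d_voxels, np.minimum(shA - 1 - cA, shB - 1 - cB))
    if np.any(hi < lo):
        return 0.0
    a = _patch(vA, cA, lo, hi).astype(float)
    b = _patch(vB, cB, lo, hi).astype(float)
    offs = np.meshgrid(*(np.arange(lo[i], hi[i] + 1) for i in range(3)), indexing="ij")
    r2 = sum(o.astype(float) ** 2 for o in offs)
    w = np.exp(-r2 / (2.0 * sigma**2))
    if spherical:
        w = np.where(r2 <= d_voxels**2, w, 0.0)
    wsum = w.sum()
    am = (w * a).sum() / wsum
    bm = (w * b).sum() / wsum
    da, db = a - am, b - bm
    num = (w * da * db).sum()
    den = np.sqrt((w * da**2).sum() * (w * db**2).sum())
    if den == 0.0:
        return 0.0
    return float(np.clip(num / den, -1.0, 1.0))


def cc_filter(
    pairs: list[MatchPair],
    vA: Volume,
    vB: Volume,
    kpA: list[KeyPoint],
    kpB: list[KeyPoint],
    cc_threshold: float = 0.7,
    d_voxels: int = 5,
    sigma: float | None = None,
    spherical: bool = False,
) -> list[MatchPair]:
    """Mark pairs whose patch correlation does not exceed the threshold.

    Surviving pairs keep status ``candidate``; the rest become
    ``removed_by_cc``. Returns the surviving pairs (statuses are mutated in
    place on the input list).
    """
    survivors = []
    for m in pairs:
        m.cc = patch_cc(vA, kpA[m.template_idx], vB, kpB[m.target_idx], d_voxels, sigma, spherical)
        if m.cc > cc_threshold:
            survivors.append(m)
        else:
            m.status = "removed_by_cc"
    return survivors


def structural_invariance_filter(
    pairs: list[MatchPair],
    kpA: list[KeyPoint],
    kpB: list[KeyPoint],
    K_neighbors: int = 8,
    consensus_threshold: int | None = None,
    iterative: bool = False,
) -> list[MatchPair]:
    """Consensus filter on neighbourhood preservation.

    For each tested pair (a, b): take the K matched template keypoints
    nearest to a (world distance, among surviving pairs, excluding a) and
    the K matched target keypoints nearest to b; count surviving pairs
    (u, v) with u in the first set and v in the second.  The pair is
    retained iff the count exceeds ``consensus_threshold`` (default K//2).

    All pairs are judged against the same pre-filter surviving set (single
    pass), so the result is independent of evaluation order;
    ``iterative=True`` repeats the pass on the survivors until a fixed point.
    """
    if K_neighbors < 1:
        raise ValueError("K_neighbors must be >= 1")
    thr = K_neighbors // 2 if consensus_threshold is None else consensus_threshold

    def one_pass(live: list[MatchPair]) -> tuple[list[MatchPair], list[MatchPair]]:
        if not live:
            return [], []
        ptsA = np.array([kpA[m.template_idx].world_mm for m in live])
        ptsB = np.array([kpB[m.target_idx].world_mm for m in live])
        K = min(K_neighbors, len(live) - 1)
        dA = cdist(ptsA, ptsA)
        dB = cdist(ptsB, ptsB)
        np.fill_diagonal(dA, np.inf)
        np.fill_diagonal(dB, np.inf)
        kept, removed = [], []
        for i, m in enumerate(live):
            if K < 1:
                kept.append(m)  # nothing to test against
                continue
            nA = set(np.argpartition(dA[i], K - 1)[:K])
            nB = set(np.argpartition(dB[i], K - 1)[:K])
            consensus = len(nA & nB)
            (kept if consensus > thr else removed).append(m)
        return kept, removed

    kept, removed = one_pass(pairs)
    if iterative:
        while removed:
            kept, newly_removed = one_pass(kept)
            if not newly_removed:
                break
            removed.extend(newly_removed)
    for m in removed:
        m.status = "removed_by_structure"
    for m in kept:
        m.status = "retained"
    return kept


def match_pipeline(
    vA: Volume,
    vB: Volume,
    kpA: list[KeyPoint],
    kpB: list[KeyPoint],
    descA: np.ndarray,
    descB: np.ndarray,
    config: MatchConfig | None = None,
):
    """Run the full cascade; returns (retained pairs, all pairs, MatchReport)."""
    cfg = config or MatchConfig()
    ab = ratio_match(descA, descB, cfg.tau)
    ba = ratio_match(descB, descA, cfg.tau)
    pairs = symmetric_filter(ab, ba)
    report = MatchReport(candidates=len(pairs))
    if not pairs:
        return [], [], report
    survivors = cc_filter(pairs, vA, vB, kpA, kpB, cfg.cc_threshold, cfg.d_voxels, cfg.cc_sigma, cfg.spherical_patch)
    report.removed_by_cc = len(pairs) - len(survivors)
    retained = structural_invariance_filter(
        survivors, kpA, kpB, cfg.K_neighbors, cfg.consensus_threshold, cfg.iterative_structural
    )
    report.removed_by_structure = len(survivors) - len(retained)
    report.retained = len(retained)
    assert report.check_conservation()
    return retained, pairs, report


def matches_to_csv(pairs: list[MatchPair], kpA: list[KeyPoint], kpB: list[KeyPoint], path) -> None:
    """Export pairs as CSV with world-mm endpoints, ratio, cc and status."""
    lines = ["template_x_mm,template_y_mm,template_z_mm,target_x_mm,target_y_mm,target_z_mm,ratio,cc,status"]
    for m in pairs:
        a = kpA[m.template_idx].world_mm
        b = kpB[m.target_idx].world_mm
        cc = "" if m.cc is None else f"{m.cc:.6f}"
        lines.append(
            f"{a[0]:.6f},{a[1]:.6f},{a[2]:.6f},{b[0]:.6f},{b[1]:.6f},{b[2]:.6f},{m.ratio:.6f},{cc},{m.status}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def report_to_json(report: MatchReport, path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")
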