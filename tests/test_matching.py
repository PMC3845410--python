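"""Match-verification cascade: ratio test, symmetry, patch CC, structure."""

from __future__ import annotations

import numpy as np
import pytest

import lungreg as lr
from lungreg.harris import KeyPoint
from lungreg.matching import MatchPair, cc_filter, structural_invariance_filter


def _kp_at(world):
    w = np.asarray(world, dtype=float)
    return KeyPoint(tuple(int(round(c)) for c in w), w, (0.0, 0.0, 0.0), 0.0)


def _pairs(n):
    return [MatchPair(i, i, 0.1, 1.0, 0.1) for i in range(n)]


class TestRatioMatch:
    def test_threshold_rule(self):
        """d1=0.4,d2=1.0 accepted at tau 0.8; d1=0.9,d2=1.0 rejected."""
        a = np.zeros((1, 4))
        b = np.array([[0.4, 0, 0, 0], [-1.0, 0, 0, 0]], dtype=float)
        got = lr.ratio_match(np.pad(a, ((0, 0), (0, 2044))), np.pad(b, ((0, 0), (0, 2044))), tau=0.8)
        assert len(got) == 1 and got[0].ratio == pytest.approx(0.4)
        b2 = np.array([[0.9, 0, 0, 0], [-1.0, 0, 0, 0]], dtype=float)
        assert lr.ratio_match(np.pad(a, ((0, 0), (0, 2044))), np.pad(b2, ((0, 0), (0, 2044))), tau=0.8) == []

    def test_self_match_identical_sets(self, rng):
        desc = rng.normal(size=(10, 32))
        got = lr.ratio_match(desc, desc, tau=0.8)
        assert all(m.template_idx == m.target_idx and m.d1 == 0.0 for m in got)
        assert len(got) == 10

    def test_matches_exhaustive_oracle(self, rng):
        """On 40x45 random descriptor sets the accepted pairs equal a direct
        all-pairs sorted-distance computation."""
        a = rng.normal(size=(40, 16))
        b = rng.normal(size=(45, 16))
        tau = 0.8
        got = {(m.template_idx, m.target_idx) for m in lr.ratio_match(a, b, tau)}
        expected = set()
        for i in range(a.shape[0]):
            dist = np.linalg.norm(b - a[i], axis=1)
            d = np.sort(dist)
            if d[1] > 0 and d[0] / d[1] < tau:
                expected.add((i, int(np.argmin(dist))))
        assert got == expected

    def test_single_target_descriptor_rejected(self, rng):
        assert lr.ratio_match(rng.normal(size=(5, 8)), rng.normal(size=(1, 8))) == []

    def test_duplicate_targets_rejected(self):
        a = np.ones((1, 8))
        b = np.vstack([np.ones(8), np.ones(8)])
        assert lr.ratio_match(a, b) == []  # d2 = 0: ambiguous identity

    def test_bad_tau(self, rng):
        with pytest.raises(ValueError):
            lr.ratio_match(rng.normal(size=(2, 4)), rng.normal(size=(3, 4)), tau=0.0)


class TestSymmetricFilter:
    def test_mutual_kept_asymmetric_dropped(self):
        ab = [MatchPair(1, 2, 0.1, 1.0, 0.1)]
        assert len(lr.symmetric_filter(ab, [MatchPair(2, 1, 0.1, 1.0, 0.1)])) == 1
        assert lr.symmetric_filter(ab, [MatchPair(2, 3, 0.1, 1.0, 0.1)]) == []

    def test_random_lists_match_set_oracle(self, rng):
        ab = [MatchPair(i, int(j), 0.1, 1.0, 0.1) for i, j in enumerate(rng.integers(0, 10, 20))]
        ba = [MatchPair(i, int(j), 0.1, 1.0, 0.1) for i, j in enumerate(rng.integers(0, 20, 10))]
        got = {(m.template_idx, m.target_idx) for m in lr.symmetric_filter(ab, ba)}
        oracle = {(m.template_idx, m.target_idx) for m in ab} & {
            (m.target_idx, m.template_idx) for m in ba
        }
        assert got == oracle


class TestPatchCC:
    def _vol(self, data):
        return lr.Volume(np.asarray(data, dtype=float))

    def test_identical_patches(self, rng):
        v = self._vol(rng.normal(size=(16, 16, 16)))
        kp = _kp_at((8, 8, 8))
        assert lr.patch_cc(v, kp, v, kp, d_voxels=5) == pytest.approx(1.0)

    def test_positive_affine_invariance(self, rng):
        a = rng.normal(size=(16, 16, 16))
        va, vb = self._vol(a), self._vol(3.0 * a + 10.0)
        kp = _kp_at((8, 8, 8))
        assert lr.patch_cc(va, kp, vb, kp, d_voxels=5) == pytest.approx(1.0)

    def test_anticorrelation(self, rng):
        a = rng.normal(size=(16, 16, 16))
        va, vb = self._vol(a), self._vol(-a)
        kp = _kp_at((8, 8, 8))
        assert lr.patch_cc(va, kp, vb, kp, d_voxels=5) == pytest.approx(-1.0)

    def test_zero_variance_patch_returns_zero(self, rng):
        va = self._vol(np.full((12, 12, 12), 5.0))
        vb = self._vol(rng.normal(size=(12, 12, 12)))
        assert lr.patch_cc(va, _kp_at((6, 6, 6)), vb, _kp_at((6, 6, 6)), d_voxels=3) == 0.0

    def test_bounded_on_random_pairs(self, rng):
        va = self._vol(rng.normal(size=(24, 24, 24)))
        vb = self._vol(rng.normal(size=(24, 24, 24)))
        for _ in range(200):
            pa = _kp_at(rng.integers(0, 24, 3))
            pb = _kp_at(rng.integers(0, 24, 3))
            assert -1.0 <= lr.patch_cc(va, pa, vb, pb, d_voxels=3) <= 1.0


class TestCCFilter:
    def test_identical_volumes_none_removed(self, rng):
        v = lr.Volume(rng.normal(size=(24, 24, 24)))
        kps = [_kp_at(p) for p in [(8, 8, 8), (8, 14, 8), (14, 8, 14), (14, 14, 14)]]
        pairs = _pairs(4)
        surv = cc_filter(pairs, v, v, kps, kps, cc_threshold=0.7, d_voxels=5)
        assert len(surv) == 4

    def test_corrupted_pair_removed(self, rng):
        data = rng.normal(size=(24, 24, 24))
        va = lr.Volume(data)
        corrupted = data.copy()
        corrupted[10:20, 10:20, 10:20] = rng.normal(size=(10, 10, 10))
        vb = lr.Volume(corrupted)
        kps = [_kp_at(p) for p in [(5, 5, 5), (15, 15, 15)]]
        pairs = _pairs(2)
        surv = cc_filter(pairs, va, vb, kps, kps, cc_threshold=0.5, d_voxels=4)
        assert [m.template_idx for m in surv] == [0]
        assert pairs[1].status == "removed_by_cc"

    def test_vacuous_threshold_removes_nothing(self, rng):
        va = lr.Volume(rng.normal(size=(16, 16, 16)))
        vb = lr.Volume(rng.normal(size=(16, 16, 16)))
        kps = [_kp_at((8, 8, 8))]
        assert len(cc_filter(_pairs(1), va, vb, kps, kps, cc_threshold=-1.0, d_voxels=3)) == 1


def _constellation(rng, n=20, extent=80.0):
    return rng.uniform(10, extent, size=(n, 3))


class TestStructuralInvariance:
    def test_rigid_translation_all_retained(self, rng):
        ptsA = _constellation(rng)
        kpA = [_kp_at(p) for p in ptsA]
        kpB = [_kp_at(p + np.array([3.0, -2.0, 7.0])) for p in ptsA]
        retained = structural_invariance_filter(_pairs(20), kpA, kpB, K_neighbors=4, consensus_threshold=2)
        assert len(retained) == 20
        assert all(m.status == "retained" for m in retained)

    def test_single_swap_exactly_removed(self, rng):
        """One pair's target endpoint is swapped with a distant keypoint:
        neighbour consensus removes exactly that pair (K=4, threshold=2)."""
        ptsA = _constellation(rng)
        ptsB = ptsA + np.array([3.0, -2.0, 7.0])
        ptsB[7] = np.array([200.0, 200.0, 200.0])  # swapped far away
        kpA = [_kp_at(p) for p in ptsA]
        kpB = [_kp_at(p) for p in ptsB]
        pairs = _pairs(20)
        retained = structural_invariance_filter(pairs, kpA, kpB, K_neighbors=4, consensus_threshold=2)
        assert {m.template_idx for m in pairs} - {m.template_idx for m in retained} == {7}
        assert pairs[7].status == "removed_by_structure"

    def test_neighbour_sets_match_enumeration_oracle(self, rng):
        """Consensus counts agree with explicit neighbour-set enumeration."""
        ptsA = _constellation(rng, n=12)
        ptsB = ptsA @ np.diag([1.0, 1.0, 1.1]) + rng.normal(0, 0.5, size=(12, 3))
        kpA = [_kp_at(p) for p in ptsA]
        kpB = [_kp_at(p) for p in ptsB]
        K, thr = 5, 2
        pairs = _pairs(12)
        retained = {m.template_idx for m in structural_invariance_filter(pairs, kpA, kpB, K, thr)}
        expected = set()
        for i in range(12):
            dA = np.linalg.norm(ptsA - ptsA[i], axis=1)
            dB = np.linalg.norm(ptsB - ptsB[i], axis=1)
            nA = set(np.argsort(dA)[1 : K + 1])
            nB = set(np.argsort(dB)[1 : K + 1])
            if len(nA & nB) > thr:
                expected.add(i)
        assert retained == expected

    def test_vacuous_threshold_retains_all(self, rng):
        ptsA = _constellation(rng, n=8)
        kpA = [_kp_at(p) for p in ptsA]
        kpB = [_kp_at(p + rng.normal(0, 20, 3)) for p in ptsA]
        retained = structural_invariance_filter(_pairs(8), kpA, kpB, K_neighbors=4, consensus_threshold=-1)
        assert len(retained) == 8

    def test_fewer_pairs_than_K_truncates(self, rng):
        ptsA = _constellation(rng, n=3)
        kpA = [_kp_at(p) for p in ptsA]
        kpB = [_kp_at(p + 2.0) for p in ptsA]
        retained = structural_invariance_filter(_pairs(3), kpA, kpB, K_neighbors=8, consensus_threshold=1)
        assert len(retained) == 3  # 2 common neighbours each > 1


class TestMatchPipeline:
    def test_identical_inputs_all_self_matched(self, rng):
        v = lr.Volume(rng.normal(size=(48, 48, 48)))
        kps, _ = lr.detect_keypoints(v, min_distance_mm=4.0, rel_threshold=0.1)
        assert len(kps) >= 5
        from lungreg.sift3d import build_descriptors

        desc, kept = build_descriptors(v, kps)
        kps = [kps[i] for i in kept]
        retained, pairs, report = lr.match_pipeline(v, v, kps, kps, desc, desc)
        assert report.candidates == len(kps)
        assert report.removed_by_cc == 0 and report.removed_by_structure == 0
        assert all(m.template_idx == m.target_idx for m in retained)

    def test_empty_keypoints_zero_report(self, rng):
        v = lr.Volume(rng.normal(size=(16, 16, 16)))
        retained, pairs, report = lr.match_pipeline(v, v, [], [], np.empty((0, 2048)), np.empty((0, 2048)))
        assert retained == [] and pairs == []
        assert report.as_dict() == {"candidates": 0, "removed_by_cc": 0, "removed_by_structure": 0, "retained": 0}

    def test_counts_conserved_and_statuses_consistent(self, registration_result):
        _, res = registration_result
        rep = res.report
        assert rep.check_conservation()
        by_status = {s: sum(m.status == s for m in res.pairs) for s in ("removed_by_cc", "removed_by_structure", "retained")}
        assert by_status["removed_by_cc"] == rep.removed_by_cc
        assert by_status["removed_by_structure"] == rep.removed_by_structure
        assert by_status["retained"] == rep.retained

    def test_symmetry_of_roles(self, phantom_noiseless):
        """Swapping template and target yields the same correspondence set
        with roles exchanged (symmetric parameters)."""
        from lungreg.phantom import lung_mask
        from lungreg.sift3d import build_descriptors

        spec, template, target, _, _ = phantom_noiseless
        mask = lung_mask(spec)
        kA, _ = lr.detect_keypoints(template, mask=mask)
        kB, _ = lr.detect_keypoints(target, mask=mask)
        dA, keptA = build_descriptors(template, kA)
        dB, keptB = build_descriptors(target, kB)
        kA = [kA[i] for i in keptA]
        kB = [kB[i] for i in keptB]
        fwd, _, _ = lr.match_pipeline(template, target, kA, kB, dA, dB)
        rev, _, _ = lr.match_pipeline(target, template, kB, kA, dB, dA)
        assert {(m.template_idx, m.target_idx) for m in fwd} == {
            (m.target_idx, m.template_idx) for m in rev
        }

    def test_decoy_false_pair_rate_monotone(self, phantom_noiseless):
        """Planted decoy keypoints: the false-pair rate does not increase
        through the cc and structural stages."""
        from lungreg.phantom import lung_mask
        from lungreg.sift3d import build_descriptors
        from lungreg.matching import MatchConfig, cc_filter, ratio_match, structural_invariance_filter, symmetric_filter

        spec, template, target, _, _ = phantom_noiseless
        mask = lung_mask(spec)
        kA, _ = lr.detect_keypoints(template, mask=mask)
        kB, _ = lr.detect_keypoints(target, mask=mask)
        kA, tagsA = lr.plant_decoys(kA, 10, template, mask, seed=3)
        kB, tagsB = lr.plant_decoys(kB, 10, target, mask, seed=4)
        dA, keptA = build_descriptors(template, kA)
        dB, keptB = build_descriptors(target, kB)
        kA = [kA[i] for i in keptA]
        tagsA = [tagsA[i] for i in keptA]
        kB = [kB[i] for i in keptB]
        tagsB = [tagsB[i] for i in keptB]

        def false_rate(pairs):
            if not pairs:
                return 0.0
            bad = sum(tagsA[m.template_idx] or tagsB[m.target_idx] for m in pairs)
            return bad / len(pairs)

        cand = symmetric_filter(ratio_match(dA, dB, 0.8), ratio_match(dB, dA, 0.8))
        after_cc = cc_filter(list(cand), template, target, kA, kB, cc_threshold=0.7, d_voxels=5)
        after_struct = structural_invariance_filter(list(after_cc), kA, kB, 8, 4)
        assert false_rate(after_cc) <= false_rate(cand)
        assert false_rate(after_struct) <= false_rate(after_cc)

    def test_phantom_matches_near_true_correspondence(self, registration_result):
        """>= 90% of retained pairs lie within 2x the spreading distance of
        the ground-truth deformed position of their template endpoint."""
        from lungreg.phantom import _default_deformation

        cfg, res = registration_result
        extent = np.asarray(res.template_iso.shape) * res.template_iso.spacing
        deform = _default_deformation(extent)
        ok = 0
        for m in res.retained:
            q = res.keypoints_template[m.template_idx].world_mm
            x = res.keypoints_target[m.target_idx].world_mm
            true_target = deform.map_template_to_target(q[None])[0]
            ok += np.linalg.norm(x - true_target) <= 2 * cfg.min_distance_mm
        assert res.retained and ok / len(res.retained) >= 0.9
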