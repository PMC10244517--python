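"""Overlap and surface metrics, Wilcoxon signed-rank, Bland-Altman."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from dixonmuscle.imgvol import LabelVolume, MuscleScheme
from dixonmuscle.metrics import (
    assd,
    bland_altman,
    dsc,
    evaluate_segmentation,
    generalized_dsc,
    per_muscle_dsc,
    wilcoxon_signed_rank,
)
from dixonmuscle.postprocess import erode_boundary


def brute_force_assd(mask_a, mask_b, spacing):
    """All-pairs oracle: boundary voxels are those with a 6-neighbour
    outside the mask (volume border outside); distances between centres."""

    def boundary(mask):
        pts = []
        for idx in np.argwhere(mask):
            for ax in range(3):
                for d in (-1, 1):
                    nb = idx.copy()
                    nb[ax] += d
                    if (nb < 0).any() or (nb >= np.array(mask.shape)).any() or not mask[tuple(nb)]:
                        pts.append(idx)
                        break
                else:
                    continue
                break
        return np.array(pts, dtype=float)

    pa = boundary(mask_a) * spacing
    pb = boundary(mask_b) * spacing
    d = cdist(pa, pb)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(pa) + len(pb))


def exhaustive_wilcoxon(diffs):
    """Exact two-sided p by enumerating every sign assignment (n <= ~12)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws)
    p_low = (ws <= w_obs + 1e-9).mean()
    p_high = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestDSC:
    def test_identical_masks_100(self, rng):
        m = rng.random((6, 6, 3)) > 0.5
        assert dsc(m, m) == 100.0

    def test_disjoint_masks_0(self):
        a = np.zeros((4, 4, 2), bool)
        b = np.zeros((4, 4, 2), bool)
        a[0, 0, 0] = True
        b[3, 3, 1] = True
        assert dsc(a, b) == 0.0

    def test_hand_counted_half_overlap(self):
        a = np.zeros((4, 1, 1), bool)
        b = np.zeros((4, 1, 1), bool)
        a[0:2] = True
        b[1:3] = True  # |A|=|B|=2, |A n B|=1 -> 2*1/4
        assert dsc(a, b) == 50.0

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), bool)
        assert dsc(z, z) == 100.0

    def test_symmetric_and_mirror_invariant(self, rng):
        a = rng.random((6, 6, 4)) > 0.6
        b = rng.random((6, 6, 4)) > 0.6
        assert dsc(a, b) == dsc(b, a)
        assert dsc(a, b) == dsc(a[::-1], b[::-1])


class TestPerMuscleAndGeneralized:
    def _volumes(self):
        scheme = MuscleScheme.first(2)
        ref = np.zeros((8, 4, 2), dtype=np.uint8)
        pred = np.zeros_like(ref)
        # left leg perfect, right leg disjoint, equal sizes for muscle 1
        ref[0:2, 0, 0] = 1
        pred[0:2, 0, 0] = 1
        ref[4:6, 0, 0] = 1
        pred[6:8, 0, 0] = 1
        return LabelVolume(pred, scheme), LabelVolume(ref, scheme)

    def test_pooled_legs_give_50(self):
        pred, ref = self._volumes()
        assert per_muscle_dsc(pred, ref, 1) == 50.0

    def test_single_id_reduces_to_per_muscle(self):
        pred, ref = self._volumes()
        assert generalized_dsc(pred, ref, ids=[1]) == per_muscle_dsc(pred, ref, 1)

    def test_matched_plus_disjoint_pools_to_50(self):
        scheme = MuscleScheme.first(2)
        ref = np.zeros((8, 2, 1), dtype=np.uint8)
        pred = np.zeros_like(ref)
        ref[0:2, 0, 0] = 1
        pred[0:2, 0, 0] = 1          # muscle 1 perfectly matched, |.|=2
        ref[4:6, 0, 0] = 2
        pred[6:8, 0, 0] = 2          # muscle 2 disjoint, |.|=2
        p, r = LabelVolume(pred, scheme), LabelVolume(ref, scheme)
        assert generalized_dsc(p, r) == 50.0

    def test_identity_is_100(self, clean_phantom):
        _, _, truth = clean_phantom
        assert generalized_dsc(truth.labels, truth.labels) == 100.0

    def test_unknown_id_rejected(self):
        pred, ref = self._volumes()
        with pytest.raises(KeyError):
            per_muscle_dsc(pred, ref, 7)

    def test_erosion_of_reference_decreases_dsc(self, clean_phantom):
        _, _, truth = clean_phantom
        eroded = erode_boundary(truth.labels, 1)
        assert generalized_dsc(truth.labels, eroded) < 100.0


class TestASSD:
    SPACING = (1.2, 1.2, 2.0)

    def test_identical_masks_zero(self, rng):
        m = np.zeros((6, 6, 4), bool)
        m[2:5, 2:5, 1:3] = True
        assert assd(m, m, self.SPACING) == 0.0

    def test_single_voxels_one_apart(self):
        a = np.zeros((4, 4, 2), bool)
        b = np.zeros((4, 4, 2), bool)
        a[1, 1, 0] = True
        b[2, 1, 0] = True
        assert assd(a, b, self.SPACING) == pytest.approx(1.2)

    def test_symmetric_in_arguments(self, rng):
        a = rng.random((6, 6, 4)) > 0.6
        b = rng.random((6, 6, 4)) > 0.6
        if a.any() and b.any():
            assert assd(a, b, self.SPACING) == assd(b, a, self.SPACING)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            a = rng.random((8, 8, 6)) > 0.7
            b = rng.random((8, 8, 6)) > 0.7
            if not (a.any() and b.any()):
                continue
            expected = brute_force_assd(a, b, self.SPACING)
            assert assd(a, b, self.SPACING) == pytest.approx(expected, abs=1e-9)

    def test_empty_mask_undefined(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError, match="empty"):
            assd(a, b, self.SPACING)


class TestWilcoxon:
    def test_identical_samples_p1_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_six_positive_distinct_exact(self):
        a = [10, 20, 30, 40, 50, 60]
        b = [9, 18, 27, 36, 45, 54]
        assert wilcoxon_signed_rank(a, b) == pytest.approx(2 / 64)

    def test_matches_scipy_exact_without_ties(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        ours = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_path_matches_enumeration_with_ties(self):
        a = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        b = np.array([2.0, 2.0, 3.0, 0.0, 3.0, 8.0, 4.0, 5.0])
        assert wilcoxon_signed_rank(a, b) == pytest.approx(exhaustive_wilcoxon(a - b))

    def test_large_sample_normal_approximation(self, rng):
        a = rng.normal(0.3, 1.0, size=40)
        b = rng.normal(0.0, 1.0, size=40)
        ours = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, method="approx", correction=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


class TestBlandAltman:
    def test_identical_vectors(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0
        assert res.limits == (0.0, 0.0)

    def test_closed_form_sd(self):
        res = bland_altman([1.0, 0.0], [0.0, 1.0])  # diffs {1, -1}
        assert res.bias == 0.0
        assert res.sd == pytest.approx(np.sqrt(2))
        lo, hi = res.limits
        assert hi == pytest.approx(1.96 * np.sqrt(2))
        assert lo == pytest.approx(-hi)

    def test_order_preserved_for_plotting(self):
        a = [3.0, 1.0, 2.0]
        b = [1.0, 1.0, 1.0]
        res = bland_altman(a, b)
        np.testing.assert_allclose(res.differences, [2.0, 0.0, 1.0])
        np.testing.assert_allclose(res.means, [2.0, 1.0, 1.5])

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2"):
            bland_altman([1.0], [2.0])


class TestReport:
    def test_absent_muscles_flagged_not_imputed(self):
        scheme = MuscleScheme.first(3)
        vals = np.zeros((6, 6, 4), dtype=np.uint8)
        vals[1:3, 1:3, 1:3] = 1
        lv = LabelVolume(vals, scheme)
        report = evaluate_segmentation(lv, lv)
        frame = report.per_muscle.set_index("muscle_id")
        assert frame.loc[1, "dsc_pct"] == 100.0
        assert frame.loc[2, "flags"] == "absent_ref+absent_pred"
        assert np.isnan(frame.loc[2, "assd_mm"])
        assert report.gdsc_pct == 100.0
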