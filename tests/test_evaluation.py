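import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gelband.evaluation import (
    dice_score,
    evaluate_method,
    hausdorff,
    holdout_regression_error,
    paired_comparison,
    per_band_accuracy,
    precision_recall,
)
from gelband.io import SegmentationMask
from gelband.quantitation import label_bands
from gelband.synthetic import SyntheticGelSpec, generate_quantitation_set


def naive_set_metrics(pred, truth):
    """Set-arithmetic recomputation of dice/precision/recall (test oracle)."""
    p = {tuple(x) for x in np.argwhere(pred > 0)}
    t = {tuple(x) for x in np.argwhere(truth > 0)}
    inter = len(p & t)
    dice = 1.0 if not p and not t else 2 * inter / (len(p) + len(t))
    precision = inter / len(p) if p else None
    recall = inter / len(t) if t else 1.0
    return dice, precision, recall


class TestDice:
    def test_identical_masks(self, rng):
        m = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        assert dice_score(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dice_score(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 20), np.uint8)
        b = np.zeros((10, 20), np.uint8)
        a[:, :10] = 1  # |P| = 100
        b[:, 5:15] = 1  # |T| = 100, overlap 50
        assert dice_score(a, b) == 0.5

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), np.uint8)
        assert dice_score(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_score(np.zeros((3, 3), np.uint8), np.zeros((4, 4), np.uint8))

    def test_oracle_agreement_and_symmetry(self, rng):
        for _ in range(25):
            p = (rng.random((16, 16)) < 0.3).astype(np.uint8)
            t = (rng.random((16, 16)) < 0.3).astype(np.uint8)
            d, prec, rec = naive_set_metrics(p, t)
            assert abs(dice_score(p, t) - d) < 1e-12
            assert dice_score(p, t) == dice_score(t, p)
            mp, mr = precision_recall(p, t)
            if prec is None:
                assert mp is None
            else:
                assert abs(mp - prec) < 1e-12
            assert abs(mr - rec) < 1e-12
            # duality: precision(P,T) == recall(T,P)
            dual_r = precision_recall(t, p)[1]
            if mp is not None and t.any():
                assert abs(mp - dual_r) < 1e-12


class TestPrecisionRecallHausdorff:
    def test_perfect_prediction(self, rng):
        m = np.zeros((12, 12), np.uint8)
        m[4:8, 4:8] = 1
        assert precision_recall(m, m) == (1.0, 1.0)
        assert hausdorff(m, m) == 0.0

    def test_translation_gives_shift_distance(self):
        a = np.zeros((30, 30), np.uint8)
        b = np.zeros((30, 30), np.uint8)
        a[10:14, 10:14] = 1
        b[13:17, 10:14] = 1  # shifted 3 rows
        assert hausdorff(a, b) == pytest.approx(3.0)

    def test_subset_prediction(self):
        t = np.zeros((10, 10), np.uint8)
        p = np.zeros((10, 10), np.uint8)
        t[2:8, 2:8] = 1
        p[3:7, 3:7] = 1
        prec, rec = precision_recall(p, t)
        assert prec == 1.0
        assert rec == pytest.approx(16 / 36)

    def test_empty_prediction_flags(self):
        t = np.zeros((5, 5), np.uint8)
        t[2, 2] = 1
        p = np.zeros((5, 5), np.uint8)
        prec, rec = precision_recall(p, t)
        assert prec is None and rec == 0.0
        with pytest.raises(ValueError):
            hausdorff(p, t)

    def test_both_empty_hausdorff_zero(self):
        z = np.zeros((5, 5), np.uint8)
        assert hausdorff(z, z) == 0.0


class TestPerBandAccuracy:
    def grid_truth(self):
        truth = np.zeros((30, 30), np.uint8)
        truth[5:10, 5:15] = 1
        truth[20:25, 5:15] = 1
        return truth, label_bands(SegmentationMask(truth))

    def test_exact_reproduction_scores_100(self):
        truth, instances = self.grid_truth()
        assert per_band_accuracy(truth, instances) == [100.0, 100.0]

    def test_split_prediction_scores_zero(self):
        truth, instances = self.grid_truth()
        pred = truth.copy()
        pred[7, 5:15] = 0  # cut the first band into two predicted instances
        accs = per_band_accuracy(pred, instances)
        assert accs[0] == 0.0 and accs[1] == 100.0

    def test_partial_coverage(self):
        truth, instances = self.grid_truth()
        pred = np.zeros_like(truth)
        pred[5:10, 5:12] = 1  # 35 of 50 px of band 1
        pred[20:25, 5:15] = 1
        accs = per_band_accuracy(pred, instances)
        assert accs == [pytest.approx(70.0), 100.0]

    def test_missed_band_scores_zero(self):
        truth, instances = self.grid_truth()
        pred = np.zeros_like(truth)
        pred[20:25, 5:15] = 1
        assert per_band_accuracy(pred, instances)[0] == 0.0

    def test_pred_denominator_variant(self):
        truth, instances = self.grid_truth()
        pred = np.zeros_like(truth)
        pred[5:12, 5:15] = 1  # covers band 1 plus 20 extra px
        accs = per_band_accuracy(pred, instances, denominator="pred")
        assert accs[0] == pytest.approx(100.0 * 50 / 70)


class TestHoldoutRegression:
    def test_proportional_volumes_zero_error(self, rng):
        masses = np.linspace(20, 200, 10)
        res = holdout_regression_error(masses * 3.1, masses, rng=rng)
        assert res.mean_pct_error < 1e-9
        assert res.n_repeats == 80

    def test_affine_volumes_zero_error(self, rng):
        masses = np.linspace(20, 200, 10)
        res = holdout_regression_error(2 * masses + 100, masses, rng=rng)
        assert res.mean_pct_error < 1e-9

    def test_affine_invariance_of_error(self):
        masses = np.linspace(20, 200, 10)
        volumes = masses * (1 + np.random.default_rng(5).normal(0, 0.05, 10))
        a = holdout_regression_error(volumes, masses, rng=np.random.default_rng(9))
        b = holdout_regression_error(3.7 * volumes + 55, masses, rng=np.random.default_rng(9))
        assert a.mean_pct_error == pytest.approx(b.mean_pct_error, abs=1e-9)

    def test_agrees_with_vectorised_oracle(self):
        rng_data = np.random.default_rng(5)
        masses = np.linspace(20, 200, 10)
        volumes = masses * (1 + rng_data.normal(0, 0.05, 10))

        # loop-free oracle: precompute all hold-out draws with an identical
        # generator, then closed-form OLS via polyfit
        res = holdout_regression_error(volumes, masses, rng=np.random.default_rng(3))
        oracle_rng = np.random.default_rng(3)
        errs = []
        for _ in range(80):
            held = oracle_rng.choice(10, size=5, replace=False)
            keep = np.setdiff1d(np.arange(10), held)
            slope, intercept = np.polyfit(volumes[keep], masses[keep], 1)
            pred = slope * volumes[held] + intercept
            errs.append(np.mean(100 * np.abs(pred - masses[held]) / masses[held]))
        assert res.mean_pct_error == pytest.approx(np.mean(errs), abs=1e-9)
        assert 2.0 < res.mean_pct_error < 12.0  # 5%-noise scale

    def test_too_few_bands_rejected(self, rng):
        with pytest.raises(ValueError):
            holdout_regression_error(np.arange(6.0), np.arange(6.0) + 1, rng=rng)

    def test_noise_monotonicity(self):
        masses = np.array([m for m, _ in SyntheticGelSpec().ladder])
        means = []
        for sigma in (0.0, 0.02, 0.05):
            rng = np.random.default_rng(17)
            errs = []
            for _ in range(40):
                m = masses * rng.uniform(0.5, 1.5)
                v = m * (1 + rng.normal(0, sigma, m.shape))
                errs.append(holdout_regression_error(v, m, rng=rng).mean_pct_error)
            means.append(np.mean(errs))
        assert means[0] < 1e-9
        assert means[0] < means[1] < means[2]


class TestPairedComparison:
    def test_zero_mean_differences(self):
        t, p, n = paired_comparison([2, 0, 2, 0], [1, 1, 1, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert n == 4

    def test_hand_computed_t(self):
        # differences {1, 2, 3}: t = 2 / (1/sqrt(3)) = 3.4641, p ~ 0.0742
        t, p, n = paired_comparison([2, 4, 6], [1, 2, 3])
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_constant_nonzero_differences_flagged(self):
        t, p, n = paired_comparison([2, 3, 4], [1, 2, 3])
        assert t is None and p is None and n == 3

    def test_all_zero_differences(self):
        t, p, n = paired_comparison([1.0, 2.0], [1.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_comparison([1, 2], [1, 2, 3])


@pytest.fixture(scope="module")
def noiseless_gels():
    spec = SyntheticGelSpec(
        background=(0.0, 0.0), noise_sigma=0.0, bit_depth=16,
        amplitude_per_ng=0.75 * 257,
    )
    return generate_quantitation_set(3, spec, seed=5)


class TestEvaluateMethod:

    def test_truth_masks_recover_masses(self, noiseless_gels):
        res = evaluate_method(noiseless_gels, None, "none", rng=0)
        assert res["summary"]["n_lanes"] == 18
        assert res["per_lane_errors"].max() < 0.5

    def test_short_lanes_excluded_and_counted(self, noiseless_gels):
        res = evaluate_method(noiseless_gels, None, "none", rng=0, min_bands=11)
        assert res["summary"]["n_lanes"] == 0
        assert res["summary"]["excluded_lanes"] == 18

    def test_erosion_shift_below_noise_spread(self, noiseless_gels):
        base = evaluate_method(noiseless_gels, None, "none", rng=0)
        eroded = evaluate_method(
            noiseless_gels, None, "none", rng=0, mask_perturbation="erode"
        )
        noisy = evaluate_method(
            noiseless_gels, None, "none", rng=0, volume_noise_sigma=0.05
        )
        shift = abs(np.mean(eroded["per_lane_errors"] - base["per_lane_errors"]))
        spread = np.mean(noisy["per_lane_errors"] - base["per_lane_errors"])
        assert shift < spread


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_metric_identities_hold_for_random_masks(seed):
    rng = np.random.default_rng(seed)
    p = (rng.random((12, 12)) < rng.uniform(0, 0.6)).astype(np.uint8)
    t = (rng.random((12, 12)) < rng.uniform(0, 0.6)).astype(np.uint8)
    d, prec, rec = naive_set_metrics(p, t)
    assert abs(dice_score(p, t) - d) < 1e-12
    mp, mr = precision_recall(p, t)
    assert (mp is None) == (prec is None)
    assert abs(mr - rec) < 1e-12
    assert 0.0 <= dice_score(p, t) <= 1.0
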