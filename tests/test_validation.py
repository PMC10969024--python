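import math

import numpy as np
import pytest

from evproteo import validation as val
from evproteo.datatypes import ValidationError


def _linear_plate(slope=-0.3, intercept=2.0, samples=None, gain=1.0):
    """Noiseless direct-ELISA plate: absorbance = intercept +
    slope*log2(dilution), zero background."""
    standards = {d: [gain * (intercept + slope * math.log2(d))] * 3
                 for d in (1, 2, 4, 8, 16)}
    samples = samples or {}
    return val.AssayPlate(
        standards=standards,
        samples={k: [gain * v] for k, v in samples.items()},
        background=[0.0, 0.0],
        blanks=[0.0, 0.005, -0.005, 0.002])


class TestStandardCurve:
    def test_undiluted_standard_reads_one(self):
        plate = _linear_plate(samples={"s": 2.0})
        res = val.standard_curve_titer(plate)
        assert res.titers["s"] == pytest.approx(1.0)

    def test_half_dilution_reads_half(self):
        plate = _linear_plate(samples={"s": 2.0 - 0.3})
        res = val.standard_curve_titer(plate)
        assert res.titers["s"] == pytest.approx(0.5)

    def test_inverting_the_stated_line(self):
        plate = _linear_plate(samples={"s": 1.85})
        res = val.standard_curve_titer(plate)
        assert res.titers["s"] == pytest.approx(2 ** -0.5, rel=1e-9)

    def test_global_gain_leaves_titers_unchanged(self):
        a = val.standard_curve_titer(_linear_plate(samples={"s": 1.85}))
        b = val.standard_curve_titer(_linear_plate(samples={"s": 1.85},
                                                   gain=3.0))
        assert b.titers["s"] == pytest.approx(a.titers["s"], rel=1e-9)

    def test_below_detection_limit_flagged(self):
        plate = _linear_plate(samples={"dim": 0.001})
        res = val.standard_curve_titer(plate)
        assert "dim" in res.below_lod

    def test_out_of_range_sample_flagged(self):
        plate = _linear_plate(samples={"hot": 5.0})
        res = val.standard_curve_titer(plate)
        assert "hot" in res.extrapolated

    def test_too_few_standards_rejected(self):
        with pytest.raises(ValidationError):
            val.AssayPlate(standards={1: [2.0], 2: [1.7]},
                           samples={}, background=[0.0])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = val.kruskal_wallis([5, 5, 5, 5, 5, 5],
                                  ["a", "a", "b", "b", "c", "c"])
        assert h == 0.0 and p == 1.0

    def test_fully_separated_groups(self):
        h, p = val.kruskal_wallis([1, 2, 3, 4, 5, 6],
                                  ["a", "a", "b", "b", "c", "c"])
        assert h == pytest.approx(4.5714, abs=1e-3)

    def test_p_decreases_with_separation(self, rng):
        base = rng.normal(0, 1, size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        last_p = 1.1
        for shift in (0.0, 1.0, 3.0, 6.0):
            vals = base.copy()
            vals[groups == "c"] += shift
            _, p = val.kruskal_wallis(vals, groups)
            assert p < last_p
            last_p = p

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            val.kruskal_wallis([1, 2, 3], ["a", "a", "b"])


class TestRoc:
    def test_perfect_separation_auc_one(self):
        roc = val.roc_curve([1, 2, 10, 11], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_all_tied_scores_auc_half(self):
        roc = val.roc_curve([3, 3, 3, 3], [0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_hand_example_three_quarters(self):
        roc = val.roc_curve([2, 4, 1, 3], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_flip_orientation_recorded(self):
        roc = val.roc_curve([10, 9, 1, 2], [0, 0, 1, 1])
        assert roc.flipped and roc.auc == pytest.approx(1.0)

    def test_auc_complement_identity_tie_free(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        a = val._auc_mann_whitney(scores[labels == 1], scores[labels == 0])
        b = val._auc_mann_whitney(-scores[labels == 1],
                                  -scores[labels == 0])
        assert a + b == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_pairwise_u(self, seed):
        """AUC from the empirical curve (trapezoid over thresholds)
        equals the Mann-Whitney pairwise statistic."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = np.round(rng.normal(size=n), 1)  # force some ties
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        roc = val.roc_curve(scores, labels)
        # thresholds ascend, so reversing gives the curve from (0,0) to
        # (1,1) with fpr and tpr jointly non-decreasing
        fpr = (1.0 - roc.specificities)[::-1]
        tpr = roc.sensitivities[::-1]
        auc_trap = float(np.trapezoid(tpr, fpr))
        assert roc.auc == pytest.approx(auc_trap, abs=1e-10)

    def test_delong_ci_and_p_behave(self, rng):
        cases = rng.normal(2, 1, size=30)
        controls = rng.normal(0, 1, size=30)
        roc = val.roc_curve(np.concatenate([cases, controls]),
                            [1] * 30 + [0] * 30)
        lo, hi = roc.ci
        assert lo <= roc.auc <= hi
        assert roc.p_value < 0.001

    def test_bootstrap_ci_close_to_delong(self, rng):
        cases = rng.normal(1.5, 1, size=40)
        controls = rng.normal(0, 1, size=40)
        scores = np.concatenate([cases, controls])
        labels = [1] * 40 + [0] * 40
        dl = val.roc_curve(scores, labels)
        bs = val.roc_curve(scores, labels, ci_method="bootstrap", seed=1)
        assert bs.auc == dl.auc
        assert bs.ci[0] == pytest.approx(dl.ci[0], abs=0.07)
        assert bs.ci[1] == pytest.approx(dl.ci[1], abs=0.07)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            val.roc_curve([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_reported_triplets_reproduce_lr(self):
        assert val.likelihood_ratio_positive(1.00, 0.71) == 3.4
        assert val.likelihood_ratio_positive(1.00, 0.54) == 2.2
        assert val.likelihood_ratio_positive(1.00, 0.64) == 2.8

    def test_perfect_specificity_infinite_lr(self):
        assert math.isinf(val.likelihood_ratio_positive(1.0, 1.0))

    def test_perfect_separation_cutoff_at_boundary(self):
        roc = val.youden_cutoff(val.roc_curve([1, 2, 10, 11],
                                              [0, 0, 1, 1]))
        assert roc.youden_j == pytest.approx(1.0)
        assert roc.cutoff == pytest.approx(2.0)  # "> 2" splits perfectly
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_tie_break_prefers_sensitivity(self):
        # two cutoffs reach J = 0.5; the chosen one has sens 1.0
        roc = val.youden_cutoff(val.roc_curve([1, 3, 2, 4], [0, 0, 1, 1]))
        assert roc.sensitivity == 1.0

    def test_j_consistency(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        roc = val.youden_cutoff(val.roc_curve(scores, labels))
        assert roc.youden_j == pytest.approx(
            roc.sensitivity + roc.specificity - 1.0)


class TestAucBand:
    @pytest.mark.parametrize("auc,label", [
        (0.91, "excellent"), (0.85, "good"), (0.77, "fair"),
        (0.5, "not discriminant"), (0.55, "fail"), (0.65, "poor"),
        (0.6, "poor"), (0.7, "fair"), (0.8, "good"), (0.9, "excellent"),
        (1.0, "excellent"),
    ])
    def test_bands(self, auc, label):
        assert val.auc_band(auc) == label

    def test_below_half_banded_after_flip(self):
        assert val.auc_band(0.09) == "excellent"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            val.auc_band(1.2)


class TestSampleSize:
    def test_one_sd_effect_needs_seventeen_per_group(self):
        # normal approximation gives 15.7 -> 16; the exact noncentral-t
        # power at 16 is 0.781, so the refinement steps to 17 (0.807)
        assert val.sample_size(1.0, alpha=0.05, power=0.80) == 17

    def test_returned_n_is_minimal_with_exact_power(self):
        for delta in (0.5, 1.0, 2.0):
            n = val.sample_size(delta)
            assert val.two_sample_t_power(n, delta) >= 0.80
            if n > 2:
                assert val.two_sample_t_power(n - 1, delta) < 0.80

    def test_huge_effect_floors_at_two(self):
        assert val.sample_size(1e6) == 2

    def test_n_decreases_with_effect_size(self):
        ns = [val.sample_size(d) for d in (0.5, 1.0, 2.0, 4.0)]
        assert ns == sorted(ns, reverse=True)

    def test_multiplicity_increases_n(self):
        assert val.sample_size(1.0, n_tests=10) > val.sample_size(1.0)

    def test_power_below_alpha_rejected(self):
        with pytest.raises(ValidationError):
            val.sample_size(1.0, alpha=0.5, power=0.4)

    def test_monte_carlo_power_meets_design_within_mc_error(self):
        n = val.sample_size(1.0, alpha=0.05, power=0.80)
        power = val.empirical_power(n, 1.0, alpha=0.05,
                                    n_replicates=2000, seed=123)
        se = np.sqrt(power * (1 - power) / 2000)
        assert power >= 0.80 - 2 * se
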