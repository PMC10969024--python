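import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evproteo import differential as diff
from evproteo.datatypes import ValidationError

from conftest import make_matrix, make_sheet


def _two_group_sheet(n=3, groups=("PA", "CH"), fraction="Tot"):
    rows = []
    for g in groups:
        for i in range(n):
            rows.append((f"{g}{i}", g, fraction))
    return make_sheet(rows)


class TestOnewayAnova:
    def test_two_cell_anova_equals_squared_t(self, rng):
        sheet = _two_group_sheet(5)
        m = make_matrix(rng.normal(25, 2, size=(20, 10)),
                        sample_ids=sheet.sample_ids)
        cells = [sheet.samples_in(group="PA"), sheet.samples_in(group="CH")]
        res = diff.oneway_anova(m, sheet, cells)
        t = stats.ttest_ind(m.values[:, :5], m.values[:, 5:], axis=1)
        np.testing.assert_allclose(res["F"], t.statistic ** 2, rtol=1e-10)
        np.testing.assert_allclose(res["p"], t.pvalue, rtol=1e-10)

    def test_identical_cells_give_f_zero(self):
        sheet = _two_group_sheet(3, groups=("PA", "CH", "MB"))
        vals = np.tile([1.0, 2.0, 3.0], (1, 3))
        m = make_matrix(vals, sample_ids=sheet.sample_ids)
        res = diff.oneway_anova(m, sheet)
        assert res["F"].iloc[0] == pytest.approx(0.0)

    def test_constant_protein_p_one_policy(self):
        sheet = _two_group_sheet(2)
        m = make_matrix(np.full((1, 4), 5.0), sample_ids=sheet.sample_ids)
        res = diff.oneway_anova(m, sheet)
        assert res["F"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_small_cell_rejected(self):
        sheet = make_sheet([("a", "PA", "Tot"), ("b", "CH", "Tot"),
                            ("c", "CH", "Tot")])
        m = make_matrix(np.zeros((1, 3)), sample_ids=["a", "b", "c"])
        with pytest.raises(ValidationError):
            diff.oneway_anova(m, sheet)


class TestWelch:
    def test_hand_example(self):
        sheet = _two_group_sheet(3)
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
                        sample_ids=sheet.sample_ids)
        res = diff.welch_ttest(m, sheet, "PA-vs-CH")
        assert res["t"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        assert res["p"].iloc[0] == pytest.approx(0.0213, abs=1e-3)
        assert res["log2fc"].iloc[0] == pytest.approx(-3.0)

    def test_identical_sides_t_zero_p_one(self):
        sheet = _two_group_sheet(3)
        m = make_matrix(np.full((1, 6), 2.0), sample_ids=sheet.sample_ids)
        res = diff.welch_ttest(m, sheet, "PA-vs-CH")
        assert res["t"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_orientation_positive_means_higher_in_pa(self, rng):
        sheet = _two_group_sheet(20)
        pa = rng.normal(2, 1, size=(1, 20))
        ch = rng.normal(0, 1, size=(1, 20))
        m = make_matrix(np.hstack([pa, ch]), sample_ids=sheet.sample_ids)
        res = diff.welch_ttest(m, sheet, "PA-vs-CH")
        se = np.sqrt(2.0 / 20)
        assert abs(res["log2fc"].iloc[0] - 2.0) < 3 * se

    def test_nonpa_pools_ch_and_mb(self):
        rows = ([(f"PA{i}", "PA", "Tot") for i in range(2)]
                + [(f"CH{i}", "CH", "Tot") for i in range(2)]
                + [(f"MB{i}", "MB", "Tot") for i in range(2)])
        sheet = make_sheet(rows)
        m = make_matrix([[4.0, 4.0, 1.0, 1.0, 3.0, 3.0]],
                        sample_ids=sheet.sample_ids)
        res = diff.welch_ttest(m, sheet, "PA-vs-nonPA")
        assert res["mean_control"].iloc[0] == pytest.approx(2.0)

    def test_small_side_rejected(self):
        sheet = make_sheet([("a", "PA", "Tot"), ("b", "PA", "Tot"),
                            ("c", "CH", "Tot")])
        m = make_matrix(np.zeros((1, 3)), sample_ids=["a", "b", "c"])
        with pytest.raises(ValidationError):
            diff.welch_ttest(m, sheet, "PA-vs-CH")


def bh_oracle(p):
    """Brute-force BH: for each p_i the smallest over thresholds t >= p_i
    of m*t/#{p <= t}, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    out = np.empty(m)
    for i, pi in enumerate(p):
        cands = [m * t / np.sum(p <= t) for t in p if t >= pi]
        out[i] = min(1.0, min(cands))
    return out


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(diff.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(diff.bh_adjust([0.2]), [0.2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 20))
        np.testing.assert_allclose(diff.bh_adjust(p), bh_oracle(p),
                                   atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(diff.bh_adjust(p), expected, atol=1e-12)

    def test_bounds_and_monotonicity(self, rng):
        p = rng.random(50)
        q = diff.bh_adjust(p)
        assert (q <= 1).all() and (q >= 0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            diff.bh_adjust([0.5, 1.5])


class TestVolcano:
    def _table(self, x, q):
        q = np.asarray(q, dtype=float)
        return pd.DataFrame({"log2fc": x, "q": q,
                             "neg_log10_q": -np.log10(q)})

    def test_point_above_curve_significant(self):
        t = self._table([1.0], [10 ** -1.001])
        assert diff.volcano_significance(t, c=1.0, q_max=0.5).iloc[0]

    def test_point_below_curve_not_significant(self):
        t = self._table([0.5], [10 ** -1.5])  # curve needs y >= 2
        assert not diff.volcano_significance(t, c=1.0, q_max=0.5).iloc[0]

    def test_boundary_inclusive(self):
        t = self._table([1.0], [0.1])  # y = 1 exactly on curve c=1
        assert diff.volcano_significance(t, c=1.0, q_max=0.5).iloc[0]

    def test_zero_fold_change_never_significant(self):
        t = self._table([0.0], [1e-30])
        assert not diff.volcano_significance(t, c=1.0, q_max=0.5).iloc[0]

    def test_q_ceiling_applies(self):
        t = self._table([5.0], [0.2])
        assert not diff.volcano_significance(t, c=1.0, q_max=0.05).iloc[0]

    def test_nonpositive_c_rejected(self):
        t = self._table([1.0], [0.01])
        with pytest.raises(ValidationError):
            diff.volcano_significance(t, c=0.0)


def _mk_table(universe, sig, comparison, fraction):
    tab = pd.DataFrame(index=pd.Index(universe, name="protein"))
    tab["log2fc"] = 0.0
    tab["p"] = 1.0
    tab["q"] = 1.0
    tab["neg_log10_q"] = 0.0
    tab["significant"] = [u in sig for u in universe]
    return diff.DifferentialTable(tab, comparison, fraction)


class TestIntersectComparisons:
    def test_hand_counted_venn(self):
        universe = ["p1", "p2", "p3", "p4"]
        tables = {
            ("PA-vs-CH", "Tot"): _mk_table(universe, {"p1", "p2"},
                                           "PA-vs-CH", "Tot"),
            ("PA-vs-MB", "Tot"): _mk_table(universe, {"p2"},
                                           "PA-vs-MB", "Tot"),
            ("PA-vs-nonPA", "Tot"): _mk_table(universe, {"p2", "p3"},
                                              "PA-vs-nonPA", "Tot"),
        }
        res = diff.intersect_comparisons(tables)
        abc = res.venn[res.venn["region"] == "ABC"].iloc[0]
        assert abc["count"] == 1
        assert abc["pct_of_union"] == pytest.approx(33.3)
        assert res.both_controls_panel == {"p2"}
        assert res.all_comparisons_panel == {"p2"}

    def test_disjoint_sets_empty_panels(self):
        universe = ["a", "b", "c"]
        tables = {
            (comp, "Tot"): _mk_table(universe, {u}, comp, "Tot")
            for comp, u in zip(diff.COMPARISONS, universe)
        }
        res = diff.intersect_comparisons(tables)
        assert res.both_controls_panel == set()
        assert res.all_comparisons_panel == set()

    def test_mismatched_universes_rejected(self):
        tables = {
            ("PA-vs-CH", "Tot"): _mk_table(["a"], set(), "PA-vs-CH", "Tot"),
            ("PA-vs-MB", "Tot"): _mk_table(["b"], set(), "PA-vs-MB", "Tot"),
            ("PA-vs-nonPA", "Tot"): _mk_table(["a"], set(), "PA-vs-nonPA",
                                              "Tot"),
        }
        with pytest.raises(ValidationError):
            diff.intersect_comparisons(tables)


def test_percent_of_rounds_to_one_decimal():
    assert diff.percent_of(7, 62) == 11.3
    assert diff.percent_of(1, 3) == 33.3
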