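"""Agreement statistics: overlap metrics and cohort-level analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tmtvnet import (
    CaseRecord,
    bland_altman,
    cohort_report,
    confusion_metrics,
    dice,
    jaccard,
    paired_t,
    spearman,
)
from tmtvnet.metrics import distribution_stats


def _average_ranks(values):
    """Brute-force average ranks with ties (independent of scipy)."""
    values = np.asarray(values, dtype=float)
    ranks = np.empty(len(values))
    order = np.argsort(values, kind="stable")
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


masks3d = hnp.arrays(bool, (4, 4, 4), elements=st.booleans())


class TestDiceJaccard:
    def test_identical_nonempty_masks(self):
        m = np.ones((3, 3, 3), bool)
        assert dice(m, m) == 1.0 and jaccard(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0, 0, 0], b[1, 1, 1] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((1, 1, 200), bool)
        b = np.zeros((1, 1, 200), bool)
        a[0, 0, :100] = True  # |a| = 100
        b[0, 0, 50:150] = True  # |b| = 100, overlap 50
        assert dice(a, b) == pytest.approx(0.5)

    def test_empty_vs_empty_is_perfect_agreement(self):
        e = np.zeros((2, 2, 2), bool)
        assert dice(e, e) == 1.0 and jaccard(e, e) == 1.0
        assert dice(e, ~e) == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(masks3d, masks3d)
    def test_jaccard_dice_identity_and_symmetry(self, a, b):
        """J = D / (2 - D) holds exactly for every binary pair."""
        d, j = dice(a, b), jaccard(a, b)
        assert j == pytest.approx(d / (2 - d), abs=1e-12)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        truth = np.zeros((3, 3, 3), bool)
        truth[0] = True
        m = confusion_metrics(truth, truth)
        assert (m.se, m.sp, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_complement_prediction(self):
        truth = np.zeros((3, 3, 3), bool)
        truth[0] = True
        m = confusion_metrics(~truth, truth)
        assert m.se == 0.0 and m.sp == 0.0

    def test_three_voxel_enumeration(self):
        """truth [1,1,0], pred [1,0,0]: TP=1 FN=1 TN=1 FP=0."""
        truth = np.array([[[True, True, False]]])
        pred = np.array([[[True, False, False]]])
        m = confusion_metrics(pred, truth)
        assert m.se == pytest.approx(0.5)
        assert m.ppv == pytest.approx(1.0)
        assert m.sp == pytest.approx(1.0)
        assert m.npv == pytest.approx(0.5)

    def test_zero_denominator_reported_missing(self):
        all_true = np.ones((2, 2, 2), bool)
        m = confusion_metrics(all_true, all_true)  # no negatives anywhere
        assert np.isnan(m.sp) and np.isnan(m.npv)


class TestBlandAltman:
    def test_identical_arms(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba == {"bias": 0.0, "loa_low": 0.0, "loa_high": 0.0}

    def test_constant_shift(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x + 5)
        assert ba["bias"] == pytest.approx(-5.0)
        assert ba["loa_high"] - ba["loa_low"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_mean_sd_computation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(100, 30, 100), rng.normal(95, 25, 100)
        ba = bland_altman(x, y)
        d = x - y
        assert ba["bias"] == pytest.approx(d.mean())
        assert ba["loa_low"] == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert ba["loa_high"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_limits_contain_about_95_percent_of_gaussian_differences(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 4000)
        x = y + rng.normal(2.0, 5.0, 4000)
        ba = bland_altman(x, y)
        d = x - y
        frac = np.mean((d >= ba["loa_low"]) & (d <= ba["loa_high"]))
        assert frac == pytest.approx(0.95, abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 3.0, 7.0, 9.0, 15.0])
        r, p = spearman(x, np.exp(x / 10))
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_reversed_order_gives_minus_one(self):
        x = np.arange(8.0)
        r, _ = spearman(x, x[::-1])
        assert r == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_with_ties(self):
        x = [1.0, 2.0, 2.0, 5.0, 7.0, 7.0, 9.0]
        y = [3.0, 1.0, 4.0, 4.0, 8.0, 6.0, 6.0]
        r, _ = spearman(x, y)
        rx, ry = _average_ranks(x), _average_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_input_reported_missing(self):
        r, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)


class TestPairedT:
    def test_identical_arms_p_one(self):
        assert paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_large_shift_small_sd_highly_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, 30)
        assert paired_t(x, x + 10) < 1e-10

    def test_five_pair_example_matches_closed_form(self):
        """d = [-1, 0, -1, 1, -1]: t = -1.0 on 4 df, two-sided p = 0.3739."""
        p = paired_t([1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 2.0, 4.0, 3.0, 6.0])
        assert p == pytest.approx(0.3739009663, rel=1e-8)


class TestCohortReport:
    def _cohort(self, n=20, disagree=False, seed=0):
        rng = np.random.default_rng(seed)
        cases = []
        for i in range(n):
            truth = rng.random((6, 6, 6)) > 0.7
            pred = truth.copy()
            if disagree:
                flip = rng.random(truth.shape) < 0.15
                pred = truth ^ flip
            t_man = float(truth.sum()) * 0.064
            t_prd = float(pred.sum()) * 0.064
            cases.append(
                CaseRecord(
                    case_id=f"c{i}",
                    subtype=("HL", "DLBCL", "FL")[i % 3],
                    manual_masks={"41pc": truth},
                    pred_masks={"41pc": pred},
                    manual_tmtv_ml={"41pc": t_man},
                    pred_tmtv_ml={"41pc": t_prd},
                )
            )
        return cases

    def test_perfect_predictions_give_perfect_stats(self):
        report = cohort_report(self._cohort(), methods=["41pc"])
        row = report.summary.iloc[0]
        assert row["dice_median"] == 1.0 and row["dice_mean"] == 1.0
        assert row["ba_bias"] == 0.0
        assert row["spearman_r"] == pytest.approx(1.0)
        assert row["paired_t_p"] == 1.0

    def test_single_case_cohort_medians_equal_case_values(self):
        cases = self._cohort(n=1)
        report = cohort_report(cases, methods=["41pc"])
        row = report.summary.iloc[0]
        assert row["n"] == 1
        assert row["manual_tmtv_median"] == cases[0].manual_tmtv_ml["41pc"]

    def test_injected_disagreement_matches_direct_recomputation(self):
        cases = self._cohort(disagree=True, seed=3)
        report = cohort_report(cases, methods=["41pc"])
        dices = [dice(c.pred_masks["41pc"], c.manual_masks["41pc"]) for c in cases]
        man = [c.manual_tmtv_ml["41pc"] for c in cases]
        prd = [c.pred_tmtv_ml["41pc"] for c in cases]
        row = report.summary.iloc[0]
        assert row["dice_median"] == pytest.approx(np.median(dices))
        assert row["dice_mean"] == pytest.approx(np.mean(dices))
        assert row["spearman_r"] == pytest.approx(spearman(man, prd)[0])
        assert row["ba_bias"] == pytest.approx(bland_altman(man, prd)["bias"])
        assert row["paired_t_p"] == pytest.approx(paired_t(man, prd))
        for k, v in distribution_stats(man).items():
            assert row[f"manual_tmtv_{k}"] == pytest.approx(v)

    def test_subtype_stratification_covers_all_subtypes(self):
        report = cohort_report(self._cohort(disagree=True), methods=["41pc"])
        assert set(report.by_subtype["subtype"]) == {"HL", "DLBCL", "FL"}

    def test_case_missing_method_excluded(self):
        cases = self._cohort(n=4)
        cases[0].manual_masks = {}
        report = cohort_report(cases, methods=["41pc"])
        assert report.summary.iloc[0]["n"] == 3
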