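"""Evaluation-protocol unit and oracle-equivalence tests."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from polypcad.evaluate import (
    map_histopathology_to_class, max_3d_diameter, size_stratum, roc_auc,
    select_threshold, confusion_metrics, category_accuracy, summarize_cohort,
    percent_half_up, evaluate_scores,
)


class TestHistopathologyMapping:
    @pytest.mark.parametrize("category,expected", [
        ("regular mucosa", "benign"),
        ("hyperplastic polyp", "benign"),
        ("lipomatous polyp", "benign"),
        ("tubular adenoma", "premalignant"),
        ("tubulovillous adenoma", "premalignant"),
        ("villous adenoma", "premalignant"),
        ("serrated adenoma", "premalignant"),
        ("adenocarcinoma", "premalignant"),
        ("Tubular Adenoma ", "premalignant"),   # case/whitespace variants
        ("  HYPERPLASTIC   POLYP", "benign"),
    ])
    def test_mapping(self, category, expected):
        assert map_histopathology_to_class(category) == expected

    def test_unknown_category_lists_accepted_values(self):
        with pytest.raises(ValueError, match="hyperplastic polyp"):
            map_histopathology_to_class("fibroma")


class TestMax3dDiameter:
    def test_single_voxel_is_zero(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert max_3d_diameter(m) == 0.0

    def test_axis_neighbours_unit_step(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = m[3, 2, 2] = True
        assert max_3d_diameter(m, (1, 1, 1)) == pytest.approx(1.0)

    def test_solid_cube_space_diagonal(self):
        m = np.zeros((7, 7, 7), bool)
        m[2:5, 2:5, 2:5] = True
        assert max_3d_diameter(m, (1, 1, 1)) == pytest.approx(np.sqrt(12.0))

    def test_anisotropic_spacing(self):
        m = np.zeros((5, 5, 5), bool)
        m[1, 2, 2] = m[3, 2, 2] = True
        assert max_3d_diameter(m, (0.5, 1, 2)) == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            max_3d_diameter(np.zeros((4, 4, 4), bool))

    def test_boundary_equals_all_pairs_on_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = np.zeros((12, 12, 12), bool)
            n = int(rng.integers(1, 40))
            centre = rng.integers(3, 9, 3)
            pts = np.clip(centre + rng.integers(-3, 4, (n, 3)), 0, 11)
            m[tuple(pts.T)] = True
            spacing = rng.uniform(0.5, 2.0, 3)
            all_pairs = 0.0
            coords = np.argwhere(m) * spacing
            if len(coords) > 1:
                all_pairs = pdist(coords).max()
            assert max_3d_diameter(m, tuple(spacing)) == pytest.approx(
                all_pairs, abs=1e-12)


class TestSizeStratum:
    @pytest.mark.parametrize("d,expected", [
        (5.4, "<=5"), (5.5, "6-9"), (9.4, "6-9"), (9.6, ">=10"),
        (0.0, "<=5"), (10.0, ">=10"),
    ])
    def test_half_up_binning(self, d, expected):
        assert size_stratum(d) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            size_stratum(-1.0)


class TestRocAuc:
    def test_worked_example(self):
        # pairs (0.35 vs 0.1, 0.4), (0.8 vs 0.1, 0.4): 3 of 4 ordered
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [0, 1] * 3) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 200))
            scores = np.round(rng.random(n), 2)  # rounding provokes ties
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                labels[0] = 1 - labels[0]
            pos, neg = scores[labels == 1], scores[labels == 0]
            diff = pos[:, None] - neg[None, :]
            brute = (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size
            mine = roc_auc(scores, labels)
            assert mine == pytest.approx(brute, abs=1e-12)
            assert mine == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestSelectThreshold:
    def test_perfect_separation_keeps_both_at_one(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        t = select_threshold(scores, labels, 0.80)
        conf = confusion_metrics(scores, labels, t)
        assert conf["sensitivity"][:2] == (2, 2)
        assert conf["specificity"][:2] == (2, 2)

    def test_target_one_captures_all_positives(self):
        scores = np.array([0.3, 0.6, 0.4, 0.9])
        labels = np.array([0, 1, 1, 0])
        t = select_threshold(scores, labels, 1.0)
        assert t <= scores[labels == 1].min()

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(6, 100))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                labels[0] = 1 - labels[0]
            t = select_threshold(scores, labels, 0.80)
            pos, neg = labels == 1, labels == 0
            sens = ((scores >= t) & pos).sum() / pos.sum()
            spec = ((scores < t) & neg).sum() / neg.sum()
            assert sens >= 0.80
            for cand in np.concatenate([scores - 1e-9, scores + 1e-9]):
                c_sens = ((scores >= cand) & pos).sum() / pos.sum()
                c_spec = ((scores < cand) & neg).sum() / neg.sum()
                if c_sens >= 0.80:
                    assert c_spec <= spec + 1e-12


class TestConfusionMetrics:
    @pytest.mark.parametrize("tp,p,expected", [(63, 79, 80), (27, 39, 69), (17, 39, 44)])
    def test_printed_fraction_percent_pairs(self, tp, p, expected):
        assert percent_half_up(tp, p) == expected

    def test_counts_from_scores(self):
        # 3 of 4 positives above threshold, 1 of 2 negatives below
        scores = [0.9, 0.8, 0.7, 0.1, 0.6, 0.2]
        labels = [1, 1, 1, 1, 0, 0]
        conf = confusion_metrics(scores, labels, 0.5)
        assert conf["sensitivity"] == (3, 4, 75)
        assert conf["specificity"] == (1, 2, 50)

    def test_half_up_rounding(self):
        assert percent_half_up(1, 8) == 13  # 12.5 rounds up


class TestCategoryAccuracy:
    def test_printed_style_fraction(self):
        cats = ["tubulovillous adenoma"] * 26
        preds = ["premalignant"] * 23 + ["benign"] * 3
        acc = category_accuracy(preds, cats)
        assert acc["tubulovillous adenoma"] == (23, 26, 88)
        assert acc["villous adenoma"] == (0, 0, None)

    def test_per_category_sums_to_overall(self):
        rng = np.random.default_rng(5)
        cats = rng.choice(list({"hyperplastic polyp", "tubular adenoma",
                                "adenocarcinoma", "regular mucosa"}), 60)
        preds = rng.choice(["benign", "premalignant"], 60)
        acc = category_accuracy(preds, cats)
        total_correct = sum(v[0] for v in acc.values())
        expected = sum(p == map_histopathology_to_class(c)
                       for p, c in zip(preds, cats))
        assert total_correct == expected
        assert sum(v[1] for v in acc.values()) == 60


class TestSummarizeCohort:
    def _manifest(self, counts: dict) -> pd.DataFrame:
        rows = [{"histopathologic_category": cat}
                for cat, n in counts.items() for _ in range(n)]
        return pd.DataFrame(rows)

    def test_screening_training_style_column(self):
        counts = {"regular mucosa": 3, "hyperplastic polyp": 78,
                  "lipomatous polyp": 2, "tubular adenoma": 57,
                  "tubulovillous adenoma": 16, "villous adenoma": 8,
                  "serrated adenoma": 4, "adenocarcinoma": 1}
        table = summarize_cohort(self._manifest(counts))
        by_cat = table.set_index("histopathologic_category")
        assert by_cat.loc["total", "count"] == 169
        assert by_cat.loc["all premalignant", "count"] == 86
        assert by_cat.loc["all benign", "count"] == 83
        assert by_cat.loc["hyperplastic polyp", "percent"] == 46

    def test_external_style_column(self):
        counts = {"regular mucosa": 9, "hyperplastic polyp": 30,
                  "lipomatous polyp": 0, "tubular adenoma": 49,
                  "tubulovillous adenoma": 26, "villous adenoma": 0,
                  "serrated adenoma": 0, "adenocarcinoma": 4}
        by_cat = summarize_cohort(self._manifest(counts)).set_index(
            "histopathologic_category")
        assert by_cat.loc["total", "count"] == 118
        assert by_cat.loc["all premalignant", "count"] == 79
        assert by_cat.loc["all benign", "count"] == 39
        assert by_cat.loc["tubular adenoma", "percent"] == 42


class TestEvaluateScores:
    def test_report_is_self_consistent(self):
        rng = np.random.default_rng(11)
        n = 80
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = np.clip(rng.normal(0.4 + 0.2 * labels, 0.2), 0, 1)
        diam = rng.uniform(3, 15, n)
        cats = np.where(labels == 1, "tubular adenoma", "hyperplastic polyp")
        rep = evaluate_scores(scores, labels, categories=cats, diameters_mm=diam)
        assert rep.auc == pytest.approx(roc_auc(scores, labels))
        s_num, s_den, _ = rep.sensitivity
        assert s_num / s_den >= 0.80
        assert s_den == labels.sum()
        assert rep.specificity[1] == (1 - labels).sum()
        strata = [size_stratum(d) for d in diam]
        for s, auc in rep.subgroup_aucs.items():
            sel = np.array([x == s for x in strata])
            if auc is not None:
                assert auc == pytest.approx(roc_auc(scores[sel], labels[sel]))
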