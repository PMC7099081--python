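"""Longitudinal test-set construction, ROC/PR/Youden/kappa statistics against
brute-force oracles, and bootstrap confidence intervals."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

import siamscore as ss
from siamscore.evaluation import (Dichotomy, LongitudinalPair, binary_change_label,
                                  bootstrap_ci, build_longitudinal_testset,
                                  linear_weighted_kappa, roc_pr_curves, spearman_rho,
                                  youden_threshold)


def _unit_manifest(grades_by_unit):
    rows = []
    for unit, grades in grades_by_unit.items():
        for t, g in enumerate(grades):
            rows.append({"patient_id": unit.split("_")[0], "unit_id": unit,
                         "timepoint": t, "latent_severity": g / 3.0, "grade": g,
                         "image_path": f"{unit}_{t}.png", "split": "test"})
    return pd.DataFrame(rows)


class TestLongitudinalTestset:
    def test_no_change_unit_uses_its_only_pair(self):
        pairs = build_longitudinal_testset(_unit_manifest({"A_U0": [0, 0]}), seed=0)
        assert len(pairs) == 1
        assert (pairs[0].record_t1["timepoint"], pairs[0].record_t2["timepoint"]) == (0, 1)

    def test_change_combination_preferred(self):
        for seed in range(10):
            pairs = build_longitudinal_testset(_unit_manifest({"A_U0": [0, 0, 1]}), seed=seed)
            assert pairs[0].record_t1["grade"] != pairs[0].record_t2["grade"]

    def test_seeded_choice_is_reproducible(self):
        man = _unit_manifest({"A_U0": [0, 1, 2]})
        p1 = build_longitudinal_testset(man, seed=5)
        p2 = build_longitudinal_testset(man, seed=5)
        assert [(p.record_t1["timepoint"], p.record_t2["timepoint"]) for p in p1] == \
               [(p.record_t1["timepoint"], p.record_t2["timepoint"]) for p in p2]

    @pytest.mark.parametrize("seed", range(5))
    def test_one_pair_per_unit_and_change_preference_property(self, seed):
        rng = np.random.default_rng(seed)
        units = {f"P{i}_U0": list(rng.integers(0, 3, rng.integers(1, 5)))
                 for i in range(20)}
        man = _unit_manifest(units)
        pairs = build_longitudinal_testset(man, seed=seed)
        assert len({p.unit_id for p in pairs}) == len(pairs)
        for p in pairs:
            assert p.record_t1["timepoint"] < p.record_t2["timepoint"]
            grades = units[p.unit_id]
            if len(set(grades)) > 1:
                assert p.grade_change != 0
        multi_visit = [u for u, g in units.items() if len(g) >= 2]
        assert len(pairs) == len(multi_visit)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            build_longitudinal_testset(_unit_manifest({}).reindex(columns=[
                "patient_id", "unit_id", "timepoint", "grade", "image_path"]), seed=0)


class TestDichotomy:
    def test_rop_partition(self):
        d = ss.rop_dichotomy()
        make = lambda g1, g2: LongitudinalPair(
            "u", pd.Series({"grade": g1, "timepoint": 0}),
            pd.Series({"grade": g2, "timepoint": 1}))
        assert binary_change_label(make(0, 1), d) == 1
        assert binary_change_label(make(1, 2), d) == 0
        assert binary_change_label(make(1, 0), d) == 1

    def test_knee_partition_crossings(self):
        d = ss.knee_dichotomy()
        make = lambda g1, g2: LongitudinalPair(
            "u", pd.Series({"grade": g1, "timepoint": 0}),
            pd.Series({"grade": g2, "timepoint": 1}))
        expected = {(1, 2): 1, (2, 4): 0, (0, 1): 0, (0, 2): 1, (4, 1): 1}
        for (g1, g2), label in expected.items():
            assert binary_change_label(make(g1, g2), d) == label

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            Dichotomy(frozenset({0, 1}), frozenset({1, 2}))
        with pytest.raises(ValueError):
            Dichotomy(frozenset({0}), frozenset({2}))


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(x, [2, 4, 6, 8]) == pytest.approx(1.0)
        assert spearman_rho(x, [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        x, y = [1, 2, 3, 4], [1, 2, 2, 3]
        # oracle: tie-averaged ranks, then Pearson correlation
        rx = np.array([1, 2, 3, 4], dtype=float)
        ry = np.array([1, 2.5, 2.5, 4], dtype=float)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(oracle)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


def _auc_concordance_oracle(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocPr:
    def test_perfect_and_inverted(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert roc_pr_curves(scores, labels)["roc_auc"] == 1.0
        assert roc_pr_curves(-scores, labels)["roc_auc"] == 0.0

    def test_six_point_example_equals_concordance_count(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.4])
        labels = np.array([0, 0, 1, 1, 1, 0])
        out = roc_pr_curves(scores, labels)
        assert out["roc_auc"] == pytest.approx(_auc_concordance_oracle(scores, labels))

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_equals_concordance_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # deliberate ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        out = roc_pr_curves(scores, labels)
        assert out["roc_auc"] == pytest.approx(_auc_concordance_oracle(scores, labels))
        assert 0.0 <= out["pr_auc"] <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves([0.1, 0.2], [1, 1])


def _youden_oracle(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    uniq = np.unique(scores)
    best, best_j = None, -np.inf
    for thr in (uniq[:-1] + uniq[1:]) / 2:
        pred = scores >= thr
        tpr = (pred & (labels == 1)).sum() / labels.sum()
        fpr = (pred & (labels == 0)).sum() / (labels == 0).sum()
        if tpr - fpr > best_j:
            best_j, best = tpr - fpr, thr
    return best


class TestYouden:
    def test_separated_classes_give_midpoint(self):
        thr = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == pytest.approx(0.5)

    def test_all_equal_scores_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.5] * 4, [0, 0, 1, 1])

    def test_overlapping_eight_point_set_matches_exhaustive_oracle(self):
        scores = [0.1, 0.3, 0.25, 0.5, 0.45, 0.7, 0.2, 0.6]
        labels = [0, 0, 1, 1, 0, 1, 0, 1]
        assert youden_threshold(scores, labels) == pytest.approx(
            _youden_oracle(scores, labels))

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 9), size=30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        if len(np.unique(scores)) < 2:
            return
        assert youden_threshold(scores, labels) == pytest.approx(
            _youden_oracle(scores, labels))


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        lo, hi = bootstrap_ci(lambda x: 1.0, np.arange(10), n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_same_seed_identical(self):
        data = np.random.default_rng(1).normal(size=30)
        ci1 = bootstrap_ci(np.mean, data, n_boot=500, seed=4)
        ci2 = bootstrap_ci(np.mean, data, n_boot=500, seed=4)
        assert ci1 == ci2

    def test_mean_ci_matches_independent_resampling_oracle(self):
        data = np.random.default_rng(2).normal(loc=1.0, size=40)
        lo, hi = bootstrap_ci(np.mean, data, n_boot=4000, seed=7)
        oracle_rng = np.random.default_rng(123)
        reps = [data[oracle_rng.integers(0, 40, 40)].mean() for _ in range(4000)]
        olo, ohi = np.percentile(reps, [2.5, 97.5])
        assert lo == pytest.approx(olo, abs=0.05)
        assert hi == pytest.approx(ohi, abs=0.05)

    def test_n_boot_floor(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, np.arange(10), n_boot=10, seed=0)


class TestKappa:
    def test_perfect_agreement(self):
        assert linear_weighted_kappa([0, 1, 1, 0], [0, 1, 1, 0]) == 1.0

    def test_one_sided_predictions_on_balanced_truth(self):
        pred = [0] * 10
        truth = [0] * 5 + [1] * 5
        assert linear_weighted_kappa(pred, truth, 2) == pytest.approx(0.0)

    def test_two_by_two_table_matches_po_pe_formula(self):
        # confusion [[40, 10], [10, 40]]: po = 0.8, pe = 0.5 -> kappa = 0.6
        truth = [0] * 50 + [1] * 50
        pred = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        assert linear_weighted_kappa(pred, truth, 2) == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_linear_weights_multiclass(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 4, 60)
        pred = np.where(rng.random(60) < 0.6, truth, rng.integers(0, 4, 60))
        if len(np.unique(truth)) < 2 or (pred == truth).all():
            return
        oracle = cohen_kappa_score(truth, pred, labels=range(4), weights="linear")
        assert linear_weighted_kappa(pred, truth, 4) == pytest.approx(oracle)

    def test_label_permutation_invariance(self):
        truth = np.array([0, 1, 1, 0, 1, 0, 0, 1])
        pred = np.array([0, 1, 0, 0, 1, 1, 0, 1])
        swapped = 1 - truth, 1 - pred
        assert linear_weighted_kappa(pred, truth, 2) == pytest.approx(
            linear_weighted_kappa(swapped[1], swapped[0], 2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            linear_weighted_kappa([], [])


class TestEvaluateChangeDetection:
    def _setup(self, tmp_path, values_by_unit, split):
        from conftest import constant_image_manifest
        frames = []
        for i, (unit, vals) in enumerate(values_by_unit.items()):
            df = constant_image_manifest(tmp_path / unit, list(vals),
                                         [0 if v < 0.5 else 1 for v in vals],
                                         unit=unit, patient=f"P{i}")
            df["split"] = split
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_perfect_separation_gives_kappa_one(self, tmp_path):
        model = ss.LinearEmbedder(np.full((1, 64), 1.0), input_size=(8, 8))
        test_units = {"A_U0": (0.1, 0.12), "B_U0": (0.1, 0.9), "C_U0": (0.2, 0.21),
                      "D_U0": (0.15, 0.85)}
        val_units = {"E_U0": (0.1, 0.11), "F_U0": (0.1, 0.95)}
        test_man = self._setup(tmp_path / "t", test_units, "test")
        val_man = self._setup(tmp_path / "v", val_units, "val")
        anchors = self._setup(tmp_path / "a", {"G_U0": (0.0, 0.05)}, "train")
        pool = ss.build_anchor_pool(anchors, pool_size=2)
        store = ss.ImageStore()
        pairs = build_longitudinal_testset(test_man, seed=0)
        val_pairs = build_longitudinal_testset(val_man, seed=1)
        dich = ss.rop_dichotomy()
        for metric in ("delta", "pairwise"):
            rep = ss.evaluate_change_detection(model, pairs, pool, dich, metric,
                                               val_pairs, store, n_boot=200, seed=0)
            assert rep.roc_auc == 1.0
            assert rep.kappa == 1.0
            assert not rep.degenerate
            assert rep.n_comparisons == 4

    def test_identical_image_pairs_flagged_degenerate(self, tmp_path):
        model = ss.LinearEmbedder(np.full((1, 64), 1.0), input_size=(8, 8))
        test_units = {"A_U0": (0.3, 0.3), "B_U0": (0.1, 0.9)}
        val_units = {"E_U0": (0.2, 0.2), "F_U0": (0.4, 0.4)}
        test_man = self._setup(tmp_path / "t", test_units, "test")
        val_man = self._setup(tmp_path / "v", val_units, "val")
        store = ss.ImageStore()
        pairs = build_longitudinal_testset(test_man, seed=0)
        val_pairs = build_longitudinal_testset(val_man, seed=1)
        rep = ss.evaluate_change_detection(model, pairs, None, ss.rop_dichotomy(),
                                           "pairwise", val_pairs, store,
                                           n_boot=200, seed=0)
        assert rep.degenerate
        assert rep.threshold is None and rep.kappa is None
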