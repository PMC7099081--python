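"""Longitudinal test-set construction, change-detection metrics, and the
conventional-classifier baseline.

The longitudinal comparison test set uses each imaged unit (one eye, one
knee) at most once: if the unit has any two-visit combination whose ordinal
grade changed, one such combination is used (sampled at random if several
exist); otherwise any combination is sampled.  Binary change is defined by a
dichotomy of the grade scale (retina: normal vs {pre-plus, plus}; knee:
KL {0,1} vs {2,3,4}) — the label is 1 iff the two visits fall on different
sides.

Statistics: Spearman rank correlation, ROC and precision-recall AUCs with
bootstrap 95% CIs, the operating threshold from Youden's J on validation
pairs, and linear-weighted Cohen's kappa for thresholded predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

from .scoring import AnchorPool, change_delta, change_pairwise
from .training import ImageStore, TrainConfig, TrainResult, classify, train_classifier

__all__ = [
    "Dichotomy",
    "rop_dichotomy",
    "knee_dichotomy",
    "LongitudinalPair",
    "EvalReport",
    "build_longitudinal_testset",
    "binary_change_label",
    "spearman_rho",
    "roc_pr_curves",
    "youden_threshold",
    "bootstrap_ci",
    "linear_weighted_kappa",
    "change_scores",
    "evaluate_change_detection",
    "train_baseline_classifier",
    "baseline_change_predictions",
]


@dataclass(frozen=True)
class Dichotomy:
    """A two-way partition of the ordinal grade scale."""

    low_set: frozenset
    high_set: frozenset

    def __post_init__(self):
        if self.low_set & self.high_set:
            raise ValueError("low_set and high_set must be disjoint")
        grades = self.low_set | self.high_set
        if grades != set(range(len(grades))):
            raise ValueError("dichotomy must partition the full grade range 0..K-1")

    def side(self, grade: int) -> int:
        if grade in self.low_set:
            return 0
        if grade in self.high_set:
            return 1
        raise ValueError(f"grade {grade} outside dichotomy")


def rop_dichotomy() -> Dichotomy:
    """Normal vs {pre-plus, plus}."""
    return Dichotomy(frozenset({0}), frozenset({1, 2}))


def knee_dichotomy() -> Dichotomy:
    """Normal-to-minimal (KL 0-1) vs mild-to-severe (KL 2-4)."""
    return Dichotomy(frozenset({0, 1}), frozenset({2, 3, 4}))


@dataclass(frozen=True)
class LongitudinalPair:
    """Two visits of one unit, earlier first."""

    unit_id: str
    record_t1: pd.Series
    record_t2: pd.Series

    @property
    def grade_change(self) -> int:
        return int(self.record_t2["grade"]) - int(self.record_t1["grade"])


def build_longitudinal_testset(manifest_split: pd.DataFrame, seed: int = 0) -> list[LongitudinalPair]:
    """One visit-pair per unit, preferring combinations whose grade changed."""
    if len(manifest_split) == 0:
        raise ValueError("empty split")
    rng = np.random.default_rng(seed)
    pairs: list[LongitudinalPair] = []
    for unit_id in sorted(manifest_split["unit_id"].unique()):
        rows = manifest_split[manifest_split["unit_id"] == unit_id].sort_values("timepoint")
        if len(rows) < 2:
            continue
        combos = list(combinations(range(len(rows)), 2))
        changed = [c for c in combos
                   if rows.iloc[c[0]]["grade"] != rows.iloc[c[1]]["grade"]]
        pick_from = changed if changed else combos
        i, j = pick_from[int(rng.integers(0, len(pick_from)))]
        pairs.append(LongitudinalPair(unit_id, rows.iloc[i], rows.iloc[j]))
    return pairs


def binary_change_label(pair: LongitudinalPair, dichotomy: Dichotomy) -> int:
    """1 iff the two visits fall on different sides of the dichotomy."""
    return int(dichotomy.side(int(pair.record_t1["grade"]))
               != dichotomy.side(int(pair.record_t2["grade"])))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (tie-averaged ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def roc_pr_curves(scores, labels) -> dict:
    """ROC (threshold sweep, trapezoid AUC = concordance probability with
    ties counting 1/2) and precision-recall (step interpolation) curves."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    return {
        "roc": {"fpr": fpr, "tpr": tpr, "thresholds": roc_thr},
        "roc_auc": float(roc_auc_score(labels, scores)),
        "pr": {"precision": precision, "recall": recall, "thresholds": pr_thr},
        "pr_auc": float(average_precision_score(labels, scores)),
    }


def youden_threshold(scores_val, labels_val) -> float:
    """Threshold maximizing J = sensitivity + specificity − 1 on validation.

    Candidates are midpoints between consecutive sorted unique scores; ties
    break toward the smallest threshold.  Prediction rule: positive iff
    score >= threshold."""
    scores = np.asarray(scores_val, dtype=float)
    labels = np.asarray(labels_val, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("validation set must contain both classes")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("all validation scores equal: no separating threshold exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_thr, best_j = None, -np.inf
    for thr in candidates:  # increasing order; strict > keeps the smallest tie
        pred = scores >= thr
        tpr = (pred & (labels == 1)).sum() / n_pos
        fpr = (pred & (labels == 0)).sum() / n_neg
        j = tpr - fpr
        if j > best_j:
            best_j, best_thr = j, float(thr)
    return best_thr


def bootstrap_ci(statistic, data, n_boot: int = 2000, seed: int = 0,
                 max_redraws: int = 100) -> tuple[float, float]:
    """Percentile 95% CI by case resampling.

    ``data`` is a tuple of equal-length arrays resampled jointly (or a single
    array).  Replicates on which ``statistic`` raises ValueError (e.g. a
    single-class resample) are redrawn, up to ``max_redraws`` extra attempts
    each."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arrays = data if isinstance(data, tuple) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    if n < 2 or any(len(a) != n for a in arrays):
        raise ValueError("data must be equal-length arrays with >= 2 cases")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            try:
                values.append(float(statistic(*(a[idx] for a in arrays))))
                break
            except ValueError:
                if attempt == max_redraws:
                    raise ValueError("statistic undefined on all bootstrap replicates")
    return (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))


def linear_weighted_kappa(pred, truth, n_classes: int | None = None) -> float:
    """Cohen's kappa with linear weights w_ij = |i−j|/(K−1).

    Computed as 1 − Σ w O / Σ w E where O is the observed confusion matrix
    and E the chance-expected one; reduces to unweighted kappa for binary
    labels."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if len(pred) == 0 or len(pred) != len(truth):
        raise ValueError("pred and truth must be equal-length and non-empty")
    k = n_classes or int(max(pred.max(), truth.max())) + 1
    if pred.min() < 0 or truth.min() < 0 or max(pred.max(), truth.max()) >= k:
        raise ValueError("labels outside [0, n_classes)")
    obs = np.zeros((k, k))
    np.add.at(obs, (truth, pred), 1)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / len(pred)
    w = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / max(k - 1, 1)
    denom = (w * exp).sum()
    if denom == 0:
        raise ValueError("kappa undefined: no expected disagreement")
    return float(1.0 - (w * obs).sum() / denom)


@dataclass
class EvalReport:
    """Change-detection evaluation summary for one metric."""

    metric: str
    spearman_rho: float | None
    roc_auc: float
    roc_auc_ci_95: tuple[float, float]
    pr_auc: float
    pr_auc_ci_95: tuple[float, float]
    threshold: float | None
    kappa: float | None
    kappa_ci_95: tuple[float, float] | None
    n_comparisons: int
    degenerate: bool = False
    curves: dict = field(default_factory=dict, repr=False)
    scores: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)
    signed_delta: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "spearman_rho": self.spearman_rho,
            "roc_auc": self.roc_auc,
            "roc_auc_ci_95": list(self.roc_auc_ci_95),
            "pr_auc": self.pr_auc,
            "pr_auc_ci_95": list(self.pr_auc_ci_95),
            "threshold": self.threshold,
            "kappa": self.kappa,
            "kappa_ci_95": list(self.kappa_ci_95) if self.kappa_ci_95 else None,
            "n_comparisons": self.n_comparisons,
            "degenerate": self.degenerate,
        }


def change_scores(model, pairs: list[LongitudinalPair], pool: AnchorPool | None,
                  metric: str, store: ImageStore) -> np.ndarray:
    """Continuous change score per pair.

    ``delta`` is the signed difference of anchor-pool severity scores (a pool
    is required); ``pairwise`` the direct embedding distance."""
    if metric not in ("delta", "pairwise"):
        raise ValueError("metric must be 'delta' or 'pairwise'")
    out = []
    for p in pairs:
        img1 = store.get(p.record_t1["image_path"])
        img2 = store.get(p.record_t2["image_path"])
        if metric == "delta":
            if pool is None:
                raise ValueError("metric='delta' requires an anchor pool")
            out.append(change_delta(img1, img2, pool, model, store))
        else:
            out.append(change_pairwise(img1, img2, model))
    return np.asarray(out, dtype=float)


def evaluate_change_detection(model, pairs: list[LongitudinalPair], pool: AnchorPool | None,
                              dichotomy: Dichotomy, metric: str,
                              val_pairs: list[LongitudinalPair], store: ImageStore,
                              n_boot: int = 2000, seed: int = 0) -> EvalReport:
    """Full binary change-detection evaluation with one continuous metric.

    For ``metric='delta'`` the ROC score is |delta| (binary change detection
    is directionless); the signed values are retained in the report.  The
    operating threshold comes from Youden's J on the validation pairs.
    """
    raw = change_scores(model, pairs, pool, metric, store)
    scores = np.abs(raw) if metric == "delta" else raw
    labels = np.array([binary_change_label(p, dichotomy) for p in pairs])
    grade_change = np.array([p.grade_change for p in pairs])

    try:
        if metric == "delta":
            rho = spearman_rho(raw, grade_change)
        else:
            rho = spearman_rho(raw, np.abs(grade_change))
    except ValueError:
        rho = None

    curves = roc_pr_curves(scores, labels)
    roc_ci = bootstrap_ci(lambda s, l: roc_pr_curves(s, l)["roc_auc"],
                          (scores, labels), n_boot=n_boot, seed=seed)
    pr_ci = bootstrap_ci(lambda s, l: roc_pr_curves(s, l)["pr_auc"],
                         (scores, labels), n_boot=n_boot, seed=seed + 1)

    val_raw = change_scores(model, val_pairs, pool, metric, store)
    val_scores = np.abs(val_raw) if metric == "delta" else val_raw
    val_labels = np.array([binary_change_label(p, dichotomy) for p in val_pairs])
    try:
        threshold = youden_threshold(val_scores, val_labels)
    except ValueError:
        return EvalReport(metric, rho, curves["roc_auc"], roc_ci, curves["pr_auc"], pr_ci,
                          None, None, None, len(pairs), degenerate=True, curves=curves,
                          scores=scores, labels=labels,
                          signed_delta=raw if metric == "delta" else None)

    pred = (scores >= threshold).astype(int)
    kappa = linear_weighted_kappa(pred, labels, n_classes=2)
    kappa_ci = bootstrap_ci(lambda p, l: linear_weighted_kappa(p, l, n_classes=2),
                            (pred, labels), n_boot=n_boot, seed=seed + 2)
    return EvalReport(metric, rho, curves["roc_auc"], roc_ci, curves["pr_auc"], pr_ci,
                      threshold, kappa, kappa_ci, len(pairs), curves=curves,
                      scores=scores, labels=labels,
                      signed_delta=raw if metric == "delta" else None)


def train_baseline_classifier(manifest: pd.DataFrame, model, config: TrainConfig,
                              store: ImageStore | None = None,
                              verbose: bool = False) -> TrainResult:
    """Train the conventional multi-class grade classifier baseline (same
    backbone and protocol, softmax cross-entropy)."""
    return train_classifier(manifest, model, config, store=store, verbose=verbose)


def baseline_change_predictions(model, pairs: list[LongitudinalPair],
                                dichotomy: Dichotomy, store: ImageStore) -> np.ndarray:
    """Binary change predicted iff the dichotomized argmax grades differ."""
    imgs1 = np.stack([store.get(p.record_t1["image_path"]) for p in pairs])
    imgs2 = np.stack([store.get(p.record_t2["image_path"]) for p in pairs])
    _, g1 = classify(model, imgs1)
    _, g2 = classify(model, imgs2)
    return np.array([int(dichotomy.side(int(a)) != dichotomy.side(int(b)))
                     for a, b in zip(g1, g2)])
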