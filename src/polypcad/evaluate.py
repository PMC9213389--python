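"""Evaluation protocol: histopathology class mapping, mask-based sizing,
ROC analysis with fixed-sensitivity thresholding, and per-category tables.

Conventions
-----------
* The positive class is "premalignant"; scores near 1 indicate premalignancy
  and the prediction rule is ``score >= threshold -> premalignant``.
* AUC is the Mann-Whitney two-sample statistic (ties counted half), which
  equals trapezoidal integration of the empirical ROC curve.
* Printed percentages are rounded half-up to whole percent, matching how
  fraction/percent pairs such as 63/79 -> 80% are conventionally reported.
* Polyp size strata (<=5 / 6-9 / >=10 mm) are assigned from the mask-derived
  maximum 3-D diameter rounded half-up to integer millimetres.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from scipy import ndimage

__all__ = [
    "map_histopathology_to_class", "max_3d_diameter", "size_stratum", "roc_auc",
    "select_threshold", "confusion_metrics", "category_accuracy", "summarize_cohort",
    "percent_half_up", "EvaluationReport", "evaluate_scores", "HISTOPATHOLOGY_CLASSES",
    "SIZE_STRATA", "plot_roc",
]

#: fixed mapping from histopathologic category to binary class
HISTOPATHOLOGY_CLASSES = {
    "regular mucosa": "benign",
    "hyperplastic polyp": "benign",
    "lipomatous polyp": "benign",
    "tubular adenoma": "premalignant",
    "tubulovillous adenoma": "premalignant",
    "villous adenoma": "premalignant",
    "serrated adenoma": "premalignant",
    "adenocarcinoma": "premalignant",
}

SIZE_STRATA = ("<=5", "6-9", ">=10")


def map_histopathology_to_class(category: str) -> str:
    """Map a histopathologic category to 'benign' or 'premalignant'.

    Matching is insensitive to case and surrounding/duplicated whitespace.
    Hyperplastic polyps, regular mucosa and lipomatous polyps are benign;
    all adenoma subtypes and adenocarcinoma are premalignant.
    """
    key = " ".join(str(category).lower().split())
    # tolerate the bare "lipomatous" phrasing used in pathology reports
    if key == "lipomatous":
        key = "lipomatous polyp"
    try:
        return HISTOPATHOLOGY_CLASSES[key]
    except KeyError:
        raise ValueError(
            f"unknown histopathologic category {category!r}; accepted: "
            f"{sorted(HISTOPATHOLOGY_CLASSES)}") from None


def max_3d_diameter(mask: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> float:
    """Maximum Euclidean distance (mm) between any two mask-voxel centres.

    Computed on the mask's boundary voxels, which leaves the all-pairs
    result unchanged (interior points never realize the maximum).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no diameter")
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary) * np.asarray(spacing_mm, float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 600:
        # the diametral pair lies on the convex hull
        from scipy.spatial import ConvexHull
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    return float(pdist(pts).max())


def size_stratum(diameter_mm: float) -> str:
    """Bin a diameter into <=5 / 6-9 / >=10 mm after half-up integer rounding."""
    if diameter_mm < 0:
        raise ValueError("diameter must be non-negative")
    r = math.floor(diameter_mm + 0.5)
    if r <= 5:
        return "<=5"
    if r <= 9:
        return "6-9"
    return ">=10"


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    if labels.min() < 0 or labels.max() > 1:
        raise ValueError("labels must be binary 0/1")
    if labels.all() or not labels.any():
        raise ValueError("AUC undefined: both classes must be present")
    return labels == 1, labels == 0


def roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC-AUC (probability a positive outscores a negative)."""
    scores = np.asarray(scores, float)
    pos, neg = _check_two_classes(labels)
    ranks = rankdata(scores)
    n1, n0 = pos.sum(), neg.sum()
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0
    return np.concatenate([[s[0] - 1.0], mids, [s[-1] + 1.0]])


def select_threshold(scores, labels, target_sensitivity: float = 0.80) -> float:
    """Operating threshold with maximal specificity at a sensitivity floor.

    Candidates are midpoints between adjacent distinct scores plus
    sentinels below/above all scores; among candidates whose sensitivity
    (score >= threshold -> premalignant) is at least ``target_sensitivity``,
    the one with the best specificity is returned, ties resolved toward the
    larger threshold. If only the classify-everything-positive sentinel
    attains the target, it is returned with a warning.
    """
    if not 0.0 < target_sensitivity <= 1.0:
        raise ValueError("target sensitivity must lie in (0, 1]")
    scores = np.asarray(scores, float)
    pos, neg = _check_two_classes(labels)
    best = None
    for t in _candidate_thresholds(scores):
        pred = scores >= t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & neg).sum() / neg.sum()
        if sens >= target_sensitivity and (
                best is None or spec > best[1] or (spec == best[1] and t > best[0])):
            best = (t, spec)
    if best is None:  # unreachable: the low sentinel always has sensitivity 1
        raise RuntimeError("no threshold attains the target sensitivity")
    if best[1] == 0.0:
        import warnings
        warnings.warn("target sensitivity only attainable by classifying "
                      "every case positive", stacklevel=2)
    return float(best[0])


def percent_half_up(numerator: int, denominator: int) -> int:
    """Whole percent, rounded half-up from the exact fraction."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def confusion_metrics(scores, labels, threshold: float) -> dict:
    """Sensitivity and specificity as (numerator, denominator, whole-percent)."""
    scores = np.asarray(scores, float)
    pos, neg = _check_two_classes(labels)
    pred = scores >= threshold
    tp = int((pred & pos).sum())
    tn = int((~pred & neg).sum())
    p, n = int(pos.sum()), int(neg.sum())
    return {
        "sensitivity": (tp, p, percent_half_up(tp, p)),
        "specificity": (tn, n, percent_half_up(tn, n)),
    }


def category_accuracy(predicted_classes, categories) -> dict[str, tuple]:
    """Per-histopathologic-category accuracy as (correct, total, percent|None).

    A prediction is correct when it equals the category's mapped class.
    Categories absent from ``categories`` are reported as (0, 0, None).
    """
    predicted_classes = list(predicted_classes)
    categories = list(categories)
    if len(predicted_classes) != len(categories):
        raise ValueError("predictions and records differ in length")
    out: dict[str, tuple] = {}
    for cat in HISTOPATHOLOGY_CLASSES:
        out[cat] = (0, 0, None)
    for pred, cat in zip(predicted_classes, categories):
        key = " ".join(str(cat).lower().split())
        truth = map_histopathology_to_class(key)
        c, t, _ = out[key]
        c += int(pred == truth)
        t += 1
        out[key] = (c, t, None)
    for cat, (c, t, _) in out.items():
        out[cat] = (c, t, percent_half_up(c, t) if t else None)
    return out


def summarize_cohort(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-category segmentation counts with whole-percent column shares,
    plus benign/premalignant subtotals and the grand total."""
    cats = manifest["histopathologic_category"].map(
        lambda c: " ".join(str(c).lower().split()))
    total = len(manifest)
    rows = []
    subtotal = {"benign": 0, "premalignant": 0}
    for cat in HISTOPATHOLOGY_CLASSES:
        n = int((cats == cat).sum())
        subtotal[HISTOPATHOLOGY_CLASSES[cat]] += n
        rows.append({"histopathologic_category": cat,
                     "class": HISTOPATHOLOGY_CLASSES[cat],
                     "count": n, "percent": percent_half_up(n, total) if total else 0})
    for cls in ("benign", "premalignant"):
        rows.append({"histopathologic_category": f"all {cls}", "class": cls,
                     "count": subtotal[cls],
                     "percent": percent_half_up(subtotal[cls], total) if total else 0})
    rows.append({"histopathologic_category": "total", "class": "",
                 "count": total, "percent": 100 if total else 0})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Summary of one model's performance on an evaluation cohort."""

    auc: float
    threshold: float
    sensitivity: tuple[int, int, int]
    specificity: tuple[int, int, int]
    subgroup_aucs: dict[str, float | None] = field(default_factory=dict)
    category_accuracy: dict[str, tuple] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "threshold": self.threshold,
            "sensitivity": list(self.sensitivity),
            "specificity": list(self.specificity),
            "subgroup_aucs": self.subgroup_aucs,
            "category_accuracy": {k: list(v) for k, v in self.category_accuracy.items()},
        }


def evaluate_scores(scores, labels, categories=None, diameters_mm=None,
                    target_sensitivity: float = 0.80,
                    threshold: float | None = None) -> EvaluationReport:
    """Full ROC + fixed-sensitivity report for a score vector.

    ``threshold=None`` selects the operating point on these scores
    (the replication mode in which the operating point is fit on the
    evaluation sample itself); pass a threshold to apply a pre-fitted one.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    auc = roc_auc(scores, labels)
    if threshold is None:
        threshold = select_threshold(scores, labels, target_sensitivity)
    conf = confusion_metrics(scores, labels, threshold)
    report = EvaluationReport(auc=auc, threshold=float(threshold),
                              sensitivity=conf["sensitivity"],
                              specificity=conf["specificity"])
    if diameters_mm is not None:
        strata = np.array([size_stratum(d) for d in np.asarray(diameters_mm, float)])
        for s in SIZE_STRATA:
            sel = strata == s
            sub = labels[sel]
            if sel.sum() and 0 < sub.sum() < sel.sum():
                report.subgroup_aucs[s] = roc_auc(scores[sel], sub)
            else:
                report.subgroup_aucs[s] = None
    if categories is not None:
        pred = np.where(scores >= threshold, "premalignant", "benign")
        report.category_accuracy = category_accuracy(pred, categories)
    return report


def plot_roc(scores_by_model: dict[str, tuple], path) -> None:
    """Render ROC curves (one per model) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (scores, labels) in scores_by_model.items():
        fpr, tpr, _ = roc_curve(labels, scores)
        ax.plot(fpr, tpr, label=f"{name} (AUC = {roc_auc(scores, labels):.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
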