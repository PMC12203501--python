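"""Per-class and macro classification metrics plus a clustering score.

Each localization class is scored as an independent binary problem:
Matthews correlation coefficient (MCC), F1, Jaccard similarity and
average precision (AP, step-interpolated precision-recall area on the
probability ranking).  Macro values are unweighted means across classes;
classes without any positive ground truth in the evaluated set carry no
signal for these metrics and are excluded from the macro average (their
per-class rows are still reported with counts).  Degenerate MCC
denominators map to 0 by convention.

Evaluation can run at the cell level or at the source-image level, where
per-cell probabilities are averaged per image before thresholding.  The
clustering score is the Calinski-Harabasz ratio of between-cluster
dispersion to within-cluster compactness, computed on feature vectors of
cells from single-location proteins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    calinski_harabasz_score,
    f1_score,
    jaccard_score,
    matthews_corrcoef,
)

__all__ = ["MetricsReport", "binary_metrics", "evaluate", "clustering_score"]


@dataclass
class MetricsReport:
    class_names: list[str]
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    counts: dict[str, int]  # positive ground-truth rows per class
    level: str = "cell"
    excluded_classes: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "level": self.level,
            "per_class": self.per_class,
            "macro": self.macro,
            "counts": self.counts,
            "excluded_classes": self.excluded_classes,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_frame(self):
        import pandas as pd

        rows = [
            {"class": c, "n_positive": self.counts[c], **m}
            for c, m in self.per_class.items()
        ]
        return pd.DataFrame(rows)


def binary_metrics(y_true, y_prob, threshold: float = 0.5
                   ) -> tuple[float, float, float, float]:
    """(MCC, F1, Jaccard, AP) for one binary problem."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true.shape != y_prob.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_prob.shape}"
        )
    y_call = (y_prob >= threshold).astype(np.int64)
    with warnings.catch_warnings():
        # degenerate single-class cases are handled by the 0 convention
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(y_true, y_call)) if y_true.size else 0.0
        f1 = float(f1_score(y_true, y_call, zero_division=0))
        js = float(jaccard_score(y_true, y_call, zero_division=0))
    ap = float(average_precision_score(y_true, y_prob)) if y_true.any() else 0.0
    return mcc, f1, js, ap


def evaluate(probabilities: np.ndarray, y_true: np.ndarray,
             class_names: list[str], *, level: str = "cell",
             image_ids: list[str] | None = None, threshold: float = 0.5
             ) -> MetricsReport:
    """Per-class and macro metrics at the cell or source-image level."""
    probs = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(y_true, dtype=np.int64)
    if probs.shape != y.shape or probs.shape[1] != len(class_names):
        raise ValueError("probabilities, y_true and class_names disagree")
    if level == "image":
        if image_ids is None:
            raise ValueError("image-level evaluation requires image_ids")
        groups: dict[str, list[int]] = {}
        for i, img in enumerate(image_ids):
            groups.setdefault(img, []).append(i)
        agg_p, agg_y = [], []
        for img in sorted(groups):
            idx = groups[img]
            agg_p.append(probs[idx].mean(axis=0))
            agg_y.append(y[idx].max(axis=0))
        probs, y = np.stack(agg_p), np.stack(agg_y)
    elif level != "cell":
        raise ValueError(f"unknown evaluation level {level!r}")

    per_class: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    excluded: list[str] = []
    macro_rows = []
    for j, name in enumerate(class_names):
        counts[name] = int(y[:, j].sum())
        mcc, f1, js, ap = binary_metrics(y[:, j], probs[:, j], threshold)
        per_class[name] = {"mcc": mcc, "f1": f1, "jaccard": js, "ap": ap}
        # a class with only positives or only negatives in the evaluated
        # set carries no discrimination signal (MCC undefined): keep its
        # row but leave it out of the macro average
        if 0 < counts[name] < len(y):
            macro_rows.append([mcc, f1, js, ap])
        else:
            excluded.append(name)
    if not macro_rows:
        raise ValueError("no class has both positive and negative ground truth")
    macro_arr = np.asarray(macro_rows).mean(axis=0)
    macro = {
        "mMCC": float(macro_arr[0]),
        "mF1": float(macro_arr[1]),
        "mJS": float(macro_arr[2]),
        "mAP": float(macro_arr[3]),
    }
    return MetricsReport(class_names=list(class_names), per_class=per_class,
                         macro=macro, counts=counts, level=level,
                         excluded_classes=excluded)


def clustering_score(features: np.ndarray, labels) -> float:
    """Calinski-Harabasz ratio [B/(k-1)] / [W/(n-k)] of feature clusters."""
    X = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("clustering score needs at least two classes")
    return float(calinski_harabasz_score(X, labels))
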