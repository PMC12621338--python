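"""Dataset splitting, confusion matrices, and classification metrics.

Implements the report arithmetic directly (precision, recall, harmonic
F1, macro and support-weighted averages, overall accuracy) so the
numbers are auditable against their definitions, and a stratified
70/11/19 split with largest-remainder rounding.  A recording-grouped
split mode keeps all windows from one recording in a single split to
avoid within-repetition leakage.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.11, 0.19)
    stratified: bool = True
    group_by_recording: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"split fractions must sum to 1, got {sum(self.fractions)}"
            )
        if any(f < 0 for f in self.fractions):
            raise ValueError("split fractions must be non-negative")


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer quotas summing to n; leftovers go to largest remainders,
    ties resolved in declaration order (train first)."""
    raw = [f * n for f in fractions]
    quotas = [int(np.floor(r)) for r in raw]
    leftover = n - sum(quotas)
    remainders = sorted(
        range(len(fractions)),
        key=lambda i: (-(raw[i] - quotas[i]), i),
    )
    for i in remainders[:leftover]:
        quotas[i] += 1
    return quotas


def split_dataset(
    labels: np.ndarray,
    spec: SplitSpec,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, validation, test) index arrays.

    Stratified per class with fraction-proportional largest-remainder
    counts.  With ``spec.group_by_recording`` (requires ``groups``),
    whole recordings are assigned so no recording spans two splits.
    """
    labels = np.asarray(labels)
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    classes = np.unique(labels)
    for c in classes:
        if (labels == c).sum() == 0:  # pragma: no cover - unique() excludes
            raise ValueError(f"class {c!r} has no windows")
    if labels.size == 0:
        raise ValueError("no windows to split")
    train, val, test = [], [], []
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        if spec.group_by_recording:
            if groups is None:
                raise ValueError("group_by_recording requires groups")
            _split_grouped(idx, np.asarray(groups)[idx], spec, rng,
                           train, val, test)
        else:
            idx = rng.permutation(idx)
            n_train, n_val, n_test = _largest_remainder(len(idx), spec.fractions)
            train.extend(idx[:n_train])
            val.extend(idx[n_train:n_train + n_val])
            test.extend(idx[n_train + n_val:])
    return (np.sort(np.array(train, dtype=np.int64)),
            np.sort(np.array(val, dtype=np.int64)),
            np.sort(np.array(test, dtype=np.int64)))


def _split_grouped(idx, grp, spec, rng, train, val, test) -> None:
    """Assign whole recordings of one class, filling test, then val."""
    unique_groups = rng.permutation(np.unique(grp))
    n = len(idx)
    _, n_val, n_test = _largest_remainder(n, spec.fractions)
    by_group = {g: idx[grp == g] for g in unique_groups}
    got_test, got_val = 0, 0
    for gi, g in enumerate(unique_groups):
        members = by_group[g]
        remaining_groups = len(unique_groups) - gi
        if got_test < n_test and remaining_groups > 2:
            test.extend(members)
            got_test += len(members)
        elif got_val < n_val and remaining_groups > 1:
            val.extend(members)
            got_val += len(members)
        else:
            train.extend(members)


# ---------------------------------------------------------------------------
# Metrics


def confusion(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """Confusion matrix: entry (i, j) counts true class i predicted j."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels out of range [0, {n_classes})")
    matrix = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(matrix, (t, p), 1)
    return matrix


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean; 0 when both inputs are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ClassMetrics:
    label: str
    precision: float
    recall: float
    f1: float
    support: int
    degenerate: bool = False  # a zero-denominator was coerced to 0


@dataclass
class EvalReport:
    label_names: tuple[str, ...]
    matrix: np.ndarray
    per_class: list[ClassMetrics]
    accuracy: float
    macro: dict = field(default_factory=dict)
    weighted: dict = field(default_factory=dict)
    total: int = 0

    def to_dict(self) -> dict:
        return {
            "label_names": list(self.label_names),
            "confusion_matrix": self.matrix.tolist(),
            "per_class": [
                {"label": m.label, "precision": m.precision, "recall": m.recall,
                 "f1": m.f1, "support": m.support, "degenerate": m.degenerate}
                for m in self.per_class
            ],
            "accuracy": self.accuracy,
            "macro": self.macro,
            "weighted": self.weighted,
            "total": self.total,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "EvalReport":
        return cls(
            label_names=tuple(payload["label_names"]),
            matrix=np.asarray(payload["confusion_matrix"], dtype=np.int64),
            per_class=[ClassMetrics(**m) for m in payload["per_class"]],
            accuracy=payload["accuracy"],
            macro=payload["macro"],
            weighted=payload["weighted"],
            total=payload["total"],
        )


def class_metrics(matrix: np.ndarray,
                  label_names: tuple[str, ...] | None = None) -> EvalReport:
    """Per-class precision/recall/F1/support plus the summary rows.

    ``precision_c = M[c, c] / column_sum_c`` and ``recall_c =
    M[c, c] / row_sum_c``; zero denominators yield 0 with the
    ``degenerate`` flag set.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (matrix < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    k = matrix.shape[0]
    if label_names is None:
        label_names = tuple(f"class_{i}" for i in range(k))
    row_sums = matrix.sum(axis=1)
    col_sums = matrix.sum(axis=0)
    total = int(matrix.sum())
    per_class = []
    for c in range(k):
        tp = float(matrix[c, c])
        degenerate = False
        if col_sums[c] == 0:
            precision, degenerate = 0.0, True
        else:
            precision = tp / col_sums[c]
        if row_sums[c] == 0:
            recall, degenerate = 0.0, True
        else:
            recall = tp / row_sums[c]
        per_class.append(ClassMetrics(
            label=label_names[c], precision=precision, recall=recall,
            f1=f1_score(precision, recall), support=int(row_sums[c]),
            degenerate=degenerate,
        ))
    accuracy = float(np.trace(matrix)) / total if total else 0.0
    macro = {
        "precision": float(np.mean([m.precision for m in per_class])),
        "recall": float(np.mean([m.recall for m in per_class])),
        "f1": float(np.mean([m.f1 for m in per_class])),
    }
    supports = np.array([m.support for m in per_class], dtype=np.float64)
    if supports.sum() > 0:
        w = supports / supports.sum()
    else:
        w = np.zeros_like(supports)
    weighted = {
        "precision": float(np.dot(w, [m.precision for m in per_class])),
        "recall": float(np.dot(w, [m.recall for m in per_class])),
        "f1": float(np.dot(w, [m.f1 for m in per_class])),
    }
    return EvalReport(
        label_names=tuple(label_names), matrix=matrix.astype(np.int64),
        per_class=per_class, accuracy=accuracy, macro=macro,
        weighted=weighted, total=total,
    )


def write_report(report: EvalReport, path: str | Path) -> tuple[Path, Path]:
    """Write the JSON report and the results-table CSV.

    The CSV mirrors the published layout: one row per class, then an
    overall-accuracy row and a weighted-average row, values rounded to
    two decimals.  The JSON carries full precision and the matrix.
    """
    path = Path(path)
    json_path = path.with_suffix(".json")
    csv_path = path.with_suffix(".csv")
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Activity", "Precision", "Recall", "F1 Score", "Support"])
        for m in report.per_class:
            writer.writerow([m.label, f"{m.precision:.2f}", f"{m.recall:.2f}",
                             f"{m.f1:.2f}", m.support])
        writer.writerow(["Accuracy (overall)", "", "",
                         f"{report.accuracy:.2f}", report.total])
        writer.writerow(["Weighted average",
                         f"{report.weighted['precision']:.2f}",
                         f"{report.weighted['recall']:.2f}",
                         f"{report.weighted['f1']:.2f}", report.total])
    return json_path, csv_path


def evaluate_predictions(true_labels, predicted_labels,
                         label_names: tuple[str, ...]) -> EvalReport:
    """Confusion + metrics in one call."""
    matrix = confusion(true_labels, predicted_labels, len(label_names))
    return class_metrics(matrix, label_names)
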