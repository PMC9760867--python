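"""Confusion matrix and per-class / macro-averaged classification metrics.

Metrics follow the standard one-vs-rest reduction per class c:
``TP = cm[c, c]``, ``FN = row_c - TP``, ``FP = col_c - TP``,
``TN = total - TP - FN - FP``, and

* Acc  = (TP + TN) / total
* Sen  = TP / (TP + FN)        (sensitivity / recall)
* Spe  = TN / (TN + FP)        (specificity)
* PPV  = TP / (TP + FP)        (positive predictive value / precision)
* F1   = 2 * PPV * Sen / (PPV + Sen)

reported as percentages.  A ratio with a zero denominator is reported as 0
and flagged.  Macro averages are unweighted means over the five classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import CLASS_NAMES, N_CLASSES

METRIC_NAMES = ("Acc", "Spe", "Sen", "PPV", "F1")


def confusion(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Confusion-matrix counts; entry (i, j) = samples with true i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class ClassMetrics:
    """Per-class metric table in percent, plus undefined-ratio flags."""

    per_class: dict[str, np.ndarray]           # metric name -> 5 values (%)
    undefined: dict[str, np.ndarray] = field(default_factory=dict)

    def macro(self, metric: str) -> float:
        return float(np.mean(self.per_class[metric]))

    @property
    def macro_averages(self) -> dict[str, float]:
        return {m: self.macro(m) for m in METRIC_NAMES}

    def to_frame(self) -> pd.DataFrame:
        """One row per class plus an average row, percentages rounded to
        2 decimals."""
        rows = []
        for i, cls in enumerate(CLASS_NAMES):
            rows.append({"class": cls,
                         **{m: round(self.per_class[m][i], 2)
                            for m in METRIC_NAMES}})
        rows.append({"class": "Average",
                     **{m: round(self.macro(m), 2) for m in METRIC_NAMES}})
        return pd.DataFrame(rows)


def per_class_metrics(cm: np.ndarray) -> ClassMetrics:
    """One-vs-rest Acc/Spe/Sen/PPV/F1 per class, in percent."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total < 1:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def ratio(num, den):
        und = den == 0
        out = np.zeros_like(num, dtype=float)
        np.divide(num, den, out=out, where=~und)
        return out, und

    acc = (tp + tn) / total
    sen, sen_und = ratio(tp, tp + fn)
    spe, spe_und = ratio(tn, tn + fp)
    ppv, ppv_und = ratio(tp, tp + fp)
    f1_den = ppv + sen
    f1, f1_und = ratio(2 * ppv * sen, f1_den)
    return ClassMetrics(
        per_class={"Acc": 100 * acc, "Spe": 100 * spe, "Sen": 100 * sen,
                   "PPV": 100 * ppv, "F1": 100 * f1},
        undefined={"Sen": sen_und, "Spe": spe_und, "PPV": ppv_und,
                   "F1": f1_und},
    )


def macro_average(values) -> float:
    """Unweighted mean over per-class values (the bold-row convention)."""
    values = np.asarray(values, dtype=float)
    if values.size != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES} per-class values")
    return float(values.mean())


def write_report(metrics: ClassMetrics, cm: np.ndarray, out_dir) -> tuple[Path, Path]:
    """Write the metrics table and confusion matrix as CSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics_path = out_dir / "metrics.csv"
    metrics.to_frame().to_csv(metrics_path, index=False)
    cm_path = out_dir / "confusion_matrix.csv"
    pd.DataFrame(cm, index=list(CLASS_NAMES),
                 columns=list(CLASS_NAMES)).to_csv(cm_path)
    return metrics_path, cm_path
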