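"""Class-wise and overall classification metrics from a confusion matrix.

All metrics derive from the K x K pooled confusion matrix (rows true,
columns predicted) and are expressed in percent.  Overall metrics:

- accuracy          trace / N
- UAR               unweighted (macro) average of class-wise recalls
- UAP               unweighted average of class-wise precisions
- macro F1          unweighted average of class-wise F1 scores
- Cohen's kappa     (p_o - p_e) / (1 - p_e), p_e from row/column marginals
- multiclass MCC    unweighted average over classes of the one-vs-rest
                    binary Matthews correlation coefficients (the
                    macro-averaged MCC; at K = 2 both one-vs-rest values
                    coincide with the classical binary MCC)
- GM                geometric mean of the class-wise recalls

Gorodkin's R_K generalisation of the MCC is also computed and exposed as
``mcc_rk`` for cross-study comparison; the headline ``mcc`` is the
macro-averaged definition.

Values are kept at full precision internally; percentages are rounded
half-up to two decimals only when formatted for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
import json
import math

import numpy as np

from .crossval import ConfusionMatrix
from .errors import ValidationError

__all__ = ["MetricReport", "classwise_metrics", "overall_metrics", "round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as results tables conventionally do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricReport:
    """Every metric the evaluation layer reports, in percent."""

    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    accuracy: float
    uar: float
    uap: float
    macro_f1: float
    mcc: float
    mcc_rk: float
    kappa: float
    gm: float
    labels: tuple[str, ...]

    def to_dict(self, ndigits: int | None = None) -> dict:
        def r(x):
            return round_half_up(float(x), ndigits) if ndigits is not None else float(x)

        return {
            "per_class": {
                lab: {
                    "recall": r(self.recall[i]),
                    "precision": r(self.precision[i]),
                    "f1": r(self.f1[i]),
                }
                for i, lab in enumerate(self.labels)
            },
            "overall": {
                "accuracy": r(self.accuracy),
                "uar": r(self.uar),
                "uap": r(self.uap),
                "macro_f1": r(self.macro_f1),
                "mcc": r(self.mcc),
                "mcc_rk": r(self.mcc_rk),
                "kappa": r(self.kappa),
                "gm": r(self.gm),
            },
        }

    def to_json(self, path, ndigits: int | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(ndigits), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def format_table(self) -> str:
        """Human-readable table: class rows then the overall metric row."""
        lines = []
        width = max(len(l) for l in self.labels) + 2
        head = f"{'class':<{width}}{'recall':>9}{'precision':>11}{'F1':>9}"
        lines.append(head)
        lines.append("-" * len(head))
        for i, lab in enumerate(self.labels):
            lines.append(
                f"{lab:<{width}}{round_half_up(self.recall[i]):>9.2f}"
                f"{round_half_up(self.precision[i]):>11.2f}"
                f"{round_half_up(self.f1[i]):>9.2f}"
            )
        lines.append("")
        lines.append(
            "overall  acc {:.2f}  UAR {:.2f}  UAP {:.2f}  F1 {:.2f}  "
            "MCC {:.2f}  kappa {:.2f}  GM {:.2f}".format(
                *[
                    round_half_up(v)
                    for v in (
                        self.accuracy, self.uar, self.uap, self.macro_f1,
                        self.mcc, self.kappa, self.gm,
                    )
                ]
            )
        )
        return "\n".join(lines)


def classwise_metrics(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (recall, precision, F1) in percent.

    recall_k = cm[k,k]/rowsum_k, precision_k = cm[k,k]/colsum_k; an empty
    predicted column gives precision 0 by convention; an empty true row is
    an error.
    """
    counts = cm.counts.astype(np.float64)
    rowsum = counts.sum(axis=1)
    colsum = counts.sum(axis=0)
    if (rowsum == 0).any():
        k = int(np.flatnonzero(rowsum == 0)[0])
        raise ValidationError(f"class {cm.labels[k]!r} has no true samples")
    diag = np.diag(counts)
    recall = diag / rowsum
    precision = np.where(colsum > 0, diag / np.where(colsum == 0, 1, colsum), 0.0)
    pr = precision + recall
    f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr == 0, 1, pr), 0.0)
    return recall * 100, precision * 100, f1 * 100


def overall_metrics(cm: ConfusionMatrix) -> MetricReport:
    """All reported metrics of a confusion matrix, in percent."""
    counts = cm.counts.astype(np.float64)
    n = counts.sum()
    if cm.n_classes < 2:
        raise ValidationError("overall metrics undefined for a single class")
    recall, precision, f1 = classwise_metrics(cm)

    rowsum = counts.sum(axis=1)  # t_k: true marginals
    colsum = counts.sum(axis=0)  # p_k: predicted marginals
    c = np.trace(counts)

    accuracy = c / n
    p_o = accuracy
    p_e = float(rowsum @ colsum) / n**2
    if p_e >= 1.0:
        raise ValidationError("kappa undefined: chance agreement is 1")
    kappa = (p_o - p_e) / (1 - p_e)

    denom = (n**2 - float(colsum @ colsum)) * (n**2 - float(rowsum @ rowsum))
    if denom <= 0:
        raise ValidationError("MCC undefined: degenerate marginals")
    mcc_rk = (c * n - float(colsum @ rowsum)) / math.sqrt(denom)

    # macro-averaged one-vs-rest binary MCC (the headline definition)
    ovr = []
    for k in range(cm.n_classes):
        tp = counts[k, k]
        fn = rowsum[k] - tp
        fp = colsum[k] - tp
        tn = n - tp - fn - fp
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        ovr.append((tp * tn - fp * fn) / den if den > 0 else 0.0)
    mcc = float(np.mean(ovr))

    gm = float(np.exp(np.mean(np.log(np.maximum(recall / 100, 1e-300))))) * 100
    if (recall == 0).any():
        gm = 0.0

    return MetricReport(
        recall=recall,
        precision=precision,
        f1=f1,
        accuracy=accuracy * 100,
        uar=float(recall.mean()),
        uap=float(precision.mean()),
        macro_f1=float(f1.mean()),
        mcc=mcc * 100,
        mcc_rk=mcc_rk * 100,
        kappa=kappa * 100,
        gm=gm,
        labels=cm.labels,
    )
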