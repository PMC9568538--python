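"""Model/Results interface over the full shutter-blinds pipeline.

``ShutterBlindsModel`` holds the data and configuration (images or a
precomputed feature matrix, the backbone, the selection range, the CV
layout); ``fit()`` runs normalization -> NCA ranking -> iterative prefix
selection -> fine-kNN cross-validation and returns a
``ShutterBlindsResults`` carrying the loss curve, the selected features,
the pooled confusion matrix, every reported metric and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .backbone import Backbone, FeatureMatrix, extract_dataset, toy_backbone
from .blinds import resize_face
from .crossval import ConfusionMatrix, CVSpec, cross_validate
from .errors import ValidationError
from .facs import PAIN_CLASS_LABELS
from .metrics import MetricReport, overall_metrics
from .selection import (
    NCARanking,
    SelectionResult,
    inca_select,
    inca_select_no_leakage,
    minmax_normalize,
    nca_rank,
)

__all__ = ["ShutterBlindsModel", "ShutterBlindsResults"]


@dataclass
class ShutterBlindsResults:
    """Fitted-pipeline results: selection, confusion matrix, metrics."""

    model: "ShutterBlindsModel"
    ranking: NCARanking | None
    selection: SelectionResult
    confusion: ConfusionMatrix
    fold_accuracies: np.ndarray
    report: MetricReport

    @property
    def accuracy(self) -> float:
        """Pooled CV accuracy in percent."""
        return self.report.accuracy

    @property
    def n_selected(self) -> int:
        return int(self.selection.best_length)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Shutter-blinds pain-intensity classification",
            "=" * 44,
            f"samples: {len(m.y)}    features: {m.X.shape[1]}    "
            f"classes: {len(set(m.y.tolist()))}",
            f"selection: mode={self.selection.mode}, "
            f"range [{self.selection.lengths[0]}, {self.selection.lengths[-1]}], "
            f"best length {self.n_selected} "
            f"(loss {self.selection.best_loss:.4f})",
            f"classifier: kNN k={m.k}, metric={m.metric}, "
            f"{m.cv.n_folds}-fold CV (seed {m.cv.seed})",
            "",
            "confusion matrix (rows true, cols predicted):",
            self.confusion.to_frame().to_string(),
            "",
            self.report.format_table(),
        ]
        return "\n".join(lines)

    def report_json(self, ndigits: int | None = None) -> str:
        """Canonical serialised metric report (stable byte-for-byte)."""
        payload = {
            "confusion": self.confusion.counts.tolist(),
            "labels": list(self.confusion.labels),
            "best_length": self.n_selected,
            "metrics": self.report.to_dict(ndigits),
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "seed": int(self.model.cv.seed),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class ShutterBlindsModel:
    """The pipeline as a fittable model over a labeled feature matrix.

    Build directly from features, or from images via :meth:`from_images`
    (which runs the blinds decomposition and backbone extraction).
    """

    X: np.ndarray
    y: np.ndarray
    lo: int = 100
    hi: int = 1000
    step: int = 1
    cv: CVSpec = field(default_factory=CVSpec)
    k: int = 1
    metric: str = "manhattan"
    mode: str = "faithful"
    nca_params: dict = field(default_factory=dict)
    labels: tuple[str, ...] = PAIN_CLASS_LABELS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValidationError("X must be 2-D with one label per row")
        if self.mode not in ("faithful", "no_leakage"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        counts = np.bincount(self.y)
        if (counts < 2).any():
            raise ValidationError("every class must appear at least twice")

    @classmethod
    def from_feature_matrix(cls, fm: FeatureMatrix, **kw) -> "ShutterBlindsModel":
        return cls(fm.X, fm.y, **kw)

    @classmethod
    def from_images(
        cls, images, labels, backbone: Backbone | None = None, **kw
    ) -> "ShutterBlindsModel":
        """Resize faces to 224, decompose into blinds, extract features."""
        bb = backbone if backbone is not None else toy_backbone(seed=0)
        faces = [resize_face(img) for img in images]
        fm = extract_dataset(faces, labels, bb)
        return cls(fm.X, fm.y, **kw)

    def fit(self) -> ShutterBlindsResults:
        """Run normalization, ranking, prefix selection and CV evaluation."""
        if self.mode == "faithful":
            Xn, _, _ = minmax_normalize(self.X)
            ranking = nca_rank(Xn, self.y, **self.nca_params)
            selection = inca_select(
                Xn, self.y, ranking, lo=self.lo, hi=self.hi,
                cv=self.cv, step=self.step, k=self.k, metric=self.metric,
            )
            X_sel = Xn[:, selection.selected]
        else:
            ranking = None
            selection = inca_select_no_leakage(
                self.X, self.y, lo=self.lo, hi=self.hi, cv=self.cv,
                step=self.step, k=self.k, metric=self.metric,
                nca_params=self.nca_params,
            )
            Xn, _, _ = minmax_normalize(self.X)
            X_sel = Xn[:, selection.selected]
        present = sorted(set(self.y.tolist()))
        labels = tuple(self.labels[i] for i in present) if max(present) < len(
            self.labels
        ) else tuple(f"C{i}" for i in present)
        cm, fold_acc = cross_validate(
            X_sel, self.y, self.cv, k=self.k, metric=self.metric, labels=labels
        )
        report = overall_metrics(cm)
        return ShutterBlindsResults(self, ranking, selection, cm, fold_acc, report)
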