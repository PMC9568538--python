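"""FACS action units -> PSPI pain scores -> four ordinal pain classes.

The Prkachin-Solomon Pain Intensity (PSPI) score summarises the six
pain-related facial action units (AUs) of the Facial Action Coding System:

    PSPI = AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43

AU4 (brow lowering), AU6 (cheek raising), AU7 (eyelid tightening), AU9
(nose wrinkling) and AU10 (upper-lip raising) are coded on a 0-5 intensity
scale; AU43 (eye closure) is binary.  The score therefore ranges from 0
("no pain") to 16 ("strong pain").  Frames are grouped into four ordinal
classes of increasing pain: PSPI = 0, PSPI = 1, 2 <= PSPI <= 3 and
PSPI > 3, and heavily over-represented classes are balanced by seeded
random under-sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "AUIntensities",
    "LabeledDataset",
    "PAIN_CLASS_LABELS",
    "pspi_score",
    "pspi_group",
    "balance_undersample",
    "read_au_table",
    "label_au_table",
    "class_frequency_table",
]

#: Canonical labels for the four ordinal pain classes, index 0-3.
PAIN_CLASS_LABELS: tuple[str, ...] = ("PSPI=0", "PSPI=1", "2<=PSPI<=3", "PSPI>3")

#: Required columns of an AU intensity table.
AU_COLUMNS: tuple[str, ...] = ("au4", "au6", "au7", "au9", "au10", "au43")

_AU_MAX = {"au4": 5, "au6": 5, "au7": 5, "au9": 5, "au10": 5, "au43": 1}


@dataclass(frozen=True)
class AUIntensities:
    """Per-frame intensities of the six pain-related action units.

    All fields are coded 0-5 except ``au43`` (eye closure), which is binary.
    """

    au4: int
    au6: int
    au7: int
    au9: int
    au10: int
    au43: int

    def __post_init__(self) -> None:
        for name, hi in _AU_MAX.items():
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if not 0 <= v <= hi:
                raise ValidationError(f"{name}={v} outside valid range [0, {hi}]")


def pspi_score(au: AUIntensities) -> int:
    """PSPI score of one frame: ``au4 + max(au6, au7) + max(au9, au10) + au43``.

    Returns an integer in [0, 16]; monotone non-decreasing in every AU.
    """
    return au.au4 + max(au.au6, au.au7) + max(au.au9, au.au10) + au.au43


def pspi_group(score: int) -> int:
    """Map a PSPI score to its ordinal pain-class index 0-3.

    0 -> class 0, 1 -> class 1, {2, 3} -> class 2, >= 4 -> class 3.
    """
    if not isinstance(score, (int, np.integer)) or isinstance(score, bool):
        raise ValidationError(f"PSPI score must be an integer, got {score!r}")
    if not 0 <= score <= 16:
        raise ValidationError(f"PSPI score {score} outside valid range [0, 16]")
    if score == 0:
        return 0
    if score == 1:
        return 1
    if score <= 3:
        return 2
    return 3


@dataclass
class LabeledDataset:
    """Frame identifiers with their pain-class indices."""

    ids: np.ndarray
    classes: np.ndarray
    n_classes: int = len(PAIN_CLASS_LABELS)
    class_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.classes = np.asarray(self.classes, dtype=int)
        if self.ids.shape != self.classes.shape:
            raise ValidationError("ids and classes must have equal length")
        if self.classes.size and (
            self.classes.min() < 0 or self.classes.max() >= self.n_classes
        ):
            raise ValidationError("class index outside [0, n_classes)")
        self.class_counts = np.bincount(self.classes, minlength=self.n_classes)

    def __len__(self) -> int:
        return len(self.ids)


def balance_undersample(
    dataset: LabeledDataset, target_counts, seed: int
) -> LabeledDataset:
    """Randomly under-sample over-represented classes to ``target_counts``.

    Within each class whose count exceeds its target, frames are drawn
    uniformly at random without replacement; classes at or below target are
    kept whole.  Deterministic given ``seed``.  Original frame order is
    preserved in the returned subset.
    """
    targets = np.asarray(target_counts, dtype=int)
    if targets.shape != (dataset.n_classes,):
        raise ValidationError(
            f"target_counts must have {dataset.n_classes} entries, got {targets.shape}"
        )
    for k, (t, avail) in enumerate(zip(targets, dataset.class_counts)):
        if t > avail:
            raise ValidationError(
                f"class {PAIN_CLASS_LABELS[k]!r}: target {t} exceeds available {avail}"
            )
        if t < 0:
            raise ValidationError(f"class {PAIN_CLASS_LABELS[k]!r}: negative target {t}")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(dataset), dtype=bool)
    for k in range(dataset.n_classes):
        members = np.flatnonzero(dataset.classes == k)
        if len(members) <= targets[k]:
            keep[members] = True
        else:
            keep[rng.choice(members, size=targets[k], replace=False)] = True
    return LabeledDataset(dataset.ids[keep], dataset.classes[keep])


def read_au_table(path) -> pd.DataFrame:
    """Read an AU intensity CSV with columns id,au4,au6,au7,au9,au10,au43.

    Missing AU columns are an error (never imputed); every intensity is
    validated against its range.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("id", *AU_COLUMNS) if c not in df.columns]
    if missing:
        raise ValidationError(f"AU table missing required column(s): {missing}")
    for col in AU_COLUMNS:
        vals = df[col]
        if vals.isna().any():
            raise ValidationError(f"AU table column {col!r} contains missing values")
        bad = (vals < 0) | (vals > _AU_MAX[col])
        if bad.any():
            raise ValidationError(
                f"AU table column {col!r} has out-of-range value "
                f"{vals[bad].iloc[0]} (row {bad.idxmax()})"
            )
    return df


def label_au_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score and group every frame of an AU table.

    Returns a frame with columns id, pspi, class_index, class_label.
    """
    au6_7 = np.maximum(df["au6"], df["au7"])
    au9_10 = np.maximum(df["au9"], df["au10"])
    pspi = (df["au4"] + au6_7 + au9_10 + df["au43"]).astype(int)
    cls = np.select([pspi == 0, pspi == 1, pspi <= 3], [0, 1, 2], default=3)
    return pd.DataFrame(
        {
            "id": df["id"],
            "pspi": pspi,
            "class_index": cls,
            "class_label": [PAIN_CLASS_LABELS[c] for c in cls],
        }
    )


def class_frequency_table(dataset: LabeledDataset) -> pd.DataFrame:
    """Per-class frequency report (rows mirror the four PSPI groups)."""
    return pd.DataFrame(
        {
            "class_index": np.arange(dataset.n_classes),
            "class_label": list(PAIN_CLASS_LABELS),
            "count": dataset.class_counts,
        }
    )
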