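"""Pluggable image->vector feature extractors and the 22-block concatenation.

The pipeline treats the deep network as a frozen, pluggable contract: any
callable mapping a square RGB image to a fixed-length feature vector.  In
the reference configuration the extractor is an ImageNet-pretrained
DarkNet19 read at its global-average-pool layer (feature_dim = 1000); that
adapter is optional and out of the library core.  For fully offline,
deterministic operation the library ships a "toy" backbone: a seeded random
linear projection of grid-pooled image statistics followed by a squashing
nonlinearity.  It is a genuine (if shallow) feature extractor, not an
approximation of DarkNet19.

Each face yields 22 inputs — the 21 shutter-blind strips plus the whole
face — and their per-input vectors are concatenated, strips first in
canonical order, whole face last: 22 x feature_dim values (22,000 at
feature_dim 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .blinds import PatchSet, make_blinds, resize_face
from .errors import ContractViolationError, ValidationError

__all__ = [
    "Backbone",
    "ConcatFeatureVector",
    "FeatureMatrix",
    "toy_backbone",
    "extract_patch_features",
    "extract_all",
    "extract_dataset",
    "save_features_csv",
    "load_features_csv",
]

N_BLOCKS = 22  # 21 strips + whole face


@dataclass(frozen=True)
class Backbone:
    """A frozen feature extractor: square RGB image -> length-feature_dim vector.

    ``extract`` receives a float64 array of shape (input_side, input_side, 3)
    scaled to [0, 1] and must be deterministic.
    """

    name: str
    input_side: int
    feature_dim: int
    extract: Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ConcatFeatureVector:
    """Concatenated per-block features with the block -> index-range map."""

    values: np.ndarray
    block_map: tuple[tuple[str, int, int], ...]  # (block name, start, stop)

    def block(self, name: str) -> np.ndarray:
        for bname, start, stop in self.block_map:
            if bname == name:
                return self.values[start:stop]
        raise KeyError(name)


@dataclass
class FeatureMatrix:
    """N x D feature matrix with per-row class labels and identifiers."""

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValidationError("X must be 2-D with one label per row")
        if not np.isfinite(self.X).all():
            raise ValidationError("feature matrix contains non-finite values")
        if self.ids is None:
            self.ids = np.array([f"row{i}" for i in range(self.X.shape[0])])
        else:
            self.ids = np.asarray(self.ids)


def toy_backbone(seed: int, input_side: int = 64, feature_dim: int = 1000,
                 grid: int = 8) -> Backbone:
    """Deterministic stand-in backbone for offline pipelines and tests.

    Pools the image over a ``grid`` x ``grid`` cell grid, collecting the mean
    and variance of each cell per channel, then applies a fixed seeded random
    linear projection to ``feature_dim`` outputs and a tanh squashing
    nonlinearity.  Identical seeds give identical extractors.
    """
    if feature_dim < 1:
        raise ValidationError(f"feature_dim must be >= 1, got {feature_dim}")
    if input_side % grid != 0:
        raise ValidationError(f"grid {grid} must divide input_side {input_side}")
    n_stats = grid * grid * 3 * 2
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((feature_dim, n_stats)) / np.sqrt(n_stats)
    b = rng.standard_normal(feature_dim) * 0.1
    cell = input_side // grid

    def extract(img: np.ndarray) -> np.ndarray:
        # (grid, cell, grid, cell, 3) view -> per-cell channel mean/variance
        blocks = img.reshape(grid, cell, grid, cell, 3)
        means = blocks.mean(axis=(1, 3))
        varis = blocks.var(axis=(1, 3))
        stats = np.concatenate([means.ravel(), varis.ravel()])
        return np.tanh(W @ stats + b)

    return Backbone(
        name=f"toy(seed={seed},grid={grid})",
        input_side=input_side,
        feature_dim=feature_dim,
        extract=extract,
    )


def _prepare_input(patch: np.ndarray, side: int) -> np.ndarray:
    """Resize a patch to the backbone's native square input, scaled to [0, 1]."""
    return resize_face(patch, side=side).astype(np.float64) / 255.0


def extract_patch_features(patch: np.ndarray, bb: Backbone) -> np.ndarray:
    """Run one image patch through a backbone, enforcing the output contract."""
    vec = np.asarray(bb.extract(_prepare_input(patch, bb.input_side)), dtype=np.float64)
    if vec.shape != (bb.feature_dim,):
        raise ContractViolationError(
            f"backbone {bb.name!r} returned shape {vec.shape}, "
            f"expected ({bb.feature_dim},)"
        )
    return vec


def extract_all(face: np.ndarray, bb: Backbone) -> ConcatFeatureVector:
    """Extract and concatenate features from all 22 blocks of one face.

    The face must already be 224x224x3.  Blocks are the 21 strips in
    canonical order followed by the whole face; total length is
    22 x feature_dim.
    """
    patches: PatchSet = make_blinds(face)
    blocks: list[np.ndarray] = []
    block_map: list[tuple[str, int, int]] = []
    pos = 0
    for s in patches.strips:
        vec = extract_patch_features(s.pixels, bb)
        blocks.append(vec)
        block_map.append((f"strip_{s.scale}_{s.index}", pos, pos + bb.feature_dim))
        pos += bb.feature_dim
    vec = extract_patch_features(patches.whole, bb)
    blocks.append(vec)
    block_map.append(("whole", pos, pos + bb.feature_dim))
    return ConcatFeatureVector(np.concatenate(blocks), tuple(block_map))


def extract_dataset(faces, labels, bb: Backbone, ids=None) -> FeatureMatrix:
    """Extract concatenated features for a sequence of 224x224 faces."""
    rows = [extract_all(face, bb).values for face in faces]
    return FeatureMatrix(np.vstack(rows), labels, ids=ids)


def save_features_csv(fm: FeatureMatrix, path) -> None:
    """Persist a feature matrix as CSV (id, class_index, f0..fD-1).

    Floats are written with 17 significant digits so the CSV round-trips
    float64 values bit-exactly.
    """
    d = fm.X.shape[1]
    df = pd.DataFrame(fm.X, columns=[f"f{i}" for i in range(d)])
    df.insert(0, "class_index", fm.y)
    df.insert(0, "id", fm.ids)
    df.to_csv(path, index=False, float_format="%.17g")


def load_features_csv(path) -> FeatureMatrix:
    # round_trip parsing: the default fast parser can be 1 ulp off
    df = pd.read_csv(path, float_precision="round_trip")
    if "id" not in df.columns or "class_index" not in df.columns:
        raise ValidationError("feature CSV must contain id and class_index columns")
    feat_cols = [c for c in df.columns if c.startswith("f")]
    return FeatureMatrix(
        df[feat_cols].to_numpy(dtype=np.float64),
        df["class_index"].to_numpy(dtype=int),
        ids=df["id"].to_numpy(),
    )
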