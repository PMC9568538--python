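"""Seeded synthetic fixtures: AU tables and face-like images with band structure.

The real shoulder-pain and spontaneous-expression image archives are
access-restricted, so the pipeline is exercised on synthetic stand-ins:

- AU tables whose rows are drawn, per class, from the set of action-unit
  combinations that score into that pain class, giving exactly
  ``n_per_class`` frames per class by construction.
- Face-like images carrying their class signal in horizontal bands aligned
  with the finest (28-row) shutter-blind scale: class c brightens bands
  {c, c + 4} of the 8 band positions, by analogy with pain expressions
  localising in brow/eye/mouth regions.  A fixed zero-mean grating
  textures the bands and Gaussian pixel noise is added on top.

Images are emitted at 448 x 448 (default) so the 224-resize path is
exercised.  Everything is bit-reproducible given the spec's seed.  These
fixtures emulate spatial localisation of class evidence only — nothing
about real facial appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ValidationError
from .facs import AU_COLUMNS, pspi_group

__all__ = ["SynthSpec", "gen_au_table", "gen_face_images", "write_fixture_dir"]

N_BANDS = 8  # matches the finest shutter-blind scale
_CLASS_SCORES = {0: (0,), 1: (1,), 2: (2, 3), 3: tuple(range(4, 17))}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic generators."""

    n_per_class: int = 25
    image_side: int = 448
    band_contrast: float = 0.6
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if not 0.0 <= self.band_contrast <= 1.0:
            raise ValidationError("band_contrast must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.image_side % N_BANDS != 0 or self.image_side < 8:
            raise ValidationError(f"image_side must be a multiple of {N_BANDS}")


@lru_cache(maxsize=None)
def _decompositions(score: int) -> tuple[tuple[int, int, int, int], ...]:
    """All (au4, max67, max910, au43) splits of a PSPI score."""
    out = []
    for a in range(6):
        for b in range(6):
            for c in range(6):
                for e in range(2):
                    if a + b + c + e == score:
                        out.append((a, b, c, e))
    return tuple(out)


def _sample_pair(rng: np.random.Generator, target_max: int) -> tuple[int, int]:
    """Two intensities 0-5 whose max equals target_max."""
    other = int(rng.integers(0, target_max + 1))
    if rng.integers(0, 2):
        return target_max, other
    return other, target_max


def gen_au_table(spec: SynthSpec) -> pd.DataFrame:
    """AU intensity table scoring into exactly n_per_class frames per class.

    For each class a target PSPI score is drawn from the class's score set,
    decomposed at random into the four terms of the PSPI formula, and the
    two max-terms expanded into concrete AU pairs.  Rows are shuffled;
    deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cls in range(4):
        scores = _CLASS_SCORES[cls]
        for _ in range(spec.n_per_class):
            s = int(scores[rng.integers(0, len(scores))])
            decs = _decompositions(s)
            au4, m67, m910, au43 = decs[rng.integers(0, len(decs))]
            au6, au7 = _sample_pair(rng, m67)
            au9, au10 = _sample_pair(rng, m910)
            rows.append((au4, au6, au7, au9, au10, au43))
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order], columns=list(AU_COLUMNS))
    df.insert(0, "id", [f"frame{i:05d}" for i in range(len(df))])
    return df


def _class_bands(cls: int) -> tuple[int, int]:
    return cls, (cls + 4) % N_BANDS


def gen_face_images(spec: SynthSpec) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Synthetic face-like images with class-dependent bright bands.

    Returns (images, class_indices, ids); images are image_side^2 x 3
    uint8.  At noise_sd = 0 all images of a class are identical, and the
    mean intensity inside a marked band exceeds the outside mean by
    band_contrast * 255 / 2 (the textural grating is zero-mean).
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    band_h = side // N_BANDS
    base = 64.0
    lift = spec.band_contrast * 255.0 / 2.0
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    # zero-mean over each band: integer number of periods per band and row
    grating = 30.0 * spec.band_contrast * np.sin(2 * np.pi * cc * 8 / side)

    templates = []
    for cls in range(4):
        img = np.full((side, side), base)
        for b in _class_bands(cls):
            sl = slice(b * band_h, (b + 1) * band_h)
            img[sl] += lift + grating[sl]
        templates.append(img)

    images, labels, ids = [], [], []
    i = 0
    for cls in range(4):
        for _ in range(spec.n_per_class):
            img = templates[cls].copy()
            if spec.noise_sd > 0:
                img += rng.normal(0.0, spec.noise_sd * 255.0, size=img.shape)
            img = np.clip(img, 0, 255).astype(np.uint8)
            images.append(np.repeat(img[:, :, None], 3, axis=2))
            labels.append(cls)
            ids.append(f"face{i:05d}")
            i += 1
    return images, np.asarray(labels), ids


def write_fixture_dir(spec: SynthSpec, outdir) -> Path:
    """Materialise a fixture directory: PNGs, labels.csv, au.csv, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    images, labels, ids = gen_face_images(spec)
    for img, iid in zip(images, ids):
        Image.fromarray(img).save(outdir / f"{iid}.png")
    pd.DataFrame({"id": ids, "class_index": labels}).to_csv(
        outdir / "labels.csv", index=False
    )
    gen_au_table(spec).to_csv(outdir / "au.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"spec": asdict(spec)}, fh, indent=1, sort_keys=True)
    return outdir


def _self_check(df: pd.DataFrame) -> np.ndarray:
    """Recompute each row's pain class from its AUs (used by tests)."""
    from .facs import AUIntensities, pspi_score

    return np.array(
        [
            pspi_group(pspi_score(AUIntensities(*[int(r[c]) for c in AU_COLUMNS])))
            for _, r in df.iterrows()
        ]
    )
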