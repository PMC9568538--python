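"""Shutter-blinds decomposition: a face image as horizontal strips at four scales.

A pre-cropped face is resized to 224x224 and cut into 21 full-width
horizontal strips ("shutter blinds"): two of height 112, four of 56, seven
of 32 and eight of 28.  Each scale tiles the 224 rows exactly (2*112 =
4*56 = 7*32 = 8*28 = 224), so strips within a scale never gap or overlap.
Strip order is canonical: scales coarse to fine, top to bottom within a
scale; the undivided face is carried alongside and enters downstream
feature concatenation last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import InputOutputError, ValidationError

__all__ = [
    "FACE_SIDE",
    "BLIND_SCALES",
    "Strip",
    "PatchSet",
    "load_face",
    "resize_face",
    "make_blinds",
]

FACE_SIDE = 224
#: Number of strips per scale (coarse to fine); heights are FACE_SIDE // scale.
BLIND_SCALES: tuple[int, ...] = (2, 4, 7, 8)

# Each scale must divide the face side exactly so strips tile without remainder.
for _s in BLIND_SCALES:
    assert FACE_SIDE % _s == 0, f"scale {_s} does not divide {FACE_SIDE}"
del _s


@dataclass(frozen=True)
class Strip:
    """One horizontal band: rows [row_start, row_stop) across the full width."""

    scale: int
    index: int
    row_start: int
    row_stop: int
    pixels: np.ndarray

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start


@dataclass(frozen=True)
class PatchSet:
    """The 21 ordered strips plus the undivided 224x224 face."""

    strips: tuple[Strip, ...]
    whole: np.ndarray

    def __len__(self) -> int:
        return len(self.strips)


def _to_rgb_array(arr: np.ndarray) -> np.ndarray:
    """Coerce an image array to H x W x 3 uint8, replicating grayscale."""
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"cannot interpret array of shape {arr.shape} as an image")
    return np.ascontiguousarray(arr, dtype=np.uint8)


def load_face(path) -> np.ndarray:
    """Load a PNG/JPEG face image as an H x W x 3 uint8 array.

    Grayscale images are channel-replicated.  Images smaller than 8x8 are
    rejected as degenerate.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB") if im.mode not in ("RGB",) else im)
    except (OSError, ValueError) as exc:
        raise InputOutputError(f"cannot read image {path!r}: {exc}") from exc
    arr = _to_rgb_array(arr)
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValidationError(f"image {path!r} smaller than 8x8: {arr.shape[:2]}")
    return arr


def resize_face(image: np.ndarray, side: int = FACE_SIDE) -> np.ndarray:
    """Resize a face image to ``side`` x ``side`` x 3 with bilinear interpolation.

    Deterministic; an already-conforming image is returned unchanged.
    """
    arr = _to_rgb_array(image)
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValidationError(f"image smaller than 8x8: {arr.shape[:2]}")
    if arr.shape[0] == side and arr.shape[1] == side:
        return arr
    im = Image.fromarray(arr).resize((side, side), Image.BILINEAR)
    return np.asarray(im, dtype=np.uint8)


def make_blinds(face: np.ndarray) -> PatchSet:
    """Cut a 224x224x3 face into its 21 canonical shutter-blind strips.

    Strips are ordered coarse to fine scale, top to bottom within each
    scale; geometry depends only on the constants above, never on pixel
    content.  Each strip's pixel array is a copy.
    """
    face = np.asarray(face)
    if face.shape != (FACE_SIDE, FACE_SIDE, 3):
        raise ValidationError(
            f"expected a {FACE_SIDE}x{FACE_SIDE}x3 face, got shape {face.shape}"
        )
    strips = []
    for scale in BLIND_SCALES:
        h = FACE_SIDE // scale
        for i in range(scale):
            r0, r1 = i * h, (i + 1) * h
            strips.append(Strip(scale, i, r0, r1, face[r0:r1].copy()))
    return PatchSet(tuple(strips), face.copy())


def export_strips(patches: PatchSet, outdir) -> list[str]:
    """Debug export: write each strip as strip_<scale>_<index>.png."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in patches.strips:
        p = outdir / f"strip_{s.scale}_{s.index}.png"
        Image.fromarray(s.pixels).save(p)
        paths.append(str(p))
    return paths
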