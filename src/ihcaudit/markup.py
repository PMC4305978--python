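"""Decode a multicolor DIA markup mask into labeled point marks.

The upstream image analysis paints every detected epithelial nucleus
into a markup raster using one saturated class color per Ki67 class
(positive red-dominant, negative blue-dominant) over near-gray
background.  Decoding proceeds by:

1. the excess-RGB transform, per pixel ``(2R-G-B, 2G-R-B, 2B-R-G)``
   (signed, unclipped; the three channels sum to zero identically),
2. fixed thresholds on the excess-red and excess-blue channels to get
   one binary mask per class,
3. connected-component labeling (8-connectivity) with a minimum-area
   filter, and
4. one mark per surviving component at its centroid, rounded half-up
   to integer pixels.

The result is the dD mark set that the expert subsequently reviews.
Any palette whose class colors have the same channel-dominance
structure decodes identically; the green-excess channel is computed but
not used by the default class rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import measure

from .marks import Label, Mark, MarkSet, Provenance, Role

log = logging.getLogger(__name__)

#: default excess-channel threshold for the positive (red-dominant) class
DEFAULT_T_POS = 80
#: default excess-channel threshold for the negative (blue-dominant) class
DEFAULT_T_NEG = 80
#: default minimum component area in pixels
DEFAULT_MIN_AREA = 20


@dataclass
class ExcessChannels:
    """Signed excess color channels of an RGB raster.

    Each channel lies in [-510, 510]; ``ex_r + ex_g + ex_b == 0`` at
    every pixel by construction.
    """

    ex_r: np.ndarray
    ex_g: np.ndarray
    ex_b: np.ndarray


def load_rgb(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster as an (H, W, 3) uint8 array."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    return np.ascontiguousarray(img, dtype=np.uint8)


def excess_rgb(image: np.ndarray) -> ExcessChannels:
    """Excess-RGB transform of an (H, W, 3) image.

    Exact integer arithmetic, no clipping; channel values span
    [-510, 510] and sum to zero at every pixel.
    """
    rgb = np.asarray(image)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {rgb.shape}")
    r = rgb[..., 0].astype(np.int16)
    g = rgb[..., 1].astype(np.int16)
    b = rgb[..., 2].astype(np.int16)
    return ExcessChannels(ex_r=2 * r - g - b, ex_g=2 * g - r - b, ex_b=2 * b - r - g)


def threshold_class_masks(
    channels: ExcessChannels,
    t_pos: int = DEFAULT_T_POS,
    t_neg: int = DEFAULT_T_NEG,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-threshold class masks from the excess channels.

    ``positive = ex_r >= t_pos`` and ``negative = ex_b >= t_neg``; a
    pixel meeting both thresholds is assigned to the class with the
    larger excess, ties going to positive.
    """
    if t_pos <= 0 or t_neg <= 0:
        raise ValueError("thresholds must be positive")
    positive = channels.ex_r >= t_pos
    negative = channels.ex_b >= t_neg
    both = positive & negative
    if both.any():
        red_wins = channels.ex_r >= channels.ex_b  # tie -> positive
        positive &= ~both | red_wins
        negative &= ~both | ~red_wins
    return positive, negative


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def _component_marks(mask: np.ndarray, min_area: int, label: Label) -> list[Mark]:
    labeled = measure.label(mask, connectivity=2)
    out = []
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            continue
        cy, cx = region.centroid  # row, col
        out.append(Mark(_round_half_up(cx), _round_half_up(cy), label))
    return out


def extract_marks(
    positive_mask: np.ndarray,
    negative_mask: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    spot_id: str = "spot",
) -> MarkSet:
    """One dD mark per connected component of area >= ``min_area``.

    Components use 8-connectivity; the mark sits at the component
    centroid (mean pixel coordinate, rounded half-up).  Marks are
    ordered row-major by centroid so the output is deterministic.
    """
    if positive_mask.shape != negative_mask.shape:
        raise ValueError("class masks must have identical dimensions")
    marks = (_component_marks(positive_mask, min_area, Label.POSITIVE)
             + _component_marks(negative_mask, min_area, Label.NEGATIVE))
    marks.sort(key=lambda m: (m.y, m.x))
    # two components can round to the same centroid pixel; a mark set
    # holds one mark per coordinate, so keep the first in row-major order
    seen: set[tuple[int, int]] = set()
    unique = []
    for m in marks:
        if (m.x, m.y) in seen:
            log.warning("dropping mark at (%d, %d): duplicate centroid", m.x, m.y)
            continue
        seen.add((m.x, m.y))
        unique.append(m)
    return MarkSet(spot_id, Role.DD, unique)


def marks_from_markup(
    markup: np.ndarray | str | Path,
    t_pos: int = DEFAULT_T_POS,
    t_neg: int = DEFAULT_T_NEG,
    min_area: int = DEFAULT_MIN_AREA,
    spot_id: str = "spot",
) -> MarkSet:
    """Full markup-to-dD pipeline: excess RGB, thresholds, centroids."""
    if not isinstance(markup, np.ndarray):
        markup = load_rgb(markup)
    channels = excess_rgb(markup)
    pos, neg = threshold_class_masks(channels, t_pos, t_neg)
    ms = extract_marks(pos, neg, min_area, spot_id)
    if len(ms) == 0:
        log.warning("markup for %s decoded to zero marks", spot_id)
    return ms


def save_class_masks(positive_mask: np.ndarray, negative_mask: np.ndarray,
                     path: str | Path) -> None:
    """Debug PNG: positive mask in red channel, negative in blue."""
    h, w = positive_mask.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[..., 0] = positive_mask.astype(np.uint8) * 255
    img[..., 2] = negative_mask.astype(np.uint8) * 255
    iio.imwrite(Path(path), img)


def load_binary_mask(path: str | Path) -> np.ndarray:
    """Read a binary raster (tissue mask): nonzero pixels are True."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img.max(axis=-1)
    return img > 0
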