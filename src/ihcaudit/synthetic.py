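"""Synthetic TMA spots with DIA-style markup masks and logged errors.

Emulates the inputs of the Ki67 marking workflow: a circular tissue
microarray spot containing an irregular epithelial region with
non-overlapping nuclear profiles (brown = Ki67-positive, blue =
negative) plus the multicolor markup mask a detection pipeline would
output for it.  Detection and labeling errors are *injected* with
known probabilities and every injected event is logged with its
category and coordinate, so the downstream audit can be checked
exactly against ground truth:

* a nucleus may be placed outside the simulated epithelial tissue mask
  (the tissue-classification component would never see it),
* a within-mask nucleus may be left out of the markup (missed by the
  nuclear segmenter),
* a detected nucleus may be painted with the wrong Ki67 class,
* spurious components may be painted where no nucleus exists.

Rendering uses axis-aligned filled ellipses with integer centers; the
pixel set is point-symmetric about the center, so the decoded centroid
reproduces the ground-truth coordinate exactly.  No stain physics,
scanner noise or overlapping-nuclei scenes are modeled.

Default error rates correspond to the per-nucleus error composition
reported for a calibrated commercial two-stage pipeline (tissue
classification followed by nuclear segmentation) on breast carcinoma
Ki67 TMAs (about 2.8% of nuclei missed with the tissue mask,
24% of the remainder missed by the segmenter, ~68 spurious detections
per spot, 1% negative-to-positive and 0.2% positive-to-negative label
errors).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import draw

from .audit import Category
from .marks import Label, Mark, MarkSet, Provenance, Role
from .stereology import FrameGrid, frame_of

log = logging.getLogger(__name__)

# markup-mask palette: class colors saturated in one channel, background
# gray (zero excess everywhere except painted nuclei)
MARKUP_POSITIVE = (230, 30, 30)
MARKUP_NEGATIVE = (30, 30, 230)
MARKUP_TISSUE_BG = (128, 128, 128)
MARKUP_NON_TISSUE = (40, 40, 40)

# spot-image palette (cosmetic; the pipeline never reads these)
SPOT_BACKGROUND = (244, 242, 240)
SPOT_TISSUE = (228, 205, 212)
SPOT_POSITIVE = (145, 90, 42)   # DAB brown
SPOT_NEGATIVE = (70, 80, 160)   # hematoxylin blue

NUCLEUS_RADIUS_MIN = 4
NUCLEUS_RADIUS_MAX = 8
#: minimum boundary gap between rendered profiles, pixels; keeps
#: components separate under 8-connectivity and puts any two centers at
#: least 2*r_min + 3 = 11 px apart — beyond the default matching
#: tolerance, so a spurious component can never pair with a real mark
_PACK_GAP = 3


@dataclass(frozen=True)
class ErrorModel:
    """Injected-error configuration for one synthetic spot."""

    p_miss_tissue: float = 0.028
    p_miss_nuclear: float = 0.241
    false_detections_per_spot: float = 68.0
    p_label_flip_pos: float = 0.002  # positive rendered negative
    p_label_flip_neg: float = 0.010  # negative rendered positive
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_miss_tissue", "p_miss_nuclear",
                     "p_label_flip_pos", "p_label_flip_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.false_detections_per_spot < 0:
            raise ValueError("false_detections_per_spot must be >= 0")

    @classmethod
    def none(cls, seed: int = 0) -> "ErrorModel":
        """Error-free model: the markup reproduces the truth exactly."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, seed)


@dataclass
class SyntheticSpot:
    """One generated spot with its markup, masks, truth and event log."""

    spot_id: str
    spot_image: np.ndarray     # (H, W, 3) uint8
    markup_mask: np.ndarray    # (H, W, 3) uint8
    tissue_mask: np.ndarray    # (H, W) bool
    truth: MarkSet             # role TRUTH
    event_log: list[tuple[Category, tuple[int, int]]] = field(default_factory=list)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    true_ki67_pct: float = 0.0


class _Packer:
    """Hard-core rejection placement on a coarse occupancy grid."""

    def __init__(self, cell: int):
        self.cell = cell
        self.placed: dict[tuple[int, int], list[tuple[int, int, int]]] = {}

    def ok(self, x: int, y: int, r: int, gap: int) -> bool:
        cx, cy = x // self.cell, y // self.cell
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for px, py, pr in self.placed.get((cx + dx, cy + dy), ()):
                    if (x - px) ** 2 + (y - py) ** 2 < (r + pr + gap) ** 2:
                        return False
        return True

    def add(self, x: int, y: int, r: int) -> None:
        self.placed.setdefault((x // self.cell, y // self.cell), []).append((x, y, r))


def _tissue_region(size: int, disc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Union of random discs ('blobs') clipped to the spot disc."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2.0
    spot_r = 0.45 * size
    mask = np.zeros((size, size), dtype=bool)
    n_blobs = 24
    for _ in range(n_blobs):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.75 * spot_r)
        bx, by = c + rad * np.cos(ang), c + rad * np.sin(ang)
        br = rng.uniform(0.2 * spot_r, 0.4 * spot_r)
        mask |= (xx - bx) ** 2 + (yy - by) ** 2 <= br ** 2
    return mask & disc


def generate_spot(
    n_nuclei: int,
    true_ki67_pct: float,
    image_size: int = 896,
    error_model: ErrorModel | None = None,
    spot_id: str = "spot",
) -> SyntheticSpot:
    """Generate one circular spot, its markup mask and its event log.

    Nuclei are placed by rejection sampling with a hard-core distance
    so rendered profiles never touch; Ki67 labels are Bernoulli draws
    matching ``true_ki67_pct`` in expectation.  Deterministic given
    ``error_model.seed``.

    Raises
    ------
    RuntimeError
        If the requested nuclei cannot be packed into the tissue area
        within a bounded number of attempts.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if not 0.0 <= true_ki67_pct <= 100.0:
        raise ValueError("true_ki67_pct must be in [0, 100]")
    if image_size < 64:
        raise ValueError("image_size must be >= 64")
    em = error_model or ErrorModel()
    rng = np.random.default_rng(em.seed)
    size = int(image_size)

    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2.0
    spot_r = 0.45 * size
    disc = (xx - c) ** 2 + (yy - c) ** 2 <= spot_r ** 2
    tissue = _tissue_region(size, disc, rng)

    # keep whole ellipses inside the spot disc
    inner = (xx - c) ** 2 + (yy - c) ** 2 <= (spot_r - NUCLEUS_RADIUS_MAX - 2) ** 2
    pool_in = np.argwhere(tissue & inner)       # (y, x) rows
    pool_out = np.argwhere(~tissue & inner)
    if n_nuclei > 0 and len(pool_in) == 0:
        raise RuntimeError("tissue region too small to place any nucleus")

    packer = _Packer(cell=2 * NUCLEUS_RADIUS_MAX + _PACK_GAP)
    # rejection sampling near the jamming density needs many draws per
    # nucleus; each check is O(1) on the occupancy grid, so be generous
    max_attempts = 2000

    placed: list[tuple[int, int, int, int, Label, bool]] = []  # x, y, a, b, label, outside
    for _ in range(n_nuclei):
        outside = bool(rng.random() < em.p_miss_tissue) and len(pool_out) > 0
        pool = pool_out if outside else pool_in
        a = int(rng.integers(NUCLEUS_RADIUS_MIN, NUCLEUS_RADIUS_MAX + 1))
        b = int(rng.integers(NUCLEUS_RADIUS_MIN, NUCLEUS_RADIUS_MAX + 1))
        r = max(a, b)
        for attempt in range(max_attempts):
            y, x = map(int, pool[rng.integers(len(pool))])
            if packer.ok(x, y, r, _PACK_GAP):
                break
        else:
            raise RuntimeError(
                f"infeasible packing: could not place nucleus "
                f"{len(placed) + 1}/{n_nuclei} after {max_attempts} attempts")
        packer.add(x, y, r)
        label = Label.POSITIVE if rng.random() < true_ki67_pct / 100.0 else Label.NEGATIVE
        placed.append((x, y, a, b, label, outside))

    # rasters
    spot_img = np.empty((size, size, 3), dtype=np.uint8)
    spot_img[:] = SPOT_BACKGROUND
    spot_img[disc] = SPOT_BACKGROUND
    spot_img[tissue] = SPOT_TISSUE
    markup = np.empty((size, size, 3), dtype=np.uint8)
    markup[:] = MARKUP_NON_TISSUE
    markup[tissue] = MARKUP_TISSUE_BG

    def paint(img, x, y, a, b, color):
        rr, cc = draw.ellipse(y, x, b, a, shape=img.shape[:2])
        img[rr, cc] = color

    events: list[tuple[Category, tuple[int, int]]] = []
    truth_marks: list[Mark] = []
    for x, y, a, b, label, outside in placed:
        truth_marks.append(Mark(x, y, label))
        paint(spot_img, x, y, a, b,
              SPOT_POSITIVE if label is Label.POSITIVE else SPOT_NEGATIVE)
        if outside:
            events.append((Category.UNDETECTED_BY_TISSUE_MASK, (x, y)))
            continue
        if rng.random() < em.p_miss_nuclear:
            events.append((Category.UNDETECTED_BY_NUCLEAR, (x, y)))
            continue
        rendered = label
        if label is Label.POSITIVE and rng.random() < em.p_label_flip_pos:
            rendered = Label.NEGATIVE
            events.append((Category.FALSE_NEGATIVE_LABEL, (x, y)))
        elif label is Label.NEGATIVE and rng.random() < em.p_label_flip_neg:
            rendered = Label.POSITIVE
            events.append((Category.FALSE_POSITIVE_LABEL, (x, y)))
        paint(markup, x, y, a, b,
              MARKUP_POSITIVE if rendered is Label.POSITIVE else MARKUP_NEGATIVE)

    n_false = int(rng.poisson(em.false_detections_per_spot)) if em.false_detections_per_spot else 0
    for _ in range(n_false):
        a = int(rng.integers(NUCLEUS_RADIUS_MIN, NUCLEUS_RADIUS_MAX + 1))
        b = int(rng.integers(NUCLEUS_RADIUS_MIN, NUCLEUS_RADIUS_MAX + 1))
        r = max(a, b)
        for attempt in range(max_attempts):
            y, x = map(int, pool_in[rng.integers(len(pool_in))])
            if packer.ok(x, y, r, _PACK_GAP):
                break
        else:
            log.warning("%s: dropped a false detection (no room left)", spot_id)
            continue
        packer.add(x, y, r)
        label = Label.POSITIVE if rng.random() < 0.5 else Label.NEGATIVE
        paint(markup, x, y, a, b,
              MARKUP_POSITIVE if label is Label.POSITIVE else MARKUP_NEGATIVE)
        events.append((Category.FALSE_DETECTION, (x, y)))

    return SyntheticSpot(
        spot_id=spot_id,
        spot_image=spot_img,
        markup_mask=markup,
        tissue_mask=tissue,
        truth=MarkSet(spot_id, Role.TRUTH, truth_marks),
        event_log=events,
        error_model=em,
        true_ki67_pct=float(true_ki67_pct),
    )


def simulate_cd(spot: SyntheticSpot, dd: MarkSet) -> MarkSet:
    """The corrected set a perfect expert would produce from ``dd``.

    Every missed truth nucleus is added (provenance EXPERT_ADDED),
    every spurious dD detection deleted, every wrong label corrected:
    the cD equals the ground truth, with provenance recording which
    marks the expert had to add.  Deterministic.
    """
    missed = {xy for cat, xy in spot.event_log
              if cat in (Category.UNDETECTED_BY_TISSUE_MASK,
                         Category.UNDETECTED_BY_NUCLEAR)}
    cd_marks = [
        Mark(m.x, m.y, m.label,
             Provenance.EXPERT_ADDED if (m.x, m.y) in missed else Provenance.AUTO)
        for m in spot.truth
    ]
    return MarkSet(spot.spot_id, Role.CD, cd_marks)


def event_tallies(
    event_log: list[tuple[Category, tuple[int, int]]],
    grid: FrameGrid | None = None,
) -> dict[Category, int]:
    """Count logged events by category, optionally restricted to the
    coordinates counted by a grid's frames."""
    tallies = {cat: 0 for cat in Category}
    for cat, (x, y) in event_log:
        if grid is not None and frame_of(grid, x, y) is None:
            continue
        tallies[cat] += 1
    return tallies


def generate_series(
    n_spots: int,
    n_nuclei: int = 660,
    image_size: int = 1024,
    ki67_range: tuple[float, float] = (5.0, 80.0),
    error_model: ErrorModel | None = None,
    seed: int = 0,
    spot_prefix: str = "spot",
) -> list[SyntheticSpot]:
    """A cohort of spots with varying Ki67% and independent seeds.

    Per-spot true Ki67% is drawn uniformly from ``ki67_range`` and each
    spot gets its own child seed from the master ``seed``, so the whole
    series is reproducible from one integer.
    """
    base = error_model or ErrorModel()
    master = np.random.default_rng(seed)
    spots = []
    for i in range(n_spots):
        ki67 = float(master.uniform(*ki67_range))
        child_seed = int(master.integers(0, 2**31 - 1))
        em = replace(base, seed=child_seed)
        spots.append(generate_spot(n_nuclei, ki67, image_size, em,
                                   spot_id=f"{spot_prefix}{i:03d}"))
    return spots


def write_fixture_bundle(spot: SyntheticSpot, outdir: str | Path) -> dict[str, Path]:
    """Write a spot's rasters, truth XML and event log to a directory.

    File naming follows the pairing convention used by the CLI:
    ``<spot_id>.spot.png``, ``<spot_id>.markup.png``,
    ``<spot_id>.tissue.png``, ``<spot_id>.truth.xml``,
    ``<spot_id>.events.json``.
    """
    from .annotation_xml import write_annotations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = spot.spot_id
    paths = {
        "spot": outdir / f"{sid}.spot.png",
        "markup": outdir / f"{sid}.markup.png",
        "tissue": outdir / f"{sid}.tissue.png",
        "truth": outdir / f"{sid}.truth.xml",
        "events": outdir / f"{sid}.events.json",
    }
    iio.imwrite(paths["spot"], spot.spot_image)
    iio.imwrite(paths["markup"], spot.markup_mask)
    iio.imwrite(paths["tissue"], spot.tissue_mask.astype(np.uint8) * 255)
    write_annotations(spot.truth, None, paths["truth"])
    paths["events"].write_text(json.dumps(
        [{"category": cat.value, "x": x, "y": y}
         for cat, (x, y) in spot.event_log], indent=2) + "\n")
    return paths
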