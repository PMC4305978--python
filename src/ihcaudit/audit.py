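"""Diff machine-generated (dD) and expert-corrected (cD) mark sets.

Every difference between the two sets is classified into the error
taxonomy used to grade each component of the upstream image analysis:

``TRUE_POSITIVE`` / ``TRUE_NEGATIVE``
    a dD mark the expert kept, with its label (no edit);
``FALSE_POSITIVE_LABEL`` / ``FALSE_NEGATIVE_LABEL``
    a kept mark whose Ki67 label the expert flipped (one RELABEL edit);
``FALSE_DETECTION``
    a dD mark with no cD counterpart — the machine marked something
    that is not an epithelial nucleus (one DELETE edit);
``UNDETECTED_BY_TISSUE_MASK`` / ``UNDETECTED_BY_NUCLEAR``
    a cD mark the machine missed (one ADD edit), attributed to the
    tissue-classification component when its coordinate falls outside
    the epithelial tissue mask, and to the nuclear-segmentation
    component when it falls inside (the nucleus was in reach of the
    segmenter and still missed).

Correspondence between the two files is established by greedy
nearest-neighbour one-to-one matching within a pixel tolerance; an
unmoved mark matches at distance zero, so in the dominant case the
matching is exact and order-independent.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .marks import Label, MarkSet
from .stereology import FrameGrid, counted_marks

#: default matching tolerance in pixels
DEFAULT_TOLERANCE = 5.0


class Category(str, enum.Enum):
    TRUE_POSITIVE = "TRUE_POSITIVE"
    TRUE_NEGATIVE = "TRUE_NEGATIVE"
    FALSE_POSITIVE_LABEL = "FALSE_POSITIVE_LABEL"
    FALSE_NEGATIVE_LABEL = "FALSE_NEGATIVE_LABEL"
    FALSE_DETECTION = "FALSE_DETECTION"
    UNDETECTED_BY_TISSUE_MASK = "UNDETECTED_BY_TISSUE_MASK"
    UNDETECTED_BY_NUCLEAR = "UNDETECTED_BY_NUCLEAR"


class EditKind(str, enum.Enum):
    NONE = "NONE"
    RELABEL = "RELABEL"
    DELETE = "DELETE"
    ADD = "ADD"


#: the edit a category implies, and vice versa
CATEGORY_EDIT: dict[Category, EditKind] = {
    Category.TRUE_POSITIVE: EditKind.NONE,
    Category.TRUE_NEGATIVE: EditKind.NONE,
    Category.FALSE_POSITIVE_LABEL: EditKind.RELABEL,
    Category.FALSE_NEGATIVE_LABEL: EditKind.RELABEL,
    Category.FALSE_DETECTION: EditKind.DELETE,
    Category.UNDETECTED_BY_TISSUE_MASK: EditKind.ADD,
    Category.UNDETECTED_BY_NUCLEAR: EditKind.ADD,
}

#: categories that consume one cD mark each (conservation identity)
CD_CATEGORIES = (
    Category.TRUE_POSITIVE, Category.TRUE_NEGATIVE,
    Category.FALSE_POSITIVE_LABEL, Category.FALSE_NEGATIVE_LABEL,
    Category.UNDETECTED_BY_TISSUE_MASK, Category.UNDETECTED_BY_NUCLEAR,
)


@dataclass(frozen=True)
class EditRecord:
    """One classified difference (or agreement) between dD and cD."""

    x: int
    y: int
    category: Category
    edit_kind: EditKind

    def __post_init__(self) -> None:
        if CATEGORY_EDIT[self.category] is not self.edit_kind:
            raise ValueError(f"{self.category} is inconsistent with {self.edit_kind}")


@dataclass
class SpotAudit:
    """Per-spot tallies of edit categories, Ki67% values and effort."""

    spot_id: str
    n_cd_nuclei: int
    tallies: dict[Category, int]
    n_edits: int
    ki67_dd: float  # percentage; NaN when the denominator is zero
    ki67_cd: float
    records: list[EditRecord] = field(default_factory=list)


def match_marks(
    dd: MarkSet, cd: MarkSet, tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy nearest-neighbour one-to-one matching of two mark sets.

    Candidate pairs with Euclidean distance <= ``tolerance`` are taken
    in ascending distance order, ties broken by (dd index, cd index);
    each mark joins at most one pair.  Returns ``(pairs, dd_only,
    cd_only)`` with ``pairs`` as (dd index, cd index) tuples and the
    leftovers as sorted index lists.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if len(dd) == 0 or len(cd) == 0:
        return [], list(range(len(dd))), list(range(len(cd)))
    dxy = np.array([(m.x, m.y) for m in dd], dtype=float)
    cxy = np.array([(m.x, m.y) for m in cd], dtype=float)
    dist = np.hypot(dxy[:, None, 0] - cxy[None, :, 0],
                    dxy[:, None, 1] - cxy[None, :, 1])
    ii, jj = np.nonzero(dist <= tolerance)
    order = sorted(range(len(ii)), key=lambda k: (dist[ii[k], jj[k]], ii[k], jj[k]))
    used_d = np.zeros(len(dd), dtype=bool)
    used_c = np.zeros(len(cd), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if used_d[i] or used_c[j]:
            continue
        used_d[i] = used_c[j] = True
        pairs.append((i, j))
    dd_only = [i for i in range(len(dd)) if not used_d[i]]
    cd_only = [j for j in range(len(cd)) if not used_c[j]]
    return pairs, dd_only, cd_only


def classify_edits(
    pairs: list[tuple[int, int]],
    dd: MarkSet,
    cd: MarkSet,
    dd_only: list[int],
    cd_only: list[int],
    tissue_mask: np.ndarray,
) -> list[EditRecord]:
    """Turn a matching into classified edit records.

    Paired marks with equal labels are TRUE_*; a label disagreement is
    a RELABEL (named for the dD error: dD-positive/cD-negative is a
    false positive label).  Unmatched dD marks are false detections;
    unmatched cD marks are under-detections attributed to the tissue
    mask (coordinate outside the mask) or the nuclear segmenter
    (inside).  The record coordinate is the cD mark's where one exists.
    """
    h, w = tissue_mask.shape
    records: list[EditRecord] = []
    for i, j in pairs:
        d, c = dd[i], cd[j]
        if d.label is c.label:
            cat = (Category.TRUE_POSITIVE if c.label is Label.POSITIVE
                   else Category.TRUE_NEGATIVE)
        elif d.label is Label.POSITIVE:
            cat = Category.FALSE_POSITIVE_LABEL
        else:
            cat = Category.FALSE_NEGATIVE_LABEL
        records.append(EditRecord(c.x, c.y, cat, CATEGORY_EDIT[cat]))
    for i in dd_only:
        d = dd[i]
        records.append(EditRecord(d.x, d.y, Category.FALSE_DETECTION, EditKind.DELETE))
    for j in cd_only:
        c = cd[j]
        if not (0 <= c.x < w and 0 <= c.y < h):
            raise ValueError(f"mark ({c.x}, {c.y}) outside the {w}x{h} tissue mask")
        cat = (Category.UNDETECTED_BY_NUCLEAR if tissue_mask[c.y, c.x]
               else Category.UNDETECTED_BY_TISSUE_MASK)
        records.append(EditRecord(c.x, c.y, cat, EditKind.ADD))
    return records


def ki67_percent(n_positive: int, n_negative: int) -> float:
    """Ki67% = 100 * positive / (positive + negative); NaN when both zero.

    The NaN marker flags spots with no counted nuclei so downstream
    regression can drop them pairwise.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("counts must be >= 0")
    total = n_positive + n_negative
    if total == 0:
        return math.nan
    return 100.0 * n_positive / total


def tally_records(records: list[EditRecord]) -> dict[Category, int]:
    tallies = {cat: 0 for cat in Category}
    for r in records:
        tallies[r.category] += 1
    return tallies


def audit_spot(
    dd: MarkSet,
    cd: MarkSet,
    grid: FrameGrid,
    tissue_mask: np.ndarray,
    tolerance: float = DEFAULT_TOLERANCE,
) -> SpotAudit:
    """Full per-spot audit of an expert's corrections.

    Both sets are first restricted to marks counted by the grid's
    counting frames (forbidden-line rule), so effort metrics reflect
    only the marks the expert actually reviewed; matching,
    classification and Ki67% all run on the restricted sets.
    """
    dd_g = counted_marks(grid, dd)
    cd_g = counted_marks(grid, cd)
    pairs, dd_only, cd_only = match_marks(dd_g, cd_g, tolerance)
    records = classify_edits(pairs, dd_g, cd_g, dd_only, cd_only, tissue_mask)
    tallies = tally_records(records)
    n_edits = sum(1 for r in records if r.edit_kind is not EditKind.NONE)
    return SpotAudit(
        spot_id=cd.spot_id or dd.spot_id,
        n_cd_nuclei=len(cd_g),
        tallies=tallies,
        n_edits=n_edits,
        ki67_dd=ki67_percent(dd_g.n_positive, dd_g.n_negative),
        ki67_cd=ki67_percent(cd_g.n_positive, cd_g.n_negative),
        records=records,
    )


def write_audit_csv(audits: list[SpotAudit], path: str | Path) -> Path:
    """Per-spot audit table: one row per spot, one column per category."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["spot_id", "n_cd_nuclei", "n_edits", "ki67_dd", "ki67_cd"]
                   + [c.value for c in Category])
        for a in audits:
            w.writerow([a.spot_id, a.n_cd_nuclei, a.n_edits,
                        f"{a.ki67_dd:.4f}", f"{a.ki67_cd:.4f}"]
                       + [a.tallies[c] for c in Category])
    return path


def write_edits_csv(audits: list[SpotAudit], path: str | Path) -> Path:
    """Per-edit table across spots (agreement records included)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["spot_id", "x", "y", "category", "edit_kind"])
        for a in audits:
            for r in a.records:
                w.writerow([a.spot_id, r.x, r.y, r.category.value, r.edit_kind.value])
    return path


def read_audit_csv(path: str | Path) -> list[SpotAudit]:
    """Load a per-spot audit table written by :func:`write_audit_csv`."""
    audits = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            tallies = {c: int(row[c.value]) for c in Category}
            audits.append(SpotAudit(
                spot_id=row["spot_id"],
                n_cd_nuclei=int(row["n_cd_nuclei"]),
                tallies=tallies,
                n_edits=int(row["n_edits"]),
                ki67_dd=float(row["ki67_dd"]),
                ki67_cd=float(row["ki67_cd"]),
            ))
    return audits
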