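"""Point-mark containers shared across the pipeline.

A *mark* is a single annotated nuclear profile: an integer pixel
coordinate plus a Ki67 label (positive = immunostained, negative =
counterstained) and a provenance flag saying whether the mark came out
of the automated image analysis or was added by the reviewing expert.

Mark sets carry a *role* describing where they sit in the workflow:

``mD``
    fully manual marks,
``dD``
    machine-generated ("digital") marks decoded from the DIA markup
    image,
``cD``
    expert-corrected marks — the quality-assured reference set,
``TRUTH``
    the synthetic generator's ground truth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator


class Label(str, enum.Enum):
    """Ki67 class of a nuclear profile."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


class Provenance(str, enum.Enum):
    """Origin of a mark: automated analysis or expert addition."""

    AUTO = "AUTO"
    EXPERT_ADDED = "EXPERT_ADDED"


class Role(str, enum.Enum):
    """Workflow role of a mark set."""

    MD = "mD"
    DD = "dD"
    CD = "cD"
    TRUTH = "TRUTH"


@dataclass(frozen=True)
class Mark:
    """One annotated nuclear profile.

    Coordinates are 0-based integer pixels, x rightward, y downward.
    """

    x: int
    y: int
    label: Label
    provenance: Provenance = Provenance.AUTO

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"mark coordinates must be non-negative, got ({self.x}, {self.y})")


@dataclass
class MarkSet:
    """A named, ordered collection of marks for one spot.

    No two marks in a set may share the same coordinate; a mark is a
    point annotation of one nucleus and duplicate coordinates would
    make the dD/cD diff ambiguous.
    """

    spot_id: str
    role: Role
    marks: list[Mark] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        self.marks = list(self.marks)
        coords = [(m.x, m.y) for m in self.marks]
        if len(set(coords)) != len(coords):
            raise ValueError(f"duplicate mark coordinates in set {self.spot_id!r}")

    def __len__(self) -> int:
        return len(self.marks)

    def __iter__(self) -> Iterator[Mark]:
        return iter(self.marks)

    def __getitem__(self, i: int) -> Mark:
        return self.marks[i]

    def count(self, label: Label) -> int:
        return sum(1 for m in self.marks if m.label is label)

    @property
    def n_positive(self) -> int:
        return self.count(Label.POSITIVE)

    @property
    def n_negative(self) -> int:
        return self.count(Label.NEGATIVE)

    def replace(self, marks: Iterable[Mark], role: Role | None = None) -> "MarkSet":
        """A copy of this set with different marks (and optionally role)."""
        return MarkSet(self.spot_id, role or self.role, list(marks))
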