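"""Unbiased counting frames on a systematic uniform random grid.

The classical 2D unbiased counting frame accepts an object when it lies
inside the frame or touches the two *accepting* edges, and rejects it
when it touches the two *forbidden* edges; applied over a systematic
grid of frames this removes the edge-counting bias of naive quadrat
counts.  Here the objects are point marks, so the rule reduces to a
half-open inclusion test on the point itself.

Conventions (pixel coordinates, y down, 0-based):

* forbidden lines: the **left** edge (x = x0) and the **bottom** edge
  (y = y0 + height),
* accepting lines: the right edge (x = x0 + width) and the top edge
  (y = y0),

so a mark is counted by a frame iff ``x0 < x <= x0 + width`` and
``y0 <= y < y0 + height``.  Adjacent frames of a full tiling therefore
partition the plane: every point belongs to at most one frame.

Grids are *systematic uniform random*: frames sit on a regular lattice
with one uniformly random (seeded) offset per grid.  Offsets are drawn
as integer pixels so frame coordinates stay exact integers and
serialize losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .marks import Label, MarkSet

#: default frame edge in pixels
DEFAULT_FRAME_SIZE = 150
#: default lattice spacing as a multiple of frame size
DEFAULT_SPACING_FACTOR = 2


@dataclass(frozen=True)
class Frame:
    """One rectangular counting frame; (x0, y0) is the top-left corner."""

    x0: int
    y0: int
    width: int
    height: int
    frame_id: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame width and height must be positive")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("frame origin must be non-negative")
        if self.frame_id < 0:
            raise ValueError("frame_id must be >= 0")


@dataclass
class FrameGrid:
    """Systematically sampled counting frames over one spot image."""

    frames: list[Frame]
    spacing_x: int
    spacing_y: int
    offset_x: int
    offset_y: int
    image_width: int
    image_height: int
    seed: int

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_width(self) -> int:
        return self.frames[0].width if self.frames else 0

    @property
    def frame_height(self) -> int:
        return self.frames[0].height if self.frames else 0

    def area_fraction(self) -> float:
        """Fraction of the image covered by frames."""
        covered = sum(f.width * f.height for f in self.frames)
        return covered / (self.image_width * self.image_height)


def generate_grid(
    image_width: int,
    image_height: int,
    frame_width: int = DEFAULT_FRAME_SIZE,
    frame_height: int = DEFAULT_FRAME_SIZE,
    spacing_x: int | None = None,
    spacing_y: int | None = None,
    seed: int = 0,
) -> FrameGrid:
    """Place counting frames on a seeded systematic uniform random lattice.

    Frames sit at ``offset + i * spacing`` for every lattice index whose
    frame fits entirely inside the image; frames that would cross the
    border are dropped, not clipped (clipping would bias the sampled
    area fraction).  The offset is one integer draw per axis, uniform on
    ``[0, spacing)``, from ``numpy.random.default_rng(seed)``.

    Raises
    ------
    ValueError
        If a dimension is non-positive, a frame is larger than its
        spacing (frames would overlap), or larger than the image (no
        frame fits).
    """
    spacing_x = int(spacing_x) if spacing_x is not None else DEFAULT_SPACING_FACTOR * frame_width
    spacing_y = int(spacing_y) if spacing_y is not None else DEFAULT_SPACING_FACTOR * frame_height
    for name, v in [
        ("image_width", image_width), ("image_height", image_height),
        ("frame_width", frame_width), ("frame_height", frame_height),
        ("spacing_x", spacing_x), ("spacing_y", spacing_y),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if frame_width > spacing_x or frame_height > spacing_y:
        raise ValueError("frame larger than spacing: frames would overlap")
    if frame_width > image_width or frame_height > image_height:
        raise ValueError("frame larger than image: no frame fits")

    rng = np.random.default_rng(seed)
    offset_x = int(rng.integers(0, spacing_x))
    offset_y = int(rng.integers(0, spacing_y))

    frames: list[Frame] = []
    fid = 0
    for y0 in range(offset_y, image_height - frame_height + 1, spacing_y):
        for x0 in range(offset_x, image_width - frame_width + 1, spacing_x):
            frames.append(Frame(x0, y0, frame_width, frame_height, fid))
            fid += 1
    return FrameGrid(
        frames=frames,
        spacing_x=spacing_x,
        spacing_y=spacing_y,
        offset_x=offset_x,
        offset_y=offset_y,
        image_width=image_width,
        image_height=image_height,
        seed=seed,
    )


def full_tiling_grid(image_width: int, image_height: int,
                     frame_width: int, frame_height: int) -> FrameGrid:
    """Edge-to-edge tiling (spacing = frame size, offset 0): reviews
    essentially every mark while keeping the forbidden-line semantics."""
    frames = []
    fid = 0
    for y0 in range(0, image_height - frame_height + 1, frame_height):
        for x0 in range(0, image_width - frame_width + 1, frame_width):
            frames.append(Frame(x0, y0, frame_width, frame_height, fid))
            fid += 1
    return FrameGrid(frames=frames, spacing_x=frame_width, spacing_y=frame_height,
                     offset_x=0, offset_y=0, image_width=image_width,
                     image_height=image_height, seed=0)


def is_counted(frame: Frame, x: float, y: float) -> bool:
    """Unbiased counting-frame rule for a point mark.

    Left and bottom edges are forbidden; right and top edges accept
    (y-down coordinates).  Pure function of its arguments.
    """
    return (frame.x0 < x <= frame.x0 + frame.width
            and frame.y0 <= y < frame.y0 + frame.height)


def frame_of(grid: FrameGrid, x: float, y: float) -> int | None:
    """frame_id of the (unique) frame counting (x, y), or None."""
    for f in grid.frames:
        if is_counted(f, x, y):
            return f.frame_id
    return None


def count_in_grid(grid: FrameGrid, marks: MarkSet) -> dict[int, tuple[int, int]]:
    """Tally marks counted by each frame, split by Ki67 label.

    Returns a mapping ``frame_id -> (n_positive, n_negative)`` with an
    entry for every frame.  Frames are disjoint, so each mark lands in
    at most one frame; marks counted by no frame are ignored.
    """
    tallies = {f.frame_id: [0, 0] for f in grid.frames}
    for m in marks:
        fid = frame_of(grid, m.x, m.y)
        if fid is not None:
            tallies[fid][0 if m.label is Label.POSITIVE else 1] += 1
    return {fid: (p, n) for fid, (p, n) in tallies.items()}


def counted_marks(grid: FrameGrid, marks: MarkSet) -> MarkSet:
    """Restrict a mark set to the marks counted by some frame."""
    kept = [m for m in marks if frame_of(grid, m.x, m.y) is not None]
    return marks.replace(kept)


def autosize_grid(
    image_width: int,
    image_height: int,
    frame_width: int,
    frame_height: int,
    n_marks_detected: int,
    target_marks: int,
    seed: int = 0,
) -> FrameGrid:
    """Pick the grid spacing so roughly ``target_marks`` of the detected
    marks fall inside frames.

    The sampled fraction of marks equals the frame-area fraction of the
    grid, so a target fraction ``f = min(1, target / detected)`` is met
    by spacing ``frame_size / sqrt(f)`` on both axes (rounded up to
    integer pixels, never below the frame size).  This is the automated
    grid resizing that adapts review effort to spot cellularity.
    """
    if n_marks_detected <= 0:
        raise ValueError("n_marks_detected must be positive")
    if target_marks <= 0:
        raise ValueError("target_marks must be positive")
    f = min(1.0, target_marks / n_marks_detected)
    spacing_x = max(frame_width, math.ceil(frame_width / math.sqrt(f)))
    spacing_y = max(frame_height, math.ceil(frame_height / math.sqrt(f)))
    return generate_grid(image_width, image_height, frame_width, frame_height,
                         spacing_x, spacing_y, seed)


def grid_to_json(grid: FrameGrid) -> dict:
    """JSON-serializable description of a grid (parameters + frame list)."""
    return {
        "spacing_x": grid.spacing_x,
        "spacing_y": grid.spacing_y,
        "offset_x": grid.offset_x,
        "offset_y": grid.offset_y,
        "image_width": grid.image_width,
        "image_height": grid.image_height,
        "seed": grid.seed,
        "frames": [
            {"frame_id": f.frame_id, "x0": f.x0, "y0": f.y0,
             "width": f.width, "height": f.height}
            for f in grid.frames
        ],
    }


def grid_from_json(obj: dict) -> FrameGrid:
    frames = [Frame(f["x0"], f["y0"], f["width"], f["height"], f["frame_id"])
              for f in obj["frames"]]
    return FrameGrid(
        frames=frames,
        spacing_x=obj["spacing_x"], spacing_y=obj["spacing_y"],
        offset_x=obj["offset_x"], offset_y=obj["offset_y"],
        image_width=obj["image_width"], image_height=obj["image_height"],
        seed=obj["seed"],
    )
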