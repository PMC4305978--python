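"""Read/write the point-mark and grid-frame annotation XML dialect.

The dialect follows the ImageScope annotation structure
(``Annotations > Annotation > Regions > Region > Vertices > Vertex``)
so files can be overlaid on the spot image in a viewer for expert
editing:

* one ``Annotation`` layer per Ki67 label (``POSITIVE``, ``NEGATIVE``)
  whose regions are single-vertex point regions, each carrying an
  optional ``Provenance`` attribute (``AUTO`` when absent);
* one optional ``GRID`` layer whose regions are two-vertex rectangles
  (top-left then bottom-right corner) with a ``FrameId`` attribute;
  the grid's lattice parameters ride along as layer attributes so the
  grid round-trips exactly.

Coordinates are 0-based integer pixels.  Writing is deterministic:
identical inputs produce byte-identical files.  Unknown layers are
skipped with a logged warning so files touched by other tools still
load.  No claim of bit-compatibility with any vendor product is made.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

from lxml import etree

from .marks import Label, Mark, MarkSet, Provenance, Role
from .stereology import Frame, FrameGrid

log = logging.getLogger(__name__)

_MARK_LAYERS = {Label.POSITIVE.value: Label.POSITIVE, Label.NEGATIVE.value: Label.NEGATIVE}
_GRID_LAYER = "GRID"


class AnnotationSchemaError(ValueError):
    """Structurally invalid annotation document (bad vertex counts etc.)."""


def _vertex(parent: etree._Element, x: int, y: int) -> None:
    etree.SubElement(parent, "Vertex", X=str(int(x)), Y=str(int(y)))


def build_document(marks: MarkSet, grid: FrameGrid | None = None) -> etree._Element:
    """Build the XML tree for a mark set and optional grid."""
    root = etree.Element("Annotations", SpotId=marks.spot_id, Role=marks.role.value)
    for layer_name, label in _MARK_LAYERS.items():
        layer = etree.SubElement(root, "Annotation", Name=layer_name, Type="marks")
        regions = etree.SubElement(layer, "Regions")
        # Id is the mark's position in the full set, so reading restores
        # the original interleaved order across the two label layers.
        for rid, m in enumerate(marks):
            if m.label is not label:
                continue
            attrs = {"Type": "Point", "Id": str(rid)}
            if m.provenance is not Provenance.AUTO:
                attrs["Provenance"] = m.provenance.value
            region = etree.SubElement(regions, "Region", **attrs)
            vertices = etree.SubElement(region, "Vertices")
            _vertex(vertices, m.x, m.y)
    if grid is not None:
        layer = etree.SubElement(
            root, "Annotation", Name=_GRID_LAYER, Type="grid",
            SpacingX=str(grid.spacing_x), SpacingY=str(grid.spacing_y),
            OffsetX=str(grid.offset_x), OffsetY=str(grid.offset_y),
            ImageWidth=str(grid.image_width), ImageHeight=str(grid.image_height),
            Seed=str(grid.seed),
        )
        regions = etree.SubElement(layer, "Regions")
        for f in grid.frames:
            region = etree.SubElement(regions, "Region", Type="Rectangle",
                                      FrameId=str(f.frame_id))
            vertices = etree.SubElement(region, "Vertices")
            _vertex(vertices, f.x0, f.y0)
            _vertex(vertices, f.x0 + f.width, f.y0 + f.height)
    return root


def write_annotations(marks: MarkSet, grid: FrameGrid | None,
                      path: str | Path) -> Path:
    """Write marks (and optionally a grid) to an annotation XML file."""
    root = build_document(marks, grid)
    data = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
    path = Path(path)
    path.write_bytes(data)
    return path


def _parse_point_region(region: etree._Element, label: Label) -> Mark:
    vertices = region.findall("Vertices/Vertex")
    if len(vertices) != 1:
        raise AnnotationSchemaError(
            f"point region must have exactly 1 vertex, found {len(vertices)}"
            f" (line {region.sourceline})")
    v = vertices[0]
    provenance = Provenance(region.get("Provenance", Provenance.AUTO.value))
    return Mark(int(v.get("X")), int(v.get("Y")), label, provenance)


def _parse_grid_layer(layer: etree._Element) -> FrameGrid:
    frames = []
    for region in layer.findall("Regions/Region"):
        vertices = region.findall("Vertices/Vertex")
        if len(vertices) != 2:
            raise AnnotationSchemaError(
                f"rectangle region must have exactly 2 vertices, found "
                f"{len(vertices)} (line {region.sourceline})")
        (x0, y0), (x1, y1) = [(int(v.get("X")), int(v.get("Y"))) for v in vertices]
        if not (x0 < x1 and y0 < y1):
            raise AnnotationSchemaError(
                f"rectangle corners must satisfy corner1 < corner2, got "
                f"({x0},{y0}) and ({x1},{y1}) (line {region.sourceline})")
        frames.append(Frame(x0, y0, x1 - x0, y1 - y0, int(region.get("FrameId"))))
    return FrameGrid(
        frames=frames,
        spacing_x=int(layer.get("SpacingX")), spacing_y=int(layer.get("SpacingY")),
        offset_x=int(layer.get("OffsetX")), offset_y=int(layer.get("OffsetY")),
        image_width=int(layer.get("ImageWidth")),
        image_height=int(layer.get("ImageHeight")),
        seed=int(layer.get("Seed")),
    )


def read_annotations(path: str | Path) -> tuple[MarkSet, FrameGrid | None]:
    """Parse an annotation XML file back into a MarkSet and optional grid.

    Marks take their Ki67 label from the layer they sit in, in document
    order within each layer.  Layers with unrecognized names are
    ignored with a warning.  Malformed XML raises ``lxml``'s parse
    error (which names the offending line); structural violations raise
    :class:`AnnotationSchemaError`.
    """
    path = Path(path)
    root = etree.parse(str(path)).getroot()
    spot_id = root.get("SpotId", path.stem)
    role = Role(root.get("Role", Role.DD.value))
    keyed: list[tuple[int, int, Mark]] = []
    grid: FrameGrid | None = None
    doc_order = 0
    for layer in root.findall("Annotation"):
        name = layer.get("Name", "")
        if name in _MARK_LAYERS:
            label = _MARK_LAYERS[name]
            for region in layer.findall("Regions/Region"):
                mark = _parse_point_region(region, label)
                rid = region.get("Id")
                keyed.append((int(rid) if rid is not None else doc_order,
                              doc_order, mark))
                doc_order += 1
        elif name == _GRID_LAYER:
            grid = _parse_grid_layer(layer)
        else:
            log.warning("ignoring unknown annotation layer %r in %s", name, path)
    keyed.sort(key=lambda t: (t[0], t[1]))
    return MarkSet(spot_id, role, [m for _, _, m in keyed]), grid


def write_marks_csv(marks: MarkSet, path: str | Path) -> Path:
    """CSV export (spot_id, x, y, label, provenance) for spreadsheet review."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["spot_id", "x", "y", "label", "provenance"])
        for m in marks:
            w.writerow([marks.spot_id, m.x, m.y, m.label.value, m.provenance.value])
    return path
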