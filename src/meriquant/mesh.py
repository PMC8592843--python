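"""2D polygonal cross-section meshes of the root meristem.

A :class:`CrossSectionMesh` is a watertight tessellation of a root cross
section into cell polygons. Cell walls are straight segments shared by at
most two cells; each wall carries a mechanical class (outer-epidermal,
epidermal-other, cortex, outer-endodermal, inner-endodermal,
pericycle-stele) that the mechanics module maps to a spring stiffness.
Coordinates are Cartesian micrometres, cell polygons are simple and
counter-clockwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

# Concentric tissues, innermost first.
TISSUES = ("stele", "pericycle", "endodermis", "cortex", "epidermis")

# Wall mechanical classes.
OUTER_EPIDERMAL = "outer-epidermal"
EPIDERMAL_OTHER = "epidermal-other"
CORTEX_WALL = "cortex"
OUTER_ENDODERMAL = "outer-endodermal"
INNER_ENDODERMAL = "inner-endodermal"
PERICYCLE_STELE = "pericycle-stele"
WALL_CLASSES = (
    OUTER_EPIDERMAL,
    EPIDERMAL_OTHER,
    CORTEX_WALL,
    OUTER_ENDODERMAL,
    INNER_ENDODERMAL,
    PERICYCLE_STELE,
)

# Tissue groups used for area bookkeeping in the radial-growth analysis.
INNER_TISSUES = frozenset({"endodermis", "pericycle", "stele"})
OUTER_TISSUES = frozenset({"epidermis", "cortex"})


class GeometryError(ValueError):
    """A cell polygon is degenerate or self-intersecting."""


@dataclass
class CrossSectionMesh:
    """Cell tessellation of a root cross section.

    Attributes
    ----------
    vertices : (n, 2) float array of vertex positions in µm.
    walls : (m, 2) int array of vertex-index pairs.
    wall_class : length-m array of wall class labels.
    rest_length : (m,) float array of spring rest lengths in µm.
    cells : list of int arrays, each the ordered (CCW) vertex loop of a cell.
    cell_tissue : list of tissue labels, parallel to ``cells``.
    """

    vertices: np.ndarray
    walls: np.ndarray
    wall_class: np.ndarray
    rest_length: np.ndarray
    cells: list
    cell_tissue: list
    _wall_index: dict = field(default=None, repr=False, compare=False)

    # -- construction -----------------------------------------------------

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.walls = np.asarray(self.walls, dtype=np.intp)
        self.wall_class = np.asarray(self.wall_class, dtype=object)
        self.rest_length = np.asarray(self.rest_length, dtype=float)
        self.cells = [np.asarray(c, dtype=np.intp) for c in self.cells]

    def copy(self) -> "CrossSectionMesh":
        return CrossSectionMesh(
            self.vertices.copy(),
            self.walls.copy(),
            self.wall_class.copy(),
            self.rest_length.copy(),
            [c.copy() for c in self.cells],
            list(self.cell_tissue),
        )

    # -- topology ---------------------------------------------------------

    @property
    def wall_index(self) -> dict:
        """Map of sorted vertex pair -> wall row."""
        if self._wall_index is None:
            self._wall_index = {
                (min(a, b), max(a, b)): i for i, (a, b) in enumerate(self.walls)
            }
        return self._wall_index

    def wall_cells(self) -> list:
        """For each wall, the list of incident cell indices (1 or 2)."""
        inc = [[] for _ in range(len(self.walls))]
        for ci, loop in enumerate(self.cells):
            for a, b in zip(loop, np.roll(loop, -1)):
                w = self.wall_index.get((min(a, b), max(a, b)))
                if w is not None:
                    inc[w].append(ci)
        return inc

    def validate(self) -> None:
        """Check watertightness, orientation and polygon simplicity.

        Raises :class:`GeometryError` on the first violation found.
        """
        if not np.all(self.rest_length > 0):
            raise GeometryError("non-positive rest length")
        areas = self.cell_areas()
        for ci, loop in enumerate(self.cells):
            if len(loop) < 3:
                raise GeometryError(f"cell {ci} has fewer than 3 vertices")
            if areas[ci] <= 0:
                raise GeometryError(f"cell {ci} is not counter-clockwise")
            poly = Polygon(self.vertices[loop])
            if not poly.is_valid:
                raise GeometryError(f"cell {ci} polygon is self-intersecting")
        for w, inc in enumerate(self.wall_cells()):
            if len(inc) not in (1, 2):
                raise GeometryError(
                    f"wall {w} incident to {len(inc)} cells (expected 1 or 2)"
                )

    # -- geometry ---------------------------------------------------------

    def wall_lengths(self) -> np.ndarray:
        d = self.vertices[self.walls[:, 1]] - self.vertices[self.walls[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def cell_areas(self) -> np.ndarray:
        """Signed shoelace area of every cell (positive when CCW)."""
        out = np.empty(len(self.cells))
        for i, loop in enumerate(self.cells):
            p = self.vertices[loop]
            q = self.vertices[np.roll(loop, -1)]
            out[i] = 0.5 * np.sum(p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1])
        return out

    def total_area(self) -> float:
        return float(self.cell_areas().sum())


def tissue_areas(mesh: CrossSectionMesh) -> dict:
    """Sum of polygon areas per tissue, in µm².

    Raises :class:`GeometryError` if any cell polygon is self-intersecting.
    """
    areas = mesh.cell_areas()
    for ci, loop in enumerate(mesh.cells):
        if areas[ci] <= 0 or not Polygon(mesh.vertices[loop]).is_valid:
            raise GeometryError(f"cell {ci} polygon is degenerate")
    out: dict = {}
    for t, a in zip(mesh.cell_tissue, areas):
        out[t] = out.get(t, 0.0) + float(a)
    return out


def normalized_profile(series) -> np.ndarray:
    """Normalize a sequence of section areas to its first entry.

    Mirrors the along-meristem radial-area profiles where each tissue's
    area is expressed relative to its value at the quiescent centre.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0 or arr[0] == 0:
        raise ValueError("profile must start with a non-zero reference value")
    return arr / arr[0]


# -- JSON serialization ---------------------------------------------------

def to_json(mesh: CrossSectionMesh, path=None) -> str:
    """Serialize a mesh to the wall-loop JSON format.

    ``vertices`` hold id/x/y in µm, ``walls`` hold vertex pairs and wall
    classes, ``cells`` hold ordered wall-id loops plus tissue labels.
    """
    cells = []
    for ci, loop in enumerate(mesh.cells):
        wall_loop = [
            mesh.wall_index[(min(a, b), max(a, b))]
            for a, b in zip(loop, np.roll(loop, -1))
        ]
        cells.append({"id": ci, "walls": wall_loop, "tissue": mesh.cell_tissue[ci]})
    doc = {
        "vertices": [
            {"id": i, "x": float(x), "y": float(y)}
            for i, (x, y) in enumerate(mesh.vertices)
        ],
        "walls": [
            {
                "id": i,
                "vertices": [int(a), int(b)],
                "wall_class": str(c),
                "rest_length": float(l0),
            }
            for i, ((a, b), c, l0) in enumerate(
                zip(mesh.walls, mesh.wall_class, mesh.rest_length)
            )
        ],
        "cells": cells,
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def from_json(source) -> CrossSectionMesh:
    """Load a mesh from the JSON format written by :func:`to_json`.

    ``source`` may be a JSON string or a file path.
    """
    if isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    nv = len(doc["vertices"])
    vertices = np.zeros((nv, 2))
    for v in doc["vertices"]:
        vertices[v["id"]] = (v["x"], v["y"])
    walls = np.array([w["vertices"] for w in doc["walls"]], dtype=np.intp)
    wall_class = np.array([w["wall_class"] for w in doc["walls"]], dtype=object)
    rest_length = np.array(
        [w.get("rest_length", np.nan) for w in doc["walls"]], dtype=float
    )
    cells, tissues = [], []
    for c in doc["cells"]:
        loop = _vertex_loop_from_walls([tuple(walls[w]) for w in c["walls"]])
        cells.append(loop)
        tissues.append(c["tissue"])
    mesh = CrossSectionMesh(vertices, walls, wall_class, rest_length, cells, tissues)
    if np.any(np.isnan(mesh.rest_length)):
        mesh.rest_length = mesh.wall_lengths()
    # enforce CCW orientation
    areas = mesh.cell_areas()
    for i, a in enumerate(areas):
        if a < 0:
            mesh.cells[i] = mesh.cells[i][::-1]
    return mesh


def _vertex_loop_from_walls(wall_pairs) -> np.ndarray:
    """Chain an unordered-orientation wall loop into a vertex loop."""
    a0, b0 = wall_pairs[0]
    if len(wall_pairs) > 1 and a0 in wall_pairs[1]:
        a0, b0 = b0, a0  # orient first wall so the chain continues at b0
    loop = [a0, b0]
    for a, b in wall_pairs[1:-1]:
        prev = loop[-1]
        if a == prev:
            loop.append(b)
        elif b == prev:
            loop.append(a)
        else:  # pragma: no cover - malformed input
            raise GeometryError("wall loop is not contiguous")
    return np.array(loop, dtype=np.intp)
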