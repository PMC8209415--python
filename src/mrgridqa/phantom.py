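"""Parametric model of the 3D-printed grid phantom.

The phantom is a water-filled photosensitive-resin disc: a 40 cm circular
front face, partly cut flat on one side for stability, 22 cm thick along the
scanner bore, whose interior is divided into 1 x 1 cm square grid cells by
thin resin walls.  A solid diamond marker at the centre defines the origin
and is aligned to the magnet isocenter during setup.

Coordinate frame (all lengths in mm):

* origin at the diamond centre,
* +y is the 0-degree reference direction; angles increase clockwise,
* z runs along the slice axis, increasing foot -> head,
* the flat cut sits on the 180-degree (-y) side.

The complete-cell count of the default build is exactly 822, matching the
manufactured phantom; ``grid_inner_radius_mm`` and ``cut_chord_offset_mm``
are calibrated constants chosen once by exhaustive enumeration so that the
default geometry reproduces that count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PhantomSpec",
    "NodeLattice",
    "build_phantom",
    "build_lattice",
    "nodes_within_radius",
]

# Geometric tolerance for "inside" tests; well below manufacturing precision.
_TOL = 1e-9


@dataclass(frozen=True)
class PhantomSpec:
    """Dimensions of the grid phantom (mm).

    Attributes
    ----------
    face_diameter_mm:
        Diameter of the circular front face.
    cut_chord_offset_mm:
        Distance from the centre to the flat stability cut on the -y side.
    thickness_mm:
        Extent along the slice (z) axis.
    cell_pitch_mm:
        Grid period; cells are ``cell_pitch_mm`` squares.
    wall_thickness_mm:
        Thickness of the resin walls separating cells (rendering only; node
        positions do not depend on it).
    diamond_halfwidth_mm:
        Half-diagonal of the solid central diamond marker.
    grid_inner_radius_mm:
        Radius of the circular region holding the grid lattice.
    """

    face_diameter_mm: float = 400.0
    cut_chord_offset_mm: float = 125.0
    thickness_mm: float = 220.0
    cell_pitch_mm: float = 10.0
    wall_thickness_mm: float = 2.0
    diamond_halfwidth_mm: float = 7.0
    grid_inner_radius_mm: float = 175.0

    def __post_init__(self) -> None:
        for name in (
            "face_diameter_mm",
            "thickness_mm",
            "cell_pitch_mm",
            "wall_thickness_mm",
            "diamond_halfwidth_mm",
            "grid_inner_radius_mm",
            "cut_chord_offset_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not self.cell_pitch_mm < self.grid_inner_radius_mm:
            raise ValueError("cell_pitch_mm must be smaller than grid_inner_radius_mm")
        if not self.cut_chord_offset_mm < self.face_diameter_mm / 2:
            raise ValueError("cut chord must lie inside the face circle")

    @property
    def face_radius_mm(self) -> float:
        return self.face_diameter_mm / 2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "PhantomSpec":
        return build_phantom(d)


def build_phantom(overrides: Mapping[str, float] | None = None) -> PhantomSpec:
    """Return the default phantom spec with optional field overrides.

    Raises
    ------
    ValueError
        On unknown field names or non-positive dimensions.
    """
    overrides = dict(overrides or {})
    known = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown phantom field(s): {sorted(unknown)}")
    return PhantomSpec(**overrides)


@dataclass(frozen=True)
class NodeLattice:
    """Reference control-point lattice of one transverse cross-section.

    ``nodes`` are the grid intersections bounding complete cells, as an
    (N, 2) array of (x, y) in mm; ``cells`` are the (M, 2) centres of the
    complete cells.  Node order is deterministic (sorted by y then x) and
    the row index is the node id.
    """

    nodes: np.ndarray
    cells: np.ndarray
    pitch_mm: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def center_id(self) -> int:
        idx = np.flatnonzero((self.nodes == 0).all(axis=1))
        if idx.size != 1:
            raise RuntimeError("lattice has no unique centre node")
        return int(idx[0])

    def radii(self) -> np.ndarray:
        """Distance of every node from the phantom centre."""
        return np.hypot(self.nodes[:, 0], self.nodes[:, 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": np.arange(self.n_nodes),
                "x_mm": self.nodes[:, 0],
                "y_mm": self.nodes[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _complete_cell_mask(
    corners_x: np.ndarray,
    corners_y: np.ndarray,
    radius: float,
    cut_offset: float,
) -> np.ndarray:
    """A cell is complete when its full extent lies inside the cut circle.

    The region is convex, so corner containment suffices.
    """
    inside = (corners_x**2 + corners_y**2 <= radius**2 + _TOL) & (
        corners_y >= -cut_offset - _TOL
    )
    return inside.all(axis=-1)


def build_lattice(spec: PhantomSpec) -> NodeLattice:
    """Enumerate the complete grid cells and their bounding intersections.

    A cell is counted when all of it lies inside the circle of
    ``grid_inner_radius_mm`` clipped by the stability cut.  With the default
    spec the cell count is exactly 822.
    """
    p = spec.cell_pitch_mm
    n = int(np.floor(spec.grid_inner_radius_mm / p)) + 1
    ij = np.arange(-n, n)
    ii, jj = np.meshgrid(ij, ij, indexing="ij")
    ii = ii.ravel()
    jj = jj.ravel()
    # corner offsets of cell [i, i+1] x [j, j+1] in pitch units
    cx = (ii[:, None] + np.array([0, 1, 0, 1])) * p
    cy = (jj[:, None] + np.array([0, 0, 1, 1])) * p
    ok = _complete_cell_mask(cx, cy, spec.grid_inner_radius_mm, spec.cut_chord_offset_mm)
    if not ok.any():
        raise ValueError("geometry admits zero complete cells")
    cells = np.column_stack([(ii[ok] + 0.5) * p, (jj[ok] + 0.5) * p])
    corners = np.unique(
        np.column_stack([cx[ok].ravel(), cy[ok].ravel()]), axis=0
    )
    order = np.lexsort((corners[:, 0], corners[:, 1]))
    nodes = corners[order]
    return NodeLattice(nodes=nodes, cells=cells, pitch_mm=p)


def nodes_within_radius(lattice: NodeLattice, r_mm: float) -> np.ndarray:
    """Nodes within a cumulative disc of radius ``r_mm`` around the centre.

    Returns the (K, 2) coordinate subset; the disc is inclusive, so a node
    exactly at ``r_mm`` is kept.
    """
    if r_mm <= 0:
        raise ValueError("r_mm must be positive")
    return lattice.nodes[lattice.radii() <= r_mm + _TOL]
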