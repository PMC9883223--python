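"""Soft-tissue protrusion landmarks and computer-calculated (CC) points.

Six convex facial landmarks are supported, each with a fixed anatomical
protrusion direction (its "normal vector"): pronasale, columella, upper and
lower lip points, and the two cheek points.  The normals encode anatomy, not
mesh geometry -- the lips and nasal tip protrude straight forward (-y), the
columella points 45 degrees down-forward, the cheeks 45 degrees laterally.

A CC point is computed from a manually seeded starting point on the terraced
surface mesh:

1. collect mesh vertices within ``radius_px`` (default 50) of the start and
   within ``band_px`` (default 1) of it along the landmark normal, keeping
   only the edge-connected patch containing the start -- the "tabletop";
2. average the member vertex coordinates.

Distances and the reference coordinate system: voxel coordinates ``v`` map
to mm as ``(v - center) * scale`` with ``center = (266.5, 266.5, 266)`` and
``scale = 0.3`` (the acquisition voxel size in mm), and ``d`` is the
Euclidean norm of the mm coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .marching import TriangleMesh, vertex_adjacency

__all__ = [
    "LandmarkDefinition",
    "TabletopRegion",
    "CCPoint",
    "CoordinateConversion",
    "landmark_catalog",
    "get_landmark",
    "snap_to_surface",
    "find_tabletop",
    "compute_cc_point",
    "convert_voxel_to_mm",
    "convert_mm_to_voxel",
    "euclidean_d",
    "tangent_directions",
    "consistency_check",
    "DEFAULT_OFFSETS_PX",
]

#: perturbation offsets (px) used by the consistency examination
DEFAULT_OFFSETS_PX = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass(frozen=True)
class LandmarkDefinition:
    """One protrusion landmark: name, abbreviation and its fixed normal."""

    name: str
    abbreviation: str
    normal_raw: tuple[float, float, float]

    @property
    def normal_unit(self) -> np.ndarray:
        v = np.asarray(self.normal_raw, dtype=float)
        return v / np.linalg.norm(v)


# raw normals as catalogued; only the direction is meaningful (the +/-0.5
# component notation leaves the printed vectors un-normalized)
_CATALOG = (
    LandmarkDefinition("Pronasale", "Pn", (0.0, -0.5, 0.0)),
    LandmarkDefinition("Columella", "Co", (0.0, -0.5, -0.5)),
    LandmarkDefinition("Upper lip point", "ULP", (0.0, -0.5, 0.0)),
    LandmarkDefinition("Lower lip point", "LLP", (0.0, -0.5, 0.0)),
    LandmarkDefinition("Cheek_right", "Ch_r", (-0.5, -0.5, 0.0)),
    LandmarkDefinition("Cheek_left", "Ch_l", (0.5, -0.5, 0.0)),
)


def landmark_catalog() -> tuple[LandmarkDefinition, ...]:
    """The six soft-tissue protrusion landmarks with their raw normals."""
    return _CATALOG


def get_landmark(abbreviation: str) -> LandmarkDefinition:
    for lm in _CATALOG:
        if lm.abbreviation == abbreviation:
            return lm
    raise KeyError(f"unknown landmark abbreviation {abbreviation!r}")


@dataclass
class CoordinateConversion:
    """Affine voxel -> mm map of the reference coordinate system."""

    center: tuple[float, float, float] = (266.5, 266.5, 266.0)
    scale: float = 0.3


def convert_voxel_to_mm(point, center=(266.5, 266.5, 266.0), scale: float = 0.3) -> np.ndarray:
    """``mm_i = (voxel_i - center_i) * scale`` per axis (exact affine map)."""
    return (np.asarray(point, dtype=float) - np.asarray(center, dtype=float)) * scale


def convert_mm_to_voxel(point, center=(266.5, 266.5, 266.0), scale: float = 0.3) -> np.ndarray:
    """Exact inverse of :func:`convert_voxel_to_mm`."""
    return np.asarray(point, dtype=float) / scale + np.asarray(center, dtype=float)


def euclidean_d(point) -> float:
    """Euclidean distance of an mm coordinate triple from the origin."""
    return float(np.linalg.norm(np.asarray(point, dtype=float)))


@dataclass
class TabletopRegion:
    """The edge-connected tabletop patch containing a starting point."""

    landmark: str
    start_index: int
    start_point: np.ndarray
    members: np.ndarray          # sorted mesh vertex indices
    radius_px: float = 50.0
    band_px: float = 1.0


@dataclass
class CCPoint:
    """A computer-calculated landmark point (tabletop centroid)."""

    landmark: str
    voxel_coords: np.ndarray
    mm_coords: np.ndarray
    d: float
    n_members: int


def _kdtree(mesh: TriangleMesh) -> cKDTree:
    tree = mesh.metadata.get("_kdtree")
    if tree is None or tree.n != mesh.n_vertices:
        tree = cKDTree(mesh.vertices)
        mesh.metadata["_kdtree"] = tree
    return tree


def snap_to_surface(point, mesh: TriangleMesh) -> int:
    """Index of the mesh vertex nearest to ``point`` (ties: lowest index)."""
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    dist, idx = _kdtree(mesh).query(np.asarray(point, dtype=float))
    # cKDTree breaks exact ties arbitrarily; enforce the documented rule
    d2 = np.einsum("ij,ij->i", mesh.vertices - np.asarray(point, float),
                   mesh.vertices - np.asarray(point, float))
    best = d2[idx]
    tied = np.flatnonzero(d2 <= best + 1e-12)
    return int(tied[0]) if len(tied) else int(idx)


def find_tabletop(mesh: TriangleMesh, start, landmark: LandmarkDefinition,
                  radius_px: float = 50.0, band_px: float = 1.0) -> TabletopRegion:
    """Tabletop patch: radius ball, normal band, connected component.

    Members are the edge-connected component containing the snapped start
    vertex of ``{v : |v - start| <= radius_px and |(v - start).n| <= band_px}``
    where ``n`` is the landmark's unit normal.  The band is a slab of
    thickness ``2 * band_px`` centred on the start point, perpendicular to
    the fixed anatomical normal (per-vertex mesh normals are used only to
    reject back-facing starts).
    """
    start_idx = snap_to_surface(start, mesh)
    start_v = mesh.vertices[start_idx]
    n_hat = landmark.normal_unit
    if mesh.vertex_normals is not None and \
            float(np.dot(mesh.vertex_normals[start_idx], n_hat)) <= 0.0:
        raise ValueError(
            f"starting point not on the landmark-facing surface for {landmark.abbreviation}")

    cand = np.array(sorted(_kdtree(mesh).query_ball_point(start_v, r=radius_px)),
                    dtype=np.int64)
    rel = mesh.vertices[cand] - start_v
    in_band = np.abs(rel @ n_hat) <= band_px
    cand = cand[in_band]
    if start_idx not in cand:  # numeric safety; the start always qualifies
        cand = np.sort(np.append(cand, start_idx))

    adj = vertex_adjacency(mesh)
    sub = adj[cand][:, cand]
    n_comp, labels = csgraph.connected_components(sub, directed=False)
    start_pos = int(np.searchsorted(cand, start_idx))
    members = cand[labels == labels[start_pos]]
    return TabletopRegion(landmark.abbreviation, start_idx, start_v.copy(),
                          np.sort(members), float(radius_px), float(band_px))


def compute_cc_point(region: TabletopRegion, mesh: TriangleMesh,
                     conversion: CoordinateConversion | None = None) -> CCPoint:
    """Unweighted mean of the tabletop member vertices, plus mm coordinates."""
    if len(region.members) == 0:
        raise ValueError("empty tabletop region")
    conversion = conversion or CoordinateConversion()
    centroid = mesh.vertices[region.members].mean(axis=0)
    mm = convert_voxel_to_mm(centroid, conversion.center, conversion.scale)
    return CCPoint(region.landmark, centroid, mm, euclidean_d(mm),
                   int(len(region.members)))


def tangent_directions(normal) -> dict[str, np.ndarray]:
    """Screen-space up/down/left/right mapped to the normal's tangent plane.

    "Up" is the unit projection of global +z onto the plane perpendicular to
    the landmark normal, "left" the unit projection of global +x (+x is
    subject-left); "down"/"right" are their negatives.  For anterior-facing
    landmarks (normal along -y) this reduces to +/-z and +/-x.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    dirs = {}
    for key, axis in (("up", np.array([0.0, 0.0, 1.0])),
                      ("left", np.array([1.0, 0.0, 0.0]))):
        t = axis - np.dot(axis, n) * n
        norm = np.linalg.norm(t)
        if norm < 1e-9:
            raise ValueError(f"global {key} axis is parallel to the landmark normal")
        dirs[key] = t / norm
    dirs["down"] = -dirs["up"]
    dirs["right"] = -dirs["left"]
    return dirs


def consistency_check(mesh: TriangleMesh, region: TabletopRegion,
                      landmark: LandmarkDefinition | None = None,
                      offsets_px=DEFAULT_OFFSETS_PX,
                      directions: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Perturbation consistency of the CC point.

    The CC point is moved by each offset along each of the four tangent
    directions, snapped back to the surface, and used as a fresh starting
    point; ``delta_d`` is the voxel-space Euclidean distance between the
    second CC point and the original one, reported for every
    (offset, direction) cell.  A moved point that lands on a different patch
    is reported with its nonzero ``delta_d``, never suppressed.
    """
    landmark = landmark or get_landmark(region.landmark)
    cc0 = compute_cc_point(region, mesh)
    if directions is None:
        directions = tangent_directions(landmark.normal_unit)
    rows = []
    for off in offsets_px:
        row = {}
        for name, direction in directions.items():
            moved = cc0.voxel_coords + float(off) * np.asarray(direction, float)
            region2 = find_tabletop(mesh, moved, landmark,
                                    radius_px=region.radius_px, band_px=region.band_px)
            cc2 = compute_cc_point(region2, mesh)
            row[name] = float(np.linalg.norm(cc2.voxel_coords - cc0.voxel_coords))
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(list(offsets_px), name="offset_px"))
    table.columns.name = "direction"
    return table


# ---------------------------------------------------------------------------
# Tabular I/O


def read_starting_points(path: str | Path) -> pd.DataFrame:
    """Starting points as ``{landmark, x, y, z}`` rows from CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = {"landmark", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"starting-point table lacks columns {sorted(missing)}")
    return df


def cc_points_to_frame(points: list[CCPoint]) -> pd.DataFrame:
    return pd.DataFrame([
        {"landmark": p.landmark,
         "x_vox": p.voxel_coords[0], "y_vox": p.voxel_coords[1], "z_vox": p.voxel_coords[2],
         "x_mm": p.mm_coords[0], "y_mm": p.mm_coords[1], "z_mm": p.mm_coords[2],
         "d_mm": p.d, "n_members": p.n_members}
        for p in points])
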