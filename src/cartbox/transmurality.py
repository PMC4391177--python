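"""Infarct transmurality from short-axis segmentations, projected on the mesh.

Transmurality at an endocardial location is the fraction of the local wall
thickness occupied by scar (0 = viable wall, 1 = transmural infarct). It is
estimated with a chord construction per short-axis slice: a ray cast from the
cavity centroid through the vertex crosses the endocardial and epicardial
contours; transmurality is the scar length along that wall chord divided by
the wall length, clamped to [0, 1]. Vertices between slice planes blend the
two adjacent slice estimates linearly. The field is classified into the five
clinical bands (0, 0-25, 25-50, 50-75, 75-100 %), and the border zone is the
isocontour at a chosen threshold (default 50 %) — the preferred target for
intramyocardial injections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union

from .errors import InvalidInputError
from .geometry import SurfaceMesh

log = logging.getLogger(__name__)

CLASS_NAMES = ("T0", "T0_25", "T25_50", "T50_75", "T75_100")
BIN_EDGES = (0.0, 0.25, 0.50, 0.75, 1.0)


@dataclass
class Slice:
    """One short-axis segmentation slice at height ``z_mm``."""

    z_mm: float
    endo_polygon: np.ndarray
    epi_polygon: np.ndarray
    scar_polygons: list[np.ndarray] = field(default_factory=list)


class SegmentationStack:
    """Stack of short-axis contours (endocardium, epicardium, scar).

    Polygons are ordered 2-D point lists in mm, in the slice plane (the
    stack's z axis is the slice normal and must coincide with the mesh z
    axis). The endocardial contour must lie strictly inside the epicardial
    one; scar polygons must lie in the endo-epi annulus.
    """

    def __init__(self, slices: list[Slice], slice_spacing: float):
        if len(slices) < 3:
            raise InvalidInputError("a contour stack needs >= 3 slices")
        if slice_spacing <= 0:
            raise InvalidInputError("slice spacing must be positive")
        self.slices = sorted(slices, key=lambda s: s.z_mm)
        self.slice_spacing = float(slice_spacing)
        for s in self.slices:
            endo = Polygon(s.endo_polygon)
            epi = Polygon(s.epi_polygon)
            if not (endo.is_valid and epi.is_valid):
                raise InvalidInputError(
                    f"slice z={s.z_mm}: malformed contour polygon")
            if not epi.contains(endo):
                raise InvalidInputError(
                    f"slice z={s.z_mm}: endocardium not inside epicardium")
            annulus = epi.difference(endo).buffer(1e-6)
            for scar in s.scar_polygons:
                sp = Polygon(scar)
                if not sp.is_valid:
                    raise InvalidInputError(
                        f"slice z={s.z_mm}: malformed scar polygon")
                if not annulus.contains(sp.buffer(-1e-6)):
                    raise InvalidInputError(
                        f"slice z={s.z_mm}: scar outside the wall annulus")

    @property
    def z_values(self) -> np.ndarray:
        return np.array([s.z_mm for s in self.slices])

    def to_dict(self) -> dict:
        return {
            "spacing_mm": self.slice_spacing,
            "slices": [
                {"z_mm": s.z_mm,
                 "endo": np.asarray(s.endo_polygon).tolist(),
                 "epi": np.asarray(s.epi_polygon).tolist(),
                 "scar": [np.asarray(p).tolist() for p in s.scar_polygons]}
                for s in self.slices],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationStack":
        slices = [Slice(z_mm=float(s["z_mm"]),
                        endo_polygon=np.asarray(s["endo"], dtype=float),
                        epi_polygon=np.asarray(s["epi"], dtype=float),
                        scar_polygons=[np.asarray(p, dtype=float)
                                       for p in s.get("scar", [])])
                  for s in d["slices"]]
        return cls(slices, float(d["spacing_mm"]))


@dataclass
class TransmuralityField:
    """Per-vertex transmurality in [0, 1] with its 5-band labels."""

    values: np.ndarray
    class_labels: np.ndarray  # integer index into CLASS_NAMES

    def label_names(self) -> list[str]:
        return [CLASS_NAMES[i] for i in self.class_labels]


@dataclass
class BorderZone:
    """Isocontour of the transmurality field at ``threshold``.

    ``polylines`` are ordered 3-D point chains on the mesh surface; each
    point lies on a mesh edge where the linearly interpolated field equals
    the threshold.
    """

    threshold: float
    polylines: list[np.ndarray]


def _slice_geoms(sl: Slice):
    """Shapely geometry for one slice, built once per slice."""
    endo = Polygon(sl.endo_polygon)
    epi = Polygon(sl.epi_polygon)
    scar = (unary_union([Polygon(s) for s in sl.scar_polygons])
            if sl.scar_polygons else None)
    centroid = np.asarray(endo.centroid.coords[0])
    return endo, epi, scar, centroid


def _chord_transmurality(geoms, xy: np.ndarray, ray_length: float):
    """Transmurality at in-plane point ``xy`` by centroid-ray interrogation.

    Returns NaN when the ray fails to cross both contours.
    """
    endo, epi, scar_union, centroid = geoms
    direction = xy - centroid
    nrm = np.linalg.norm(direction)
    if nrm < 1e-9:
        return np.nan
    direction = direction / nrm
    far = centroid + direction * ray_length
    ray = LineString([centroid, far])

    def first_crossing(ring):
        hit = ray.intersection(ring)
        if hit.is_empty:
            return None
        pts = []
        for geom in getattr(hit, "geoms", [hit]):
            pts.extend(np.asarray(geom.coords))
        t = [np.dot(np.asarray(q) - centroid, direction) for q in pts]
        return min(t)

    r_endo = first_crossing(endo.exterior)
    r_epi = first_crossing(epi.exterior)
    if r_endo is None or r_epi is None or r_epi <= r_endo + 1e-12:
        return np.nan
    if scar_union is None:
        return 0.0
    p0 = centroid + direction * r_endo
    p1 = centroid + direction * r_epi
    wall = LineString([p0, p1])
    scar_len = wall.intersection(scar_union).length
    return float(np.clip(scar_len / wall.length, 0.0, 1.0))


def _slice_values(stack: SegmentationStack, mesh: SurfaceMesh, needed):
    """Per-slice transmurality at each vertex's (x, y), evaluated only for
    the (slice, vertex) pairs in ``needed`` (a dict slice -> vertex ids)."""
    span = max(np.abs(np.concatenate(
        [np.asarray(s.epi_polygon).ravel() for s in stack.slices])))
    ray_length = 4.0 * span + 10.0
    vals = np.full((len(stack.slices), len(mesh.vertices)), np.nan)
    for i, vertex_ids in needed.items():
        geoms = _slice_geoms(stack.slices[i])
        for j in vertex_ids:
            vals[i, j] = _chord_transmurality(geoms, mesh.vertices[j, :2],
                                              ray_length)
    return vals


def compute_transmurality(stack: SegmentationStack,
                          mesh: SurfaceMesh) -> TransmuralityField:
    """Project infarct transmurality from the contour stack onto the mesh.

    Each endocardial vertex is interrogated in its slice plane by the
    centroid-ray chord construction; vertices lying between slice planes
    blend the two adjacent slices linearly in z. Vertices whose chord fails
    (no epicardial crossing) inherit the value of the nearest valid vertex,
    with a logged warning. The mesh may overhang the stack's z range by at
    most one slice spacing on either end.
    """
    z = stack.z_values
    vz = mesh.vertices[:, 2]
    if vz.min() < z.min() - stack.slice_spacing - 1e-6 or \
            vz.max() > z.max() + stack.slice_spacing + 1e-6:
        raise InvalidInputError(
            "mesh extends more than one slice spacing beyond the stack")
    upper = np.clip(np.searchsorted(z, vz), 1, len(z) - 1)
    needed: dict[int, list[int]] = {}
    for j, i in enumerate(upper):
        needed.setdefault(int(i) - 1, []).append(j)
        needed.setdefault(int(i), []).append(j)
    per_slice = _slice_values(stack, mesh, needed)
    values = np.empty(len(mesh.vertices))
    for j in range(len(mesh.vertices)):
        zj = vz[j]
        i = int(upper[j])
        z0, z1 = z[i - 1], z[i]
        w = float(np.clip((zj - z0) / (z1 - z0), 0.0, 1.0))
        v0, v1 = per_slice[i - 1, j], per_slice[i, j]
        if np.isnan(v0) and np.isnan(v1):
            values[j] = np.nan
        elif np.isnan(v0):
            values[j] = v1
        elif np.isnan(v1):
            values[j] = v0
        else:
            values[j] = (1 - w) * v0 + w * v1
    bad = np.isnan(values)
    if bad.any():
        log.warning("chord interrogation failed at %d vertices; using "
                    "nearest valid neighbour", int(bad.sum()))
        good_ix = np.flatnonzero(~bad)
        if good_ix.size == 0:
            raise InvalidInputError("chord interrogation failed everywhere")
        from scipy.spatial import cKDTree
        tree = cKDTree(mesh.vertices[good_ix])
        _, nn = tree.query(mesh.vertices[bad])
        values[bad] = values[good_ix[nn]]
    values = np.clip(values, 0.0, 1.0)
    return TransmuralityField(values=values, class_labels=classify(values))


def classify(values) -> np.ndarray:
    """Five-band labels: 0 -> T0, (0,0.25] -> T0_25, ..., (0.75,1] -> T75_100.

    Exactly-zero transmurality is its own class (viable wall); the remaining
    bands are half-open on the left. Returns integer indices into
    ``CLASS_NAMES``.
    """
    v = np.asarray(values, dtype=float)
    if ((v < 0) | (v > 1)).any() or not np.isfinite(v).all():
        raise InvalidInputError("transmurality values must lie in [0, 1]")
    labels = np.zeros(v.shape, dtype=np.int64)
    for k, (lo, hi) in enumerate(zip(BIN_EDGES[:-1], BIN_EDGES[1:]),
                                 start=1):
        labels[(v > lo) & (v <= hi)] = k
    return labels


def triangle_labels(mesh: SurfaceMesh, labels: np.ndarray) -> np.ndarray:
    """Label of each triangle: majority vote of its vertices, ties to the
    lower class."""
    lv = np.asarray(labels)[mesh.faces]  # (m, 3)
    out = np.empty(len(mesh.faces), dtype=np.int64)
    for i, row in enumerate(lv):
        vals, counts = np.unique(row, return_counts=True)
        maxc = counts.max()
        out[i] = vals[counts == maxc].min()
    return out


def class_areas(mesh: SurfaceMesh, labels: np.ndarray):
    """Endocardial area per transmurality class.

    Each triangle is assigned to its majority vertex class; areas therefore
    sum exactly to the total mesh area. Returns
    ``(area_cm2: {name: cm2}, percent: {name: %})``.
    """
    if len(labels) != len(mesh.vertices):
        raise InvalidInputError("labels must cover all vertices")
    tl = triangle_labels(mesh, labels)
    areas = mesh.triangle_areas_mm2()
    total = areas.sum()
    area_cm2 = {}
    percent = {}
    for k, name in enumerate(CLASS_NAMES):
        a = float(areas[tl == k].sum())
        area_cm2[name] = a / 100.0
        percent[name] = 100.0 * a / total
    return area_cm2, percent


def border_zone(mesh: SurfaceMesh, values, threshold: float = 0.5
                ) -> BorderZone:
    """Marching-triangles isocontour of the per-vertex field at ``threshold``.

    Edge crossings are placed by linear interpolation; the per-triangle
    segments are chained into ordered polylines (closed loops where the
    contour is closed). Returns an empty set of polylines when the field
    never crosses the threshold.
    """
    v = np.asarray(values, dtype=float)
    above = v > threshold
    segments = []  # ((edge_a, sa), (edge_b, sb)) with edge = sorted pair
    for tri in mesh.faces:
        crossings = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if above[a] != above[b]:
                s = (threshold - v[a]) / (v[b] - v[a])
                edge = (int(min(a, b)), int(max(a, b)))
                s = s if a < b else 1.0 - s
                crossings.append((edge, float(s)))
        if len(crossings) == 2:
            segments.append(tuple(crossings))
    if not segments:
        return BorderZone(threshold=float(threshold), polylines=[])

    def node_key(edge, s):
        return (edge, round(s, 12))

    # adjacency between crossing nodes
    adj: dict[tuple, list[tuple]] = {}
    for n1, n2 in segments:
        k1, k2 = node_key(*n1), node_key(*n2)
        adj.setdefault(k1, []).append(k2)
        adj.setdefault(k2, []).append(k1)

    def node_point(key):
        (a, b), s = key
        return (1 - s) * mesh.vertices[a] + s * mesh.vertices[b]

    polylines = []
    visited: set[tuple] = set()
    # open chains first (endpoints with degree 1), then closed loops
    for start in sorted(adj, key=lambda k: (len(adj[k]) != 1, k)):
        if start in visited:
            continue
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = [n for n in adj[cur] if n not in visited]
            if not nxt:
                break
            cur = nxt[0]
            chain.append(cur)
            visited.add(cur)
        if len(chain) >= 2:
            pts = np.stack([node_point(k) for k in chain])
            if len(adj[chain[-1]]) > 1 and chain[0] in adj[chain[-1]] \
                    and len(chain) > 2:
                pts = np.vstack([pts, pts[0]])  # close the loop explicitly
            polylines.append(pts)
    return BorderZone(threshold=float(threshold), polylines=polylines)
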