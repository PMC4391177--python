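"""Projection of catheter scalars onto the mesh, bullseye maps, densities.

Measured electrical/mechanical scalars (unipolar/bipolar voltage, linear
local shortening) are attached to each point's surface footpoint and spread
to mesh vertices by distance-weighted local linear interpolation inside a
finite support radius; vertices with no nearby measurement stay masked
rather than extrapolated. The bullseye map is the standard polar display of
the left ventricle: apex at the centre (radius 0), basal rim at the edge
(radius 1), circumferential position as the angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError
from .geometry import SurfaceMesh, points_to_surface
from .registration import EMMDataset
from .transmurality import CLASS_NAMES, BorderZone, triangle_labels

_EXACT_HIT_MM = 1e-9


def project_scalar(dataset: EMMDataset, mesh: SurfaceMesh, scalar_name: str,
                   radius_mm: float = 15.0):
    """Interpolate a per-point scalar onto mesh vertices.

    Every non-excluded point carrying ``scalar_name`` contributes its value
    at its surface footpoint; each vertex within ``radius_mm`` of at least
    one footpoint receives a distance-weighted local linear fit (moving
    least squares, inverse-square distance weights) of the in-range values,
    evaluated at the vertex and clamped to the overall range of the input
    scalars so the projection never overshoots the measurements. Neighbourhoods
    too small or too degenerate for a linear fit fall back to the weighted
    mean. Returns ``(values, mask)`` where masked-out vertices (no footpoint
    in range) hold NaN.
    """
    pts = [p for p in dataset.used_points
           if getattr(p, scalar_name, None) is not None]
    if not pts:
        raise InsufficientDataError(
            f"no usable points carry scalar {scalar_name!r}")
    pos = np.stack([p.position for p in pts])
    vals = np.array([float(getattr(p, scalar_name)) for p in pts])
    _, feet = points_to_surface(pos, mesh)
    foot_pos = np.stack([f.position for f in feet])

    diff = mesh.vertices[:, None, :] - foot_pos[None, :, :]
    d = np.linalg.norm(diff, axis=2)  # (n_vertices, n_points)
    in_range = d <= radius_mm
    out = np.full(len(mesh.vertices), np.nan)
    mask = in_range.any(axis=1)
    exact = (d < _EXACT_HIT_MM) & in_range
    has_exact = exact.any(axis=1)
    lo, hi = vals.min(), vals.max()
    for i in np.flatnonzero(mask):
        sel = in_range[i]
        if has_exact[i]:
            out[i] = vals[np.argmax(exact[i])]
            continue
        w = 1.0 / d[i, sel] ** 2
        est = _weighted_linear_estimate(foot_pos[sel] - mesh.vertices[i],
                                        vals[sel], w)
        out[i] = float(np.clip(est, lo, hi))
    return out, mask


def _weighted_linear_estimate(rel_pos, vals, w):
    """Weighted linear fit value at the origin; weighted mean on fallback.

    Three non-collinear footpoints already determine the restriction of a
    linear field to their plane (the minimum-norm solution has no gradient
    normal to it), so the fit is used whenever the neighbourhood spans a
    plane; degenerate neighbourhoods fall back to the weighted mean.
    """
    if len(vals) >= 3:
        X = np.hstack([np.ones((len(vals), 1)), rel_pos])
        sw = np.sqrt(w)
        beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], vals * sw,
                                           rcond=None)
        if rank >= 3 and np.isfinite(beta[0]):
            return beta[0]
    return float(np.dot(w, vals) / w.sum())


@dataclass
class BullseyeMap:
    """Polar parameterisation of the endocardium with a rasterised scalar.

    ``vertex_polar`` holds (radius in [0,1], angle in [0,2pi)) per vertex;
    ``raster`` is a masked 2-D image over the unit disc (NaN outside
    coverage); ``overlay_contours`` are border-zone polylines mapped through
    the same parameterisation, as (x, y) disc coordinates.
    """

    vertex_polar: np.ndarray
    raster: np.ndarray
    extent: tuple = (-1.0, 1.0, -1.0, 1.0)
    overlay_contours: list[np.ndarray] = field(default_factory=list)
    reference_direction: np.ndarray | None = None


def _polar_coords(points, mesh: SurfaceMesh, reference_direction=None):
    """Map 3-D points near the surface to (radius, angle).

    Radius is the normalised height above the apex along the long axis
    (apex 0, mean basal-rim height 1); angle is the circumferential position
    about the long axis measured from a fixed in-plane reference direction
    (toward the right coronary ostium when supplied).
    """
    lz = mesh.long_axis
    apex = mesh.vertices[mesh.apex_vertex]
    if not mesh.boundary_loops:
        raise InvalidInputError("bullseye needs an open basal rim")
    rim = mesh.vertices[mesh.boundary_loops[0]]
    h_rim = float(np.dot(rim - apex, lz).mean())
    if h_rim <= 0:
        raise InvalidInputError("basal rim is not above the apex along the "
                                "long axis")
    if reference_direction is None:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, lz)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
    else:
        ref = np.asarray(reference_direction, dtype=float)
    e1 = ref - np.dot(ref, lz) * lz
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(lz, e1)

    rel = np.atleast_2d(points) - apex
    h = rel @ lz
    radius = np.clip(h / h_rim, 0.0, 1.0)
    x = rel @ e1
    y = rel @ e2
    angle = np.mod(np.arctan2(y, x), 2 * np.pi)
    return np.stack([radius, angle], axis=1), e1


def bullseye(mesh: SurfaceMesh, values, overlay: BorderZone | None = None,
             resolution: int = 200, reference_direction=None) -> BullseyeMap:
    """Rasterise a per-vertex scalar into a bullseye (polar disc) image.

    The raster is filled triangle by triangle with barycentric interpolation
    in disc coordinates; triangles straddling the angular seam are unwrapped
    before rasterisation. NaN vertex values leave their triangles masked.
    """
    v = np.asarray(values, dtype=float)
    if len(v) != len(mesh.vertices):
        raise InvalidInputError("values must cover all vertices")
    polar, e1 = _polar_coords(mesh.vertices, mesh, reference_direction)
    r, th = polar[:, 0], polar[:, 1]

    n = resolution
    img = np.full((n, n), np.nan)
    # pixel centres over [-1, 1]^2
    axis = (np.arange(n) + 0.5) / n * 2.0 - 1.0

    def disc_xy(rr, tt):
        return rr * np.cos(tt), rr * np.sin(tt)

    for tri in mesh.faces:
        if np.isnan(v[tri]).any():
            continue
        tt = th[tri].copy()
        # unwrap around the first corner so the triangle is contiguous
        tt[1:] = tt[0] + np.mod(tt[1:] - tt[0] + np.pi, 2 * np.pi) - np.pi
        xs, ys = disc_xy(r[tri], tt)
        # pixel bounding box
        i0 = np.searchsorted(axis, min(xs) - 2.0 / n)
        i1 = np.searchsorted(axis, max(xs) + 2.0 / n)
        j0 = np.searchsorted(axis, min(ys) - 2.0 / n)
        j1 = np.searchsorted(axis, max(ys) + 2.0 / n)
        if i0 >= i1 or j0 >= j1:
            continue
        px, py = np.meshgrid(axis[i0:i1], axis[j0:j1], indexing="ij")
        det = (ys[1] - ys[2]) * (xs[0] - xs[2]) + \
              (xs[2] - xs[1]) * (ys[0] - ys[2])
        if abs(det) < 1e-15:
            continue
        l0 = ((ys[1] - ys[2]) * (px - xs[2]) +
              (xs[2] - xs[1]) * (py - ys[2])) / det
        l1 = ((ys[2] - ys[0]) * (px - xs[2]) +
              (xs[0] - xs[2]) * (py - ys[2])) / det
        l2 = 1.0 - l0 - l1
        inside = (l0 >= -1e-9) & (l1 >= -1e-9) & (l2 >= -1e-9)
        val = l0 * v[tri[0]] + l1 * v[tri[1]] + l2 * v[tri[2]]
        block = img[i0:i1, j0:j1]
        block[inside] = val[inside]
        img[i0:i1, j0:j1] = block

    contours = []
    if overlay is not None:
        for line in overlay.polylines:
            pol, _ = _polar_coords(line, mesh, reference_direction)
            xy = np.stack([pol[:, 0] * np.cos(pol[:, 1]),
                           pol[:, 0] * np.sin(pol[:, 1])], axis=1)
            contours.append(xy)
    return BullseyeMap(vertex_polar=polar, raster=img,
                       overlay_contours=contours, reference_direction=e1)


def render_bullseye(bmap: BullseyeMap, path, title: str = "",
                    cmap: str = "turbo", vmin=None, vmax=None):
    """Write the bullseye raster to a PNG plus a JSON metadata sidecar."""
    import json

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = bmap.raster
    finite = np.isfinite(data)
    lo = float(np.nanmin(data)) if vmin is None and finite.any() else vmin
    hi = float(np.nanmax(data)) if vmax is None and finite.any() else vmax
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(data.T, origin="lower", extent=bmap.extent, cmap=cmap,
                   vmin=lo, vmax=hi)
    for xy in bmap.overlay_contours:
        ax.plot(xy[:, 0], xy[:, 1], "k-", lw=1.5)
    circ = plt.Circle((0, 0), 1.0, fill=False, color="0.3", lw=1)
    ax.add_patch(circ)
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    meta = {"vmin": lo, "vmax": hi, "extent": list(bmap.extent),
            "radius": "normalised long-axis height, apex=0 rim=1",
            "angle_reference":
                None if bmap.reference_direction is None
                else [float(x) for x in bmap.reference_direction]}
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


@dataclass
class DensityReport:
    """Per-transmurality-class point counts, areas and densities."""

    per_class: dict
    anova_p: float | None = None

    def to_dict(self) -> dict:
        d = {"per_class": self.per_class}
        if self.anova_p is not None:
            d["anova_p"] = self.anova_p
        return d


def point_classes(dataset: EMMDataset, mesh: SurfaceMesh,
                  labels: np.ndarray) -> np.ndarray:
    """Transmurality class of each non-excluded point (via its footpoint's
    majority-label triangle)."""
    used = dataset.used_points
    if not used:
        raise InsufficientDataError("no usable points")
    tl = triangle_labels(mesh, labels)
    pos = np.stack([p.position for p in used])
    _, feet = points_to_surface(pos, mesh)
    return np.array([tl[f.face_index] for f in feet], dtype=np.int64)


def density_report(dataset: EMMDataset, mesh: SurfaceMesh,
                   labels: np.ndarray, area_cm2: dict) -> DensityReport:
    """Points per cm^2 in each transmurality class for one map.

    A class with zero area but at least one point is reported with infinite
    density; a class with zero area and zero points with density 0.
    """
    cls = point_classes(dataset, mesh, labels)
    per_class = {}
    for k, name in enumerate(CLASS_NAMES):
        npts = int((cls == k).sum())
        a = float(area_cm2.get(name, 0.0))
        if a > 0:
            dens = npts / a
        else:
            dens = float("inf") if npts > 0 else 0.0
        per_class[name] = {"n_points": npts, "area_cm2": a,
                           "density_points_per_cm2": dens}
    return DensityReport(per_class=per_class)


def density_anova(reports: list[DensityReport]) -> float | None:
    """One-way ANOVA of point density across transmurality classes.

    Groups are the five classes; observations are the per-map densities.
    Classes absent from a map (zero area) contribute no observation, and a
    p-value is only computed when at least two classes have two or more
    observations each.
    """
    groups = []
    for name in CLASS_NAMES:
        obs = [r.per_class[name]["density_points_per_cm2"]
               for r in reports
               if r.per_class[name]["area_cm2"] > 0]
        if len(obs) >= 2:
            groups.append(obs)
    if len(groups) < 2:
        return None
    return float(stats.f_oneway(*groups).pvalue)
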