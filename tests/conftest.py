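import numpy as np
import pytest

from cartbox import PhantomSpec, SurfaceMesh, make_lv, sample_emm
from cartbox.geometry import _closest_on_triangles


@pytest.fixture(scope="session")
def default_phantom():
    """Default LV phantom: endo/epi meshes, contour stack, ground truth."""
    spec = PhantomSpec()
    endo, epi, stack, truth = make_lv(spec)
    return spec, endo, epi, stack, truth


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse phantom for the heavier statistical tests."""
    spec = PhantomSpec(n_rings=10, n_circumferential=20)
    endo, epi, stack, truth = make_lv(spec)
    return spec, endo, epi, stack, truth


def planar_patch(nx=11, ny=11, size_x=100.0, size_y=100.0):
    """Rectangular z=0 grid mesh, corner at the origin."""
    xs = np.linspace(0, size_x, nx)
    ys = np.linspace(0, size_y, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)], axis=1)
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01 = v00 + 1
            v10 = v00 + ny
            v11 = v10 + 1
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    return SurfaceMesh(verts, faces, long_axis=[1, 0, 0], apex_vertex=0)


@pytest.fixture
def patch():
    return planar_patch()


def brute_force_distance(p, mesh):
    """Exhaustive per-triangle minimum distance — the independent oracle for
    the spatially accelerated implementation."""
    a, b, c = mesh.triangle_corners
    pts, _ = _closest_on_triangles(np.asarray(p, dtype=float)[None, :],
                                   a, b, c)
    d2 = np.einsum("ij,ij->i", pts - p, pts - p)
    k = int(np.argmin(d2))
    return float(np.sqrt(d2[k])), k


def brute_force_distance_independent(p, mesh):
    """Fully independent per-triangle distance: scalar projection logic,
    shares no code with the library's closest-point routine."""
    p = np.asarray(p, dtype=float)
    best = np.inf
    for tri in mesh.faces:
        a, b, c = mesh.vertices[tri]
        best = min(best, _point_triangle_distance(p, a, b, c))
    return best


def _point_triangle_distance(p, a, b, c):
    # project onto the triangle plane, then clamp to the triangle
    n = np.cross(b - a, c - a)
    n = n / np.linalg.norm(n)
    q = p - np.dot(p - a, n) * n
    # barycentric of q
    v0, v1, v2 = b - a, c - a, q - a
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    den = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    if v >= 0 and w >= 0 and v + w <= 1:
        return float(np.linalg.norm(p - q))
    return min(_point_segment_distance(p, a, b),
               _point_segment_distance(p, b, c),
               _point_segment_distance(p, c, a))


def _point_segment_distance(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / (ab @ ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def ray_parity_inside(points, vertices, faces, rng):
    """Ray-casting parity oracle on a closed triangle soup."""
    out = np.zeros(len(points), dtype=bool)
    a = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - a
    e2 = vertices[faces[:, 2]] - a
    for i, p in enumerate(points):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # Moller-Trumbore over all triangles
        h = np.cross(direction, e2)
        det = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(det) > 1e-12
        s = p - a
        u = np.einsum("ij,ij->i", s, h) / np.where(ok, det, 1.0)
        q = np.cross(s, e1)
        v = np.dot(q, direction) / np.where(ok, det, 1.0)
        t = np.einsum("ij,ij->i", e2, q) / np.where(ok, det, 1.0)
        hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        out[i] = hits.sum() % 2 == 1
    return out
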