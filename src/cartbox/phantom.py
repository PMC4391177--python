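"""Synthetic left-ventricle phantom with known ground truth.

Stands in for in-vivo datasets: a truncated-ellipsoid endocardium/epicardium
pair (apex closed, base open), a short-axis contour stack with a wedge-shaped
subendocardial scar of prescribed angular extent and depth fraction, and a
noisy electromechanical-map sampling of the endocardium carried into a
"catheter" frame by the inverse of a known rigid transform. Every quantity
the pipeline estimates (transform, transmurality, landmark positions) is
available as ground truth, so registration and transmurality recovery can be
verified end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .geometry import SurfaceMesh
from .registration import EMMDataset, EMMPoint, RigidTransform
from .transmurality import SegmentationStack, Slice


@dataclass
class WedgeSpec:
    """Wedge-shaped scar: angular sector, wall-depth fraction, z range."""

    angle_start_deg: float = 30.0
    angle_extent_deg: float = 90.0
    depth_fraction: float = 0.6
    apicobasal_range: tuple | None = None  # (z_lo, z_hi) mm, None = full

    def __post_init__(self):
        if not 0.0 <= self.depth_fraction <= 1.0:
            raise InvalidInputError("depth_fraction must lie in [0, 1]")
        if not 0.0 < self.angle_extent_deg <= 360.0:
            raise InvalidInputError("angle_extent_deg must be in (0, 360]")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic LV study.

    Defaults emulate a porcine left ventricle at the scale of the intended
    application: endocardial semi-axes 25 x 25 x 45 mm, 10 mm wall, basal
    truncation keeping 80 % of the long axis, ~66 mapping points with 1 mm
    isotropic catheter noise, contours every 5 mm.
    """

    endo_semi_axes: tuple = (25.0, 25.0, 45.0)
    wall_thickness: float = 10.0
    truncation_fraction: float = 0.8
    wedge: WedgeSpec = field(default_factory=WedgeSpec)
    n_emm_points: int = 66
    noise_sigma: float = 1.0
    true_transform: RigidTransform = field(
        default_factory=RigidTransform.identity)
    seed: int = 0
    n_rings: int = 24
    n_circumferential: int = 48
    slice_spacing: float = 5.0
    n_polygon_points: int = 72
    healthy_unipolar_mV: float = 12.0
    scar_unipolar_mV: float = 4.0
    healthy_bipolar_mV: float = 3.0
    scar_bipolar_mV: float = 0.8
    healthy_lls_pct: float = 12.0
    scar_lls_pct: float = 2.0
    voltage_noise_mV: float = 0.5
    scar_voltage_coupled: bool = True

    def __post_init__(self):
        if min(self.endo_semi_axes) <= 0 or self.wall_thickness <= 0:
            raise InvalidInputError("semi-axes and wall must be positive")
        if not 0.1 <= self.truncation_fraction <= 1.0:
            raise InvalidInputError("truncation_fraction must be in "
                                    "[0.1, 1]")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    transform: RigidTransform
    transmurality: np.ndarray
    landmarks: dict

    def landmark_array(self) -> np.ndarray:
        return np.stack([self.landmarks[k]
                         for k in ("apex", "left_ostium", "right_ostium")])


def _ellipsoid_shell(semi_axes, z_top, n_rings, n_circ):
    """Open-top ellipsoid mesh from the south pole up to plane z = z_top."""
    a, b, c = semi_axes
    phi_max = np.arccos(np.clip(-z_top / c, -1.0, 1.0))
    verts = [np.array([0.0, 0.0, -c])]
    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    for i in range(1, n_rings + 1):
        phi = phi_max * i / n_rings
        ring = np.stack([a * np.sin(phi) * np.cos(theta),
                         b * np.sin(phi) * np.sin(theta),
                         np.full(n_circ, -c * np.cos(phi))], axis=1)
        verts.append(ring)
    vertices = np.vstack([verts[0][None, :], *verts[1:]])
    faces = []
    # apex fan
    for j in range(n_circ):
        faces.append([0, 1 + j, 1 + (j + 1) % n_circ])
    # quad strips
    for i in range(n_rings - 1):
        r0 = 1 + i * n_circ
        r1 = r0 + n_circ
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            faces.append([r0 + j, r1 + j, r1 + j1])
            faces.append([r0 + j, r1 + j1, r0 + j1])
    return vertices, np.asarray(faces, dtype=np.int64)


def _ellipse_ring(a, b, c, z, n):
    s = np.sqrt(max(1.0 - (z / c) ** 2, 0.0))
    th = 2 * np.pi * np.arange(n) / n
    return np.stack([a * s * np.cos(th), b * s * np.sin(th)], axis=1)


def _in_sector(theta_deg, start, extent, tol=1e-9):
    rel = np.mod(theta_deg - start, 360.0)
    return (rel <= extent + tol) | (rel >= 360.0 - tol)


def true_transmurality(vertices, spec: PhantomSpec) -> np.ndarray:
    """Analytic wedge transmurality at endocardial positions (MRI frame)."""
    a, b, c = spec.endo_semi_axes
    w = spec.wedge
    z_lo, z_hi = w.apicobasal_range if w.apicobasal_range is not None \
        else (-c - 1.0, c + 1.0)
    v = np.atleast_2d(vertices)
    theta = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    in_wedge = _in_sector(theta, w.angle_start_deg, w.angle_extent_deg) & \
        (v[:, 2] >= z_lo - 1e-9) & (v[:, 2] <= z_hi + 1e-9)
    return np.where(in_wedge, w.depth_fraction, 0.0)


def _wedge_polygon(spec: PhantomSpec, z: float):
    """Annular-sector scar polygon at slice height z, or None."""
    a, b, c = spec.endo_semi_axes
    wall = spec.wall_thickness
    ae, be, ce = a + wall, b + wall, c + wall
    w = spec.wedge
    if w.depth_fraction <= 0:
        return None
    z_lo, z_hi = w.apicobasal_range if w.apicobasal_range is not None \
        else (-c - 1.0, c + 1.0)
    if not (z_lo - 1e-9 <= z <= z_hi + 1e-9):
        return None
    s_endo = np.sqrt(max(1.0 - (z / c) ** 2, 0.0))
    s_epi = np.sqrt(max(1.0 - (z / ce) ** 2, 0.0))
    n_arc = max(8, int(spec.n_polygon_points * w.angle_extent_deg / 360.0))
    th = np.radians(w.angle_start_deg +
                    w.angle_extent_deg * np.linspace(0, 1, n_arc + 1))
    inner = np.stack([a * s_endo * np.cos(th), b * s_endo * np.sin(th)],
                     axis=1)
    outer_full = np.stack([ae * s_epi * np.cos(th), be * s_epi * np.sin(th)],
                          axis=1)
    d = w.depth_fraction
    outer = inner + d * (outer_full - inner)
    return np.vstack([inner, outer[::-1]])


def make_lv(spec: PhantomSpec):
    """Build the phantom: endo/epi meshes, contour stack, ground truth.

    Returns ``(endo, epi, stack, truth)``. The endocardial mesh has a single
    basal boundary loop, vertex 0 at the apex, and the +z long axis; ground
    truth carries the true transform, per-vertex wedge transmurality, and
    the three landmark positions (apex, two mock ostia on the basal rim 90
    degrees apart).
    """
    a, b, c = spec.endo_semi_axes
    wall = spec.wall_thickness
    z_top = -c + spec.truncation_fraction * 2.0 * c
    if z_top >= c:
        z_top = c - 1e-6
    endo_v, endo_f = _ellipsoid_shell((a, b, c), z_top, spec.n_rings,
                                      spec.n_circumferential)
    epi_v, epi_f = _ellipsoid_shell((a + wall, b + wall, c + wall), z_top,
                                    spec.n_rings, spec.n_circumferential)
    endo = SurfaceMesh(endo_v, endo_f, long_axis=[0, 0, 1], apex_vertex=0)
    epi = SurfaceMesh(epi_v, epi_f, long_axis=[0, 0, 1], apex_vertex=0)

    # contour stack: slices from just above the endocardial apex to the base
    z0 = -c + 2.0
    n_slices = max(3, int(np.floor((z_top - z0) / spec.slice_spacing)) + 1)
    zs = z_top - spec.slice_spacing * np.arange(n_slices)[::-1]
    slices = []
    n_poly = spec.n_polygon_points
    for z in zs:
        endo_poly = _ellipse_ring(a, b, c, z, n_poly)
        epi_poly = _ellipse_ring(a + wall, b + wall, c + wall, z, n_poly)
        scar = _wedge_polygon(spec, z)
        slices.append(Slice(z_mm=float(z), endo_polygon=endo_poly,
                            epi_polygon=epi_poly,
                            scar_polygons=[] if scar is None else [scar]))
    stack = SegmentationStack(slices, spec.slice_spacing)

    # landmarks: apex + two mock coronary ostia on the basal rim, 90 deg
    # apart (right ostium at the angular reference direction)
    s_top = np.sqrt(max(1.0 - (z_top / c) ** 2, 0.0))
    right_ostium = np.array([a * s_top, 0.0, z_top])
    left_ostium = np.array([0.0, b * s_top, z_top])
    truth = GroundTruth(
        transform=spec.true_transform,
        transmurality=true_transmurality(endo_v, spec),
        landmarks={"apex": endo_v[0].copy(),
                   "left_ostium": left_ostium,
                   "right_ostium": right_ostium})
    return endo, epi, stack, truth


def _area_uniform_surface_samples(mesh: SurfaceMesh, n: int, rng):
    areas = mesh.triangle_areas_mm2()
    tri = rng.choice(len(areas), size=n, p=areas / areas.sum())
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    u = 1.0 - r1
    v = r1 * (1.0 - r2)
    w = r1 * r2
    a, bb, cc = mesh.triangle_corners
    return (u[:, None] * a[tri] + v[:, None] * bb[tri]
            + w[:, None] * cc[tri])


def sample_emm(endo: SurfaceMesh, truth: GroundTruth,
               spec: PhantomSpec) -> EMMDataset:
    """Simulate a catheter map of the phantom endocardium (catheter frame).

    ``n_emm_points`` surface-uniform samples are displaced by isotropic
    Gaussian noise (emulating catheter-tip and respiratory jitter) and moved
    by the inverse of the true transform into the catheter frame; three
    noise-free landmark points (apex, left/right ostium) are appended and
    tagged. Voltage and shortening scalars follow a linear healthy-to-scar
    ramp in true transmurality plus Gaussian noise when
    ``scar_voltage_coupled``, and are scar-independent otherwise (emulating
    the poor voltage/scar agreement seen in vivo).
    """
    if spec.n_emm_points < 4:
        raise InvalidInputError("need at least 4 EMM points")
    rng = np.random.default_rng(spec.seed)
    pos = _area_uniform_surface_samples(endo, spec.n_emm_points, rng)
    t_true = true_transmurality(pos, spec)
    noisy = pos + rng.normal(0.0, spec.noise_sigma, pos.shape)
    inv = spec.true_transform.inverse()
    noisy = inv.apply(noisy)

    if spec.scar_voltage_coupled:
        level = t_true
    else:
        level = rng.random(len(pos))
    uni = spec.healthy_unipolar_mV - \
        (spec.healthy_unipolar_mV - spec.scar_unipolar_mV) * level
    bip = spec.healthy_bipolar_mV - \
        (spec.healthy_bipolar_mV - spec.scar_bipolar_mV) * level
    lls = spec.healthy_lls_pct - \
        (spec.healthy_lls_pct - spec.scar_lls_pct) * level
    uni = np.clip(uni + rng.normal(0, spec.voltage_noise_mV, len(pos)), 0,
                  None)
    bip = np.clip(bip + rng.normal(0, spec.voltage_noise_mV, len(pos)), 0,
                  None)
    lls = lls + rng.normal(0, spec.voltage_noise_mV, len(pos))

    points = [EMMPoint(id=i, position=noisy[i],
                       unipolar_mV=float(uni[i]), bipolar_mV=float(bip[i]),
                       lls_percent=float(lls[i]))
              for i in range(spec.n_emm_points)]
    next_id = spec.n_emm_points
    for tag in ("apex", "left_ostium", "right_ostium"):
        points.append(EMMPoint(id=next_id,
                               position=inv.apply(truth.landmarks[tag]),
                               tag=tag))
        next_id += 1
    return EMMDataset(points)


def inject_outflow_outliers(dataset: EMMDataset, endo: SurfaceMesh,
                            truth: GroundTruth, n_outliers: int,
                            offset_mm: float = 20.0,
                            seed: int = 0) -> tuple[EMMDataset, list[int]]:
    """Append mock outflow-tract points ``offset_mm`` basal of the rim.

    The outliers live outside the capped cavity (catheter points beyond the
    imaged ventricle); they are placed in the catheter frame like the rest
    of the dataset. Returns the augmented dataset and the outlier ids.
    """
    rng = np.random.default_rng(seed)
    rim = endo.vertices[endo.boundary_loops[0]]
    inv = truth.transform.inverse()
    base_id = max(p.id for p in dataset.points) + 1
    points = list(dataset.points)
    ids = []
    for k in range(n_outliers):
        anchor = rim[rng.integers(len(rim))]
        p = anchor + endo.long_axis * (offset_mm + 2.0 * rng.random())
        points.append(EMMPoint(id=base_id + k, position=inv.apply(p)))
        ids.append(base_id + k)
    return EMMDataset(points, set(dataset.excluded_ids)), ids


def random_rigid_transform(rng, max_angle_deg: float = 8.0,
                           max_translation_mm: float = 10.0
                           ) -> RigidTransform:
    """Random proper rigid motion with per-axis angles and translation
    bounded by the given magnitudes."""
    from scipy.spatial.transform import Rotation

    ang = rng.uniform(-max_angle_deg, max_angle_deg, 3)
    R = Rotation.from_euler("XYZ", ang, degrees=True).as_matrix()
    t = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    return RigidTransform(R, t)
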