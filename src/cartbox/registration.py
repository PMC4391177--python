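"""Rigid registration of catheter (EMM) point clouds onto an MRI surface mesh.

Three phases, mirroring the clinical workflow: (1) coarse landmark alignment
by weighted closed-form least squares over the apex and the two coronary
ostia, with the apex weighted 10x; (2) iterative-closest-point refinement
against the mesh surface, with the cumulative rotation restricted to 10
degrees in the sagittal plane and 20 degrees in the transverse and coronal
planes; (3) optional manual adjustment. The registration error is the mean
+/- SD of the shortest distance from each (non-excluded) EMM point to the
mesh surface; points outside the capped mesh volume are excluded from ICP,
error calculation, and further processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (DegenerateConfigurationError, InsufficientDataError,
                     InvalidInputError)
from .geometry import SurfaceMesh, points_inside_capped, points_to_surface

LANDMARK_TAGS = ("apex", "left_ostium", "right_ostium")
DEFAULT_LANDMARK_WEIGHTS = {"apex": 10.0, "left_ostium": 1.0,
                            "right_ostium": 1.0}


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation then translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.isfinite(R).all() and np.isfinite(t).all()):
            raise InvalidInputError("non-finite transform")
        if abs(np.linalg.det(R) - 1.0) > 1e-6 or \
                np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise InvalidInputError("rotation is not proper orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)

    def to_dict(self) -> dict:
        return {"rotation": [float(x) for x in self.rotation.ravel()],
                "translation_mm": [float(x) for x in self.translation]}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"], dtype=float).reshape(3, 3),
                   np.asarray(d["translation_mm"], dtype=float))


@dataclass
class EMMPoint:
    """One catheter measurement: 3-D tip position plus local scalars.

    ``unipolar_mV``/``bipolar_mV`` are depolarisation amplitudes (reduced
    over scar), ``lls_percent`` is linear local shortening. ``tag`` marks
    anatomical landmark points (apex, left/right coronary ostium).
    """

    id: int
    position: np.ndarray
    unipolar_mV: float | None = None
    bipolar_mV: float | None = None
    lls_percent: float | None = None
    tag: str = "none"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.isfinite(self.position).all():
            raise InvalidInputError(f"point {self.id}: non-finite position")
        if self.tag not in ("none",) + LANDMARK_TAGS:
            raise InvalidInputError(f"point {self.id}: unknown tag "
                                    f"{self.tag!r}")
        for name in ("unipolar_mV", "bipolar_mV"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidInputError(f"point {self.id}: negative {name}")


@dataclass
class EMMDataset:
    """An electromechanical map: EMM points plus the set of excluded ids."""

    points: list[EMMPoint]
    excluded_ids: set[int] = field(default_factory=set)

    def __post_init__(self):
        ids = [p.id for p in self.points]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate EMM point ids")
        if not set(self.excluded_ids) <= set(ids):
            raise InvalidInputError("excluded_ids not a subset of ids")
        n_apex = sum(1 for p in self.points if p.tag == "apex")
        if n_apex > 1:
            raise InvalidInputError("more than one apex landmark")

    def __len__(self):
        return len(self.points)

    @property
    def used_points(self) -> list[EMMPoint]:
        return [p for p in self.points if p.id not in self.excluded_ids]

    def positions(self, used_only: bool = True) -> np.ndarray:
        pts = self.used_points if used_only else self.points
        if not pts:
            return np.empty((0, 3))
        return np.stack([p.position for p in pts])

    def landmarks(self) -> dict[str, np.ndarray]:
        return {p.tag: p.position for p in self.points
                if p.tag in LANDMARK_TAGS}

    def transformed(self, transform: RigidTransform) -> "EMMDataset":
        pts = [replace(p, position=transform.apply(p.position))
               for p in self.points]
        return EMMDataset(pts, set(self.excluded_ids))


@dataclass
class RotationConstraint:
    """Per-plane rotation limits for ICP, in degrees.

    Rotation in the sagittal plane is rotation about the left-right axis
    (axes[0]); transverse about the head-foot axis (axes[1]); coronal about
    the anterior-posterior axis (axes[2]). The cumulative rotation relative
    to the initial transform is decomposed into intrinsic angles about these
    axes and each is saturated at its limit.
    """

    sagittal_limit: float = 10.0
    transverse_limit: float = 20.0
    coronal_limit: float = 20.0
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if min(self.sagittal_limit, self.transverse_limit,
               self.coronal_limit) <= 0:
            raise InvalidInputError("rotation limits must be positive")
        if np.abs(self.axes @ self.axes.T - np.eye(3)).max() > 1e-6:
            raise InvalidInputError("constraint axes must be orthonormal")

    @property
    def limits_deg(self) -> np.ndarray:
        return np.array([self.sagittal_limit, self.transverse_limit,
                         self.coronal_limit])

    def decompose_deg(self, rotation: np.ndarray) -> np.ndarray:
        """Intrinsic XYZ angles (deg) of ``rotation`` in the axes frame.

        ``axes`` rows are the anatomical axis vectors; the returned angles
        are about (sagittal, transverse, coronal) axes respectively.
        """
        A = self.axes.T  # columns = axis vectors
        local = A.T @ rotation @ A
        return Rotation.from_matrix(local).as_euler("XYZ", degrees=True)

    def clamp(self, rotation: np.ndarray) -> np.ndarray:
        """Saturate each per-axis angle of ``rotation`` at its limit."""
        ang = self.decompose_deg(rotation)
        clamped = np.clip(ang, -self.limits_deg, self.limits_deg)
        if np.allclose(ang, clamped):
            return rotation
        A = self.axes.T
        local = Rotation.from_euler("XYZ", clamped, degrees=True).as_matrix()
        return A @ local @ A.T


def anatomical_axes(mesh: SurfaceMesh,
                    right_ostium: np.ndarray | None = None) -> np.ndarray:
    """Default anatomical axis frame (rows: sagittal-, transverse-,
    coronal-plane rotation axes).

    The transverse axis is the mesh long axis; the sagittal (left-right)
    axis points from the long axis toward the right coronary ostium when
    given, else toward an arbitrary perpendicular; the coronal axis
    completes the right-handed frame.
    """
    lz = mesh.long_axis
    if right_ostium is not None:
        ref = np.asarray(right_ostium, dtype=float) - \
            mesh.vertices[mesh.apex_vertex]
    else:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, lz)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
    lx = ref - np.dot(ref, lz) * lz
    n = np.linalg.norm(lx)
    if n < 1e-12:
        lx = np.array([0.0, 1.0, 0.0]) - lz[1] * lz
        n = np.linalg.norm(lx)
    lx = lx / n
    ly = np.cross(lx, lz)  # chosen so the (lx, lz, ly) frame is right-handed
    return np.stack([lx, lz, ly])


@dataclass
class RegistrationReport:
    """Outcome of a registration phase."""

    transform: RigidTransform
    mean_error: float
    sd_error: float
    per_point_error: dict[int, float]
    n_used: int
    n_excluded: int
    iterations: int
    converged: bool
    error_history: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "mean_error_mm": self.mean_error,
            "sd_error_mm": self.sd_error,
            "per_point_error_mm": {str(k): v
                                   for k, v in
                                   sorted(self.per_point_error.items())},
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "iterations": self.iterations,
            "converged": self.converged,
        }


def weighted_rigid_fit(src: np.ndarray, dst: np.ndarray,
                       weights: np.ndarray) -> RigidTransform:
    """Closed-form weighted absolute orientation (rigid, no scale).

    Minimises sum_i w_i ||R src_i + t - dst_i||^2 via SVD of the weighted
    cross-covariance, with the determinant sign corrected so the rotation is
    proper.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise InvalidInputError("weights must be positive")
    wn = w / w.sum()
    cs = wn @ src
    cd = wn @ dst
    H = (src - cs).T @ ((dst - cd) * wn[:, None])
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise DegenerateConfigurationError(
            "landmarks are collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    return RigidTransform(R, t)


def landmark_register(src_landmarks: dict[str, np.ndarray],
                      dst_landmarks: dict[str, np.ndarray],
                      weights: dict[str, float] | None = None
                      ) -> RigidTransform:
    """Coarse registration from tagged anatomical landmarks.

    ``src_landmarks``/``dst_landmarks`` map landmark tags to 3-D positions
    in catheter and MRI space; only tags present in both are used (>= 3
    non-collinear required). Default weights give the apex 10x the weight of
    each coronary ostium.
    """
    if weights is None:
        weights = DEFAULT_LANDMARK_WEIGHTS
    tags = [t for t in LANDMARK_TAGS
            if t in src_landmarks and t in dst_landmarks]
    if len(tags) < 3:
        raise InsufficientDataError(
            f"need >= 3 matched landmarks, got {len(tags)}")
    src = np.stack([np.asarray(src_landmarks[t], dtype=float) for t in tags])
    dst = np.stack([np.asarray(dst_landmarks[t], dtype=float) for t in tags])
    w = np.array([float(weights.get(t, 1.0)) for t in tags])
    return weighted_rigid_fit(src, dst, w)


def registration_error(dataset: EMMDataset, mesh: SurfaceMesh,
                       transform: RigidTransform | None = None):
    """Mean +/- SD (sample, n-1) of the shortest point-to-surface distance.

    Only non-excluded points contribute. Returns
    ``(mean_mm, sd_mm, {id: distance_mm})``.
    """
    used = dataset.used_points
    if not used:
        raise InsufficientDataError("all points are excluded")
    pos = np.stack([p.position for p in used])
    if transform is not None:
        pos = transform.apply(pos)
    d, _ = points_to_surface(pos, mesh)
    per_point = {p.id: float(di) for p, di in zip(used, d)}
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return mean, sd, per_point


def exclude_outside_points(dataset: EMMDataset, mesh: SurfaceMesh,
                           margin_mm: float = 5.0) -> EMMDataset:
    """Flag points outside the capped mesh volume.

    A point is excluded when it is not inside the capped cavity AND its
    shortest distance to the surface exceeds ``margin_mm``, or when its
    nearest footpoint lies on the basal rim with distance above the margin
    (the catheter sitting beyond the imaged ventricle, e.g. in the outflow
    tract). Order of points is preserved; previously excluded ids stay
    excluded.
    """
    pos = dataset.positions(used_only=False)
    if not len(pos):
        return EMMDataset([], set())
    d, feet = points_to_surface(pos, mesh)
    inside = points_inside_capped(pos, mesh)
    excluded = set(dataset.excluded_ids)
    for p, di, foot, ins in zip(dataset.points, d, feet, inside):
        if di > margin_mm and (not ins or foot.on_boundary):
            excluded.add(p.id)
    return EMMDataset(list(dataset.points), excluded)


def icp_register(dataset: EMMDataset, mesh: SurfaceMesh,
                 init: RigidTransform | None = None,
                 constraint: RotationConstraint | None = None,
                 tol: float = 1e-4, max_iter: int = 100
                 ) -> RegistrationReport:
    """Constrained iterative-closest-point refinement against the surface.

    Each iteration matches every non-excluded point to its closest surface
    footpoint, solves the closed-form rigid fit to those footpoints, and
    saturates the cumulative rotation (relative to ``init``) at the
    per-plane limits. Iteration stops when the mean-error improvement falls
    below ``tol`` (mm), when the transform update is negligible, or after
    ``max_iter`` iterations. A candidate transform that would increase the
    mean error is rejected, so the mean error is non-increasing across
    accepted iterations.
    """
    if init is None:
        init = RigidTransform.identity()
    if constraint is None:
        constraint = RotationConstraint(axes=anatomical_axes(mesh))
    used = dataset.used_points
    if len(used) < 4:
        raise InsufficientDataError(
            f"ICP needs >= 4 usable points, got {len(used)}")
    src = np.stack([p.position for p in used])
    if not np.isfinite(src).all():
        raise InvalidInputError("non-finite point coordinates")

    current = RigidTransform(constraint.clamp(init.rotation),
                             init.translation)
    pos = current.apply(src)
    d, feet = points_to_surface(pos, mesh)
    mean_err = float(d.mean())
    history = [mean_err]
    converged = False
    iterations = 0

    for iterations in range(1, max_iter + 1):
        targets = np.stack([f.position for f in feet])
        step = weighted_rigid_fit(pos, targets, np.ones(len(pos)))
        cand = step.compose(current)
        R_rel = cand.rotation @ init.rotation.T
        R_rel_clamped = constraint.clamp(R_rel)
        if not np.allclose(R_rel_clamped, R_rel):
            Rc = R_rel_clamped @ init.rotation
            # re-fit translation for the clamped rotation
            tc = targets.mean(axis=0) - Rc @ src.mean(axis=0)
            cand = RigidTransform(Rc, tc)
        new_pos = cand.apply(src)
        new_d, new_feet = points_to_surface(new_pos, mesh)
        new_mean = float(new_d.mean())
        if new_mean > mean_err + 1e-12:
            converged = True
            break
        delta_T = max(np.abs(cand.rotation - current.rotation).max(),
                      np.abs(cand.translation - current.translation).max())
        improvement = mean_err - new_mean
        current, pos, d, feet, mean_err = cand, new_pos, new_d, new_feet, \
            new_mean
        history.append(mean_err)
        if improvement < tol or delta_T < 1e-6:
            converged = True
            break

    per_point = {p.id: float(di) for p, di in zip(used, d)}
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return RegistrationReport(
        transform=current, mean_error=mean_err, sd_error=sd,
        per_point_error=per_point, n_used=len(used),
        n_excluded=len(dataset.excluded_ids), iterations=iterations,
        converged=converged, error_history=history)


def manual_adjust(current: RigidTransform, delta_rotation_deg,
                  delta_translation,
                  axes: np.ndarray | None = None) -> RigidTransform:
    """Compose an interactive correction onto a transform.

    The three angles are applied as intrinsic rotations about the anatomical
    axes in the fixed order (sagittal, transverse, coronal), followed by the
    translation; the delta premultiplies ``current`` (it acts in the target,
    MRI, frame). Pure function: the input transform is not modified.
    """
    ang = np.asarray(delta_rotation_deg, dtype=float).reshape(3)
    t = np.asarray(delta_translation, dtype=float).reshape(3)
    if not (np.isfinite(ang).all() and np.isfinite(t).all()):
        raise InvalidInputError("non-finite manual adjustment")
    A = (np.eye(3) if axes is None else
         np.asarray(axes, dtype=float).reshape(3, 3)).T
    local = Rotation.from_euler("XYZ", ang, degrees=True).as_matrix()
    delta = RigidTransform(A @ local @ A.T, t)
    return delta.compose(current)
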