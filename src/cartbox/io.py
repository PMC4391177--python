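"""File formats and run configuration.

EMM point files use a small CSV dialect (header required)::

    id,x_mm,y_mm,z_mm,unipolar_mV,bipolar_mV,lls_pct,tag

with empty fields for missing scalars and ``tag`` one of
none/apex/left_ostium/right_ostium; a JSON mirror uses the same keys.
Transforms are JSON objects ``{"rotation": [9 row-major], "translation_mm":
[3]}``. Contour stacks are JSON (see ``SegmentationStack``). All vertex/face
indices in files are 0-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .registration import EMMDataset, EMMPoint, RigidTransform
from .transmurality import SegmentationStack

EMM_COLUMNS = ["id", "x_mm", "y_mm", "z_mm", "unipolar_mV", "bipolar_mV",
               "lls_pct", "tag"]


@dataclass
class RunConfig:
    """Pipeline constants. Defaults are the clinically used values:
    apex weighted 10x in landmark registration, ICP rotation limited to
    10 degrees in the sagittal and 20 degrees in the transverse and coronal
    planes, 5 mm exclusion margin, 15 mm projection radius, 50 %
    border-zone threshold."""

    apex_weight: float = 10.0
    sagittal_limit_deg: float = 10.0
    transverse_limit_deg: float = 20.0
    coronal_limit_deg: float = 20.0
    exclude_margin_mm: float = 5.0
    icp_tol_mm: float = 1e-4
    icp_max_iter: int = 100
    projection_radius_mm: float = 15.0
    border_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("apex_weight", "sagittal_limit_deg",
                     "transverse_limit_deg", "coronal_limit_deg",
                     "exclude_margin_mm", "icp_tol_mm", "icp_max_iter",
                     "projection_radius_mm", "border_threshold"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = str(path)
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls(**(d or {}))

    def to_dict(self) -> dict:
        return asdict(self)


def save_emm_csv(path, dataset: EMMDataset):
    rows = []
    for p in dataset.points:
        rows.append({
            "id": p.id,
            "x_mm": p.position[0], "y_mm": p.position[1],
            "z_mm": p.position[2],
            "unipolar_mV": p.unipolar_mV, "bipolar_mV": p.bipolar_mV,
            "lls_pct": p.lls_percent, "tag": p.tag,
        })
    df = pd.DataFrame(rows, columns=EMM_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def load_emm_csv(path) -> EMMDataset:
    df = pd.read_csv(path)
    missing = set(EMM_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"EMM CSV lacks columns: {sorted(missing)}")
    points = []
    for _, r in df.iterrows():
        def opt(v):
            return None if (v is None or (isinstance(v, float)
                                          and math.isnan(v))) else float(v)
        tag = r["tag"]
        if not isinstance(tag, str) or tag != tag:  # NaN guard
            tag = "none"
        points.append(EMMPoint(
            id=int(r["id"]),
            position=np.array([r["x_mm"], r["y_mm"], r["z_mm"]],
                              dtype=float),
            unipolar_mV=opt(r["unipolar_mV"]),
            bipolar_mV=opt(r["bipolar_mV"]),
            lls_percent=opt(r["lls_pct"]),
            tag=tag))
    return EMMDataset(points)


def save_emm_json(path, dataset: EMMDataset):
    rows = [{"id": p.id, "x_mm": p.position[0], "y_mm": p.position[1],
             "z_mm": p.position[2], "unipolar_mV": p.unipolar_mV,
             "bipolar_mV": p.bipolar_mV, "lls_pct": p.lls_percent,
             "tag": p.tag} for p in dataset.points]
    dump_json(path, {"points": rows,
                     "excluded_ids": sorted(dataset.excluded_ids)})


def load_emm_json(path) -> EMMDataset:
    with open(path) as fh:
        d = json.load(fh)
    points = [EMMPoint(id=int(r["id"]),
                       position=np.array([r["x_mm"], r["y_mm"], r["z_mm"]],
                                         dtype=float),
                       unipolar_mV=r.get("unipolar_mV"),
                       bipolar_mV=r.get("bipolar_mV"),
                       lls_percent=r.get("lls_pct"),
                       tag=r.get("tag", "none"))
              for r in d["points"]]
    return EMMDataset(points, set(d.get("excluded_ids", [])))


def save_transform(path, transform: RigidTransform):
    dump_json(path, transform.to_dict())


def load_transform(path) -> RigidTransform:
    with open(path) as fh:
        return RigidTransform.from_dict(json.load(fh))


def save_stack(path, stack: SegmentationStack):
    dump_json(path, stack.to_dict())


def load_stack(path) -> SegmentationStack:
    with open(path) as fh:
        return SegmentationStack.from_dict(json.load(fh))


def dump_json(path, obj):
    """Deterministic JSON writer: sorted keys, fixed float handling."""
    with open(path, "w") as fh:
        json.dump(_plain(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def labels_volume_to_stack(path, slice_axis: int = 2,
                           n_polygon_points: int = 72) -> SegmentationStack:
    """Convert a NIfTI label volume (0 background, 1 myocardium, 2 scar)
    into a contour stack.

    Per slice, the endocardial contour is the inner boundary of the
    myocardium+scar ring, the epicardial contour its outer boundary, and
    scar contours the boundaries of label-2 components; contours are taken
    at sub-pixel precision from marching squares and mapped to mm with the
    affine's scaling.
    """
    import nibabel as nib
    from skimage import measure

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    spacing = float(zooms[slice_axis])
    in_plane = [zooms[i] for i in range(3) if i != slice_axis]
    from .transmurality import Slice
    slices = []
    for k in range(vol.shape[slice_axis]):
        sl = np.take(vol, k, axis=slice_axis)
        wall = sl >= 1
        if wall.sum() < 16:
            continue
        conts = measure.find_contours(wall.astype(float), 0.5)
        if len(conts) < 2:
            continue
        conts = sorted(conts, key=lambda c: -_poly_area(c))
        epi = conts[0][:, ::-1] * np.asarray(in_plane)
        endo = conts[1][:, ::-1] * np.asarray(in_plane)
        scars = [c[:, ::-1] * np.asarray(in_plane)
                 for c in measure.find_contours((sl == 2).astype(float),
                                                0.5)]
        slices.append(Slice(z_mm=k * spacing, endo_polygon=endo,
                            epi_polygon=epi, scar_polygons=scars))
    if len(slices) < 3:
        raise InvalidInputError("label volume yields fewer than 3 usable "
                                "slices")
    return SegmentationStack(slices, spacing)


def _poly_area(c):
    x, y = c[:, 0], c[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
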