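"""Readers and writers: NIfTI images with JSON sidecars, CSV point sets,
JSON transform records, DICOM metadata extraction (read-only).

NIfTI-1 is the canonical on-disk image format (it round-trips geometry
simply); acquisition metadata that NIfTI cannot carry — per-slice trigger
delays, R-R intervals, phase ordering, perfusion plane geometry — travels in a
JSON sidecar next to the image.  Point sets are human-diffable CSV.  Transform
records use a documented JSON schema of this package, since no standard format
covers the composite spatiotemporal record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import (
    CineSeries,
    Contour,
    ImageGrid,
    PerfusionSeries,
    PerfusionSlice,
    SlicePlane,
    Volume3D,
)
from .motion import Rigid2D
from .spatiotemporal import (
    MediatedTransform,
    SpatioTemporalParams,
    TranslationTransform,
)
from .territories import CoronaryTree

__all__ = [
    "SeriesMetadata",
    "read_image",
    "write_volume",
    "read_volume",
    "write_cine",
    "read_cine",
    "write_perfusion",
    "read_perfusion",
    "write_pointset",
    "read_pointset",
    "write_transform",
    "read_transform",
    "transform_to_record",
    "transform_from_record",
    "read_dicom_metadata",
]


@dataclass(frozen=True)
class SeriesMetadata:
    """Per-slice acquisition metadata relevant to phase normalisation."""

    trigger_delay_ms: float
    rr_ms: float
    slice_thickness_mm: float | None = None
    location: str | None = None

    def __post_init__(self):
        if self.trigger_delay_ms < 0:
            raise ValueError("trigger delay must be non-negative")
        if self.rr_ms <= 0:
            raise ValueError("R-R interval must be positive")

    @property
    def reduced_trigger_ms(self) -> float:
        """Trigger delay reduced modulo the R-R interval (always < R-R)."""
        return float(self.trigger_delay_ms % self.rr_ms)


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------


def _grid_to_affine(grid: ImageGrid) -> np.ndarray:
    a = np.eye(4)
    a[:3, :3] = grid.direction * np.asarray(grid.spacing)
    a[:3, 3] = grid.origin
    return a


def _affine_to_grid(affine: np.ndarray, size) -> ImageGrid:
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    direction = m / spacing
    return ImageGrid(
        size=tuple(int(s) for s in size),
        spacing=tuple(spacing),
        origin=tuple(affine[:3, 3]),
        direction=direction,
    )


def write_volume(vol: Volume3D, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), _grid_to_affine(vol.grid)), str(path))


def read_volume(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    return Volume3D(grid=_affine_to_grid(img.affine, data.shape), data=data)


def write_cine(cine: CineSeries, path, phase_order: list[int] | None = None) -> None:
    """Write a 4D cine NIfTI plus a JSON sidecar.

    ``phase_order`` permutes the on-disk phase axis (``disk frame i`` holds
    acquisition phase ``phase_order[i]``); the sidecar records it so readers
    restore acquisition order.
    """
    n = cine.n_phases
    order = list(range(n)) if phase_order is None else list(phase_order)
    if sorted(order) != list(range(n)):
        raise ValueError("phase_order must be a permutation of the phases")
    data = cine.data[..., order]
    nib.save(
        nib.Nifti1Image(data.astype(np.float32), _grid_to_affine(cine.grid)), str(path)
    )
    sidecar = {
        "kind": "cine",
        "phase_order": order,
        "trigger_delay_ms": cine.trigger_delay_ms.tolist(),
        "rr_ms": cine.rr_ms.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _load_sidecar(path, fields: list[str]) -> dict:
    sp = _sidecar_path(path)
    if not sp.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sp}")
    meta = json.loads(sp.read_text())
    for f in fields:
        if f not in meta:
            raise KeyError(f"metadata sidecar {sp} lacks required field {f!r}")
    return meta


def read_cine(path) -> CineSeries:
    img = nib.load(str(path))
    disk = np.asanyarray(img.dataobj, dtype=float)
    if disk.ndim != 4:
        raise ValueError("a cine image must be 4D")
    meta = _load_sidecar(path, ["phase_order", "trigger_delay_ms", "rr_ms"])
    order = list(meta["phase_order"])
    data = np.empty_like(disk)
    data[..., order] = disk  # disk frame i holds phase order[i]
    return CineSeries(
        grid=_affine_to_grid(img.affine, disk.shape[:3]),
        data=data,
        trigger_delay_ms=np.asarray(meta["trigger_delay_ms"], dtype=float),
        rr_ms=np.asarray(meta["rr_ms"], dtype=float),
    )


def write_perfusion(series: PerfusionSeries, basepath) -> None:
    """Write one 3D (nu, nv, frames) NIfTI per slice location plus a sidecar."""
    base = Path(basepath)
    sidecar: dict = {"kind": "perfusion", "max_contrast_frame": series.max_contrast_frame, "slices": {}}
    for loc, sl in series.slices.items():
        p = sl.plane
        grid = ImageGrid(
            size=(p.size[0], p.size[1], sl.n_frames),
            spacing=(p.spacing[0], p.spacing[1], 1.0),
            origin=p.origin,
            direction=np.stack([p.u, p.v, p.normal], axis=1),
        )
        write_volume(Volume3D(grid, sl.frames), base.parent / f"{base.name}_{loc}.nii.gz")
        sidecar["slices"][loc] = {
            "trigger_delay_ms": sl.trigger_delay_ms,
            "rr_ms": sl.rr_ms,
            "thickness_mm": p.thickness,
        }
    (base.parent / f"{base.name}.json").write_text(json.dumps(sidecar, indent=1))


def read_perfusion(basepath) -> PerfusionSeries:
    base = Path(basepath)
    sp = base.parent / f"{base.name}.json"
    if not sp.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sp}")
    meta = json.loads(sp.read_text())
    for f in ("max_contrast_frame", "slices"):
        if f not in meta:
            raise KeyError(f"metadata sidecar {sp} lacks required field {f!r}")
    slices = {}
    for loc in ("basal", "medial", "apical"):
        if loc not in meta["slices"]:
            raise KeyError(f"metadata sidecar lacks slice location {loc!r}")
        m = meta["slices"][loc]
        vol = read_volume(base.parent / f"{base.name}_{loc}.nii.gz")
        g = vol.grid
        plane = SlicePlane(
            origin=g.origin,
            u=tuple(g.direction[:, 0]),
            v=tuple(g.direction[:, 1]),
            size=(g.size[0], g.size[1]),
            spacing=(g.spacing[0], g.spacing[1]),
            thickness=float(m.get("thickness_mm", 0.0)),
        )
        slices[loc] = PerfusionSlice(
            plane=plane,
            frames=vol.data,
            trigger_delay_ms=float(m["trigger_delay_ms"]),
            rr_ms=float(m["rr_ms"]),
        )
    return PerfusionSeries(slices=slices, max_contrast_frame=int(meta["max_contrast_frame"]))


def read_image(path, kind: str):
    """Dispatching reader: ``kind`` in {'volume', 'cine', 'perfusion'}."""
    if kind == "volume":
        return read_volume(path)
    if kind == "cine":
        return read_cine(path)
    if kind == "perfusion":
        return read_perfusion(path)
    raise ValueError(f"unknown image kind {kind!r}")


# --------------------------------------------------------------------------
# point sets
# --------------------------------------------------------------------------


def write_pointset(obj, path) -> None:
    lines = []
    if isinstance(obj, Contour):
        lines.append(f"# cardiofuse pointset kind=contour role={obj.role}")
        lines.append("x,y,z")
        for p in obj.points:
            lines.append(f"{float(p[0])!r},{float(p[1])!r},{float(p[2])!r}")
    elif isinstance(obj, CoronaryTree):
        lines.append("# cardiofuse pointset kind=tree")
        lines.append("segment,x,y,z")
        for s in sorted(obj.segments):
            for p in obj.segments[s]:
                lines.append(f"{s},{float(p[0])!r},{float(p[1])!r},{float(p[2])!r}")
    else:
        raise TypeError("write_pointset accepts a Contour or a CoronaryTree")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pointset(path):
    text = Path(path).read_text().strip().splitlines()
    if not text or not text[0].startswith("# cardiofuse pointset"):
        raise ValueError(f"{path}: not a cardiofuse point-set file")
    header = dict(tok.split("=") for tok in text[0].split()[3:])
    kind = header.get("kind")
    if kind == "contour":
        pts = [[float(v) for v in line.split(",")] for line in text[2:]]
        return Contour(points=np.array(pts), role=header["role"])
    if kind == "tree":
        segments: dict[int, list] = {}
        for line in text[2:]:
            s, x, y, z = line.split(",")
            s = int(s)
            if not 1 <= s <= 9:
                raise ValueError(f"{path}: segment label {s} outside 1-9")
            segments.setdefault(s, []).append([float(x), float(y), float(z)])
        return CoronaryTree(segments={s: np.array(p) for s, p in segments.items()})
    raise ValueError(f"{path}: unknown point-set kind {kind!r}")


# --------------------------------------------------------------------------
# transform records
# --------------------------------------------------------------------------

_PARAM_COUNTS = {"translation": 3, "rigid2d": 5, "spatiotemporal": 7}


def transform_to_record(t) -> dict:
    from .registration import BSplineStepTransform, ChainTransform

    if isinstance(t, SpatioTemporalParams):
        return {"kind": "spatiotemporal", "parameters": list(t.as_vector())}
    if isinstance(t, TranslationTransform):
        return {"kind": "translation", "parameters": list(t.offset)}
    if isinstance(t, Rigid2D):
        return {"kind": "rigid2d", "parameters": [t.theta, *t.centre, *t.t]}
    if isinstance(t, BSplineStepTransform):
        tx = t.sitk_transform
        return {
            "kind": "bspline",
            "parameters": list(tx.GetParameters()),
            "fixed_parameters": list(tx.GetFixedParameters()),
        }
    if isinstance(t, ChainTransform):
        return {"kind": "composite", "children": [transform_to_record(c) for c in t.components]}
    if isinstance(t, MediatedTransform):
        return {
            "kind": "mediated",
            "direction": t.direction,
            "phi_p": t.phi_p,
            "phi_a": t.phi_a,
            "n_phases": t.n_phases,
            "children": [
                transform_to_record(t.t_p),
                transform_to_record(t.t_c),
                transform_to_record(t.t_a),
            ],
        }
    raise TypeError(f"cannot serialise transform of type {type(t).__name__}")


def transform_from_record(rec: dict):
    from .registration import BSplineStepTransform, ChainTransform
    import SimpleITK as sitk

    kind = rec.get("kind")
    if kind in _PARAM_COUNTS:
        params = rec.get("parameters")
        if params is None or len(params) != _PARAM_COUNTS[kind]:
            raise ValueError(
                f"transform kind {kind!r} requires {_PARAM_COUNTS[kind]} parameters"
            )
        if kind == "spatiotemporal":
            return SpatioTemporalParams.from_vector(params)
        if kind == "translation":
            return TranslationTransform(tuple(params))
        return Rigid2D(theta=params[0], centre=(params[1], params[2]), t=(params[3], params[4]))
    if kind == "bspline":
        tx = sitk.BSplineTransform(3, 3)
        tx.SetFixedParameters(rec["fixed_parameters"])
        tx.SetParameters(rec["parameters"])
        return BSplineStepTransform(tx)
    if kind == "composite":
        children = rec.get("children")
        if not children:
            raise ValueError("composite transform requires children")
        return ChainTransform([transform_from_record(c) for c in children])
    if kind == "mediated":
        children = rec.get("children")
        if not children or len(children) != 3:
            raise ValueError("mediated transform requires exactly 3 children")
        tp, tc, ta = (transform_from_record(c) for c in children)
        return MediatedTransform(
            t_p=tp,
            t_c=tc,
            t_a=ta,
            direction=rec["direction"],
            phi_p=rec["phi_p"],
            phi_a=rec["phi_a"],
            n_phases=rec["n_phases"],
        )
    raise ValueError(f"unknown transform kind {kind!r}")


def write_transform(t, path) -> None:
    Path(path).write_text(json.dumps(transform_to_record(t), indent=1))


def read_transform(path):
    return transform_from_record(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# DICOM (read-only metadata)
# --------------------------------------------------------------------------


def read_dicom_metadata(path) -> SeriesMetadata:
    """Pull trigger time, R-R interval and slice geometry from a DICOM file."""
    import pydicom

    ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    trigger = getattr(ds, "TriggerTime", None)
    if trigger is None:
        raise KeyError("DICOM dataset lacks TriggerTime")
    rr = getattr(ds, "NominalInterval", None)
    if not rr:
        hr = getattr(ds, "HeartRate", None)
        if not hr:
            raise KeyError("DICOM dataset lacks NominalInterval and HeartRate")
        rr = 60000.0 / float(hr)
    return SeriesMetadata(
        trigger_delay_ms=float(trigger),
        rr_ms=float(rr),
        slice_thickness_mm=(
            float(ds.SliceThickness) if getattr(ds, "SliceThickness", None) else None
        ),
        location=str(getattr(ds, "SliceLocation", "")) or None,
    )
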