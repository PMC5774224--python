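"""Evaluation primitives: Hausdorff distance, Dice, contour extraction,
territory-wise diagnosis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .core import Contour, SlicePlane, Volume3D, resample_volume, ImageGrid
from .territories import TERRITORY_ORDER

__all__ = [
    "hausdorff_distance",
    "dice_coefficient",
    "resample_contour",
    "slice_contours_from_segmentation",
    "DiagnosisTable",
    "territory_diagnosis",
]


def hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (mm).

    ``max(sup_a inf_b d, sup_b inf_a d)`` on the vertices; resample polylines
    densely first (:func:`resample_contour`) to approximate the continuous
    metric.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be non-empty")
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; defined as 1.0 for two empty masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def resample_contour(contour: Contour, spacing_mm: float = 1.0) -> Contour:
    """Resample a closed contour to (approximately) uniform vertex spacing."""
    pts = contour.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / spacing_mm)), 3)
    si = np.linspace(0, total, n, endpoint=False)
    out = np.stack([np.interp(si, s, closed[:, k]) for k in range(3)], axis=1)
    return Contour(points=out, role=contour.role)


def slice_contours_from_segmentation(
    seg: Volume3D,
    transform,
    plane: SlicePlane,
    role_map: dict[int, str],
) -> list[Contour]:
    """Extract contours where a warped volumetric segmentation meets a plane.

    The label volume is warped with the (forward, image-resampling) transform
    onto the plane grid using nearest-neighbour interpolation; each label's
    connected components yield ordered boundary contours tagged with the
    label's role.  No overlap -> empty list plus a warning.
    """
    grid = ImageGrid(
        size=(plane.size[0], plane.size[1], 1),
        spacing=(plane.spacing[0], plane.spacing[1], max(plane.thickness, 1.0)),
        origin=plane.origin,
        direction=np.stack([plane.u, plane.v, plane.normal], axis=1),
    )
    warped = resample_volume(seg, transform, grid, interpolation="nearest")
    img = warped.data[:, :, 0]
    contours: list[Contour] = []
    for value, role in role_map.items():
        binary = img == value
        if not binary.any():
            continue
        labelled = measure.label(binary)
        for comp in range(1, labelled.max() + 1):
            for ring in measure.find_contours((labelled == comp).astype(float), 0.5):
                if len(ring) < 3:
                    continue
                world = plane.plane_to_world(ring)
                contours.append(Contour(points=world, role=role))
    if not contours:
        warnings.warn("no segmentation labels intersect the plane")
    return contours


@dataclass
class DiagnosisTable:
    """Per-artery perfusion score and binary ischaemia call."""

    scores: dict[str, float]
    calls: dict[str, bool]
    threshold: float
    method: str  # PST | AHA

    def __post_init__(self):
        for t in TERRITORY_ORDER:
            if t not in self.scores:
                raise ValueError(f"missing territory {t}")
        for t, s in self.scores.items():
            if self.calls[t] != (s < self.threshold):
                raise ValueError("calls must follow deterministically from scores")


def territory_diagnosis(
    scores: dict[str, float], threshold: float, method: str = "PST"
) -> DiagnosisTable:
    """Call an artery ischaemic iff its territory score is below threshold."""
    missing = [t for t in TERRITORY_ORDER if t not in scores]
    if missing:
        raise ValueError(f"missing territory scores: {missing}")
    calls = {t: scores[t] < threshold for t in scores}
    return DiagnosisTable(scores=dict(scores), calls=calls, threshold=threshold, method=method)
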