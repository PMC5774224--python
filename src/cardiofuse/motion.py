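"""Respiratory motion correction of perfusion series.

Each frame of a dynamic slice is registered to the evolving *average image* of
its series (the average contains features of every contrast phase, so
pre-contrast, ventricular-contrast and wash-out frames all find something to
match), in two staged passes: translation-only, then rigid 2D initialised from
the translation result.  The maximal-contrast key frame is constrained to the
identity so contours and masks defined on it are the fixed reference.

Because the three slice locations of a frame are acquired within ~150 ms of
the same cardiac cycle, respiratory displacement is shared between them: the
basal slice (highest information density) can be corrected alone and its
transforms propagated to the medial and apical slices.

Transform conventions: the stored *direct* transform of frame f maps frame-f
anatomy coordinates to key-frame coordinates (it is the correction); its
closed-form *inverse* places key-frame contours and masks onto frame f, and is
what the exported vector deformation fields (VDFs) sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._similarity import mutual_information, regular_step_descent
from .core import Contour, PerfusionSeries, SlicePlane
from .registration import RegistrationConfig

__all__ = [
    "Rigid2D",
    "MotionCorrectionResult",
    "VectorField2D",
    "temporal_average",
    "correct_series",
    "correct_perfusion",
    "propagate_basal",
    "export_vdf",
    "propagate_contours",
    "gradient_energy",
]


@dataclass(frozen=True)
class Rigid2D:
    """Rigid in-plane transform: rotation ``theta`` about ``centre`` plus ``t`` (mm)."""

    theta: float = 0.0
    centre: tuple[float, float] = (0.0, 0.0)
    t: tuple[float, float] = (0.0, 0.0)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c, s = np.cos(self.theta), np.sin(self.theta)
        x = pts[:, 0] - self.centre[0]
        y = pts[:, 1] - self.centre[1]
        out = np.empty_like(pts)
        out[:, 0] = c * x - s * y + self.t[0] + self.centre[0]
        out[:, 1] = s * x + c * y + self.t[1] + self.centre[1]
        return out

    def inverse(self) -> "Rigid2D":
        return Rigid2D(
            theta=-self.theta,
            centre=(self.centre[0] + self.t[0], self.centre[1] + self.t[1]),
            t=(-self.t[0], -self.t[1]),
        )

    def compose(self, other: "Rigid2D") -> "Rigid2D":
        """The rigid map ``self o other`` (apply ``other`` first)."""
        tha, thb = self.theta, other.theta
        ca, sa = np.cos(tha), np.sin(tha)
        # affine forms p -> R p + o
        o_b = np.asarray(other.apply(np.zeros((1, 2))))[0]
        o_a = np.asarray(self.apply(np.zeros((1, 2))))[0]
        o_c = np.array([ca * o_b[0] - sa * o_b[1], sa * o_b[0] + ca * o_b[1]]) + o_a
        th_c = tha + thb
        c0 = np.asarray(self.centre)
        rc0 = np.array(
            [np.cos(th_c) * c0[0] - np.sin(th_c) * c0[1], np.sin(th_c) * c0[0] + np.cos(th_c) * c0[1]]
        )
        t = o_c + rc0 - c0
        return Rigid2D(theta=th_c, centre=tuple(c0), t=tuple(t))

    @property
    def is_identity(self) -> bool:
        return self.theta == 0.0 and self.t == (0.0, 0.0)


@dataclass
class MotionCorrectionResult:
    """Per-frame, per-location direct transforms (frame -> key space)."""

    transforms: dict[str, list[Rigid2D]]
    stage: str  # translation | rigid
    strategy: str = "all-slice"  # all-slice | basal-propagated
    key_frame: int = 0

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.transforms.values())))

    def transform(self, location: str, f: int) -> Rigid2D:
        return self.transforms[location][f]

    def translations(self, location: str) -> np.ndarray:
        return np.array([t.t for t in self.transforms[location]])


@dataclass
class VectorField2D:
    """Per-pixel 2D displacement image (mm) on a slice plane grid."""

    plane: SlicePlane
    field: np.ndarray  # (nu, nv, 2)

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=float)
        if self.field.shape != tuple(self.plane.size) + (2,):
            raise ValueError("field shape must be plane.size + (2,)")


def _pixel_mm(plane: SlicePlane) -> np.ndarray:
    ii, jj = np.meshgrid(
        np.arange(plane.size[0], dtype=float) * plane.spacing[0],
        np.arange(plane.size[1], dtype=float) * plane.spacing[1],
        indexing="ij",
    )
    return np.stack([ii, jj], axis=-1)


def _warp_frame(frame: np.ndarray, plane: SlicePlane, mapping: Rigid2D) -> np.ndarray:
    """Resample a frame at ``mapping``-transformed pixel coordinates (mm)."""
    if mapping.is_identity:
        return frame
    pts = _pixel_mm(plane).reshape(-1, 2)
    src = mapping.apply(pts) / np.asarray(plane.spacing)
    return ndimage.map_coordinates(
        frame, src.T, order=1, mode="constant", cval=0.0
    ).reshape(plane.size)


def temporal_average(
    frames: np.ndarray, plane: SlicePlane, transforms: list[Rigid2D] | None = None
) -> np.ndarray:
    """Pixel-wise mean of the dynamic frames, optionally motion-compensated.

    When transforms are given, frame f is warped into key space first by
    sampling it at the *inverse*-transformed pixel positions (the inverse maps
    key coordinates onto frame-f anatomy).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] == 0:
        raise ValueError("need a (nu, nv, n_frames) stack with at least one frame")
    if transforms is None:
        return frames.mean(axis=2)
    if len(transforms) != frames.shape[2]:
        raise ValueError("one transform per frame required")
    acc = np.zeros(frames.shape[:2])
    for f in range(frames.shape[2]):
        acc += _warp_frame(frames[..., f], plane, transforms[f].inverse())
    return acc / frames.shape[2]


def correct_series(
    frames: np.ndarray,
    plane: SlicePlane,
    stage: str,
    key_frame: int,
    init: list[Rigid2D] | None = None,
    cfg: RegistrationConfig = RegistrationConfig(),
    outer_iterations: int = 2,
) -> list[Rigid2D]:
    """Average-image registration loop for one slice location.

    Iterates: build the average under the current transforms, register every
    frame to it (MI metric, regular-step gradient descent, two smoothing
    levels), update.  ``stage='rigid'`` requires the translation-stage result
    as ``init``.  The key frame keeps the identity transform throughout.
    """
    if stage not in ("translation", "rigid"):
        raise ValueError("stage must be 'translation' or 'rigid'")
    if stage == "rigid" and init is None:
        raise ValueError("the rigid stage must be initialised from the translation result")
    n_frames = frames.shape[2]
    centre = (
        (plane.size[0] - 1) / 2 * plane.spacing[0],
        (plane.size[1] - 1) / 2 * plane.spacing[1],
    )
    current: list[Rigid2D] = list(init) if init is not None else [Rigid2D()] * n_frames
    current = [replace(t, centre=centre) for t in current]
    current[key_frame] = Rigid2D(centre=centre)
    pts = _pixel_mm(plane).reshape(-1, 2)
    sp = np.asarray(plane.spacing)
    m_range = (float(frames.min()), float(frames.max()))
    sigmas = [cfg.smooth_sigma_px * (cfg.pyramid_levels - 1 - l) for l in range(cfg.pyramid_levels)]
    for _ in range(outer_iterations):
        avg = temporal_average(frames, plane, current)
        f_range = (float(avg.min()), float(avg.max()))
        for f in range(n_frames):
            frame = frames[..., f]
            if stage == "translation":
                x0 = np.array(current[f].t)
                scales = np.ones(2)

                def make(params):
                    return Rigid2D(centre=centre, t=(params[0], params[1]))

            else:
                x0 = np.array([current[f].theta, *current[f].t])
                scales = np.array([30.0, 1.0, 1.0])

                def make(params):
                    return Rigid2D(theta=params[0], centre=centre, t=(params[1], params[2]))

            for sigma, (step, min_step) in zip(
                sigmas,
                [(cfg.gd_step, cfg.gd_min_step * 5)] + [(cfg.gd_step / 2, cfg.gd_min_step)] * 8,
            ):
                a = ndimage.gaussian_filter(avg, sigma) if sigma else avg
                fr = ndimage.gaussian_filter(frame, sigma) if sigma else frame
                f_vals = a.ravel()

                def cost(params):
                    # sampling map: key space -> frame anatomy = inverse(direct)
                    src = make(params).inverse().apply(pts) / sp
                    m_vals = ndimage.map_coordinates(
                        fr, src.T, order=1, mode="constant", cval=0.0
                    )
                    return -mutual_information(
                        f_vals, m_vals, bins=cfg.bins, fixed_range=f_range, moving_range=m_range
                    )

                x0, _, _ = regular_step_descent(
                    cost, x0, scales, step=step, min_step=min_step, max_iter=cfg.gd_max_iter
                )
            current[f] = make(x0)
        # re-reference to the key frame: the average is only a registration
        # target, the key frame is the spatial reference (held at identity)
        key_inv = current[key_frame].inverse()
        current = [key_inv.compose(t) for t in current]
        current[key_frame] = Rigid2D(centre=centre)
    return current


def correct_perfusion(
    series: PerfusionSeries,
    stage: str = "translation",
    strategy: str = "basal-propagated",
    init: MotionCorrectionResult | None = None,
    cfg: RegistrationConfig = RegistrationConfig(),
    outer_iterations: int = 2,
) -> MotionCorrectionResult:
    """Motion-correct a perfusion study, optionally basal-only with propagation."""
    key = series.max_contrast_frame
    locations = list(series.slices) if strategy == "all-slice" else ["basal"]
    transforms: dict[str, list[Rigid2D]] = {}
    for loc in locations:
        sl = series.slices[loc]
        transforms[loc] = correct_series(
            sl.frames,
            sl.plane,
            stage=stage,
            key_frame=key,
            init=init.transforms[loc] if init is not None else None,
            cfg=cfg,
            outer_iterations=outer_iterations,
        )
    result = MotionCorrectionResult(
        transforms=transforms, stage=stage, strategy=strategy, key_frame=key
    )
    if strategy == "basal-propagated":
        result = propagate_basal(result, list(series.slices))
    return result


def propagate_basal(result: MotionCorrectionResult, locations: list[str]) -> MotionCorrectionResult:
    """Copy the basal per-frame transforms to the other slice locations.

    Justified by the acquisition timing: all three slices of a frame fall
    within ~150 ms of the same cardiac cycle, over which respiratory motion is
    negligible.
    """
    if "basal" not in result.transforms:
        raise ValueError("basal correction result required")
    basal = result.transforms["basal"]
    out = {}
    for loc in locations:
        existing = result.transforms.get(loc)
        if existing is not None and loc == "basal":
            out[loc] = list(existing)
        else:
            out[loc] = list(basal)
    return MotionCorrectionResult(
        transforms=out,
        stage=result.stage,
        strategy="basal-propagated",
        key_frame=result.key_frame,
    )


def export_vdf(result: MotionCorrectionResult, plane: SlicePlane) -> dict[tuple[str, int], VectorField2D]:
    """Vector deformation fields sampled from the inverse transforms.

    The inverse moves key-frame contours onto each frame, so the field at
    pixel x is ``inverse(x) - x``.
    """
    pts = _pixel_mm(plane).reshape(-1, 2)
    out = {}
    for loc, ts in result.transforms.items():
        for f, t in enumerate(ts):
            disp = t.inverse().apply(pts) - pts
            out[(loc, f)] = VectorField2D(
                plane=plane, field=disp.reshape(tuple(plane.size) + (2,))
            )
    return out


def propagate_contours(
    key_contours: list[Contour],
    result: MotionCorrectionResult,
    location: str,
    plane: SlicePlane,
) -> list[list[Contour]]:
    """Map key-frame contours onto every frame via the inverse transforms.

    The transforms act in the plane-local mm frame they were estimated in;
    contour points are converted in and out of it.  Point ordering and closure
    are preserved; returns one contour list per frame.
    """
    if location not in result.transforms:
        raise KeyError(f"no transforms for location {location!r}")
    sp = np.asarray(plane.spacing)
    out = []
    for f, t in enumerate(result.transforms[location]):
        inv = t.inverse()

        def move(pts, inv=inv):
            pts = np.atleast_2d(pts)
            local = plane.world_to_plane(pts) * sp
            return plane.plane_to_world(inv.apply(local) / sp)

        out.append([c.transformed(move) for c in key_contours])
    return out


def gradient_energy(img: np.ndarray) -> float:
    """Mean squared gradient magnitude — a sharpness score for average images."""
    gx, gy = np.gradient(np.asarray(img, dtype=float))
    return float(np.mean(gx**2 + gy**2))
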