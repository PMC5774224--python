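"""The four registration stages of the mediated pipeline.

1. :func:`align_cine_stack` — breath-hold slice-misalignment correction of the
   cine stack against the whole-heart volume, optimising one in-plane
   translation per slice *jointly* (a single parameter vector scored by one
   pooled mutual-information metric, which preserves stack integrity).
2. :func:`register_perfusion_to_cine` — slice-to-4D registration with the
   7-parameter spatiotemporal transform; the temporal position is initialised
   from ECG trigger-delay normalisation and searched within a hard window.
3. :func:`select_angiography_phase` — translation-only registration of the
   whole-heart volume against every cine phase; the best final metric value
   selects the matching (end-diastolic) phase.
4. :func:`register_phase_pair` / :func:`build_phase_chain` — consecutive
   B-spline deformable registration between neighbouring cine phases, each
   step warm-started from the previous, accumulated as an ordered composition
   (never resampled into one field); the inverse chain is computed at the same
   time by swapping fixed and moving images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage, optimize

from ._similarity import elliptic_mask, mutual_information, regular_step_descent
from .core import CineSeries, PerfusionSlice, SlicePlane, Volume3D
from .spatiotemporal import (
    SpatioTemporalParams,
    TranslationTransform,
    normalise_trigger_delay,
)

__all__ = [
    "RegistrationConfig",
    "PhaseSelection",
    "PhaseChainResult",
    "ChainTransform",
    "BSplineStepTransform",
    "align_cine_stack",
    "register_perfusion_to_cine",
    "select_angiography_phase",
    "register_phase_pair",
    "build_phase_chain",
    "cyclic_step",
]


@dataclass(frozen=True)
class RegistrationConfig:
    """Knobs shared by the registration stages.

    The similarity metric everywhere is Mattes-style mutual information with
    ``bins`` histogram bins; rigid/translation stages use regular-step gradient
    descent over ``pyramid_levels`` smoothing levels, the deformable stage a
    bounded quasi-Newton (L-BFGS-B) optimiser on a B-spline mesh.
    """

    bins: int = 32
    pyramid_levels: int = 2
    smooth_sigma_px: float = 1.5  # coarse-level Gaussian sigma
    gd_step: float = 2.0  # initial step (scaled-space units ~ mm)
    gd_min_step: float = 0.02
    gd_max_iter: int = 120
    temporal_halfwidth: float = 3.0  # hard phase-search bound (phases)
    bspline_mesh: tuple[int, int, int] = (5, 5, 2)  # mesh cells at the fine level
    bspline_iterations: int = 30
    bspline_sampling: float = 0.25  # metric sampling fraction (seeded, reproducible)
    sampling_seed: int = 1234
    stack_max_offset_mm: float = 12.0

    def __post_init__(self):
        if self.bins < 8:
            raise ValueError("need at least 8 histogram bins")
        if self.pyramid_levels < 1:
            raise ValueError("need at least one pyramid level")
        if self.temporal_halfwidth < 0:
            raise ValueError("temporal half-width must be non-negative")


@dataclass
class PhaseSelection:
    """Per-phase metric trace and the winning phase (MI: higher is better).

    ``rule='argmax'``: the phase with the best recorded metric wins
    (registration-based selection, used for angiography-to-cine).
    ``rule='round'``: the winner is the rounded continuous temporal optimum
    (used for the spatiotemporal perfusion-to-cine stage, whose optimiser
    works on a continuous phase axis); the trace is diagnostic.
    """

    phases: list[int]
    metric_values: list[float]
    selected_phase: int
    transform: object = None
    converged: bool = True
    rule: str = "argmax"

    def __post_init__(self):
        if len(self.phases) != len(self.metric_values):
            raise ValueError("one metric value per examined phase")
        if self.rule == "argmax" and self.selected_phase != self.phases[
            int(np.argmax(self.metric_values))
        ]:
            raise ValueError("selected phase must be the metric argmax")


def _grids_overlap(a, b) -> bool:
    """Axis-aligned world bounding-box intersection test."""

    def bbox(g):
        corners = np.array(
            [
                g.index_to_world(np.array(c, dtype=float) * (np.asarray(g.size) - 1))
                for c in np.ndindex(2, 2, 2)
            ]
        )
        return corners.min(axis=0), corners.max(axis=0)

    (alo, ahi), (blo, bhi) = bbox(a), bbox(b)
    return bool(np.all(ahi >= blo) & np.all(bhi >= alo))


def _smooth2d(img: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma) if sigma > 0 else img


# --------------------------------------------------------------------------
# stage 1: cine stack misalignment correction
# --------------------------------------------------------------------------


def align_cine_stack(
    cine: CineSeries,
    reference: Volume3D,
    cfg: RegistrationConfig = RegistrationConfig(),
    phase: int = 0,
) -> tuple[np.ndarray, CineSeries]:
    """Jointly recover per-slice in-plane translations against a reference.

    All slices of cine ``phase`` are scored by a single pooled MI metric while
    one translation per slice is optimised in one parameter vector (Powell's
    method — derivative-free, deterministic).  The recovered translation of a
    slice is applied across all its phases.

    Returns ``(offsets_mm, corrected)`` where ``offsets_mm[k]`` is the
    recovered content displacement of slice ``k``.
    """
    if not _grids_overlap(cine.grid, reference.grid):
        raise ValueError("reference volume does not overlap the cine stack")
    n_sl = cine.n_slices
    sx, sy = cine.grid.spacing[0], cine.grid.spacing[1]
    fixed_slices = []
    moving_slices = []
    from .core import reformat_slice

    for k in range(n_sl):
        plane = cine.slice_plane(k)
        fixed_slices.append(reformat_slice(reference, plane))
        moving_slices.append(cine.data[:, :, k, phase])
    f_ranges = (min(f.min() for f in fixed_slices), max(f.max() for f in fixed_slices))
    m_ranges = (min(m.min() for m in moving_slices), max(m.max() for m in moving_slices))

    def pooled_cost(x, fixed, moving):
        fvals, mvals = [], []
        for k in range(n_sl):
            tx, ty = x[2 * k] / sx, x[2 * k + 1] / sy
            shifted = ndimage.shift(moving[k], (-tx, -ty), order=1, mode="constant")
            fvals.append(fixed[k].ravel())
            mvals.append(shifted.ravel())
        return -mutual_information(
            np.concatenate(fvals),
            np.concatenate(mvals),
            bins=cfg.bins,
            fixed_range=f_ranges,
            moving_range=m_ranges,
        )

    x = np.zeros(2 * n_sl)
    lim = cfg.stack_max_offset_mm
    bounds = [(-lim, lim)] * (2 * n_sl)
    sigmas = [cfg.smooth_sigma_px * (cfg.pyramid_levels - 1 - l) for l in range(cfg.pyramid_levels)]
    for sigma in sigmas:
        fx = [_smooth2d(f, sigma) for f in fixed_slices]
        mv = [_smooth2d(m, sigma) for m in moving_slices]
        res = optimize.minimize(
            pooled_cost,
            x,
            args=(fx, mv),
            method="Powell",
            bounds=bounds,
            options={"xtol": 0.02, "ftol": 1e-6, "maxiter": 6},
        )
        x = res.x
    offsets = x.reshape(n_sl, 2)
    corrected = cine.copy()
    for k in range(n_sl):
        tx, ty = offsets[k, 0] / sx, offsets[k, 1] / sy
        if abs(tx) + abs(ty) < 1e-9:
            continue
        for p in range(cine.n_phases):
            corrected.data[:, :, k, p] = ndimage.shift(
                cine.data[:, :, k, p], (-tx, -ty), order=1, mode="constant"
            )
    return offsets, corrected


# --------------------------------------------------------------------------
# stage 2: perfusion-to-cine spatiotemporal registration
# --------------------------------------------------------------------------


def register_perfusion_to_cine(
    perf_slice: PerfusionSlice,
    cine: CineSeries,
    roi_rect: tuple[int, int, int, int],
    cfg: RegistrationConfig = RegistrationConfig(),
    frame: int | None = None,
) -> tuple[SpatioTemporalParams, PhaseSelection]:
    """Slice-to-4D registration of a maximal-contrast perfusion slice.

    The temporal position is initialised by ECG trigger-delay normalisation
    and constrained to a hard window of +-``cfg.temporal_halfwidth`` phases;
    the centre of rotation sits at the ROI centre; {theta, Tx, Ty, Tz, Tphi}
    are optimised against an MI metric restricted to the elliptic ROI mask.

    The returned transform's ``tphi`` is the absolute converged temporal
    position, so applying it to a point with phase coordinate 0 lands at the
    matching cine phase.
    """
    n = cine.n_phases
    if frame is None:
        frame = perf_slice.n_frames - 1
    fixed = perf_slice.frames[..., frame]
    plane = perf_slice.plane
    mask = elliptic_mask(fixed.shape, roi_rect)
    phi_init = normalise_trigger_delay(perf_slice.trigger_delay_ms, perf_slice.rr_ms, n)
    # centre of rotation: ROI centre, in world mm
    ci = (roi_rect[0] + roi_rect[2] - 1) / 2
    cj = (roi_rect[1] + roi_rect[3] - 1) / 2
    centre = plane.plane_to_world(np.array([[ci, cj]]))[0]
    pts_fixed = plane.grid_points().reshape(-1, 3)[mask.ravel()]
    f_vals_full = fixed.ravel()[mask.ravel()]
    f_range = (float(fixed.min()), float(fixed.max()))
    m_range = (float(cine.data.min()), float(cine.data.max()))
    hw = cfg.temporal_halfwidth

    def make_cost(cine_data, f_vals):
        series = CineSeries(cine.grid, cine_data, cine.trigger_delay_ms, cine.rr_ms)

        def cost(x):
            params = SpatioTemporalParams(
                theta=x[0], cx=centre[0], cy=centre[1], tx=x[1], ty=x[2], tz=x[3]
            )
            pts = params.apply_points(pts_fixed)
            pts4 = np.concatenate(
                [pts, np.full((len(pts), 1), phi_init + x[4])], axis=1
            )
            m_vals = series.sample(pts4)
            return -mutual_information(
                f_vals, m_vals, bins=cfg.bins, fixed_range=f_range, moving_range=m_range
            )

        return cost

    x = np.zeros(5)
    scales = np.array([30.0, 1.0, 1.0, 1.0, 3.0])  # rad, mm, mm, mm, phase
    bounds = [(-np.pi, np.pi), (-30, 30), (-30, 30), (-20, 20), (-hw, hw)]
    converged = True
    sigmas = [cfg.smooth_sigma_px * (cfg.pyramid_levels - 1 - l) for l in range(cfg.pyramid_levels)]
    for sigma, (step, min_step) in zip(
        sigmas, [(cfg.gd_step, cfg.gd_min_step * 5)] + [(cfg.gd_step / 2, cfg.gd_min_step)] * 8
    ):
        if sigma > 0:
            cine_d = ndimage.gaussian_filter(cine.data, (sigma, sigma, 0, 0))
            f_vals = _smooth2d(fixed, sigma).ravel()[mask.ravel()]
        else:
            cine_d, f_vals = cine.data, f_vals_full
        cost = make_cost(cine_d, f_vals)
        x, _, ok = regular_step_descent(
            cost,
            x,
            scales,
            step=step,
            min_step=min_step,
            max_iter=cfg.gd_max_iter,
            bounds=bounds,
        )
        converged = converged and ok
    params = SpatioTemporalParams(
        theta=x[0],
        cx=centre[0],
        cy=centre[1],
        tx=x[1],
        ty=x[2],
        tz=x[3],
        tphi=phi_init + x[4],
    )
    # integer-phase metric trace at the converged spatial parameters
    cost_fine = make_cost(cine.data, f_vals_full)
    lo = int(np.floor(phi_init - hw))
    hi = int(np.ceil(phi_init + hw))
    phases = list(range(lo, hi + 1))
    values = [-cost_fine(np.array([x[0], x[1], x[2], x[3], p - phi_init])) for p in phases]
    selection = PhaseSelection(
        phases=phases,
        metric_values=values,
        selected_phase=int(np.round(params.tphi)) % n,
        transform=params,
        converged=converged,
        rule="round",
    )
    return params, selection


# --------------------------------------------------------------------------
# stage 3: angiography-to-cine phase selection
# --------------------------------------------------------------------------


def select_angiography_phase(
    angio: Volume3D,
    cine: CineSeries,
    roi_rect: tuple[int, int, int, int],
    cfg: RegistrationConfig = RegistrationConfig(),
) -> tuple[PhaseSelection, TranslationTransform]:
    """Translation-only registration against every cine phase.

    Each cine frame is the fixed image (its coarser grid keeps the metric
    sample count down) masked by the extruded elliptic ROI; the whole-heart
    volume moves.  The phase with the best final MI wins; its translation is
    T_A, mapping cine points into angiography space.
    """
    if not _grids_overlap(cine.grid, angio.grid):
        raise ValueError("angiography volume does not overlap the cine stack")
    in_plane = elliptic_mask((cine.grid.size[0], cine.grid.size[1]), roi_rect)
    mask3 = np.repeat(in_plane[:, :, None], cine.grid.size[2], axis=2)
    pts = cine.grid.meshgrid_world().reshape(-1, 3)[mask3.ravel()]
    m_range = (float(angio.data.min()), float(angio.data.max()))
    f_range = (float(cine.data.min()), float(cine.data.max()))
    sigmas = [cfg.smooth_sigma_px * (cfg.pyramid_levels - 1 - l) for l in range(cfg.pyramid_levels)]
    angio_levels = [
        Volume3D(angio.grid, ndimage.gaussian_filter(angio.data, (s, s, 0)) if s else angio.data)
        for s in sigmas
    ]
    values, transforms = [], []
    for p in range(cine.n_phases):
        x = np.zeros(3)
        for sigma, av, (step, min_step) in zip(
            sigmas,
            angio_levels,
            [(cfg.gd_step, cfg.gd_min_step * 5)] + [(cfg.gd_step / 2, cfg.gd_min_step)] * 8,
        ):
            fdata = (
                ndimage.gaussian_filter(cine.data[..., p], (sigma, sigma, 0))
                if sigma
                else cine.data[..., p]
            )
            f_vals = fdata.reshape(-1)[mask3.ravel()]

            def cost(t):
                return -mutual_information(
                    f_vals,
                    av.sample(pts + t),
                    bins=cfg.bins,
                    fixed_range=f_range,
                    moving_range=m_range,
                )

            x, c, _ = regular_step_descent(
                cost,
                x,
                np.ones(3),
                step=step,
                min_step=min_step,
                max_iter=cfg.gd_max_iter,
            )
        values.append(-c)
        transforms.append(TranslationTransform(tuple(x)))
    best = int(np.argmax(values))
    selection = PhaseSelection(
        phases=list(range(cine.n_phases)),
        metric_values=values,
        selected_phase=best,
        transform=transforms[best],
    )
    return selection, transforms[best]


# --------------------------------------------------------------------------
# stage 4: deformable phase-to-phase chain
# --------------------------------------------------------------------------


class BSplineStepTransform:
    """One deformable step: wraps a SimpleITK B-spline transform as a point map."""

    def __init__(self, transform: sitk.Transform, metric: float | None = None, flagged: bool = False):
        self.sitk_transform = transform
        self.metric = metric
        self.flagged = flagged

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        t = self.sitk_transform
        return np.array([t.TransformPoint(tuple(p)) for p in pts])

    def __call__(self, pts):
        return self.apply_points(pts)


class ChainTransform:
    """Ordered composition of point maps, applied sequentially.

    Keeping the per-step transforms avoids compounding interpolation error
    from resampling intermediate displacement fields.
    """

    def __init__(self, components: list):
        self.components = list(components)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        for c in self.components:
            pts = c.apply_points(pts) if hasattr(c, "apply_points") else c(pts)
        return pts

    def __call__(self, pts):
        return self.apply_points(pts)

    def __len__(self):
        return len(self.components)


def _to_sitk(vol: Volume3D) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.grid.origin))
    img.SetDirection(tuple(vol.grid.direction.flatten()))
    return img


def register_phase_pair(
    fixed: Volume3D,
    moving: Volume3D,
    init: BSplineStepTransform | None = None,
    cfg: RegistrationConfig = RegistrationConfig(),
    roi_rect: tuple[int, int, int, int] | None = None,
) -> BSplineStepTransform:
    """B-spline deformable registration of one cine phase pair.

    Mattes MI, L-BFGS-B, two image-pyramid levels, seeded metric sampling for
    reproducibility.  ``init`` warm-starts the mesh coefficients (the mesh
    lives on the shared cine grid, so parameters carry over between
    consecutive steps).  ``roi_rect`` restricts the metric to the extruded
    elliptic mask inscribed in the in-plane rectangle.
    """
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    tx = sitk.BSplineTransformInitializer(f_img, [int(m) for m in cfg.bspline_mesh])
    if init is not None:
        tx.SetParameters(init.sitk_transform.GetParameters())
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(cfg.bins)
    reg.SetInterpolator(sitk.sitkLinear)
    if roi_rect is not None:
        in_plane = elliptic_mask((fixed.grid.size[0], fixed.grid.size[1]), roi_rect)
        mask3 = np.repeat(in_plane[:, :, None], fixed.grid.size[2], axis=2)
        m = sitk.GetImageFromArray(
            np.ascontiguousarray(mask3.transpose(2, 1, 0).astype(np.uint8))
        )
        m.CopyInformation(f_img)
        reg.SetMetricFixedMask(m)
    if cfg.bspline_sampling < 1.0:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(cfg.bspline_sampling, cfg.sampling_seed)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=cfg.bspline_iterations,
        maximumNumberOfCorrections=5,
        maximumNumberOfFunctionEvaluations=1000,
        costFunctionConvergenceFactor=1e7,
    )
    reg.SetInitialTransform(tx, inPlace=True)
    shrink = [2, 1][-cfg.pyramid_levels:]
    sigmas = [1, 0][-cfg.pyramid_levels:]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    try:
        reg.Execute(f_img, m_img)
        return BSplineStepTransform(tx, metric=reg.GetMetricValue())
    except RuntimeError:
        ident = sitk.BSplineTransformInitializer(f_img, [int(m) for m in cfg.bspline_mesh])
        return BSplineStepTransform(ident, metric=None, flagged=True)


def cyclic_step(phi_a: int, target: int, n: int) -> tuple[int, int]:
    """(direction, distance) of the shorter cyclic arc from phi_a to target."""
    d_plus = (target - phi_a) % n
    d_minus = (phi_a - target) % n
    if d_plus <= d_minus:
        return +1, d_plus
    return -1, d_minus


@dataclass
class PhaseChainResult:
    """Per-step transforms and accumulated compositions per target phase."""

    phi_a: int
    targets: dict[str, int]  # slice location -> perfusion-selected phase
    direct: dict[int, ChainTransform] = field(default_factory=dict)
    inverse: dict[int, ChainTransform] = field(default_factory=dict)
    steps: dict[int, list] = field(default_factory=dict)  # direction -> step transforms

    def n_steps(self) -> int:
        return sum(len(s) for s in self.steps.values())


def _snapshot(step: BSplineStepTransform) -> BSplineStepTransform:
    tx = step.sitk_transform
    copy = sitk.BSplineTransform(3, 3)
    copy.SetFixedParameters(tx.GetFixedParameters())
    copy.SetParameters(tx.GetParameters())
    return BSplineStepTransform(copy, metric=step.metric, flagged=step.flagged)


def build_phase_chain(
    cine: CineSeries,
    phi_a: int,
    targets: dict[str, int],
    cfg: RegistrationConfig = RegistrationConfig(),
    roi_rect: tuple[int, int, int, int] | None = None,
) -> PhaseChainResult:
    """Walk the cine cycle from the angiography phase to each perfusion phase.

    Eulerian incremental registration: at every step along the shorter cyclic
    arc, the angiography-selected frame (the moving image throughout) is
    re-registered to the next fixed frame, initialised with the accumulated
    transform of the preceding step.  The accumulated transform is therefore a
    single B-spline refined as the span grows — a direct long-span
    registration would fail for spans over a few phases, while each
    incremental refinement only has to absorb one phase's worth of motion.
    Parameter snapshots are recorded whenever the walk passes a target phase
    (the longest arc per direction is registered once; nearer targets are the
    recorded intermediate states).  The inverse transforms are estimated
    simultaneously by swapping the fixed and moving images.

    The direct transform of target t maps frame-t points onto the
    angiography-phase frame (for resampling images into the perfusion-selected
    phase); the inverse maps angiography-phase points onto frame t (for
    warping coronary point sets).
    """
    if not targets:
        raise ValueError("at least one target phase is required")
    n = cine.n_phases
    phi_a = int(phi_a) % n
    result = PhaseChainResult(phi_a=phi_a, targets={k: int(v) % n for k, v in targets.items()})
    arcs: dict[int, int] = {}
    for t in result.targets.values():
        d, m = cyclic_step(phi_a, t, n)
        if m:
            arcs[d] = max(arcs.get(d, 0), m)
    identity = ChainTransform([])
    for t in result.targets.values():
        if t == phi_a:
            result.direct[t] = identity
            result.inverse[t] = identity
    moving = cine.phase_volume(phi_a)
    for direction, m in arcs.items():
        steps: list[tuple[BSplineStepTransform, BSplineStepTransform]] = []
        acc_f = acc_i = None
        for k in range(1, m + 1):
            p_k = (phi_a + direction * k) % n
            fixed = cine.phase_volume(p_k)
            acc_f = register_phase_pair(fixed, moving, init=acc_f, cfg=cfg, roi_rect=roi_rect)
            acc_i = register_phase_pair(moving, fixed, init=acc_i, cfg=cfg, roi_rect=roi_rect)
            snap_f, snap_i = _snapshot(acc_f), _snapshot(acc_i)
            steps.append((snap_f, snap_i))
            for t in result.targets.values():
                dt, mt = cyclic_step(phi_a, t, n)
                if dt == direction and mt == k:
                    result.direct[t] = ChainTransform([snap_f])
                    result.inverse[t] = ChainTransform([snap_i])
        result.steps[direction] = steps
    return result
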