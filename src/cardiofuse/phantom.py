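"""Synthetic cardiac phantom with analytic ground truth.

The phantom emulates the three MR acquisitions the pipeline consumes — a 4D
cine stack, a high-resolution whole-heart angiography volume with bright
coronary vessels, and a dynamic three-slice first-pass perfusion series — all
rendered from one closed-form deforming left ventricle, so every stage of
registration, motion correction and territory mapping can be scored against
exact truth.

Deformation model (about the LV long axis, here the z axis): a phase-dependent
radial contraction ``r' = r * (1 - a * sin^2(pi * p / n))`` combined with a
long-axis twist linear in distance from the base and peaking mid-cycle.  Both
are smooth and invertible in closed form; phase 0 is end-diastole (identity).
Peak epicardial displacement at the default amplitude is ~7 mm, the magnitude
reported for coronary points between end-systole and end-diastole.

Image intensity is a function of *material* (reference-configuration)
coordinates, so a gentle angular texture inside the myocardium advects with
the deformation the way trabecular features do in real cine images; deformable
registration has something to grip between edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    CineSeries,
    ImageGrid,
    Contour,
    PerfusionSeries,
    PerfusionSlice,
    SlicePlane,
    Volume3D,
)
from .territories import CoronaryTree, GROUPS

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "default_respiratory_trace",
    "gamma_variate",
    "make_cine_phantom",
    "make_angiography_phantom",
    "make_perfusion_phantom",
    "inject_misalignment",
]


def gamma_variate(t, t0: float, alpha: float, beta: float, amplitude: float):
    """First-pass bolus model, peak ``amplitude`` at ``t0 + alpha*beta``."""
    t = np.asarray(t, dtype=float)
    u = np.clip(t - t0, 0.0, None)
    peak = (alpha * beta) ** alpha * np.exp(-alpha)
    return amplitude * np.where(u > 0, u**alpha * np.exp(-u / beta) / peak, 0.0)


def default_respiratory_trace(
    n_frames: int,
    amplitude_mm: float = 6.0,
    period_frames: float = 5.0,
    breath_hold: tuple[int, int] = (8, 28),
) -> np.ndarray:
    """Breath-hold rest period followed by drift plus shallow sinusoid.

    Returns per-frame 3D translations (mm); through-plane (z) component zero,
    matching the in-plane view of respiratory motion the 2D correction takes.
    """
    t = np.arange(n_frames, dtype=float)
    lo, hi = breath_hold
    out = np.zeros((n_frames, 3))
    after = np.clip(t - hi, 0, None)
    before = np.clip(lo - t, 0, None)
    envelope = 1 - np.exp(-(after + before) / 3.0)
    osc = np.sin(2 * np.pi * t / period_frames)
    drift = 0.4 * np.sqrt(after)
    out[:, 0] = envelope * (0.7 * amplitude_mm * osc) + drift
    out[:, 1] = envelope * (0.4 * amplitude_mm * np.sin(2 * np.pi * t / period_frames + 1.1))
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """All tunable phantom parameters (mm, rad, phase counts)."""

    # grids
    cine_size: tuple[int, int, int] = (64, 64, 12)
    cine_spacing: tuple[float, float, float] = (2.5, 2.5, 10.0)
    angio_size: tuple[int, int, int] = (96, 96, 80)
    angio_spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    perf_size: tuple[int, int] = (64, 64)
    perf_spacing: tuple[float, float] = (2.5, 2.5)
    n_phases: int = 12
    n_frames: int = 40
    rr_ms: float = 1000.0
    # LV geometry: long axis along +z, apex low, base high
    lv_center: tuple[float, float] = (0.0, 0.0)
    apex_z: float = -50.0
    base_z: float = 50.0
    endo_radius: float = 18.0
    epi_radius: float = 30.0
    edge_mm: float = 2.0  # smoothstep width of tissue interfaces
    # motion
    contraction_amplitude: float = 0.2
    twist_amplitude: float = 0.15
    systolic_fraction: float = 0.4  # peak contraction at this fraction of the cycle
    respiratory_trace: np.ndarray | None = None  # (n_frames, 3) mm; default trace if None
    # perfusion acquisition
    slice_fractions: tuple[float, float, float] = (0.85, 0.60, 0.35)  # apex->base
    slice_phase_fractions: tuple[float, float, float] = (0.2, 0.45, 0.7)
    # contrast model: (t0, alpha, beta, amplitude) in frame units
    rv_bolus: tuple[float, float, float, float] = (4.0, 3.0, 1.5, 1.6)
    lv_bolus: tuple[float, float, float, float] = (8.0, 3.0, 2.0, 1.4)
    myo_bolus: tuple[float, float, float, float] = (12.0, 3.0, 3.0, 0.7)
    # cardiac phase the whole-heart acquisition captures (end-diastole = 0)
    angio_phase: float = 0.0
    # coronary tree layout: trunk angles (rad) about the long axis
    trunk_angles: dict = field(
        default_factory=lambda: {"RCA": np.pi / 2, "LAD": 7 * np.pi / 6, "LCX": 11 * np.pi / 6}
    )
    with_branches: bool = True
    vessel_radius: float = 1.5
    # right ventricle (static half-annulus attached at the septum)
    rv_angle: float = np.pi  # angular position of the RV centre
    hypo_territory: str | None = None
    hypo_factor: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.endo_radius >= self.epi_radius:
            raise ValueError("endocardial radius must be smaller than epicardial")
        if self.contraction_amplitude < 0 or self.twist_amplitude < 0:
            raise ValueError("motion amplitudes must be non-negative")
        if self.n_phases < 4:
            raise ValueError("need at least 4 cardiac phases")
        if self.contraction_amplitude >= 1:
            raise ValueError("contraction amplitude must be < 1")

    # --- derived geometry -------------------------------------------------
    @property
    def lv_length(self) -> float:
        return self.base_z - self.apex_z

    def height_fraction(self, z):
        """0 at apex, 1 at base, clipped."""
        return np.clip((np.asarray(z, dtype=float) - self.apex_z) / self.lv_length, 0.0, 1.0)

    def radius_profile(self, z, r_base):
        """Bullet-shaped taper of a base radius toward the apex."""
        return r_base * np.sqrt(self.height_fraction(z))

    def slice_z(self, location: str) -> float:
        idx = {"basal": 0, "medial": 1, "apical": 2}[location]
        return self.apex_z + self.slice_fractions[idx] * self.lv_length

    def slice_phase(self, location: str) -> float:
        idx = {"basal": 0, "medial": 1, "apical": 2}[location]
        return self.slice_phase_fractions[idx] * self.n_phases

    def cine_grid(self) -> ImageGrid:
        size, sp = self.cine_size, self.cine_spacing
        origin = tuple(-(n - 1) / 2 * s for n, s in zip(size, sp))
        return ImageGrid(size=size, spacing=sp, origin=origin)

    def angio_grid(self) -> ImageGrid:
        size, sp = self.angio_size, self.angio_spacing
        origin = tuple(-(n - 1) / 2 * s for n, s in zip(size, sp))
        return ImageGrid(size=size, spacing=sp, origin=origin)

    def perf_plane(self, location: str) -> SlicePlane:
        z = self.slice_z(location)
        nu, nv = self.perf_size
        su, sv = self.perf_spacing
        return SlicePlane(
            origin=(-(nu - 1) / 2 * su, -(nv - 1) / 2 * sv, z),
            u=(1.0, 0.0, 0.0),
            v=(0.0, 1.0, 0.0),
            size=(nu, nv),
            spacing=(su, sv),
            thickness=10.0,
        )


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


class PhantomTruth:
    """Closed-form ground truth attached to one :class:`PhantomSpec`.

    Exposes the analytic deformation (forward/inverse/phase-to-phase), true
    contours and coronary points per phase, the construction territory labels,
    injected respiratory translations and stack offsets, and the contrast
    model's maximal-contrast frame.
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.respiratory_mm = (
            np.array(spec.respiratory_trace, dtype=float)
            if spec.respiratory_trace is not None
            else default_respiratory_trace(spec.n_frames)
        )
        if self.respiratory_mm.shape != (spec.n_frames, 3):
            raise ValueError("respiratory trace must be (n_frames, 3)")
        self.stack_offsets_mm = np.zeros((spec.cine_size[2], 2))
        self.perfusion_phases = {loc: spec.slice_phase(loc) for loc in ("basal", "medial", "apical")}

    # --- analytic deformation --------------------------------------------
    def activation(self, phase: float) -> float:
        """Contractile activation in [0, 1]: ``sin^2(pi * h(u))`` with the cycle
        fraction ``u`` warped so peak contraction falls at ``systolic_fraction``
        — systole is shorter than diastole, which breaks the mirror symmetry
        that would otherwise make pre- and post-systolic phases look alike.
        """
        u = np.mod(phase, self.spec.n_phases) / self.spec.n_phases
        f = self.spec.systolic_fraction
        h = np.where(u < f, 0.5 * u / f, 0.5 + 0.5 * (u - f) / (1 - f))
        return np.sin(np.pi * h) ** 2

    def _factors(self, phase: float):
        g = self.activation(phase)
        s = 1 - self.spec.contraction_amplitude * g
        return s, g

    def forward_map(self, phase: float, pts: np.ndarray) -> np.ndarray:
        """Map reference (end-diastolic) points to their position at ``phase``."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        cx, cy = self.spec.lv_center
        s, g = self._factors(phase)
        x, y, z = pts[:, 0] - cx, pts[:, 1] - cy, pts[:, 2]
        r = np.hypot(x, y) * s
        tw = self.spec.twist_amplitude * (1 - self.spec.height_fraction(z)) * g
        th = np.arctan2(y, x) + tw
        out = np.empty_like(pts)
        out[:, 0] = cx + r * np.cos(th)
        out[:, 1] = cy + r * np.sin(th)
        out[:, 2] = z
        return out

    def inverse_map(self, phase: float, pts: np.ndarray) -> np.ndarray:
        """Map points observed at ``phase`` back to reference coordinates."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        cx, cy = self.spec.lv_center
        s, g = self._factors(phase)
        x, y, z = pts[:, 0] - cx, pts[:, 1] - cy, pts[:, 2]
        r = np.hypot(x, y) / s
        tw = self.spec.twist_amplitude * (1 - self.spec.height_fraction(z)) * g
        th = np.arctan2(y, x) - tw
        out = np.empty_like(pts)
        out[:, 0] = cx + r * np.cos(th)
        out[:, 1] = cy + r * np.sin(th)
        out[:, 2] = z
        return out

    def phase_to_phase(self, p: float, q: float, pts: np.ndarray) -> np.ndarray:
        """Carry points observed at phase ``p`` to their position at phase ``q``."""
        return self.forward_map(q, self.inverse_map(p, pts))

    def displacement(self, p: float, q: float, pts: np.ndarray) -> np.ndarray:
        return self.phase_to_phase(p, q, pts) - np.atleast_2d(np.asarray(pts, dtype=float))

    # --- structures --------------------------------------------------------
    def contour(self, role: str, z: float, phase: float = 0.0, n_points: int = 120) -> Contour:
        """True LV contour at height ``z`` and cardiac ``phase`` (fixed ordering)."""
        r_base = {"lv-endo": self.spec.endo_radius, "lv-epi": self.spec.epi_radius}[role]
        r = self.spec.radius_profile(z, r_base)
        th = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
        cx, cy = self.spec.lv_center
        ref = np.stack(
            [cx + r * np.cos(th), cy + r * np.sin(th), np.full(n_points, float(z))], axis=1
        )
        return Contour(points=self.forward_map(phase, ref), role=role)

    def myocardium_mask(self, plane: SlicePlane, phase: float = 0.0) -> np.ndarray:
        """Boolean myocardium mask on a plane's pixel grid at a phase."""
        pts = plane.grid_points().reshape(-1, 3)
        ref = self.inverse_map(phase, pts)
        cx, cy = self.spec.lv_center
        r = np.hypot(ref[:, 0] - cx, ref[:, 1] - cy)
        r_en = self.spec.radius_profile(ref[:, 2], self.spec.endo_radius)
        r_ep = self.spec.radius_profile(ref[:, 2], self.spec.epi_radius)
        inside = (r >= r_en) & (r <= r_ep) & (ref[:, 2] >= self.spec.apex_z) & (
            ref[:, 2] <= self.spec.base_z
        )
        return inside.reshape(plane.size)

    def territory_label(self, pts: np.ndarray) -> np.ndarray:
        """Construction-truth supply territory: nearest trunk by circular angle."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        cx, cy = self.spec.lv_center
        th = np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)
        names = list(self.spec.trunk_angles)
        d = np.stack(
            [
                np.abs(np.angle(np.exp(1j * (th - a))))
                for a in self.spec.trunk_angles.values()
            ],
            axis=1,
        )
        return np.asarray(names, dtype=object)[np.argmin(d, axis=1)]

    def tree_at_phase(self, phase: float) -> CoronaryTree:
        ref = _reference_tree(self.spec)
        return CoronaryTree(
            segments={s: self.forward_map(phase, p) for s, p in ref.segments.items()}
        )

    # --- contrast model -----------------------------------------------------
    def compartment_curves(self, frames=None) -> dict[str, np.ndarray]:
        t = np.arange(self.spec.n_frames) if frames is None else np.asarray(frames)
        return {
            "rv": gamma_variate(t, *self.spec.rv_bolus),
            "lv": gamma_variate(t, *self.spec.lv_bolus),
            "myo": gamma_variate(t, *self.spec.myo_bolus),
        }

    @property
    def max_contrast_frame(self) -> int:
        t0, alpha, beta, _ = self.spec.myo_bolus
        peak = t0 + alpha * beta
        t = np.arange(self.spec.n_frames)
        return int(np.argmin(np.abs(t - peak)))


# --- intensity model -------------------------------------------------------


def _wave_field(seed: int, n_waves: int, wavelength_mm: tuple[float, float]):
    """Deterministic band-limited random field: a sum of 3D cosine waves.

    Analytic, so it evaluates consistently at any point of any acquisition
    grid; used for the static thoracic background clutter and the advected
    myocardial texture that real cine images carry and registration relies on.
    """
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    wl = rng.uniform(*wavelength_mm, size=n_waves)
    k = dirs * (2 * np.pi / wl)[:, None]
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    amps = rng.uniform(0.5, 1.0, size=n_waves)
    amps /= np.sqrt((amps**2).sum() / 2)  # unit-ish variance

    def field(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return np.cos(pts @ k.T + phases) @ amps

    return field


def _tissue_fields(spec: PhantomSpec, ref_pts: np.ndarray):
    """Soft compartment memberships and structural intensity at reference points.

    Returns (background, myo, lv_pool, rv_pool, texture) weights in [0, 1].
    """
    cx, cy = spec.lv_center
    x = ref_pts[:, 0] - cx
    y = ref_pts[:, 1] - cy
    z = ref_pts[:, 2]
    r = np.hypot(x, y)
    th = np.arctan2(y, x)
    e = spec.edge_mm
    r_en = spec.radius_profile(z, spec.endo_radius)
    r_ep = spec.radius_profile(z, spec.epi_radius)
    in_lv_extent = _smoothstep((z - spec.apex_z) / e) * _smoothstep((spec.base_z - z) / e)
    lv_pool = _smoothstep((r_en - r) / e) * in_lv_extent
    myo = _smoothstep((r - r_en) / e) * _smoothstep((r_ep - r) / e) * in_lv_extent
    # RV: crescent hugging the epicardium on the septal side, upper half of LV
    rv_c = spec.radius_profile(z, spec.epi_radius + 10.0)
    d_ang = np.angle(np.exp(1j * (th - spec.rv_angle)))
    rv_pool = (
        _smoothstep((r - r_ep) / e)
        * _smoothstep(((rv_c + 8.0) - r) / e)
        * _smoothstep((1.2 - np.abs(d_ang)) / 0.3)
        * _smoothstep((z - (spec.apex_z + 0.4 * spec.lv_length)) / (2 * e))
        * in_lv_extent
    )
    myo_waves = _wave_field(spec.seed + 11, 12, (10.0, 25.0))
    texture = (
        1.0
        + 0.18 * np.cos(3 * th + 2 * np.pi * z / 45.0)
        + 0.22 * myo_waves(ref_pts)
    )
    # thoracic clutter: band-limited structure everywhere (advects with the
    # same analytic field, so the truth displacement stays exact image-wide)
    clutter = _wave_field(spec.seed + 12, 14, (18.0, 45.0))(ref_pts)
    background = np.clip(1.0 - lv_pool - myo - rv_pool, 0.0, 1.0)
    return background, myo, lv_pool, rv_pool, texture, clutter


def _structural_intensity(spec: PhantomSpec, ref_pts: np.ndarray) -> np.ndarray:
    bg, myo, lv, rv, tex, clutter = _tissue_fields(spec, ref_pts)
    return 0.05 * bg + 0.45 * myo * tex + 0.85 * lv + 0.75 * rv + 0.06 * clutter


def _apply_noise(data: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return data
    return np.hypot(data + rng.normal(0, sigma, data.shape), rng.normal(0, sigma, data.shape))


# --- generators ------------------------------------------------------------


def make_cine_phantom(spec: PhantomSpec) -> tuple[CineSeries, PhantomTruth]:
    """Render the 4D cine acquisition and its analytic truth."""
    grid = spec.cine_grid()
    extent_xy = min(grid.size[0] * grid.spacing[0], grid.size[1] * grid.spacing[1])
    if extent_xy < 2 * spec.epi_radius:
        raise ValueError("cine grid too small to contain the LV")
    truth = PhantomTruth(spec)
    rng = np.random.default_rng(spec.seed)
    pts = grid.meshgrid_world().reshape(-1, 3)
    data = np.empty(tuple(grid.size) + (spec.n_phases,))
    for p in range(spec.n_phases):
        ref = truth.inverse_map(p, pts)
        data[..., p] = _structural_intensity(spec, ref).reshape(grid.size)
    data = _apply_noise(data, spec.noise_sigma, rng)
    n_sl = grid.size[2]
    phases = np.arange(spec.n_phases, dtype=float)
    trig = np.tile(phases / spec.n_phases * spec.rr_ms, (n_sl, 1))
    cine = CineSeries(
        grid=grid, data=data, trigger_delay_ms=trig, rr_ms=np.full(n_sl, spec.rr_ms)
    )
    return cine, truth


def _reference_tree(spec: PhantomSpec) -> CoronaryTree:
    """Centreline points on the end-diastolic epicardial surface.

    Nine segments in the conventional grouping: RCA trunk + PDA; LMS, LAD, two
    diagonals; LCX and two obtuse marginals.  Branches stay within +-0.3 rad of
    their trunk so the construction-truth angular sectors remain meaningful.
    """

    def surface_points(angles, h_fracs):
        z = spec.apex_z + np.asarray(h_fracs) * spec.lv_length
        r = spec.radius_profile(z, spec.epi_radius)
        cx, cy = spec.lv_center
        return np.stack(
            [cx + r * np.cos(angles), cy + r * np.sin(angles), z], axis=1
        )

    def run(angle0, angle1, h0, h1, n=40):
        t = np.linspace(0, 1, n)
        return surface_points(angle0 + (angle1 - angle0) * t, h0 + (h1 - h0) * t)

    a = spec.trunk_angles
    if not a:
        return CoronaryTree(segments={s: np.zeros((0, 3)) for s in range(1, 10)})
    segments: dict[int, np.ndarray] = {}
    segments[1] = run(a["RCA"], a["RCA"], 0.95, 0.45)  # RCA trunk
    segments[3] = run(a["LAD"], a["LAD"], 0.98, 0.90, n=10)  # LMS
    segments[4] = run(a["LAD"], a["LAD"], 0.90, 0.15)  # LAD
    segments[7] = run(a["LCX"], a["LCX"], 0.95, 0.40)  # LCX
    if spec.with_branches:
        segments[2] = run(a["RCA"], a["RCA"] + 0.25, 0.45, 0.20, n=20)  # PDA
        segments[5] = run(a["LAD"], a["LAD"] + 0.25, 0.75, 0.55, n=20)  # D1
        segments[6] = run(a["LAD"], a["LAD"] - 0.25, 0.55, 0.35, n=20)  # D2
        segments[8] = run(a["LCX"], a["LCX"] + 0.25, 0.70, 0.50, n=20)  # OM1
        segments[9] = run(a["LCX"], a["LCX"] - 0.25, 0.55, 0.35, n=20)  # OM2
    else:
        for s in (2, 5, 6, 8, 9):
            segments[s] = np.zeros((0, 3))
    return CoronaryTree(segments=segments)


def make_angiography_phantom(spec: PhantomSpec) -> tuple[Volume3D, CoronaryTree]:
    """Render the whole-heart volume with bright coronary tubes.

    The volume captures the cardiac phase ``spec.angio_phase`` (default 0,
    end-diastole — the diastolic rest period a navigator-gated whole-heart
    acquisition targets); the returned tree is deformed to the same phase.
    """
    grid = spec.angio_grid()
    pts = grid.meshgrid_world().reshape(-1, 3)
    truth = PhantomTruth(spec)
    ref = truth.inverse_map(spec.angio_phase, pts) if spec.angio_phase else pts
    data = _structural_intensity(spec, ref)
    tree = _reference_tree(spec)
    if spec.angio_phase:
        tree = tree.transformed(lambda p: truth.forward_map(spec.angio_phase, p))
    all_pts = tree.all_points()
    if len(all_pts):
        # densify the centrelines, then paint a Gaussian tube profile
        dense = []
        for seg in tree.segments.values():
            if len(seg) < 2:
                continue
            for p0, p1 in zip(seg[:-1], seg[1:]):
                n = max(2, int(np.linalg.norm(p1 - p0) / 0.5))
                dense.append(p0 + (p1 - p0) * np.linspace(0, 1, n)[:, None])
        dense = np.concatenate(dense, axis=0)
        d, _ = cKDTree(dense).query(pts, distance_upper_bound=4 * spec.vessel_radius)
        vessel = np.where(np.isfinite(d), np.exp(-((d / spec.vessel_radius) ** 2)), 0.0)
        data = np.maximum(data, 1.0 * vessel)
    vol = Volume3D(grid, data.reshape(grid.size))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        vol.data = _apply_noise(vol.data, spec.noise_sigma, rng)
    return vol, tree


def make_perfusion_phantom(spec: PhantomSpec) -> tuple[PerfusionSeries, PhantomTruth]:
    """Render the three-slice dynamic perfusion acquisition.

    Each slice location is acquired at its own cardiac phase every heartbeat
    (ECG gating); intensities follow gamma-variate bolus passage through RV
    pool, LV pool and myocardium; the respiratory trace translates the imaged
    anatomy in-plane frame by frame.
    """
    truth = PhantomTruth(spec)
    rng = np.random.default_rng(spec.seed + 2)
    curves = truth.compartment_curves()
    slices: dict[str, PerfusionSlice] = {}
    for loc in ("basal", "medial", "apical"):
        plane = spec.perf_plane(loc)
        z = spec.slice_z(loc)
        if not (spec.apex_z < z < spec.base_z):
            raise ValueError(f"{loc} slice plane lies outside the LV extent")
        phase = spec.slice_phase(loc)
        base_pts = plane.grid_points().reshape(-1, 3)
        frames = np.empty(tuple(plane.size) + (spec.n_frames,))
        for f in range(spec.n_frames):
            # anatomy translated by the respiratory offset: image content at x
            # shows tissue at x - resp
            pts = base_pts - truth.respiratory_mm[f]
            ref = truth.inverse_map(phase, pts)
            bg, myo, lv, rv, tex, clutter = _tissue_fields(spec, ref)
            myo_gain = np.ones(len(ref))
            if spec.hypo_territory is not None:
                lab = truth.territory_label(ref)
                myo_gain[lab == spec.hypo_territory] = spec.hypo_factor
            img = (
                0.05 * bg
                + myo * tex * (0.25 + curves["myo"][f] * myo_gain)
                + lv * (0.20 + curves["lv"][f])
                + rv * (0.20 + curves["rv"][f])
                + 0.06 * clutter
            )
            frames[..., f] = img.reshape(plane.size)
        frames = _apply_noise(frames, spec.noise_sigma, rng)
        slices[loc] = PerfusionSlice(
            plane=plane,
            frames=frames,
            trigger_delay_ms=phase / spec.n_phases * spec.rr_ms,
            rr_ms=spec.rr_ms,
        )
    series = PerfusionSeries(slices=slices, max_contrast_frame=truth.max_contrast_frame)
    return series, truth


def render_perfusion_slice(
    spec: PhantomSpec,
    location: str,
    phase: float | None = None,
    frame: int | None = None,
    respiratory_mm=(0.0, 0.0, 0.0),
    spatial_map=None,
) -> PerfusionSlice:
    """Render one perfusion slice analytically, with optional injected motion.

    ``spatial_map`` (a point map, e.g. a spatiotemporal transform's spatial
    action) displaces the sampling positions before evaluation, so the imaged
    anatomy appears moved by the *inverse* of that map — registering the result
    back to the cine phantom recovers exactly ``spatial_map``.  Used to build
    recovery experiments with known truth.
    """
    truth = PhantomTruth(spec)
    plane = spec.perf_plane(location)
    if phase is None:
        phase = spec.slice_phase(location)
    if frame is None:
        frame = truth.max_contrast_frame
    curves = truth.compartment_curves([frame])
    pts = plane.grid_points().reshape(-1, 3)
    if spatial_map is not None:
        pts = np.asarray(spatial_map(pts), dtype=float)
    pts = pts - np.asarray(respiratory_mm, dtype=float)
    ref = truth.inverse_map(phase, pts)
    bg, myo, lv, rv, tex, clutter = _tissue_fields(spec, ref)
    img = (
        0.05 * bg
        + myo * tex * (0.25 + float(curves["myo"][0]))
        + lv * (0.20 + float(curves["lv"][0]))
        + rv * (0.20 + float(curves["rv"][0]))
        + 0.06 * clutter
    )
    return PerfusionSlice(
        plane=plane,
        frames=img.reshape(plane.size)[..., None],
        trigger_delay_ms=(phase % spec.n_phases) / spec.n_phases * spec.rr_ms,
        rr_ms=spec.rr_ms,
    )


def inject_misalignment(cine: CineSeries, per_slice_offsets_mm) -> CineSeries:
    """Translate each cine slice in-plane by its offset, across all phases.

    Emulates breath-hold inconsistency between slice acquisitions: the imaged
    content of slice k moves by ``offsets[k]`` (mm) in every phase.
    """
    offsets = np.asarray(per_slice_offsets_mm, dtype=float)
    if offsets.shape != (cine.n_slices, 2):
        raise ValueError("need one (x, y) mm offset per slice")
    out = cine.copy()
    from scipy import ndimage as ndi

    sx, sy = cine.grid.spacing[0], cine.grid.spacing[1]
    for k in range(cine.n_slices):
        if np.allclose(offsets[k], 0):
            continue
        shift_px = (offsets[k][0] / sx, offsets[k][1] / sy)
        for p in range(cine.n_phases):
            out.data[:, :, k, p] = ndi.shift(
                cine.data[:, :, k, p], shift_px, order=1, mode="constant", cval=0.0
            )
    return out
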