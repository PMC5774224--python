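"""Shared geometric and image data model.

Conventions used throughout the package:

* world coordinates are physical millimetres,
* voxel indices are 0-based and arrays are indexed ``[i, j, k]`` along the
  (x, y, z) grid axes (the NIfTI convention), intervals are half-open,
* the 4th (cardiac phase) axis is measured in phase *index* units and is
  cyclic modulo ``n_phases``; all cyclic arithmetic lives in
  :class:`CineSeries` and :func:`wrap_phase`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "Volume3D",
    "SlicePlane",
    "CineSeries",
    "PerfusionSlice",
    "PerfusionSeries",
    "Contour",
    "wrap_phase",
    "resample_volume",
    "reformat_slice",
]


def wrap_phase(phi, n_phases: int):
    """Wrap a continuous phase index into ``[0, n_phases)``.

    Guards the half-open upper bound: for a tiny negative input floating-point
    modulo can return exactly ``n_phases``.
    """
    out = np.mod(phi, n_phases)
    return np.where(out >= n_phases, 0.0, out) if np.ndim(out) else (
        0.0 if out >= n_phases else float(out)
    )


@dataclass(frozen=True)
class ImageGrid:
    """Regular sampling grid: voxel lattice embedded in physical space.

    ``world = origin + direction @ (spacing * index)``.
    """

    size: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...]
    direction: np.ndarray | None = None  # (ndim, ndim) orthonormal

    def __post_init__(self):
        size = tuple(int(s) for s in self.size)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(size) != len(spacing) or len(size) != len(origin):
            raise ValueError("size, spacing and origin must have equal length")
        if any(s <= 0 for s in size):
            raise ValueError("grid size must be positive on every axis")
        if any(s <= 0 for s in spacing):
            raise ValueError("grid spacing must be positive on every axis")
        d = self.direction
        if d is None:
            d = np.eye(len(size))
        d = np.asarray(d, dtype=float)
        if d.shape != (len(size), len(size)):
            raise ValueError("direction matrix shape mismatch")
        if not np.allclose(d @ d.T, np.eye(len(size)), atol=1e-8):
            raise ValueError("direction vectors must be orthonormal")
        object.__setattr__(self, "size", size)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", d)

    @property
    def ndim(self) -> int:
        return len(self.size)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        sp = np.asarray(self.spacing)
        return np.asarray(self.origin) + (idx * sp) @ self.direction.T

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        rel = (pts - np.asarray(self.origin)) @ self.direction
        return rel / np.asarray(self.spacing)

    def meshgrid_world(self) -> np.ndarray:
        """All voxel centres as an ``size + (ndim,)`` array of world points."""
        axes = [np.arange(n, dtype=float) for n in self.size]
        idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return self.index_to_world(idx.reshape(-1, self.ndim)).reshape(
            tuple(self.size) + (self.ndim,)
        )


@dataclass
class Volume3D:
    """A 3D scalar image on an :class:`ImageGrid`."""

    grid: ImageGrid
    data: np.ndarray

    def __post_init__(self):
        if self.grid.ndim != 3:
            raise ValueError("Volume3D requires a 3-axis grid")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != tuple(self.grid.size):
            raise ValueError(
                f"array shape {self.data.shape} does not match grid size {self.grid.size}"
            )

    def sample(self, pts: np.ndarray, order: int = 1, background: float = 0.0) -> np.ndarray:
        """Interpolate intensities at world points (trilinear by default)."""
        idx = self.grid.world_to_index(np.asarray(pts, dtype=float))
        return ndimage.map_coordinates(
            self.data, idx.T, order=order, mode="constant", cval=background
        )

    def copy(self) -> "Volume3D":
        return Volume3D(self.grid, self.data.copy())


@dataclass(frozen=True)
class SlicePlane:
    """2D sampling plane in 3D space: origin plus two in-plane axes.

    ``world(i, j) = origin + i*spacing[0]*u + j*spacing[1]*v``.
    """

    origin: tuple[float, float, float]
    u: tuple[float, float, float]
    v: tuple[float, float, float]
    size: tuple[int, int]
    spacing: tuple[float, float]
    thickness: float = 0.0

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if not (np.isclose(np.linalg.norm(u), 1) and np.isclose(np.linalg.norm(v), 1)):
            raise ValueError("plane axes must be unit vectors")
        if not np.isclose(np.dot(u, v), 0, atol=1e-8):
            raise ValueError("plane axes must be orthogonal")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("plane spacing must be positive")
        object.__setattr__(self, "u", tuple(u))
        object.__setattr__(self, "v", tuple(v))

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    def grid_points(self) -> np.ndarray:
        """World coordinates of all plane pixels, shape ``size + (3,)``."""
        ii, jj = np.meshgrid(
            np.arange(self.size[0], dtype=float),
            np.arange(self.size[1], dtype=float),
            indexing="ij",
        )
        o = np.asarray(self.origin)
        u = np.asarray(self.u) * self.spacing[0]
        v = np.asarray(self.v) * self.spacing[1]
        return o + ii[..., None] * u + jj[..., None] * v

    def world_to_plane(self, pts: np.ndarray) -> np.ndarray:
        """Project world points to in-plane (i, j) pixel coordinates."""
        rel = np.asarray(pts, dtype=float) - np.asarray(self.origin)
        i = rel @ np.asarray(self.u) / self.spacing[0]
        j = rel @ np.asarray(self.v) / self.spacing[1]
        return np.stack([i, j], axis=-1)

    def plane_to_world(self, ij: np.ndarray) -> np.ndarray:
        ij = np.asarray(ij, dtype=float)
        o = np.asarray(self.origin)
        u = np.asarray(self.u) * self.spacing[0]
        v = np.asarray(self.v) * self.spacing[1]
        return o + ij[..., :1] * u + ij[..., 1:2] * v


@dataclass
class CineSeries:
    """4D cine acquisition: one :class:`Volume3D` per cardiac phase.

    ``data`` has shape ``grid.size + (n_phases,)``; all phases share the grid.
    ``trigger_delay_ms`` is per-slice-per-phase, ``rr_ms`` per slice.
    """

    grid: ImageGrid
    data: np.ndarray
    trigger_delay_ms: np.ndarray  # (n_slices, n_phases)
    rr_ms: np.ndarray  # (n_slices,)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("cine grid must be 3D; phase is the 4th array axis")
        if self.data.ndim != 4 or self.data.shape[:3] != tuple(self.grid.size):
            raise ValueError("cine data shape must be grid.size + (n_phases,)")
        if self.n_phases < 2:
            raise ValueError("a cine series needs at least 2 phases")
        self.trigger_delay_ms = np.asarray(self.trigger_delay_ms, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        n_sl = self.grid.size[2]
        if self.trigger_delay_ms.shape != (n_sl, self.n_phases):
            raise ValueError("trigger_delay_ms must be (n_slices, n_phases)")
        if self.rr_ms.shape != (n_sl,) or np.any(self.rr_ms <= 0):
            raise ValueError("rr_ms must be positive, one value per slice")

    @property
    def n_phases(self) -> int:
        return self.data.shape[3]

    @property
    def n_slices(self) -> int:
        return self.grid.size[2]

    def phase_volume(self, p: int) -> Volume3D:
        p = int(p) % self.n_phases
        return Volume3D(self.grid, self.data[..., p])

    def volume_at(self, phi: float) -> np.ndarray:
        """3D array linearly interpolated at a fractional (cyclic) phase."""
        phi = wrap_phase(float(phi), self.n_phases)
        p0 = int(np.floor(phi))
        w = phi - p0
        p1 = (p0 + 1) % self.n_phases
        if w == 0.0:
            return self.data[..., p0]
        return (1 - w) * self.data[..., p0] + w * self.data[..., p1]

    def sample(self, pts4: np.ndarray, background: float = 0.0) -> np.ndarray:
        """Quadrilinear interpolation at 4D world points (x, y, z in mm, phase index).

        Spatial axes are trilinear with constant background fill; the phase axis
        is linear and cyclic.
        """
        pts4 = np.asarray(pts4, dtype=float)
        phi = wrap_phase(pts4[:, 3], self.n_phases)
        idx = self.grid.world_to_index(pts4[:, :3]).T
        p0 = np.floor(phi).astype(int) % self.n_phases
        p1 = (p0 + 1) % self.n_phases
        w = phi - np.floor(phi)
        out = np.empty(len(pts4))
        # group by the bracketing phase pair so each group is one 3D interpolation
        key = p0 * self.n_phases + p1
        for k in np.unique(key):
            m = key == k
            a, b = p0[m][0], p1[m][0]
            va = ndimage.map_coordinates(
                self.data[..., a], idx[:, m], order=1, mode="constant", cval=background
            )
            if a == b:
                out[m] = va
            else:
                vb = ndimage.map_coordinates(
                    self.data[..., b], idx[:, m], order=1, mode="constant", cval=background
                )
                out[m] = (1 - w[m]) * va + w[m] * vb
        return out

    def slice_plane(self, k: int) -> SlicePlane:
        """The axial sampling plane of slice ``k`` (cine stacks are short-axis)."""
        o = self.grid.index_to_world(np.array([0.0, 0.0, float(k)]))
        d = self.grid.direction
        return SlicePlane(
            origin=tuple(o),
            u=tuple(d[:, 0]),
            v=tuple(d[:, 1]),
            size=(self.grid.size[0], self.grid.size[1]),
            spacing=(self.grid.spacing[0], self.grid.spacing[1]),
            thickness=self.grid.spacing[2],
        )

    def copy(self) -> "CineSeries":
        return CineSeries(
            self.grid, self.data.copy(), self.trigger_delay_ms.copy(), self.rr_ms.copy()
        )


@dataclass
class PerfusionSlice:
    """Dynamic 2D acquisition at one slice location."""

    plane: SlicePlane
    frames: np.ndarray  # (nu, nv, n_frames)
    trigger_delay_ms: float
    rr_ms: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[:2] != tuple(self.plane.size):
            raise ValueError("frames shape must be plane.size + (n_frames,)")
        if self.rr_ms <= 0:
            raise ValueError("R-R interval must be positive")
        if self.trigger_delay_ms < 0:
            raise ValueError("trigger delay must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]


LOCATIONS = ("basal", "medial", "apical")


@dataclass
class PerfusionSeries:
    """First-pass perfusion study: basal, medial and apical dynamic slices."""

    slices: dict[str, PerfusionSlice]
    max_contrast_frame: int

    def __post_init__(self):
        if tuple(self.slices.keys()) != LOCATIONS:
            raise ValueError(f"slice locations must be {LOCATIONS} in order")
        counts = {s.n_frames for s in self.slices.values()}
        if len(counts) != 1:
            raise ValueError("all slice locations must have equal frame counts")
        normals = [s.plane.normal for s in self.slices.values()]
        for n in normals[1:]:
            if not np.isclose(abs(np.dot(normals[0], n)), 1, atol=1e-6):
                raise ValueError("perfusion slice planes must be parallel")
        if not 0 <= self.max_contrast_frame < next(iter(counts)):
            raise ValueError("maximal-contrast frame index out of range")

    @property
    def n_frames(self) -> int:
        return next(iter(self.slices.values())).n_frames


@dataclass
class Contour:
    """Closed planar 3D contour (last point connects to first)."""

    points: np.ndarray  # (N, 3) mm
    role: str  # lv-endo | lv-epi | rv-endo

    ROLES = ("lv-endo", "lv-epi", "rv-endo")

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 3:
            raise ValueError("a contour needs at least 3 points of dimension 3")
        if self.role not in self.ROLES:
            raise ValueError(f"unknown contour role {self.role!r}")
        # coplanarity within tolerance
        c = self.points - self.points.mean(axis=0)
        if len(self.points) > 3:
            _, s, _ = np.linalg.svd(c, full_matrices=False)
            if s[2] > 1e-6 * max(s[0], 1.0) + 1e-6:
                raise ValueError("contour points are not coplanar")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def arc_lengths(self) -> np.ndarray:
        """Edge lengths including the closing edge, shape (N,)."""
        nxt = np.roll(self.points, -1, axis=0)
        return np.linalg.norm(nxt - self.points, axis=1)

    def perimeter(self) -> float:
        return float(self.arc_lengths().sum())

    def transformed(self, fn) -> "Contour":
        return replace(self, points=np.asarray(fn(self.points), dtype=float))


def _as_point_map(transform):
    """Accept a callable ``(N,3)->(N,3)`` or an object with ``apply_points``."""
    if transform is None:
        return lambda p: p
    if callable(transform):
        return transform
    if hasattr(transform, "apply_points"):
        return transform.apply_points
    raise TypeError("transform must be callable or expose apply_points()")


def resample_volume(
    volume: Volume3D,
    transform,
    target_grid: ImageGrid,
    interpolation: str = "linear",
    background: float = 0.0,
) -> Volume3D:
    """Resample ``volume`` onto ``target_grid``.

    ``transform`` maps *target* physical points into *source* physical space
    (the image-warping convention: the output pulls intensities from the source).
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError("interpolation must be 'nearest' or 'linear'")
    order = 0 if interpolation == "nearest" else 1
    fn = _as_point_map(transform)
    pts = target_grid.meshgrid_world().reshape(-1, 3)
    src = np.asarray(fn(pts), dtype=float)
    idx = volume.grid.world_to_index(src)
    vals = ndimage.map_coordinates(
        volume.data, idx.T, order=order, mode="constant", cval=background
    )
    return Volume3D(target_grid, vals.reshape(tuple(target_grid.size)))


def reformat_slice(
    volume: Volume3D,
    plane: SlicePlane,
    interpolation: str = "linear",
    background: float = 0.0,
) -> np.ndarray:
    """Sample a 2D image from a volume on an arbitrary plane (trilinear).

    A plane that misses the volume entirely yields an all-background image and
    a warning.
    """
    order = 0 if interpolation == "nearest" else 1
    pts = plane.grid_points().reshape(-1, 3)
    idx = volume.grid.world_to_index(pts)
    inside = np.all((idx > -0.5) & (idx < np.asarray(volume.grid.size) - 0.5), axis=1)
    if not inside.any():
        warnings.warn("reformat plane lies entirely outside the volume", stacklevel=2)
    vals = ndimage.map_coordinates(
        volume.data, idx.T, order=order, mode="constant", cval=background
    )
    return vals.reshape(plane.size)
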