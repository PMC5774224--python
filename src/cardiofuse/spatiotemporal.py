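"""Spatiotemporal transform algebra.

The perfusion-to-cine transform augments a centred rigid 2D transform with
translations along the through-plane (z) and cardiac-phase axes, giving seven
parameters {theta, Cx, Cy, Tx, Ty, Tz, Tphi}.  Out-of-plane rotations are
structurally impossible: slice-to-volume registration with full 3D rotations is
badly conditioned, so rotational error is confined to the imaging plane.

The mediated composite chains three components: the perfusion-to-cine transform
T_P, the deformable cine phase-to-phase chain T_C, and the angiography-to-cine
translation T_A.  The forward composite warps angiography images into the
perfusion frame; the inverse maps coronary point sets into perfusion space.
Because the deformable component is only ever inverted by re-registering with
fixed and moving images swapped, the composite requires the chain for its own
direction and never inverts one numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import wrap_phase

__all__ = [
    "SpatioTemporalParams",
    "IdentityTransform",
    "TranslationTransform",
    "MediatedTransform",
    "apply_spatiotemporal",
    "invert_spatiotemporal",
    "normalise_trigger_delay",
    "compose_mediated",
]


def _wrap_angle(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    t = (-theta + np.pi) % (2 * np.pi)
    return float(np.pi - t)


@dataclass(frozen=True)
class SpatioTemporalParams:
    """Seven-parameter spatiotemporal transform.

    In-plane rotation ``theta`` (rad) about centre ``(cx, cy)`` (mm), in-plane
    translations ``(tx, ty)`` (mm), through-plane translation ``tz`` (mm) and a
    temporal translation ``tphi`` in continuous phase-index units.
    """

    theta: float = 0.0
    cx: float = 0.0
    cy: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    tphi: float = 0.0

    def __post_init__(self):
        vals = [self.theta, self.cx, self.cy, self.tx, self.ty, self.tz, self.tphi]
        if not np.all(np.isfinite(vals)):
            raise ValueError("spatiotemporal parameters must be finite")
        object.__setattr__(self, "theta", _wrap_angle(float(self.theta)))

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.theta, self.cx, self.cy, self.tx, self.ty, self.tz, self.tphi]
        )

    @classmethod
    def from_vector(cls, v) -> "SpatioTemporalParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (7,):
            raise ValueError("expected 7 parameters")
        return cls(*v)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Spatial action on (N, 3) points (the phase offset is bookkeeping)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c, s = np.cos(self.theta), np.sin(self.theta)
        x = pts[:, 0] - self.cx
        y = pts[:, 1] - self.cy
        out = np.empty_like(pts)
        out[:, 0] = c * x - s * y + self.tx + self.cx
        out[:, 1] = s * x + c * y + self.ty + self.cy
        out[:, 2] = pts[:, 2] + self.tz
        return out

    def inverse(self) -> "SpatioTemporalParams":
        return invert_spatiotemporal(self)


def apply_spatiotemporal(params: SpatioTemporalParams, p, n_phases: int):
    """Apply the 7-parameter transform to a 4D point ``(x, y, z, phi)``.

    The rotated/translated spatial part acts in-plane about the centre of
    rotation; z and phi are pure translations, with phi wrapped cyclically
    into ``[0, n_phases)``.
    """
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != 4:
        raise ValueError("points must be 4D (x, y, z, phi)")
    out = np.empty_like(p)
    out[:, :3] = params.apply_points(p[:, :3])
    out[:, 3] = wrap_phase(p[:, 3] + params.tphi, n_phases)
    return out[0] if single else out


def invert_spatiotemporal(params: SpatioTemporalParams) -> SpatioTemporalParams:
    """Closed-form inverse: same parameterisation, trivially negated motion.

    With ``x' = R(x - C) + T + C`` the inverse is a rotation by ``-theta``
    about the shifted centre ``C + T`` with translation ``-T``.
    """
    return SpatioTemporalParams(
        theta=-params.theta,
        cx=params.cx + params.tx,
        cy=params.cy + params.ty,
        tx=-params.tx,
        ty=-params.ty,
        tz=-params.tz,
        tphi=-params.tphi,
    )


def normalise_trigger_delay(delay_ms: float, rr_ms: float, n_phases: int) -> float:
    """ECG trigger-delay normalisation to a continuous phase index.

    The trigger delay is the offset (ms) after the start of the R-R interval;
    reduced modulo the R-R interval and scaled to ``[0, n_phases)``.
    """
    if rr_ms <= 0:
        raise ValueError("R-R interval must be positive")
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    return float((delay_ms % rr_ms) / rr_ms * n_phases)


class IdentityTransform:
    """Point-map identity; usable wherever a chain component is expected."""

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float)

    def __call__(self, pts):
        return self.apply_points(pts)


@dataclass(frozen=True)
class TranslationTransform:
    """Pure 3D translation (mm)."""

    offset: tuple[float, float, float]

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) + np.asarray(self.offset)

    def inverse(self) -> "TranslationTransform":
        return TranslationTransform(tuple(-np.asarray(self.offset)))

    def __call__(self, pts):
        return self.apply_points(pts)


@dataclass(frozen=True)
class MediatedTransform:
    """Ordered composite of the three mediated-registration components.

    direction='forward' (image warping): a perfusion-frame point is mapped by
    T_P, then the direct phase chain (perfusion-selected phase toward the
    angiography-selected phase), then T_A, landing in angiography space — used
    to pull angiography intensities into the perfusion frame.

    direction='inverse' (point mapping): T_A^-1, then the *swapped-registration*
    inverse chain, then T_P^-1 — used to carry coronary centreline points into
    perfusion coordinates.  ``t_p`` and ``t_a`` are always stored in their
    forward sense; ``t_c`` must be the chain matching ``direction``.
    """

    t_p: SpatioTemporalParams
    t_c: object  # point map phi_P -> phi_A frame (forward) or phi_A -> phi_P (inverse)
    t_a: TranslationTransform
    direction: str
    phi_p: float
    phi_a: float
    n_phases: int

    def __post_init__(self):
        if self.direction not in ("forward", "inverse"):
            raise ValueError("direction must be 'forward' or 'inverse'")
        for name, comp in (("t_p", self.t_p), ("t_c", self.t_c), ("t_a", self.t_a)):
            if comp is None:
                raise ValueError(f"missing composite component {name}")
        if not hasattr(self.t_c, "apply_points") and not callable(self.t_c):
            raise TypeError("t_c must be a point map")
        for phi in (self.phi_p, self.phi_a):
            if not 0 <= phi < self.n_phases:
                raise ValueError("selected phases must lie in [0, n_phases)")

    def _chain(self, pts):
        if hasattr(self.t_c, "apply_points"):
            return self.t_c.apply_points(pts)
        return self.t_c(pts)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if self.direction == "forward":
            return self.t_a.apply_points(self._chain(self.t_p.apply_points(pts)))
        return self.t_p.inverse().apply_points(
            self._chain(self.t_a.inverse().apply_points(pts))
        )

    def __call__(self, pts):
        return self.apply_points(pts)


def compose_mediated(
    t_p: SpatioTemporalParams,
    t_c,
    t_a: TranslationTransform,
    direction: str,
    phi_p: float,
    phi_a: float,
    n_phases: int,
) -> MediatedTransform:
    """Build the mediated composite from its three components.

    ``t_p`` and ``t_a`` are the forward-estimated components; ``t_c`` is the
    deformable chain *for the requested direction* (the inverse chain comes from
    registration with fixed/moving swapped, never from numeric inversion).
    """
    return MediatedTransform(
        t_p=t_p,
        t_c=t_c,
        t_a=t_a,
        direction=direction,
        phi_p=phi_p,
        phi_a=phi_a,
        n_phases=n_phases,
    )
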