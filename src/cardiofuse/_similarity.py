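"""Internal similarity metric and optimiser for the custom registration stages.

The deformable phase-to-phase stage uses SimpleITK; the stages built on
transforms SimpleITK has no model for (the 4D cyclic spatiotemporal transform,
the joint stack transform, the 2D motion-correction loop) share this
mutual-information metric and regular-step gradient-descent optimiser.

The joint histogram uses linear binning (each sample splits its mass
bilinearly over the four neighbouring bins), which makes the metric a smooth
function of the transform parameters — a requirement for finite-difference
gradient descent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mutual_information", "elliptic_mask", "regular_step_descent"]


def _linear_bin(values: np.ndarray, lo: float, hi: float, bins: int):
    span = max(hi - lo, 1e-12)
    u = np.clip((values - lo) / span * (bins - 1), 0.0, bins - 1 - 1e-9)
    i0 = np.floor(u).astype(int)
    w = u - i0
    return i0, w


def mutual_information(
    fixed: np.ndarray,
    moving: np.ndarray,
    bins: int = 32,
    fixed_range: tuple[float, float] | None = None,
    moving_range: tuple[float, float] | None = None,
) -> float:
    """Mutual information (nats) between paired intensity samples.

    Non-finite pairs are dropped.  Ranges default to the sample min/max; pass
    fixed ranges when comparing metric values across transform candidates.
    """
    fixed = np.asarray(fixed, dtype=float).ravel()
    moving = np.asarray(moving, dtype=float).ravel()
    ok = np.isfinite(fixed) & np.isfinite(moving)
    fixed, moving = fixed[ok], moving[ok]
    if len(fixed) < 8:
        return 0.0
    flo, fhi = fixed_range if fixed_range else (fixed.min(), fixed.max())
    mlo, mhi = moving_range if moving_range else (moving.min(), moving.max())
    fi, fw = _linear_bin(fixed, flo, fhi, bins)
    mi_, mw = _linear_bin(moving, mlo, mhi, bins)
    h = np.zeros((bins, bins))
    np.add.at(h, (fi, mi_), (1 - fw) * (1 - mw))
    np.add.at(h, (fi, mi_ + 1), (1 - fw) * mw)
    np.add.at(h, (fi + 1, mi_), fw * (1 - mw))
    np.add.at(h, (fi + 1, mi_ + 1), fw * mw)
    p = h / h.sum()
    pf = p.sum(axis=1, keepdims=True)
    pm = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (pf @ pm)[nz])))


def elliptic_mask(shape: tuple[int, int], roi_rect: tuple[int, int, int, int]) -> np.ndarray:
    """Boolean mask: the ellipse inscribed in a pixel-coordinate rectangle.

    ``roi_rect`` is ``(i0, j0, i1, j1)`` with half-open upper bounds.
    """
    i0, j0, i1, j1 = roi_rect
    if not (0 <= i0 < i1 <= shape[0] and 0 <= j0 < j1 <= shape[1]):
        raise ValueError("ROI rectangle outside the image")
    ci, cj = (i0 + i1 - 1) / 2, (j0 + j1 - 1) / 2
    ai, aj = max((i1 - i0) / 2, 0.5), max((j1 - j0) / 2, 0.5)
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return ((ii - ci) / ai) ** 2 + ((jj - cj) / aj) ** 2 <= 1.0


def regular_step_descent(
    cost,
    x0: np.ndarray,
    scales: np.ndarray,
    step: float = 1.0,
    min_step: float = 0.01,
    max_iter: int = 100,
    bounds=None,
    grad_delta: float = 0.05,
):
    """Regular-step gradient descent with central-difference gradients.

    Works in the scaled parameter space ``y = scales * x`` so heterogeneous
    units (radians, millimetres, phase indices) share one step length.  The
    step is halved whenever the gradient direction reverses; iteration stops
    when it falls below ``min_step``.  Returns ``(best_x, best_cost,
    converged)``; the best-so-far point is returned even without convergence.
    """
    x = np.array(x0, dtype=float)
    scales = np.asarray(scales, dtype=float)
    n = len(x)

    def clip(v):
        if bounds is None:
            return v
        return np.clip(v, [b[0] for b in bounds], [b[1] for b in bounds])

    def gradient(v):
        g = np.empty(n)
        for i in range(n):
            d = grad_delta / scales[i]
            vp, vm = v.copy(), v.copy()
            vp[i] += d
            vm[i] -= d
            g[i] = (cost(clip(vp)) - cost(clip(vm))) / (2 * d)
        return g / scales  # gradient in scaled space

    best_x = x.copy()
    best_c = cost(x)
    prev_g = None
    it = 0
    while step >= min_step and it < max_iter:
        g = gradient(x)
        norm = np.linalg.norm(g)
        if norm < 1e-14:
            break
        if prev_g is not None and float(np.dot(g, prev_g)) < 0:
            step /= 2
            if step < min_step:
                break
        x = clip(x - step * (g / norm) / scales)
        c = cost(x)
        if c < best_c:
            best_c, best_x = c, x.copy()
        prev_g = g
        it += 1
    converged = step < min_step or it < max_iter
    return best_x, best_c, converged
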