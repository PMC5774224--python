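"""Patient-specific coronary supply territories.

Given a coronary centreline tree warped into the coordinate space of a
perfusion slice, the supply territory of each of the three main arteries (RCA,
LAD, LCX) is computed from proximity of the vessels to the myocardium:

1. per arterial segment, a distance map along the LV epicardial contour using
   the extruded-cylinder approximation — the distance from contour point c_i to
   a segment is the hypotenuse of the shorter-arc distance along the contour
   from the anchor point c_S and the Euclidean anchor gap ||p_S - c_S||;
2. segment maps are combined per territory by pointwise minimum;
3. each contour point takes the label of the territory with minimal distance;
4. Voronoi partitioning (exact nearest labelled contour point per pixel)
   extends the labels to the whole slice, then the result is restricted to the
   myocardium between the endo- and epicardial contours.

Also here: the polar (phi, h) parameterisation about the LV long axis used for
bull's-eye plots, the population-based AHA 17-segment baseline, territory mask
propagation through motion-correction transforms, and uptake-curve extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import Contour, PerfusionSeries, SlicePlane

__all__ = [
    "GROUPS",
    "SEGMENT_NAMES",
    "TERRITORY_ORDER",
    "AHA_ARTERY_MAP",
    "CoronaryTree",
    "LongAxisFrame",
    "ContourDistanceMap",
    "TerritoryMask",
    "BullsEyeData",
    "polar_parameterise",
    "project_bep",
    "plot_bep",
    "warp_tree_to_perfusion",
    "segment_distance_map",
    "combine_territory_maps",
    "label_contour",
    "voronoi_fill",
    "propagate_territory_masks",
    "aha_model_territories",
    "extract_uptake_curves",
]

# conventional grouping of the nine annotated segments into supply territories
GROUPS: dict[str, tuple[int, ...]] = {"RCA": (1, 2), "LAD": (3, 4, 5, 6), "LCX": (7, 8, 9)}

SEGMENT_NAMES: dict[int, str] = {
    1: "RCA",
    2: "PDA",
    3: "LMS",
    4: "LAD",
    5: "D1",
    6: "D2",
    7: "LCX",
    8: "OM1",
    9: "OM2",
}

# deterministic tie-break order for equal distances
TERRITORY_ORDER: tuple[str, ...] = ("RCA", "LAD", "LCX")

TERRITORY_LABELS: dict[str, int] = {"background": 0, "RCA": 1, "LAD": 2, "LCX": 3}

# standard AHA 17-segment to artery assignment (LAD list as conventionally printed)
AHA_ARTERY_MAP: dict[int, str] = {
    **{s: "LAD" for s in (1, 2, 7, 8, 13, 14, 17)},
    **{s: "RCA" for s in (3, 4, 9, 10, 15)},
    **{s: "LCX" for s in (5, 6, 11, 12, 16)},
}


@dataclass
class CoronaryTree:
    """Labelled 3D centreline point sets, segment ids 1-9, fixed grouping."""

    segments: dict[int, np.ndarray]

    def __post_init__(self):
        segs = {}
        for s, pts in self.segments.items():
            s = int(s)
            if not 1 <= s <= 9:
                raise ValueError(f"segment id {s} outside 1-9")
            pts = np.asarray(pts, dtype=float).reshape(-1, 3)
            segs[s] = pts
        self.segments = segs

    def all_points(self) -> np.ndarray:
        arrs = [p for p in self.segments.values() if len(p)]
        return np.concatenate(arrs, axis=0) if arrs else np.zeros((0, 3))

    def group_points(self, territory: str) -> np.ndarray:
        arrs = [
            self.segments[s]
            for s in GROUPS[territory]
            if s in self.segments and len(self.segments[s])
        ]
        return np.concatenate(arrs, axis=0) if arrs else np.zeros((0, 3))

    def transformed(self, fn) -> "CoronaryTree":
        return CoronaryTree(
            segments={
                s: (np.asarray(fn(p), dtype=float) if len(p) else p)
                for s, p in self.segments.items()
            }
        )

    def n_points(self) -> int:
        return sum(len(p) for p in self.segments.values())


@dataclass(frozen=True)
class LongAxisFrame:
    """LV long-axis coordinate frame: apex, long-axis direction, SA reference.

    The short-axis (SA) reference vector lies in the SA plane and defines the
    zero of the polar angle phi.
    """

    apex: tuple[float, float, float]
    long_axis: tuple[float, float, float]
    sa_ref: tuple[float, float, float]

    def __post_init__(self):
        la = np.asarray(self.long_axis, dtype=float)
        sa = np.asarray(self.sa_ref, dtype=float)
        if not np.isclose(np.linalg.norm(la), 1) or not np.isclose(np.linalg.norm(sa), 1):
            raise ValueError("long_axis and sa_ref must be unit vectors")
        if not np.isclose(np.dot(la, sa), 0, atol=1e-8):
            raise ValueError("long_axis and sa_ref must be orthogonal")
        object.__setattr__(self, "long_axis", tuple(la))
        object.__setattr__(self, "sa_ref", tuple(sa))

    @property
    def third_axis(self) -> np.ndarray:
        return np.cross(self.long_axis, self.sa_ref)


def polar_parameterise(pts: np.ndarray, frame: LongAxisFrame):
    """Polar coordinates (phi, h) of points about the LV long axis.

    ``h`` is the signed distance to the SA plane through the apex; ``phi`` is
    the angle in [0, 2*pi) between the SA reference vector and the shortest
    vector from the point to the long axis.  Points on the axis are degenerate:
    phi = 0 with the returned mask set.

    Returns ``(phi, h, degenerate)`` arrays (scalars for a single point).
    """
    p = np.asarray(pts, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    rel = p - np.asarray(frame.apex)
    la = np.asarray(frame.long_axis)
    h = rel @ la
    radial = rel - np.outer(h, la)
    x = radial @ np.asarray(frame.sa_ref)
    y = radial @ frame.third_axis
    degenerate = np.hypot(x, y) < 1e-12
    phi = np.where(degenerate, 0.0, np.mod(np.arctan2(y, x), 2 * np.pi))
    if single:
        return float(phi[0]), float(h[0]), bool(degenerate[0])
    return phi, h, degenerate


@dataclass
class BullsEyeData:
    """Polar plot data: per-segment (phi, h) point arrays plus band radii."""

    segments: dict[int, np.ndarray]  # segment id -> (M, 2) columns (phi, h)
    basal_band: tuple[float, float]  # (inner, outer) radius of the basal band
    medial_band: tuple[float, float]
    apical_band: tuple[float, float]


def project_bep(
    tree: CoronaryTree,
    frame: LongAxisFrame,
    basal_slice_h: float,
    slice_thickness: float,
    inter_slice_offset: float,
) -> BullsEyeData:
    """Unfold the coronary tree onto a bull's-eye plot.

    Each point is plotted at polar radius ``h`` (its height above the apex SA
    plane) and angle ``phi``; the registered basal perfusion slice height sets
    the basal band radius, the medial/apical bands follow from the slice
    thickness and inter-slice offset.
    """
    segs = {}
    for s, pts in tree.segments.items():
        if not len(pts):
            continue
        phi, h, _ = polar_parameterise(pts, frame)
        segs[s] = np.stack([phi, h], axis=1)
    half = slice_thickness / 2
    basal = (basal_slice_h - half, basal_slice_h + half)
    medial_c = basal_slice_h - inter_slice_offset
    apical_c = basal_slice_h - 2 * inter_slice_offset
    return BullsEyeData(
        segments=segs,
        basal_band=basal,
        medial_band=(medial_c - half, medial_c + half),
        apical_band=(apical_c - half, apical_c + half),
    )


def plot_bep(bep: BullsEyeData, path=None):
    """Render a bull's-eye plot; writes to ``path`` (PNG/SVG) when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    colors = {"RCA": "tab:red", "LAD": "tab:blue", "LCX": "tab:green"}
    seg_to_group = {s: g for g, ids in GROUPS.items() for s in ids}
    for s, ph in bep.segments.items():
        g = seg_to_group[s]
        ax.plot(ph[:, 0], ph[:, 1], ".", ms=3, color=colors[g], label=g)
    for band in (bep.basal_band, bep.medial_band, bep.apical_band):
        for r in band:
            if r > 0:
                ax.plot(np.linspace(0, 2 * np.pi, 200), np.full(200, r), "k-", lw=0.4)
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    ax.legend(uniq.values(), uniq.keys(), loc="upper right", fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def warp_tree_to_perfusion(tree: CoronaryTree, transform) -> CoronaryTree:
    """Carry coronary centreline points into perfusion coordinates.

    Requires an inverse-direction mediated transform: the forward composite
    warps images, not point sets.
    """
    direction = getattr(transform, "direction", None)
    if direction != "inverse":
        raise ValueError("warping point sets requires an inverse-direction transform")
    return tree.transformed(transform.apply_points)


@dataclass
class ContourDistanceMap:
    """Per-contour-point distances to one segment (or one territory)."""

    distances: np.ndarray  # (N,)
    anchor_contour_index: int
    anchor_point: np.ndarray  # p_S, (3,)
    anchor_distance: float  # ||p_S - c_S||

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")


def contour_arc_distances(contour: Contour, anchor: int) -> np.ndarray:
    """Shorter-arc accumulated polyline distance from the anchor to each point."""
    edges = contour.arc_lengths()
    total = edges.sum()
    fwd = np.roll(np.concatenate([[0.0], np.cumsum(np.roll(edges, -anchor))[:-1]]), 0)
    # fwd[i] = distance walking forward from anchor to anchor+i
    fwd_full = np.empty(len(contour))
    fwd_full[(anchor + np.arange(len(contour))) % len(contour)] = fwd
    return np.minimum(fwd_full, total - fwd_full)


def segment_distance_map(segment_points: np.ndarray, contour: Contour) -> ContourDistanceMap | None:
    """Distance map along the epicardial contour for one arterial segment.

    Finds the closest pair (p_S, c_S) between segment and contour, then for
    every contour point combines the shorter-arc contour distance with the
    anchor gap as the hypotenuse on the extruded-cylinder surface.  An empty
    segment contributes nothing (returns None).
    """
    P = np.asarray(segment_points, dtype=float).reshape(-1, 3)
    if len(P) == 0:
        return None
    D = cdist(P, contour.points)
    pi, ci = np.unravel_index(np.argmin(D), D.shape)
    gap = float(D[pi, ci])
    delta = contour_arc_distances(contour, int(ci))
    return ContourDistanceMap(
        distances=np.hypot(delta, gap),
        anchor_contour_index=int(ci),
        anchor_point=P[pi],
        anchor_distance=gap,
    )


def combine_territory_maps(
    segment_maps: dict[int, ContourDistanceMap | None],
    grouping: dict[str, tuple[int, ...]] = GROUPS,
) -> dict[str, ContourDistanceMap]:
    """Pointwise-minimum combination of segment maps into territory maps.

    A territory with no present segment is absent from the output.
    """
    out: dict[str, ContourDistanceMap] = {}
    for territory in TERRITORY_ORDER:
        maps = [
            segment_maps[s]
            for s in grouping.get(territory, ())
            if segment_maps.get(s) is not None
        ]
        if not maps:
            continue
        stack = np.stack([m.distances for m in maps], axis=0)
        best = maps[int(np.argmin([m.distances.min() for m in maps]))]
        out[territory] = ContourDistanceMap(
            distances=stack.min(axis=0),
            anchor_contour_index=best.anchor_contour_index,
            anchor_point=best.anchor_point,
            anchor_distance=best.anchor_distance,
        )
    if not out:
        raise ValueError("no territory has any segment points")
    return out


def label_contour(territory_maps: dict[str, ContourDistanceMap]) -> np.ndarray:
    """Per-contour-point territory labels by minimum distance.

    Ties broken by the fixed order RCA < LAD < LCX.
    """
    names = [t for t in TERRITORY_ORDER if t in territory_maps]
    if not names:
        raise ValueError("need at least one territory map")
    stack = np.stack([territory_maps[t].distances for t in names], axis=0)
    idx = np.argmin(stack, axis=0)  # argmin returns the first minimum: the tie order
    return np.asarray(names, dtype=object)[idx]


@dataclass
class TerritoryMask:
    """Per-slice territory label image restricted to the myocardium.

    Integer labels: 0 background, 1 RCA, 2 LAD, 3 LCX.
    """

    plane: SlicePlane
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != tuple(self.plane.size):
            raise ValueError("label image shape must match the plane grid")

    def myocardium(self) -> np.ndarray:
        return self.labels > 0

    def territory(self, name: str) -> np.ndarray:
        return self.labels == TERRITORY_LABELS[name]


def _inplane_mm(plane: SlicePlane, pts3: np.ndarray) -> np.ndarray:
    ij = plane.world_to_plane(pts3)
    return ij * np.asarray(plane.spacing)


def _polygon_path(plane: SlicePlane, contour: Contour) -> MplPath:
    return MplPath(_inplane_mm(plane, contour.points))


def voronoi_fill(
    plane: SlicePlane,
    contour_points: np.ndarray,
    point_labels: np.ndarray,
    endo: Contour,
    epi: Contour,
) -> TerritoryMask:
    """Extend contour-point labels to the myocardial annulus of a slice.

    Every pixel takes the label of its nearest (in-plane Euclidean) labelled
    contour point; the result is then masked to the myocardium (inside the
    epicardial, outside the endocardial contour).  The nearest-point assignment
    is exact — the Voronoi cells are realised pixel by pixel.
    """
    contour_points = np.asarray(contour_points, dtype=float).reshape(-1, 3)
    point_labels = np.asarray(point_labels, dtype=object)
    if len(contour_points) == 0 or len(contour_points) != len(point_labels):
        raise ValueError("labelled contour points required, one label per point")
    epi_path = _polygon_path(plane, epi)
    endo_2d = _inplane_mm(plane, endo.points)
    if not epi_path.contains_points(endo_2d).all():
        raise ValueError("endocardial contour must lie strictly inside the epicardial")
    pix = _inplane_mm(plane, plane.grid_points().reshape(-1, 3))
    myo = epi_path.contains_points(pix) & ~MplPath(endo_2d).contains_points(pix)
    # tie-stable nearest lookup: order points so earlier territories win exact ties
    order = np.argsort([TERRITORY_ORDER.index(l) for l in point_labels], kind="stable")
    cp = _inplane_mm(plane, contour_points)[order]
    lab_sorted = point_labels[order]
    d, nearest = cKDTree(cp).query(pix[myo])
    labels = np.zeros(len(pix), dtype=int)
    labels[myo] = [TERRITORY_LABELS[l] for l in lab_sorted[nearest]]
    return TerritoryMask(plane=plane, labels=labels.reshape(plane.size))


def compute_slice_territories(
    tree: CoronaryTree,
    epi: Contour,
    endo: Contour,
    plane: SlicePlane,
    contour_choice: str = "epicardial",
) -> tuple[TerritoryMask, dict[str, ContourDistanceMap], np.ndarray]:
    """Run distance maps -> territory maps -> contour labels -> Voronoi fill.

    ``contour_choice`` selects the contour the distance maps follow; the
    epicardial surface is the default (the vessels run on it).
    """
    ref = epi if contour_choice == "epicardial" else endo
    seg_maps = {s: segment_distance_map(p, ref) for s, p in tree.segments.items()}
    terr_maps = combine_territory_maps(seg_maps)
    labels = label_contour(terr_maps)
    mask = voronoi_fill(plane, ref.points, labels, endo, epi)
    return mask, terr_maps, labels


def propagate_territory_masks(mask: TerritoryMask, motion, location: str) -> list[TerritoryMask]:
    """Carry the key-frame territory mask to every frame of the series.

    Uses the per-frame inverse motion-correction transforms (they place the
    key-frame labels over the myocardium as imaged in each original frame);
    labels are resampled nearest-neighbour.
    """
    plane = mask.plane
    pix = _inplane_mm(plane, plane.grid_points().reshape(-1, 3))
    sp = np.asarray(plane.spacing)
    out = []
    for f in range(motion.n_frames):
        t = motion.transform(location, f)
        # frame-f pixel x shows the anatomy the key frame has at direct(x)
        src = t.apply(pix)
        ij = np.round(src / sp).astype(int)
        valid = (
            (ij[:, 0] >= 0)
            & (ij[:, 0] < plane.size[0])
            & (ij[:, 1] >= 0)
            & (ij[:, 1] < plane.size[1])
        )
        labels = np.zeros(len(pix), dtype=int)
        labels[valid] = mask.labels[ij[valid, 0], ij[valid, 1]]
        out.append(TerritoryMask(plane=plane, labels=labels.reshape(plane.size)))
    return out


def aha_model_territories(
    frame: LongAxisFrame,
    rv_insertion,
    slices: dict[str, tuple[SlicePlane, np.ndarray]],
) -> tuple[dict[str, np.ndarray], dict[int, str]]:
    """Population-based AHA 17-segment partition on the given slices.

    ``slices`` maps location tags (basal | medial | apical | apex) to a plane
    and its boolean myocardium mask.  The RV insertion point fixes the angular
    origin of segment 1; basal and mid rings have six 60-degree sectors,
    the apical ring four 90-degree sectors, the apex is one segment (17).

    Returns per-slice segment-id images (0 outside myocardium) and the fixed
    segment-to-artery map.
    """
    rv = np.asarray(rv_insertion, dtype=float)
    phi0, _, deg = polar_parameterise(rv, frame)
    if deg:
        raise ValueError("RV insertion point lies on the long axis")
    ring = {
        "basal": (1, 6),
        "medial": (7, 6),
        "apical": (13, 4),
        "apex": (17, 1),
    }
    out: dict[str, np.ndarray] = {}
    for loc, (plane, myo) in slices.items():
        if loc not in ring:
            raise ValueError(f"unknown slice location {loc!r}")
        first, nseg = ring[loc]
        pts = plane.grid_points().reshape(-1, 3)
        phi, _, _ = polar_parameterise(pts, frame)
        rel = np.mod(phi - phi0, 2 * np.pi)
        seg = first + np.floor(rel / (2 * np.pi / nseg)).astype(int) % nseg
        seg_img = np.where(np.asarray(myo).reshape(-1), seg, 0)
        out[loc] = seg_img.reshape(plane.size)
    return out, dict(AHA_ARTERY_MAP)


def aha_territory_mask(segment_image: np.ndarray, plane: SlicePlane) -> TerritoryMask:
    """Collapse an AHA segment-id image to the three-artery territory mask."""
    labels = np.zeros_like(segment_image, dtype=int)
    for seg, artery in AHA_ARTERY_MAP.items():
        labels[segment_image == seg] = TERRITORY_LABELS[artery]
    return TerritoryMask(plane=plane, labels=labels)


def extract_uptake_curves(
    series: PerfusionSeries,
    masks: dict[str, list[TerritoryMask]],
    lv_pool: dict[str, list[Contour]],
) -> dict[str, np.ndarray]:
    """Signal-intensity-vs-time curves per territory and for the LV blood pool.

    Intensities are averaged over all three slice locations per frame.  An
    empty region yields NaN for that frame and a warning.
    """
    n = series.n_frames
    territory_names = list(TERRITORY_ORDER)
    sums = {t: np.zeros(n) for t in territory_names + ["lv_pool"]}
    counts = {t: np.zeros(n) for t in territory_names + ["lv_pool"]}
    for loc, sl in series.slices.items():
        if len(masks[loc]) != n or len(lv_pool[loc]) != n:
            raise ValueError("masks and pool contours must cover all frames")
        pix = sl.plane.grid_points().reshape(-1, 3)
        pix2 = _inplane_mm(sl.plane, pix)
        for f in range(n):
            img = sl.frames[..., f].reshape(-1)
            m = masks[loc][f]
            for t in territory_names:
                sel = m.territory(t).reshape(-1)
                sums[t][f] += img[sel].sum()
                counts[t][f] += sel.sum()
            pool = MplPath(_inplane_mm(sl.plane, lv_pool[loc][f].points)).contains_points(pix2)
            sums["lv_pool"][f] += img[pool].sum()
            counts["lv_pool"][f] += pool.sum()
    curves = {}
    for t, s in sums.items():
        c = counts[t]
        if np.any(c == 0):
            warnings.warn(f"empty region for {t!r} in some frames; entries set to NaN")
        with np.errstate(invalid="ignore", divide="ignore"):
            curves[t] = np.where(c > 0, s / np.maximum(c, 1), np.nan)
    return curves
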