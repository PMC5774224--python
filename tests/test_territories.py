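import numpy as np
import pytest

from cardiofuse.core import Contour, SlicePlane
from cardiofuse.motion import MotionCorrectionResult, Rigid2D
from cardiofuse.spatiotemporal import (
    IdentityTransform,
    SpatioTemporalParams,
    TranslationTransform,
    compose_mediated,
)
from cardiofuse.territories import (
    AHA_ARTERY_MAP,
    GROUPS,
    TERRITORY_LABELS,
    TERRITORY_ORDER,
    ContourDistanceMap,
    CoronaryTree,
    LongAxisFrame,
    aha_model_territories,
    combine_territory_maps,
    compute_slice_territories,
    extract_uptake_curves,
    label_contour,
    polar_parameterise,
    project_bep,
    propagate_territory_masks,
    segment_distance_map,
    voronoi_fill,
    warp_tree_to_perfusion,
)

Z_FRAME = LongAxisFrame(apex=(0, 0, -50), long_axis=(0, 0, 1), sa_ref=(1, 0, 0))


def circle_contour(r=20.0, z=0.0, n=90, role="lv-epi", centre=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.stack(
        [centre[0] + r * np.cos(th), centre[1] + r * np.sin(th), np.full(n, z)], axis=1
    )
    return Contour(points=pts, role=role)


def centred_plane(n=48, sp=1.0, z=0.0):
    return SlicePlane(
        origin=(-(n - 1) / 2 * sp, -(n - 1) / 2 * sp, z),
        u=(1, 0, 0),
        v=(0, 1, 0),
        size=(n, n),
        spacing=(sp, sp),
    )


class TestPolarParameterise:
    def test_apex_plane_has_zero_height(self):
        phi, h, deg = polar_parameterise(np.array([10.0, 0.0, -50.0]), Z_FRAME)
        assert h == 0.0 and not deg

    def test_sa_reference_direction_is_zero_angle(self):
        phi, h, _ = polar_parameterise(np.array([7.0, 0.0, -30.0]), Z_FRAME)
        assert phi == 0.0 and np.isclose(h, 20.0)

    def test_on_axis_degenerate_flag(self):
        phi, h, deg = polar_parameterise(np.array([0.0, 0.0, 0.0]), Z_FRAME)
        assert deg and phi == 0.0

    def test_matches_vector_algebra_oracle(self, rng):
        frame = LongAxisFrame(
            apex=(3.0, -2.0, 1.0),
            long_axis=tuple(np.array([1.0, 2.0, 2.0]) / 3.0),
            sa_ref=tuple(np.array([2.0, 1.0, -2.0]) / 3.0),
        )
        pts = rng.uniform(-40, 40, (100, 3))
        phi, h, deg = polar_parameterise(pts, frame)
        la, sa = np.array(frame.long_axis), np.array(frame.sa_ref)
        third = np.cross(la, sa)
        for i in range(100):
            rel = pts[i] - np.array(frame.apex)
            h_o = rel @ la
            r = rel - h_o * la
            phi_o = np.arctan2(r @ third, r @ sa) % (2 * np.pi)
            assert np.isclose(h[i], h_o, atol=1e-9)
            assert np.isclose(phi[i], phi_o, atol=1e-9) or deg[i]


class TestBullsEye:
    def test_apex_point_plots_at_origin(self):
        tree = CoronaryTree(segments={1: np.array([[0.0, 0.0, -50.0]])})
        bep = project_bep(tree, Z_FRAME, basal_slice_h=80.0, slice_thickness=10.0, inter_slice_offset=25.0)
        assert np.isclose(bep.segments[1][0, 1], 0.0)

    def test_cylinder_tree_angles_and_heights(self):
        th = np.array([0.5, 1.5, 2.5])
        z = np.array([-20.0, 0.0, 20.0])
        tree = CoronaryTree(
            segments={4: np.stack([10 * np.cos(th), 10 * np.sin(th), z], axis=1)}
        )
        bep = project_bep(tree, Z_FRAME, basal_slice_h=80.0, slice_thickness=10.0, inter_slice_offset=25.0)
        assert np.allclose(bep.segments[4][:, 0], th)
        assert np.allclose(bep.segments[4][:, 1], z + 50.0)

    def test_axial_rotation_equivariance(self):
        th = np.array([0.3, 1.1])
        pts = np.stack([15 * np.cos(th), 15 * np.sin(th), [0.0, 10.0]], axis=1)
        delta = 0.7
        rot = np.stack(
            [15 * np.cos(th + delta), 15 * np.sin(th + delta), [0.0, 10.0]], axis=1
        )
        bep_a = project_bep(CoronaryTree(segments={1: pts}), Z_FRAME, 80, 10, 25)
        bep_b = project_bep(CoronaryTree(segments={1: rot}), Z_FRAME, 80, 10, 25)
        assert np.allclose(
            np.mod(bep_b.segments[1][:, 0] - bep_a.segments[1][:, 0], 2 * np.pi), delta
        )


class TestWarpTree:
    def test_identity_and_translation(self):
        tree = CoronaryTree(segments={1: np.array([[1.0, 2, 3], [4, 5, 6]])})
        ident = compose_mediated(
            SpatioTemporalParams(), IdentityTransform(), TranslationTransform((0, 0, 0)),
            direction="inverse", phi_p=0, phi_a=0, n_phases=8,
        )
        out = warp_tree_to_perfusion(tree, ident)
        assert np.allclose(out.segments[1], tree.segments[1])
        shift = compose_mediated(
            SpatioTemporalParams(), IdentityTransform(), TranslationTransform((-1.0, -2.0, -3.0)),
            direction="inverse", phi_p=0, phi_a=0, n_phases=8,
        )
        out2 = warp_tree_to_perfusion(tree, shift)
        assert np.allclose(out2.segments[1], tree.segments[1] + [1.0, 2.0, 3.0])

    def test_forward_transform_rejected(self):
        tree = CoronaryTree(segments={1: np.zeros((1, 3))})
        fwd = compose_mediated(
            SpatioTemporalParams(), IdentityTransform(), TranslationTransform((0, 0, 0)),
            direction="forward", phi_p=0, phi_a=0, n_phases=8,
        )
        with pytest.raises(ValueError, match="inverse"):
            warp_tree_to_perfusion(tree, fwd)


class TestSegmentDistanceMap:
    def test_anchor_distance_zero_when_coincident(self):
        c = circle_contour(r=10.0)
        p = c.points[5:6]
        m = segment_distance_map(p, c)
        assert m.anchor_contour_index == 5
        assert m.distances[5] == 0.0
        assert np.argmin(m.distances) == 5

    def test_three_four_five_pythagoras(self):
        # circle of circumference 360 -> 1 mm arc per degree of index
        r = 180.0 / np.pi
        c = circle_contour(r=r, n=360)
        # anchor at index 0, offset 3 mm radially outward; point at arc distance 4
        p = np.array([[r + 3.0, 0.0, 0.0]])
        m = segment_distance_map(p, c)
        assert np.isclose(m.anchor_distance, 3.0, atol=1e-9)
        assert np.isclose(m.distances[4], 5.0, atol=5e-3)  # 3-4-5 triangle

    def test_empty_segment_returns_none(self):
        assert segment_distance_map(np.zeros((0, 3)), circle_contour()) is None

    def test_matches_geodesic_graph_oracle(self):
        """Distances agree with shortest paths on a finely meshed unrolled
        extruded cylinder (Dijkstra with a radius-3 stencil)."""
        from scipy.sparse import lil_matrix
        from scipy.sparse.csgraph import dijkstra

        rng = np.random.default_rng(2)
        r = 25.0
        c = circle_contour(r=r, n=240)
        p = np.array([[r + 6.0, 0.0, 4.0]])
        m = segment_distance_map(p, c)
        d0 = m.anchor_distance
        # unrolled surface: s in [0, L) cyclic, t in [0, d0]
        L = c.perimeter()
        ns = 480
        ds = L / ns
        nt = max(int(round(d0 / ds)), 2) + 1  # near-isotropic cells for the stencil
        dt = d0 / (nt - 1)
        idx = lambda i, j: (i % ns) * nt + j
        offsets = [
            (1, 0), (0, 1), (1, 1), (1, -1), (1, 2), (2, 1), (1, -2), (2, -1),
            (1, 3), (3, 1), (1, -3), (3, -1), (2, 3), (3, 2), (2, -3), (3, -2),
        ]
        g = lil_matrix((ns * nt, ns * nt))
        for i in range(ns):
            for di, dj in offsets:
                for j in range(nt):
                    jj = j + dj
                    if 0 <= jj < nt:
                        w = np.hypot(di * ds, dj * dt)
                        g[idx(i, j), idx(i + di, jj)] = w
                        g[idx(i + di, jj), idx(i, j)] = w
        # the segment point sits at arc position of the anchor, height d0
        src = idx(m.anchor_contour_index * 2, nt - 1)
        dist = dijkstra(g.tocsr(), directed=False, indices=src)
        for ci in rng.integers(0, 240, 25):
            oracle = dist[idx(ci * 2, 0)]
            assert abs(m.distances[ci] - oracle) / max(oracle, 1e-9) < 0.02


class TestCombineAndLabel:
    def test_single_segment_territory_passthrough(self):
        c = circle_contour(n=40)
        m = segment_distance_map(c.points[3:4] * 1.2, c)
        combined = combine_territory_maps({1: m})
        assert np.allclose(combined["RCA"].distances, m.distances)
        assert "LAD" not in combined

    def test_dominated_segment_is_ignored(self):
        n = 40
        near = ContourDistanceMap(np.full(n, 1.0), 0, np.zeros(3), 1.0)
        far = ContourDistanceMap(np.full(n, 9.0), 0, np.zeros(3), 9.0)
        combined = combine_territory_maps({3: near, 4: far})
        assert np.allclose(combined["LAD"].distances, 1.0)

    def test_pointwise_min_oracle(self, rng):
        n = 60
        maps = {s: ContourDistanceMap(rng.uniform(0, 30, n), 0, np.zeros(3), 1.0) for s in range(1, 10)}
        combined = combine_territory_maps(maps)
        for t, segs in GROUPS.items():
            expected = np.min([maps[s].distances for s in segs], axis=0)
            assert np.array_equal(combined[t].distances, expected)

    def test_label_single_territory(self):
        m = {"LAD": ContourDistanceMap(np.ones(10), 0, np.zeros(3), 1.0)}
        assert all(l == "LAD" for l in label_contour(m))

    def test_tie_broken_by_fixed_order(self):
        m = {
            t: ContourDistanceMap(np.ones(10), 0, np.zeros(3), 1.0)
            for t in ("LCX", "LAD", "RCA")
        }
        assert all(l == "RCA" for l in label_contour(m))

    def test_symmetric_two_artery_boundary(self):
        """Equidistant contour points sit exactly at the label boundary."""
        c = circle_contour(r=20.0, n=72)
        p_rca = np.array([[20.0, 0.0, 0.0]])    # angle 0
        p_lad = np.array([[-20.0, 0.0, 0.0]])   # angle pi
        maps = {1: segment_distance_map(p_rca, c), 4: segment_distance_map(p_lad, c)}
        labels = label_contour(combine_territory_maps(maps))
        th = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        boundary = np.isclose(th, np.pi / 2) | np.isclose(th, 3 * np.pi / 2)
        expect_rca = (th < np.pi / 2) | (th > 3 * np.pi / 2)
        for l, e, b in zip(labels, expect_rca, boundary):
            if not b:  # boundary points are equidistant only to float precision
                assert (l == "RCA") == e


class TestVoronoiFill:
    def test_uniform_label_fills_annulus(self):
        plane = centred_plane()
        epi, endo = circle_contour(18.0), circle_contour(10.0, role="lv-endo")
        labels = np.array(["LAD"] * len(epi.points), dtype=object)
        mask = voronoi_fill(plane, epi.points, labels, endo, epi)
        myo = mask.myocardium()
        assert myo.sum() > 100
        assert np.all(mask.labels[myo] == TERRITORY_LABELS["LAD"])
        assert np.all(mask.labels[~myo] == 0)

    def test_three_arteries_at_120_degrees_split_in_thirds(self):
        plane = centred_plane(n=96, sp=0.5)
        epi, endo = circle_contour(18.0, n=180), circle_contour(10.0, n=180, role="lv-endo")
        th = np.linspace(0, 2 * np.pi, 180, endpoint=False)
        sectors = np.array(
            ["RCA", "LAD", "LCX"], dtype=object
        )[(np.floor((th + np.pi / 3) / (2 * np.pi / 3)).astype(int)) % 3]
        mask = voronoi_fill(plane, epi.points, sectors, endo, epi)
        myo = mask.myocardium().sum()
        for t in TERRITORY_ORDER:
            frac = mask.territory(t).sum() / myo
            assert abs(frac - 1 / 3) < 0.05

    def test_matches_brute_force_nearest_scan(self, rng):
        plane = centred_plane(n=40)
        epi, endo = circle_contour(16.0, n=50), circle_contour(8.0, n=50, role="lv-endo")
        labels = np.array(rng.choice(TERRITORY_ORDER, 50), dtype=object)
        mask = voronoi_fill(plane, epi.points, labels, endo, epi)
        # exhaustive per-pixel scan
        from matplotlib.path import Path as MplPath

        pix = plane.grid_points().reshape(-1, 3)[:, :2]
        myo = MplPath(epi.points[:, :2]).contains_points(pix) & ~MplPath(
            endo.points[:, :2]
        ).contains_points(pix)
        got = mask.labels.reshape(-1)
        order = {t: i for i, t in enumerate(TERRITORY_ORDER)}
        for i in np.flatnonzero(myo):
            d = np.linalg.norm(epi.points[:, :2] - pix[i], axis=1)
            best = np.min(d)
            cands = [labels[j] for j in np.flatnonzero(np.isclose(d, best, atol=1e-9))]
            winner = min(cands, key=lambda t: order[t])
            assert got[i] == TERRITORY_LABELS[winner]
        assert np.all(got[~myo] == 0)

    def test_crossing_contours_rejected(self):
        plane = centred_plane()
        epi = circle_contour(12.0)
        endo = circle_contour(14.0, role="lv-endo")  # outside epi
        labels = np.array(["RCA"] * len(epi.points), dtype=object)
        with pytest.raises(ValueError, match="inside"):
            voronoi_fill(plane, epi.points, labels, endo, epi)

    def test_partition_is_exact_tiling(self, rng):
        plane = centred_plane()
        epi, endo = circle_contour(17.0, n=60), circle_contour(9.0, n=60, role="lv-endo")
        labels = np.array(rng.choice(TERRITORY_ORDER, 60), dtype=object)
        mask = voronoi_fill(plane, epi.points, labels, endo, epi)
        myo = mask.myocardium()
        # every myocardial pixel exactly one territory, none outside
        assert np.all(mask.labels[myo] > 0)
        assert np.all(mask.labels[~myo] == 0)

    def test_reducing_anchor_gap_never_flips_label_away(self):
        """Monotonicity of the min/argmin structure: shrinking a segment's
        anchor gap (same anchor position) lowers its whole distance map, so no
        contour point already labelled with that artery can flip away."""
        c = circle_contour(r=20.0, n=72)
        th1 = 2 * np.pi / 72  # exactly at vertex 1
        p_lad = np.array([[-22.0, -2.0, 0.0]])
        far = np.array([[24 * np.cos(th1), 24 * np.sin(th1), 0.0]])
        near = np.array([[20.5 * np.cos(th1), 20.5 * np.sin(th1), 0.0]])
        maps = {1: segment_distance_map(far, c), 4: segment_distance_map(p_lad, c)}
        labels_before = label_contour(combine_territory_maps(maps))
        maps[1] = segment_distance_map(near, c)
        assert maps[1].anchor_contour_index == 1  # anchor position unchanged
        assert np.all(maps[1].distances <= segment_distance_map(far, c).distances)
        labels_after = label_contour(combine_territory_maps(maps))
        for lb, la in zip(labels_before, labels_after):
            if lb == "RCA":
                assert la == "RCA"


class TestRotationalEquivariance:
    def test_territory_mask_rotates_with_scene(self):
        from cardiofuse.evaluation import dice_coefficient

        plane = centred_plane(n=72, sp=0.75)
        delta = np.pi / 5

        def scene(rot):
            th0 = np.array([np.pi / 2, 7 * np.pi / 6, 11 * np.pi / 6]) + rot
            segs = {}
            for s, (t0, grp) in enumerate(zip(th0, TERRITORY_ORDER)):
                seg_id = GROUPS[grp][0]
                zz = np.linspace(-5, 5, 12)
                segs[seg_id] = np.stack(
                    [21 * np.cos(t0) * np.ones(12), 21 * np.sin(t0) * np.ones(12), zz], axis=1
                )
            tree = CoronaryTree(segments=segs)
            epi = circle_contour(18.0, n=120)
            endo = circle_contour(10.0, n=120, role="lv-endo")
            mask, _, _ = compute_slice_territories(tree, epi, endo, plane)
            return mask

        a = scene(0.0)
        b = scene(delta)
        # rotate mask a by delta and compare labels
        pix = plane.grid_points().reshape(-1, 3)
        c, s = np.cos(-delta), np.sin(-delta)
        back = np.stack(
            [c * pix[:, 0] - s * pix[:, 1], s * pix[:, 0] + c * pix[:, 1]], axis=1
        )
        ij = np.round(back / 0.75 + (72 - 1) / 2).astype(int)
        ok = (ij >= 0).all(axis=1) & (ij < 72).all(axis=1)
        rotated = np.zeros(len(pix), dtype=int)
        rotated[ok] = a.labels[ij[ok, 0], ij[ok, 1]]
        for t in TERRITORY_ORDER:
            d = dice_coefficient(
                (rotated == TERRITORY_LABELS[t]) & ok,
                (b.labels.reshape(-1) == TERRITORY_LABELS[t]) & ok,
            )
            assert d >= 0.9


class TestMaskPropagation:
    def test_identity_motion_identical_masks(self):
        plane = centred_plane()
        epi, endo = circle_contour(18.0), circle_contour(10.0, role="lv-endo")
        labels = np.array(["RCA"] * len(epi.points), dtype=object)
        mask = voronoi_fill(plane, epi.points, labels, endo, epi)
        motion = MotionCorrectionResult(transforms={"basal": [Rigid2D()] * 3}, stage="translation")
        out = propagate_territory_masks(mask, motion, "basal")
        for m in out:
            assert np.array_equal(m.labels, mask.labels)

    def test_translation_moves_mask_centroid(self):
        plane = centred_plane()
        epi, endo = circle_contour(14.0), circle_contour(7.0, role="lv-endo")
        labels = np.array(["LAD"] * len(epi.points), dtype=object)
        mask = voronoi_fill(plane, epi.points, labels, endo, epi)
        motion = MotionCorrectionResult(
            transforms={"basal": [Rigid2D(t=(-4.0, -2.0))]}, stage="translation"
        )
        out = propagate_territory_masks(mask, motion, "basal")[0]
        com0 = np.array(np.nonzero(mask.labels)).mean(axis=1)
        com1 = np.array(np.nonzero(out.labels)).mean(axis=1)
        # inverse of direct (-4,-2) moves content by (+4,+2) mm = (4, 2) px
        assert np.allclose(com1 - com0, [4.0, 2.0], atol=0.5)


class TestAhaModel:
    def test_lad_has_seven_segments(self):
        lad = [s for s, a in AHA_ARTERY_MAP.items() if a == "LAD"]
        assert sorted(lad) == [1, 2, 7, 8, 13, 14, 17]

    def test_basal_ring_has_six_equal_sectors(self):
        plane = centred_plane(n=64, sp=1.0, z=30.0)
        pix = plane.grid_points().reshape(-1, 3)
        r = np.hypot(pix[:, 0], pix[:, 1])
        myo = ((r > 10) & (r < 20)).reshape(plane.size)  # annular myocardium
        segs, artery = aha_model_territories(
            Z_FRAME, rv_insertion=(0.0, 20.0, 30.0), slices={"basal": (plane, myo)}
        )
        ids = np.unique(segs["basal"])
        assert set(ids) == {0, 1, 2, 3, 4, 5, 6}
        counts = [(segs["basal"] == i).sum() for i in range(1, 7)]
        assert max(counts) - min(counts) < 0.15 * np.mean(counts)
        assert artery[1] == "LAD" and artery[3] == "RCA" and artery[5] == "LCX"

    def test_rotating_insertion_rotates_labels_by_one(self):
        plane = centred_plane(n=64, sp=1.0, z=30.0)
        myo = np.ones(plane.size, dtype=bool)
        a, _ = aha_model_territories(
            Z_FRAME, rv_insertion=(20.0, 0.0, 30.0), slices={"basal": (plane, myo)}
        )
        b, _ = aha_model_territories(
            Z_FRAME,
            rv_insertion=(20.0 * np.cos(np.pi / 3), 20.0 * np.sin(np.pi / 3), 30.0),
            slices={"basal": (plane, myo)},
        )
        sa, sb = a["basal"], b["basal"]
        mapped = np.where(sa > 0, (sb - 1) % 6 + 1, 0)
        rotated = np.where(sa > 0, sa % 6 + 1, 0)
        agree = (mapped[sa > 0] == ((sa[sa > 0] - 2) % 6 + 1)).mean()
        assert agree > 0.95

    def test_apical_ring_and_apex(self):
        plane = centred_plane(z=-10.0)
        myo = np.ones(plane.size, dtype=bool)
        segs, _ = aha_model_territories(
            Z_FRAME, rv_insertion=(0, 20, -10), slices={"apical": (plane, myo), "apex": (plane, myo)}
        )
        assert set(np.unique(segs["apical"])) == {13, 14, 15, 16}
        assert set(np.unique(segs["apex"])) == {17}


class TestUptakeCurves:
    def _mask_and_pool(self, perf, truth, spec):
        masks, pools = {}, {}
        for loc, sl in perf.slices.items():
            phase = truth.perfusion_phases[loc]
            z = spec.slice_z(loc)
            epi = truth.contour("lv-epi", z, phase)
            endo = truth.contour("lv-endo", z, phase)
            tree = truth.tree_at_phase(phase)
            mask, _, _ = compute_slice_territories(tree, epi, endo, sl.plane)
            masks[loc] = [mask] * perf.n_frames
            pools[loc] = [endo] * perf.n_frames
        return masks, pools

    def test_uniform_image_gives_constant_curves(self):
        from cardiofuse.phantom import PhantomSpec, make_perfusion_phantom

        spec = PhantomSpec(
            cine_size=(48, 48, 8), cine_spacing=(3.0, 3.0, 13.0),
            perf_size=(48, 48), perf_spacing=(3.0, 3.0), n_phases=8, n_frames=6,
            respiratory_trace=np.zeros((6, 3)), seed=3,
        )
        perf, truth = make_perfusion_phantom(spec)
        for loc in perf.slices:
            perf.slices[loc].frames[:] = 7.0
        masks, pools = self._mask_and_pool(perf, truth, spec)
        curves = extract_uptake_curves(perf, masks, pools)
        for k in ("RCA", "LAD", "LCX", "lv_pool"):
            assert np.allclose(curves[k], 7.0)

    def test_myocardial_curve_follows_gamma_variate(self):
        from cardiofuse.phantom import PhantomSpec, make_perfusion_phantom

        spec = PhantomSpec(
            cine_size=(48, 48, 8), cine_spacing=(3.0, 3.0, 13.0),
            perf_size=(48, 48), perf_spacing=(3.0, 3.0), n_phases=8, n_frames=24,
            respiratory_trace=np.zeros((24, 3)), seed=3,
        )
        perf, truth = make_perfusion_phantom(spec)
        masks, pools = self._mask_and_pool(perf, truth, spec)
        curves = extract_uptake_curves(perf, masks, pools)
        model = truth.compartment_curves()["myo"]
        for t in TERRITORY_ORDER:
            r = np.corrcoef(curves[t], model)[0, 1]
            assert r > 0.99

    def test_hypo_enhanced_territory_has_reduced_peak(self):
        from cardiofuse.phantom import PhantomSpec, make_perfusion_phantom

        spec = PhantomSpec(
            cine_size=(48, 48, 8), cine_spacing=(3.0, 3.0, 13.0),
            perf_size=(48, 48), perf_spacing=(3.0, 3.0), n_phases=8, n_frames=24,
            respiratory_trace=np.zeros((24, 3)),
            hypo_territory="LCX", hypo_factor=0.6, seed=3,
        )
        perf, truth = make_perfusion_phantom(spec)
        masks, pools = self._mask_and_pool(perf, truth, spec)
        curves = extract_uptake_curves(perf, masks, pools)
        baseline = 0.25 * 0.45  # resting myocardial signal share
        peak = {t: np.nanmax(curves[t]) - curves[t][0] for t in TERRITORY_ORDER}
        ratio = peak["LCX"] / np.mean([peak["RCA"], peak["LAD"]])
        assert abs(ratio - 0.6) < 0.1

    def test_missing_frames_rejected(self):
        from cardiofuse.phantom import PhantomSpec, make_perfusion_phantom

        spec = PhantomSpec(
            cine_size=(48, 48, 8), cine_spacing=(3.0, 3.0, 13.0),
            perf_size=(48, 48), perf_spacing=(3.0, 3.0), n_phases=8, n_frames=6, seed=3,
        )
        perf, truth = make_perfusion_phantom(spec)
        masks, pools = self._mask_and_pool(perf, truth, spec)
        masks["basal"] = masks["basal"][:-1]
        with pytest.raises(ValueError, match="frames"):
            extract_uptake_curves(perf, masks, pools)
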