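import numpy as np
import pytest

from cardiofuse.core import Contour, SlicePlane
from cardiofuse.motion import (
    MotionCorrectionResult,
    Rigid2D,
    correct_perfusion,
    correct_series,
    export_vdf,
    gradient_energy,
    propagate_basal,
    propagate_contours,
    temporal_average,
)
from cardiofuse.phantom import PhantomSpec, default_respiratory_trace, make_perfusion_phantom


def motion_spec(trace=None, n_frames=16):
    return PhantomSpec(
        cine_size=(48, 48, 8),
        cine_spacing=(3.0, 3.0, 13.0),
        perf_size=(48, 48),
        perf_spacing=(3.0, 3.0),
        n_phases=8,
        n_frames=n_frames,
        rv_bolus=(2.0, 3.0, 1.0, 1.6),
        lv_bolus=(4.0, 3.0, 1.0, 1.4),
        myo_bolus=(6.0, 3.0, 1.0, 0.7),
        respiratory_trace=trace,
        seed=11,
    )


def simple_plane(n=20, sp=1.0):
    return SlicePlane(origin=(0, 0, 0), u=(1, 0, 0), v=(0, 1, 0), size=(n, n), spacing=(sp, sp))


class TestRigid2D:
    def test_inverse_round_trip(self, rng):
        t = Rigid2D(theta=0.3, centre=(5, -2), t=(1.5, 2.5))
        pts = rng.uniform(-20, 20, (50, 2))
        assert np.max(np.abs(t.inverse().apply(t.apply(pts)) - pts)) < 1e-9

    def test_compose_matches_sequential(self, rng):
        a = Rigid2D(theta=0.2, centre=(3, 1), t=(1, -1))
        b = Rigid2D(theta=-0.4, centre=(-2, 2), t=(0.5, 2))
        pts = rng.uniform(-20, 20, (50, 2))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-9)


class TestTemporalAverage:
    def test_identical_frames_idempotent(self):
        plane = simple_plane()
        frames = np.repeat(np.random.default_rng(0).random((20, 20))[..., None], 5, axis=2)
        assert np.allclose(temporal_average(frames, plane), frames[..., 0])

    def test_two_frame_arithmetic(self):
        plane = simple_plane()
        frames = np.stack([np.zeros((20, 20)), np.full((20, 20), 10.0)], axis=2)
        assert np.allclose(temporal_average(frames, plane), 5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            temporal_average(np.zeros((20, 20, 0)), simple_plane())

    def test_exact_correction_sharpens_average(self):
        plane = simple_plane(n=40)
        ii = np.arange(40)
        blob = np.exp(-((ii[:, None] - 20) ** 2 + (ii[None, :] - 20) ** 2) / 20.0)
        shifts = [(-3, 0), (0, 0), (3, 0)]
        frames = np.stack(
            [np.roll(blob, s, axis=(0, 1)) for s in shifts], axis=2
        )
        # content moved by s -> direct (correction) transform is -s
        transforms = [Rigid2D(t=(-s[0], -s[1])) for s in shifts]
        blurred = temporal_average(frames, plane)
        sharp = temporal_average(frames, plane, transforms)
        assert gradient_energy(sharp) > gradient_energy(blurred)


class TestCorrectSeries:
    def test_motion_free_series_recovers_null(self):
        spec = motion_spec(trace=np.zeros((16, 3)))
        perf, _ = make_perfusion_phantom(spec)
        res = correct_perfusion(perf, stage="translation", strategy="basal-propagated")
        t = res.translations("basal")
        assert np.abs(t).max() < 0.25 * 3.0  # 0.25 px

    def test_injected_trace_recovered(self):
        trace = default_respiratory_trace(16, amplitude_mm=8.0, period_frames=5.0, breath_hold=(3, 9))
        spec = motion_spec(trace=trace)
        perf, truth = make_perfusion_phantom(spec)
        res = correct_perfusion(perf, stage="translation", strategy="basal-propagated")
        key = perf.max_contrast_frame
        d_true = truth.respiratory_mm[:, :2] - truth.respiratory_mm[key, :2]
        err = np.linalg.norm(-res.translations("basal") - d_true, axis=1)
        assert err.mean() < 0.5 * 3.0  # half a pixel

    def test_rigid_stage_requires_translation_init_and_finds_no_rotation(self):
        trace = default_respiratory_trace(16, amplitude_mm=5.0, breath_hold=(3, 9))
        spec = motion_spec(trace=trace)
        perf, _ = make_perfusion_phantom(spec)
        with pytest.raises(ValueError, match="init"):
            correct_series(
                perf.slices["basal"].frames, perf.slices["basal"].plane,
                stage="rigid", key_frame=perf.max_contrast_frame,
            )
        trans = correct_perfusion(perf, stage="translation", strategy="basal-propagated")
        rigid = correct_perfusion(
            perf, stage="rigid", strategy="basal-propagated", init=trans
        )
        thetas = [t.theta for t in rigid.transforms["basal"]]
        assert np.abs(thetas).max() < 0.01  # no true rotation injected

    def test_direct_inverse_identity(self):
        spec = motion_spec(trace=default_respiratory_trace(16, breath_hold=(3, 9)))
        perf, _ = make_perfusion_phantom(spec)
        res = correct_perfusion(perf, stage="translation", strategy="basal-propagated")
        pts = np.random.default_rng(1).uniform(0, 140, (50, 2))
        for t in res.transforms["basal"]:
            assert np.max(np.abs(t.inverse().apply(t.apply(pts)) - pts)) < 1e-9

    def test_average_sharpness_nondecreasing_across_stages(self):
        trace = default_respiratory_trace(16, amplitude_mm=8.0, breath_hold=(3, 9))
        spec = motion_spec(trace=trace)
        perf, _ = make_perfusion_phantom(spec)
        sl = perf.slices["basal"]
        uncorrected = temporal_average(sl.frames, sl.plane)
        trans = correct_perfusion(perf, stage="translation", strategy="basal-propagated")
        corrected = temporal_average(sl.frames, sl.plane, trans.transforms["basal"])
        assert gradient_energy(corrected) >= gradient_energy(uncorrected)


class TestPropagation:
    def test_basal_identity_propagates_identity(self):
        res = MotionCorrectionResult(
            transforms={"basal": [Rigid2D()] * 4}, stage="translation"
        )
        out = propagate_basal(res, ["basal", "medial", "apical"])
        for loc in ("medial", "apical"):
            assert all(t.is_identity for t in out.transforms[loc])

    def test_copy_semantics_per_frame(self):
        ts = [Rigid2D(t=(2.0, 1.0)) if f == 3 else Rigid2D() for f in range(5)]
        res = MotionCorrectionResult(transforms={"basal": ts}, stage="translation")
        out = propagate_basal(res, ["basal", "medial", "apical"])
        assert out.transforms["medial"][3].t == (2.0, 1.0)
        assert out.transforms["apical"][3].t == (2.0, 1.0)
        assert out.strategy == "basal-propagated"


class TestVdfExport:
    def test_identity_gives_zero_fields(self):
        plane = simple_plane()
        res = MotionCorrectionResult(transforms={"basal": [Rigid2D()] * 3}, stage="translation")
        vdf = export_vdf(res, plane)
        for f in range(3):
            assert np.all(vdf[("basal", f)].field == 0)

    def test_translation_field_is_negated_direct(self):
        plane = simple_plane()
        res = MotionCorrectionResult(
            transforms={"basal": [Rigid2D(t=(3.0, 0.0))]}, stage="translation"
        )
        vdf = export_vdf(res, plane)[("basal", 0)]
        assert np.allclose(vdf.field[..., 0], -3.0)
        assert np.allclose(vdf.field[..., 1], 0.0)

    def test_rigid_field_matches_pointwise_inverse(self, rng):
        plane = simple_plane()
        t = Rigid2D(theta=0.2, centre=(10, 10), t=(1.0, -2.0))
        res = MotionCorrectionResult(transforms={"basal": [t]}, stage="rigid")
        vdf = export_vdf(res, plane)[("basal", 0)]
        inv = t.inverse()
        for _ in range(10):
            i, j = rng.integers(0, 20, 2)
            p = np.array([i * 1.0, j * 1.0])
            assert np.allclose(vdf.field[i, j], inv.apply(p[None])[0] - p, atol=1e-9)


class TestContourPropagation:
    def test_identity_and_translation(self):
        plane = simple_plane(n=40)
        c = Contour(
            points=np.array([[10.0, 10, 0], [20, 10, 0], [20, 20, 0], [10, 20, 0]]),
            role="lv-epi",
        )
        res = MotionCorrectionResult(
            transforms={"basal": [Rigid2D(), Rigid2D(t=(-2.0, -1.0))]}, stage="translation"
        )
        out = propagate_contours([c], res, "basal", plane)
        assert np.allclose(out[0][0].points, c.points)
        # inverse of direct (-2,-1) moves the contour by (+2,+1)
        assert np.allclose(out[1][0].points[:, :2], c.points[:, :2] + [2.0, 1.0])
        assert np.allclose(out[1][0].points[:, 2], c.points[:, 2])

    def test_phantom_epicardial_contour_lands_on_anatomy(self):
        trace = default_respiratory_trace(16, amplitude_mm=8.0, breath_hold=(3, 9))
        spec = motion_spec(trace=trace)
        perf, truth = make_perfusion_phantom(spec)
        res = correct_perfusion(perf, stage="translation", strategy="basal-propagated")
        key = perf.max_contrast_frame
        z = spec.slice_z("basal")
        phase = truth.perfusion_phases["basal"]
        epi = truth.contour("lv-epi", z, phase)
        # observed key-frame contour: anatomy shifted by the key respiratory offset
        key_contour = epi.transformed(lambda p: p + truth.respiratory_mm[key])
        out = propagate_contours([key_contour], res, "basal", perf.slices["basal"].plane)
        for f in range(perf.n_frames):
            expected = epi.points + truth.respiratory_mm[f]
            d = np.linalg.norm(out[f][0].points[:, :2] - expected[:, :2], axis=1)
            assert d.mean() < 3.0  # < 1 px


def test_basal_propagated_dice_close_to_all_slice():
    """Respiration shared across locations: propagating the basal transforms
    performs essentially as well as correcting every slice."""
    from matplotlib.path import Path as MplPath

    trace = default_respiratory_trace(16, amplitude_mm=8.0, breath_hold=(3, 9))
    spec = motion_spec(trace=trace)
    perf, truth = make_perfusion_phantom(spec)
    key = perf.max_contrast_frame

    def epi_dice(res):
        vals = []
        for loc in ("basal", "medial", "apical"):
            sl = perf.slices[loc]
            z = spec.slice_z(loc)
            phase = truth.perfusion_phases[loc]
            epi = truth.contour("lv-epi", z, phase)
            key_contour = epi.transformed(lambda p: p + truth.respiratory_mm[key])
            moved = propagate_contours([key_contour], res, loc, sl.plane)
            pix = sl.plane.grid_points().reshape(-1, 3)[:, :2]
            for f in range(perf.n_frames):
                a = MplPath(moved[f][0].points[:, :2]).contains_points(pix)
                b = MplPath((epi.points + truth.respiratory_mm[f])[:, :2]).contains_points(pix)
                vals.append(2 * (a & b).sum() / max(a.sum() + b.sum(), 1))
        return float(np.mean(vals))

    basal = correct_perfusion(perf, stage="translation", strategy="basal-propagated")
    allsl = correct_perfusion(perf, stage="translation", strategy="all-slice")
    d_basal, d_all = epi_dice(basal), epi_dice(allsl)
    assert d_basal >= 0.95
    assert d_basal >= d_all - 0.02
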