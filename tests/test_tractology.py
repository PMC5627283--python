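import numpy as np
import pandas as pd
import pytest

from tractatlas.core_tensor import ScalarVolume, TensorVolume
from tractatlas.registration import DeformationField, identity_field
from tractatlas.tractology import (FiberBundle, ParameterizedTractSet,
                                   Streamline, load_bundle,
                                   map_to_native_and_sample, parameterize,
                                   resample_arclength, save_bundle,
                                   select_bundle, track)

AFF = np.diag([2.0, 2.0, 2.0, 1.0])


def slab_template(shape=(24, 24, 24), lo=8, hi=16):
    """Uniform x-oriented anisotropic slab (lo <= y < hi), isotropic rest."""
    tensors = np.zeros(shape + (3, 3))
    tensors[...] = np.diag([0.75e-3, 0.7e-3, 0.65e-3])
    slab = np.zeros(shape, bool)
    slab[:, lo:hi, :] = True
    tensors[slab] = np.diag([1.7e-3, 0.35e-3, 0.25e-3])
    return TensorVolume(tensors, AFF), slab


class TestTrack:
    def test_slab_gives_straight_x_lines(self):
        template, slab = slab_template()
        lines = track(template, fa_thresh=0.2, step_mm=1.0)
        assert len(lines) > 0
        for sl in lines[::50]:
            spread_yz = np.ptp(sl.points[:, 1:], axis=0)
            assert spread_yz.max() < 0.5          # straight, x-parallel
            # spans the volume in x within a couple of steps of the faces
            assert sl.points[:, 0].min() < 4.0
            assert sl.points[:, 0].max() > 42.0

    def test_no_seed_below_threshold(self):
        template, _ = slab_template()
        seeds = np.array([[24.0, 4.0, 24.0]])    # isotropic region
        assert track(template, seeds=seeds) == []

    def test_quarter_circle_arc_length(self):
        # sharp (untapered) arc: tracked length = centerline arc + end caps
        from tractatlas.synthetic_data import (BundleSpec, PhantomSpec,
                                               build_phantom, _densify)
        theta = np.linspace(np.pi * 0.2, np.pi * 0.8, 40)
        arc = np.stack([48 + 26 * np.cos(theta),
                        np.full_like(theta, 48.0),
                        30 + 20 * np.sin(theta)], axis=1)
        spec = PhantomSpec(bundles=[BundleSpec("arc", arc, radius=6.0)],
                           taper=0.0)
        ph = build_phantom(spec)
        line = _densify(arc)
        seg = np.linalg.norm(np.diff(line, axis=0), axis=1).sum()
        mid = line[len(line) // 2]
        lines = track(ph.tensor, seeds=mid[None], step_mm=1.0)
        assert len(lines) == 1
        expected = seg + 2 * 6.0              # hemispherical end caps
        assert abs(lines[0].length - expected) / expected < 0.08

    def test_termination_criteria_hold(self):
        template, _ = slab_template()
        step = 1.0
        lines = track(template, fa_thresh=0.2, angle_thresh_deg=30.0,
                      step_mm=step)
        sl = lines[0]
        d = np.diff(sl.points, axis=0)
        assert (np.linalg.norm(d, axis=1) <= step + 1e-6).all()
        cos = np.einsum("ij,ij->i", d[:-1], d[1:]) / (
            np.linalg.norm(d[:-1], axis=1) * np.linalg.norm(d[1:], axis=1))
        assert (cos >= np.cos(np.radians(30.0)) - 1e-9).all()

    def test_deterministic(self):
        template, _ = slab_template()
        a = track(template, step_mm=1.0)
        b = track(template, step_mm=1.0)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.points, sb.points)

    def test_parameter_validation(self):
        template, _ = slab_template()
        with pytest.raises(ValueError):
            track(template, fa_thresh=0.0)
        with pytest.raises(ValueError):
            track(template, angle_thresh_deg=120.0)
        with pytest.raises(ValueError):
            track(template, step_mm=-1.0)


class TestSelectBundle:
    def _lines(self):
        ys = [10.0, 20.0, 30.0]
        return [Streamline(np.stack([np.linspace(0, 46, 24),
                                     np.full(24, y), np.full(24, 24.0)],
                                    axis=1)) for y in ys]

    def _mask(self, ylo, yhi, shape=(24, 24, 24)):
        m = np.zeros(shape, bool)
        m[:, ylo:yhi, :] = True
        return m

    def test_and_all_is_identity(self):
        lines = self._lines()
        rois = {"all": np.ones((24, 24, 24), bool)}
        out = select_bundle(lines, rois, [("AND", "all")], AFF)
        assert len(out) == 3

    def test_not_all_is_empty(self):
        lines = self._lines()
        rois = {"all": np.ones((24, 24, 24), bool)}
        out = select_bundle(lines, rois, [("NOT", "all")], AFF)
        assert out.empty

    def test_waypoint_selects_one_line(self):
        lines = self._lines()
        rois = {"wp": self._mask(4, 7)}           # y in [8, 14) mm
        out = select_bundle(lines, rois, [("AND", "wp")], AFF)
        assert len(out) == 1
        assert out.streamlines[0].points[0, 1] == 10.0

    def test_or_terms(self):
        lines = self._lines()
        rois = {"a": self._mask(4, 7), "b": self._mask(14, 17)}
        out = select_bundle(lines, rois, [("OR", "a"), ("OR", "b")], AFF)
        assert len(out) == 2

    def test_selection_log_counts(self):
        lines = self._lines()
        rois = {"wp": self._mask(4, 7)}
        out = select_bundle(lines, rois, [("AND", "wp")], AFF)
        assert out.selection_log[0]["count"] == 3
        assert out.selection_log[-1]["count"] == 1

    def test_unknown_roi_raises(self):
        with pytest.raises(KeyError):
            select_bundle(self._lines(), {}, [("AND", "nope")], AFF)

    def test_crossing_bundles_separated(self, phantom):
        lines = track(phantom.tensor, step_mm=1.0)
        wp = phantom.atlas["cst_like_waypoint"]
        out = select_bundle(lines, phantom.atlas.masks,
                            [("AND", "cst_like_waypoint")],
                            phantom.tensor.affine)
        assert 0 < len(out) < len(lines)
        # every kept line passes the waypoint; spot-check geometry:
        # cst-like bundle is x ~ 24 mm, y ~ 72 mm
        for sl in out.streamlines[::20]:
            assert abs(sl.points[:, 0].mean() - 24.0) < 8.0


class TestParameterize:
    def test_equal_fraction_resampling(self):
        pts = np.stack([np.linspace(0, 40, 9), np.zeros(9), np.zeros(9)],
                       axis=1)
        sl = Streamline(pts)
        out = parameterize(FiberBundle([sl]), K=5)
        np.testing.assert_allclose(out.representative[:, 0],
                                   [0, 10, 20, 30, 40], atol=1e-9)
        np.testing.assert_allclose(out.arc_fractions, [0, .25, .5, .75, 1])

    def test_identical_streamlines_mean_is_member(self):
        pts = np.stack([np.linspace(0, 30, 16), np.linspace(0, 10, 16),
                        np.zeros(16)], axis=1)
        bundle = FiberBundle([Streamline(pts)] * 5)
        out = parameterize(bundle, K=8)
        np.testing.assert_allclose(out.representative,
                                   resample_arclength(pts, 8), atol=1e-9)

    def test_antiparallel_copies_are_flipped(self):
        t = np.linspace(0, 1, 20)
        pts = np.stack([30 * t, 10 * np.sin(np.pi * t), np.zeros(20)],
                       axis=1)
        bundle = FiberBundle([Streamline(pts), Streamline(pts[::-1])])
        out = parameterize(bundle, K=10)
        gap = np.linalg.norm(out.streamline_points[0]
                             - out.streamline_points[1], axis=1)
        assert gap.max() < 1e-9

    def test_arc_length_preserved(self, rng):
        t = np.linspace(0, 1, 200)
        pts = np.stack([50 * t, 8 * np.sin(2 * np.pi * t), 5 * t ** 2],
                       axis=1)
        sl = Streamline(pts)
        out = parameterize(FiberBundle([sl]), K=20)
        resampled_len = np.linalg.norm(
            np.diff(out.streamline_points[0], axis=0), axis=1).sum()
        assert abs(resampled_len - sl.length) / sl.length < 0.01

    def test_validation(self):
        with pytest.raises(ValueError):
            parameterize(FiberBundle([]), K=5)
        sl = Streamline(np.zeros((3, 3)) + np.arange(3)[:, None])
        with pytest.raises(ValueError):
            parameterize(FiberBundle([sl]), K=1)

    def test_arc_fraction_invariant(self):
        with pytest.raises(ValueError):
            ParameterizedTractSet(3, np.zeros((3, 3)),
                                  np.array([0.0, 0.7, 0.9]),
                                  np.zeros((1, 3, 3)))


class TestMapToNativeAndSample:
    def _pts(self, K=6):
        rep = np.stack([np.linspace(4, 40, K), np.full(K, 24.0),
                        np.full(K, 24.0)], axis=1)
        return ParameterizedTractSet(K, rep, np.linspace(0, 1, K),
                                     rep[None])

    def test_identity_fields_sample_population_values(self):
        pts = self._pts()
        ramp = np.indices((24, 24, 24), dtype=float)[0] * 2.0   # world x
        meas = ScalarVolume(ramp, AFF)
        out = map_to_native_and_sample(
            pts, {"s1": identity_field((24, 24, 24), AFF)}, {"s1": meas})
        np.testing.assert_allclose(out["value"].to_numpy(),
                                   pts.representative[:, 0], atol=1e-9)

    def test_translation_field_shifts_samples(self):
        pts = self._pts()
        ramp = np.indices((24, 24, 24), dtype=float)[0] * 2.0
        meas = ScalarVolume(ramp, AFF)
        disp = np.zeros((24, 24, 24, 3))
        disp[..., 0] = 3.0
        out = map_to_native_and_sample(
            pts, {"s1": DeformationField(disp, AFF)}, {"s1": meas})
        np.testing.assert_allclose(out["value"].to_numpy(),
                                   pts.representative[:, 0] + 3.0, atol=1e-9)

    def test_out_of_volume_points_are_nan(self):
        pts = self._pts()
        meas = ScalarVolume(np.ones((24, 24, 24)), AFF)
        disp = np.zeros((24, 24, 24, 3))
        disp[..., 0] = -30.0                    # push first points outside
        out = map_to_native_and_sample(
            pts, {"s1": DeformationField(disp, AFF)}, {"s1": meas})
        assert out["value"].isna().sum() > 0

    def test_missing_subject_raises(self):
        pts = self._pts()
        meas = ScalarVolume(np.ones((24, 24, 24)), AFF)
        with pytest.raises(ValueError, match="s2"):
            map_to_native_and_sample(
                pts, {"s1": identity_field((24, 24, 24), AFF),
                      "s2": identity_field((24, 24, 24), AFF)},
                {"s1": meas})


class TestStreamlineIO:
    def test_tck_roundtrip(self, tmp_path, rng):
        lines = [Streamline(np.cumsum(rng.random((10, 3)), axis=0))
                 for _ in range(4)]
        bundle = FiberBundle(lines, space="population",
                             selection_log=[{"term": "input", "count": 4}])
        p = tmp_path / "bundle.tck"
        save_bundle(bundle, p)
        back = load_bundle(p)
        assert len(back) == 4
        assert back.space == "population"
        assert back.selection_log[0]["count"] == 4
        for a, b in zip(lines, back.streamlines):
            np.testing.assert_allclose(a.points, b.points, atol=1e-5)

    def test_trk_readable(self, tmp_path, rng):
        import nibabel.streamlines as nibs
        lines = [np.cumsum(rng.random((8, 3)), axis=0).astype(np.float32)
                 for _ in range(3)]
        tg = nibs.Tractogram(lines, affine_to_rasmm=np.eye(4))
        trk_path = str(tmp_path / "bundle.trk")
        nibs.save(tg, trk_path)
        back = load_bundle(trk_path)
        assert len(back) == 3
        np.testing.assert_allclose(back.streamlines[0].points, lines[0],
                                   atol=1e-4)

    def test_streamline_invariants(self):
        with pytest.raises(ValueError):
            Streamline(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            Streamline(np.zeros((5, 2)))
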