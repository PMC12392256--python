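"""Forward-simulator ground truth, noise statistics, and spectra."""

import numpy as np
import pytest
from scipy import stats

import cryoeels as ce


class TestBuildScene:
    def test_empty_scene_has_no_coverage(self):
        spec = ce.SceneSpec(field_size=(10, 10), pixel_size=0.5, ice_thickness=80.0)
        scene = ce.build_scene(spec)
        assert scene.coverage == {}
        np.testing.assert_allclose(scene.thickness, 80.0)

    def test_disk_area_matches_pixel_counting(self):
        # rasterized disk of radius 25 nm at 0.21 nm/px: pi*(25/0.21)^2 px
        spec = ce.SceneSpec(
            field_size=(63, 63), pixel_size=0.21, ice_thickness=60.0,
            particles=[ce.ParticleSpec(center=(31.5, 31.5), radius=25, element="Si")],
        )
        scene = ce.build_scene(spec)
        area = (scene.coverage["Si"] > 0).sum()
        assert area == pytest.approx(np.pi * (25 / 0.21) ** 2, rel=0.02)

    def test_disjoint_disks_cover_union(self):
        spec = ce.SceneSpec(
            field_size=(60, 60), pixel_size=0.3, ice_thickness=50.0,
            particles=[
                ce.ParticleSpec(center=(15, 15), radius=5, element="Si"),
                ce.ParticleSpec(center=(45, 45), radius=7, element="Si"),
            ],
        )
        scene = ce.build_scene(spec)
        mask = scene.coverage["Si"] > 0
        spec1 = ce.SceneSpec(
            field_size=(60, 60), pixel_size=0.3, ice_thickness=50.0,
            particles=[ce.ParticleSpec(center=(15, 15), radius=5, element="Si")],
        )
        spec2 = ce.SceneSpec(
            field_size=(60, 60), pixel_size=0.3, ice_thickness=50.0,
            particles=[ce.ParticleSpec(center=(45, 45), radius=7, element="Si")],
        )
        m1 = ce.build_scene(spec1).coverage["Si"] > 0
        m2 = ce.build_scene(spec2).coverage["Si"] > 0
        assert not (m1 & m2).any()
        np.testing.assert_array_equal(mask, m1 | m2)

    def test_particle_outside_field_raises(self):
        spec = ce.SceneSpec(
            field_size=(20, 20), pixel_size=0.5, ice_thickness=50.0,
            particles=[ce.ParticleSpec(center=(19, 10), radius=5, element="Si")],
        )
        with pytest.raises(ValueError, match="particle 0"):
            ce.build_scene(spec)

    def test_film_region_adds_carbon(self):
        film = np.zeros((20, 20), bool)
        film[:, :10] = True
        spec = ce.SceneSpec(
            field_size=(10, 10), pixel_size=0.5, ice_thickness=50.0,
            film_region=film, film_thickness=20.0,
        )
        scene = ce.build_scene(spec)
        assert "C" in scene.coverage
        np.testing.assert_array_equal(scene.coverage["C"] > 0, film)
        np.testing.assert_allclose(scene.thickness[film], 70.0)
        np.testing.assert_allclose(scene.thickness[~film], 50.0)


class TestExpectedImages:
    def test_pure_background_lies_on_power_law(self, flat_scene, si_triplet):
        for win in (si_triplet.prepre, si_triplet.pre, si_triplet.core):
            img = ce.expected_window_image(flat_scene, win)
            a = flat_scene.amplitude[0, 0]
            r = flat_scene.exponent[0, 0]
            np.testing.assert_allclose(img, a * win.center**-r * win.width, rtol=1e-12)

    def test_full_coverage_pixel_core_value(self, si_triplet):
        # at the particle centre with coverage 1: core = (1+J) * background
        spec = ce.SceneSpec(
            field_size=(20, 20), pixel_size=0.5, ice_thickness=60.0,
            particles=[ce.ParticleSpec(center=(10, 10), radius=4, element="Si", coverage=1.0)],
        )
        scene = ce.build_scene(spec)
        img = ce.expected_window_image(scene, si_triplet.core)
        j = scene.edges["Si"].jump_ratio
        cy = cx = int(round(10 / 0.5))
        a = scene.amplitude[cy, cx]
        r = scene.exponent[cy, cx]
        bg = a * si_triplet.core.center**-r * si_triplet.core.width
        assert img[cy, cx] == pytest.approx((1 + j) * bg, rel=1e-12)

    def test_three_window_of_expected_images_is_exact_jump_term(self, si_triplet):
        spec = ce.SceneSpec(
            field_size=(40, 40), pixel_size=0.5, ice_thickness=60.0,
            particles=[
                ce.ParticleSpec(center=(14, 14), radius=5, element="Si", coverage=0.3),
                ce.ParticleSpec(center=(28, 26), radius=4, element="Si", coverage=0.8),
            ],
        )
        scene = ce.build_scene(spec)
        imgs = [ce.expected_window_image(scene, w) for w in
                (si_triplet.prepre, si_triplet.pre, si_triplet.core)]
        m = ce.three_window_map(*imgs, si_triplet, intensity_floor=0.0)
        truth = ce.true_jump_image(scene, si_triplet)
        assert m.valid.all()
        np.testing.assert_allclose(m.values, truth, rtol=1e-10, atol=1e-15)

    def test_low_energy_edge_cancels_in_higher_triplet(self):
        # an Si edge (105 eV) present under a C triplet (~220-310 eV)
        # multiplies all three windows equally and must vanish from the map
        spec = ce.SceneSpec(
            field_size=(30, 30), pixel_size=0.5, ice_thickness=60.0,
            particles=[ce.ParticleSpec(center=(15, 15), radius=5, element="Si", coverage=0.5)],
        )
        scene = ce.build_scene(spec)
        tri_c = ce.default_triplet("C")
        imgs = [ce.expected_window_image(scene, w) for w in (tri_c.prepre, tri_c.pre, tri_c.core)]
        m = ce.three_window_map(*imgs, tri_c, intensity_floor=0.0)
        scale = imgs[2].max()
        assert np.abs(m.values).max() < 1e-10 * scale


class TestSimulateAcquisition:
    def _acq(self, triplet, **kw):
        defaults = dict(
            windows=triplet,
            exposures=dict(zero_loss=0.5, prepre=4.0, pre=20.0, core=20.0),
            dose_rate=8.0,
        )
        defaults.update(kw)
        return ce.AcquisitionSpec(**defaults)

    def test_zero_dose_gives_zero_counts(self, flat_scene, si_triplet):
        out = ce.simulate_acquisition(flat_scene, self._acq(si_triplet, dose_rate=0.0), seed=1)
        for img in out.values():
            arr = img.as_array() if isinstance(img, ce.FrameStack) else img.pixels
            assert not arr.any()

    def test_fixed_seed_is_bit_identical(self, flat_scene, si_triplet):
        a = ce.simulate_acquisition(flat_scene, self._acq(si_triplet), seed=33)
        b = ce.simulate_acquisition(flat_scene, self._acq(si_triplet), seed=33)
        for key in a:
            xa = a[key].as_array() if isinstance(a[key], ce.FrameStack) else a[key].pixels
            xb = b[key].as_array() if isinstance(b[key], ce.FrameStack) else b[key].pixels
            np.testing.assert_array_equal(xa, xb)

    def test_sample_mean_within_clt_bound(self, si_triplet):
        # constant scene, many repeats: per-pixel mean within 3 SE
        spec = ce.SceneSpec(field_size=(4, 4), pixel_size=0.5, ice_thickness=60.0)
        scene = ce.build_scene(spec)
        acq = self._acq(si_triplet)
        n = 400
        sums = np.zeros(scene.shape)
        for s in range(n):
            sums += ce.simulate_acquisition(scene, acq, seed=s)["pre"].frames[0]
        mean = sums / n
        expected = (
            ce.expected_window_image(scene, si_triplet.pre)
            * acq.dose_rate * acq.exposures["pre"] * (scene.pixel_size * 10) ** 2
        )
        se = np.sqrt(expected / n)
        assert np.all(np.abs(mean - expected) < 3.5 * se)

    def test_poisson_variance_matches_mean(self, si_triplet):
        # chi-squared dispersion test per pixel at the 1% level
        spec = ce.SceneSpec(field_size=(4, 4), pixel_size=0.5, ice_thickness=60.0)
        scene = ce.build_scene(spec)
        acq = self._acq(si_triplet, exposures=dict(zero_loss=1, prepre=4, pre=4, core=4))
        reps = np.stack(
            [ce.simulate_acquisition(scene, acq, seed=s)["pre"].frames[0] for s in range(1000)]
        )
        n = reps.shape[0]
        disp = (n - 1) * reps.var(0, ddof=1) / reps.mean(0)
        lo = stats.chi2.ppf(0.005, n - 1)
        hi = stats.chi2.ppf(0.995, n - 1)
        reject = ((disp < lo) | (disp > hi)).mean()
        assert reject < 0.08  # nominal 1%, allow sampling slack on 64 pixels

    def test_zero_loss_ratio_encodes_thickness(self, flat_scene, si_triplet):
        zl = ce.expected_zero_loss(flat_scene)
        un = ce.expected_unfiltered(flat_scene)
        t = flat_scene.mean_free_path * np.log(un / zl)
        np.testing.assert_allclose(t, flat_scene.thickness, rtol=1e-12)

    def test_drift_shifts_frames(self, si_triplet):
        spec = ce.SceneSpec(
            field_size=(32, 32), pixel_size=0.5, ice_thickness=60.0,
            particles=[ce.ParticleSpec(center=(16, 16), radius=6, element="Si")],
        )
        scene = ce.build_scene(spec)
        acq = self._acq(
            si_triplet, frames_per_exposure=3, drift_per_frame=(2.0, 0.0),
            dose_rate=1e4,  # high dose so the shift is visible above noise
        )
        stack = ce.simulate_acquisition(scene, acq, seed=7)["core"]
        d = ce.register_translation(stack.frames[2], stack.frames[0], upsample=1)
        assert (d.dy, d.dx) == (4.0, 0.0)


class TestSimulateSpectrum:
    def test_tail_slope_recovers_exponent(self):
        e = np.arange(-20, 400, 0.5)
        s = ce.simulate_spectrum(e, thickness=100.0, seed=5)
        sel = (e > 60) & (e < 250)
        slope, _ = np.polyfit(np.log(e[sel]), np.log(np.clip(s[sel], 0.5, None)), 1)
        assert slope == pytest.approx(-3.0, rel=0.05)

    def test_edge_step_rises_above_extrapolated_power_law(self):
        e = np.arange(-20, 400, 0.5)
        edge = ce.default_edge_model("Si")
        s = ce.simulate_spectrum(e, thickness=100.0, elements=[(edge, 1.0)])
        s0 = ce.simulate_spectrum(e, thickness=100.0)
        post = (e > 130) & (e < 300)  # sigmoid saturated well above onset
        ratio = s[post] / s0[post]
        np.testing.assert_allclose(ratio, 1 + edge.jump_ratio, rtol=0.02)
        pre = (e > 30) & (e < 85)  # below onset minus the sigmoid skirt
        np.testing.assert_allclose(s[pre], s0[pre], rtol=1e-3)

    def test_seeded_spectrum_is_deterministic(self):
        e = np.arange(0, 200, 1.0)
        np.testing.assert_array_equal(
            ce.simulate_spectrum(e, seed=9), ce.simulate_spectrum(e, seed=9)
        )

    def test_nonmonotone_axis_rejected(self):
        with pytest.raises(ValueError):
            ce.simulate_spectrum(np.array([0.0, 2.0, 1.0]))
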