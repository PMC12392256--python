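"""Three-window / two-window mapping algebra, masks, and the fit oracle."""

import numpy as np
import pytest

import cryoeels as ce


def const(value: float, shape=(4, 4)) -> np.ndarray:
    return np.full(shape, float(value))


class TestExponentMap:
    def test_flat_spectrum_gives_zero_exponent(self, toy_triplet):
        r = ce.estimate_exponent_map(const(1000), const(1000), toy_triplet)
        assert r.valid.all()
        np.testing.assert_allclose(r.r, 0.0)

    def test_two_point_power_law(self, toy_triplet):
        # 1000 * (250/200)**-3 = 512: exponent must come out exactly 3
        r = ce.estimate_exponent_map(const(1000), const(512), toy_triplet)
        np.testing.assert_allclose(r.r, 3.0, rtol=1e-12)

    def test_nonpositive_intensity_masks_pixel(self, toy_triplet):
        pre = const(512)
        pre[1, 2] = 0.0
        r = ce.estimate_exponent_map(const(1000), pre, toy_triplet)
        assert not r.valid[1, 2]
        assert r.r[1, 2] == 0.0
        assert r.valid.sum() == r.valid.size - 1

    def test_exposure_normalisation(self, toy_triplet):
        # same underlying rate, pre acquired 5x longer: raw counts 5x higher
        prepre = ce.FilteredImage(const(1000), exposure=1.0)
        pre = ce.FilteredImage(const(512 * 5), exposure=5.0)
        r = ce.estimate_exponent_map(prepre, pre, toy_triplet)
        np.testing.assert_allclose(r.r, 3.0, rtol=1e-12)

    def test_extreme_exponent_masked(self, toy_triplet):
        # a hot pixel in the pre image yields r far outside [-10, 10]
        pre = const(512)
        pre[0, 0] = 1e18
        r = ce.estimate_exponent_map(const(1000), pre, toy_triplet)
        assert not r.valid[0, 0]

    def test_shape_mismatch_raises(self, toy_triplet):
        with pytest.raises(ValueError, match="mismatch"):
            ce.estimate_exponent_map(const(1, (3, 3)), const(1, (4, 4)), toy_triplet)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(ValueError):
            tri = ce.WindowTriplet(
                ce.EnergyWindow(200, 20), ce.EnergyWindow(200, 20), ce.EnergyWindow(300, 20)
            )
            ce.estimate_exponent_map(const(1), const(1), tri)


class TestAmplitude:
    def test_zero_exponent_returns_intensity(self, toy_triplet):
        r = ce.estimate_exponent_map(const(700), const(700), toy_triplet)
        amp = ce.power_law_amplitude(const(700), 200.0, r)
        np.testing.assert_allclose(amp, 700.0)

    def test_amplitude_consistency_between_windows(self, toy_triplet):
        # 1000 * 200**3 == 512 * 250**3 == 8e9
        r = ce.estimate_exponent_map(const(1000), const(512), toy_triplet)
        a_pp = ce.power_law_amplitude(const(1000), 200.0, r)
        a_p = ce.power_law_amplitude(const(512), 250.0, r)
        np.testing.assert_allclose(a_pp, 8.0e9, rtol=1e-12)
        np.testing.assert_allclose(a_pp, a_p, rtol=1e-12)

    def test_amplitude_tracks_scene_thickness(self):
        # noise-free simulated background: A map proportional to thickness
        grad = np.linspace(50, 150, 32)[:, None] * np.ones((1, 32))
        spec = ce.SceneSpec(field_size=(0.5 * 32, 0.5 * 32), pixel_size=0.5, ice_thickness=grad)
        scene = ce.build_scene(spec)
        tri = ce.default_triplet("Si")
        ipp = ce.expected_window_image(scene, tri.prepre)
        ip = ce.expected_window_image(scene, tri.pre)
        r = ce.estimate_exponent_map(ipp, ip, tri, intensity_floor=0.0)
        amp = ce.power_law_amplitude(ipp, tri.prepre.center, r)
        ratio = amp / scene.thickness
        np.testing.assert_allclose(ratio, ratio[0, 0], rtol=1e-10)


class TestBackgroundConstant:
    def test_zero_exponent_gives_unity(self, toy_triplet):
        r = ce.ExponentMap(r=np.zeros((3, 3)), valid=np.ones((3, 3), bool))
        np.testing.assert_allclose(ce.background_constant_map(r, toy_triplet), 1.0)

    def test_known_value(self, toy_triplet):
        r = ce.ExponentMap(r=const(3.0, (2, 2)), valid=np.ones((2, 2), bool))
        k = ce.background_constant_map(r, toy_triplet)
        np.testing.assert_allclose(k, (300 / 250) ** -3, rtol=1e-12)
        np.testing.assert_allclose(k, 0.578703703703, rtol=1e-10)

    def test_monotone_decreasing_in_r(self, toy_triplet):
        rs = np.linspace(0, 8, 30).reshape(5, 6)
        rm = ce.ExponentMap(r=rs, valid=np.ones(rs.shape, bool))
        k = ce.background_constant_map(rm, toy_triplet).ravel()
        assert np.all(np.diff(k) < 0)
        assert np.all((k > 0) & (k <= 1))


class TestThreeWindowMap:
    def test_perfect_background_gives_zero(self, toy_triplet):
        prepre, pre = const(1000), const(512)
        k = (300 / 250) ** -3
        core = pre * k
        m = ce.three_window_map(prepre, pre, core, toy_triplet)
        assert m.valid.all()
        np.testing.assert_allclose(m.values, 0.0, atol=1e-10)

    def test_jump_term_recovered_exactly(self, toy_triplet):
        prepre, pre = const(1000), const(512)
        bg_core = 512 * (300 / 250) ** -3
        jump = const(37.5)
        core = bg_core + jump
        m = ce.three_window_map(prepre, pre, core, toy_triplet)
        np.testing.assert_allclose(m.values, jump, rtol=1e-12)

    def test_scale_equivariance(self, toy_triplet):
        rng = np.random.default_rng(0)
        prepre = 1000 + rng.uniform(0, 100, (6, 6))
        pre = 500 + rng.uniform(0, 50, (6, 6))
        core = 300 + rng.uniform(0, 30, (6, 6))
        m1 = ce.three_window_map(prepre, pre, core, toy_triplet)
        c = 7.3
        m2 = ce.three_window_map(c * prepre, c * pre, c * core, toy_triplet)
        np.testing.assert_allclose(m2.values, c * m1.values, rtol=1e-10)
        np.testing.assert_allclose(m2.k_map, m1.k_map, rtol=1e-10)

    def test_matches_independent_least_squares_fit(self, toy_triplet):
        """Oracle: per-pixel two-point log-log least-squares fit,
        extrapolated and subtracted, must agree to 1e-10 relative."""
        rng = np.random.default_rng(42)
        shape = (5, 5)
        prepre = 800 + rng.uniform(0, 400, shape)
        pre = 300 + rng.uniform(0, 300, shape)
        core = 100 + rng.uniform(0, 200, shape)
        m = ce.three_window_map(prepre, pre, core, toy_triplet, r_bounds=(-50, 50))

        e = np.array([toy_triplet.prepre.center, toy_triplet.pre.center])
        design = np.column_stack([np.ones(2), np.log(e)])
        expected = np.empty(shape)
        for idx in np.ndindex(shape):
            coef, *_ = np.linalg.lstsq(
                design, np.log([prepre[idx], pre[idx]]), rcond=None
            )
            log_a, slope = coef  # I(E) = exp(log_a) * E**slope
            bg = np.exp(log_a) * toy_triplet.core.center**slope
            expected[idx] = core[idx] - bg
        np.testing.assert_allclose(m.values, expected, rtol=1e-10, atol=1e-10)


class TestTwoWindowMap:
    def test_identical_images_give_zero(self):
        m = ce.two_window_map(const(5), const(5))
        np.testing.assert_allclose(m.values, 0.0)

    def test_decaying_background_leaves_negative_residual(self, toy_triplet):
        # pure power law r=3: residual = A*(E_P^-r - E_C^-r)*w < 0
        a, r, w = 8.0e9, 3.0, 20.0
        pre = const(a * 250.0**-r * w)
        core = const(a * 300.0**-r * w)
        m = ce.two_window_map(pre, core)
        expected = -a * (250.0**-r - 300.0**-r) * w
        np.testing.assert_allclose(m.values, expected, rtol=1e-12)
        assert np.all(m.values < 0)

    def test_three_window_beats_two_window_on_background(self, toy_triplet):
        for r in (1.0, 2.5, 4.0):
            prepre = const(1e4 * 200.0**-r * 200**r)  # just a positive level
            a = 5e9
            prepre = const(a * 200.0**-r * 20)
            pre = const(a * 250.0**-r * 20)
            core = const(a * 300.0**-r * 20)
            m3 = ce.three_window_map(prepre, pre, core, toy_triplet)
            m2 = ce.two_window_map(pre, core)
            assert np.abs(m2.values).min() > np.abs(m3.values).max()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ce.two_window_map(const(1, (2, 2)), const(1, (3, 3)))
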