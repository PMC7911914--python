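"""NE curve, NPC centroid, perpendicularity filter, NE-frame projection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from speedkin import (
    CameraModel,
    NEModel,
    NPCRef,
    NEFitError,
    SimScene,
    check_perpendicularity,
    estimate_registration_error,
    fit_ne,
    fit_npc,
    render_gaussian_spot,
    simulate_ne_image,
    simulate_npc_image,
    to_ne_frame,
)


def _ne(coeffs, side="left", yr=(-1e4, 1e4)):
    return NEModel(poly_coeffs=coeffs, valid_y_range=yr, residual_rms_nm=0.0,
                   cytoplasm_side=side)


def _npc(center):
    return NPCRef(center_nm=center, sigma_x_nm=150.0, sigma_y_nm=267.0,
                  width_ratio=1.78, perpendicular_ok=True,
                  centroid_precision_nm=1.0)


class TestFitNE:
    def _noiseless_ne_image(self, coeffs, shape=(48, 48), px=107.0):
        img = np.zeros(shape)
        c0, c1, c2 = coeffs
        for y in np.arange(-px, shape[0] * px + px, 20.0):
            x = c0 + c1 * y + c2 * y * y
            render_gaussian_spot(shape, x, y, 3000.0, 150.0, px, out=img)
        return img

    def test_straight_ne_recovered(self):
        cam = CameraModel()
        img = self._noiseless_ne_image((1700.0, 0.0, 0.0))
        ne = fit_ne(img, cam)
        assert ne.poly_coeffs[0] == pytest.approx(1700.0, abs=0.5)
        assert abs(ne.poly_coeffs[1]) < 1e-3
        assert abs(ne.poly_coeffs[2]) < 1e-6

    def test_curved_ne_noiseless_near_exact(self):
        """Sub-2 nm on a noiseless curved NE; the residual bias comes from
        the row-profile reading of a sloped line, not from noise."""
        cam = CameraModel()
        coeffs = (1650.0, 0.04, 1.5e-5)
        img = self._noiseless_ne_image(coeffs)
        ne = fit_ne(img, cam)
        ys = np.linspace(*ne.valid_y_range, 60)
        truth = coeffs[0] + coeffs[1] * ys + coeffs[2] * ys ** 2
        assert np.max(np.abs(ne.x_at(ys) - truth)) < 2.0

    def test_simulated_ne_image_within_10nm(self, camera, optics):
        scene = SimScene(ne_poly_coeffs=(1700.0, 0.05, 2e-5), rng_seed=3,
                         fov_px=48)
        stack, truth = simulate_ne_image(scene, camera, optics)
        ne = fit_ne(stack, camera)
        ys = np.linspace(*ne.valid_y_range, 100)
        assert np.max(np.abs(ne.x_at(ys) - scene.ne_x(ys))) < 10.0

    def test_blank_image_raises(self, camera):
        with pytest.raises(NEFitError):
            fit_ne(np.zeros((32, 32)), camera)


class TestFitNPC:
    def test_perpendicular_spot_accepted(self, camera, optics):
        stack, _ = simulate_npc_image(SimScene(rng_seed=8), camera, optics,
                                      width_ratio=1.78)
        ref = fit_npc(stack, camera)
        assert ref.perpendicular_ok
        assert ref.width_ratio == pytest.approx(1.78, rel=0.02)

    def test_symmetric_spot_rejected(self, camera, optics):
        stack, _ = simulate_npc_image(SimScene(rng_seed=9), camera, optics,
                                      width_ratio=1.0)
        ref = fit_npc(stack, camera)
        assert not ref.perpendicular_ok

    def test_mean_fitted_ratio_unbiased(self, camera, optics):
        """Render-then-fit at movie-level photons: mean ratio within 2%."""
        ratios = []
        for s in range(60):
            stack, _ = simulate_npc_image(
                SimScene(rng_seed=4000 + s), camera, optics,
                width_ratio=1.78, photons=8 * 3000.0)
            ratios.append(fit_npc(stack, camera).width_ratio)
        assert np.mean(ratios) == pytest.approx(1.78, rel=0.02)

    def test_centroid_close_to_truth(self, camera, optics):
        scene = SimScene(rng_seed=12)
        stack, truth = simulate_npc_image(scene, camera, optics)
        ref = fit_npc(stack, camera)
        assert np.hypot(ref.center_nm[0] - truth.npc_center_nm[0],
                        ref.center_nm[1] - truth.npc_center_nm[1]) < 5.0


class TestPerpendicularity:
    @pytest.mark.parametrize("ratio,expected", [
        (1.74, True), (1.78, True), (1.82, True),
        (1.73, False), (1.83, False), (1.0, False),
    ])
    def test_band_membership(self, ratio, expected):
        assert check_perpendicularity(ratio) is expected

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(ratio=st.floats(0.1, 3.0))
    def test_equals_interval_membership(self, ratio):
        assert check_perpendicularity(ratio) == (1.74 <= ratio <= 1.82)


class TestRegistration:
    def test_identical_channels_zero_error(self):
        a = np.array([[0.0, 0.0], [100.0, 50.0], [3.0, 7.0]])
        rms, off = estimate_registration_error(a, a)
        assert rms == 0.0
        assert np.allclose(off, 0.0)

    def test_constant_offset_removed(self):
        a = np.array([[0.0, 0.0], [100.0, 50.0], [3.0, 7.0]])
        rms, off = estimate_registration_error(a, a + [5.0, -2.0])
        assert rms == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(off, [5.0, -2.0])

    def test_recovers_3nm_system_error(self):
        """230 paired immobile molecules with 3 nm residual scatter."""
        rng = np.random.default_rng(230)
        a = rng.uniform(0, 5000, size=(230, 2))
        scatter = rng.normal(0.0, 3.0 / math.sqrt(2), size=(230, 2))
        b = a + [12.0, -4.0] + scatter
        rms, _ = estimate_registration_error(a, b)
        assert rms == pytest.approx(3.0, rel=0.15)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            estimate_registration_error(np.zeros((1, 2)), np.zeros((1, 2)))


class TestToNEFrame:
    def test_point_on_curve_has_zero_axial(self):
        ne = _ne((1000.0, 0.02, 1e-5))
        npc = _npc((1000.0, 0.0))
        for y in (-500.0, 0.0, 800.0):
            x = ne.x_at(y)
            axial, _ = to_ne_frame((float(x), y), ne, npc)
            assert abs(axial) < 1e-6

    def test_straight_vertical_ne_sign_convention(self):
        """Cytoplasm left: +100 nm on the nucleoplasmic (right) side."""
        ne = _ne((1000.0, 0.0, 0.0))
        npc = _npc((1000.0, 500.0))
        axial, lateral = to_ne_frame((1100.0, 700.0), ne, npc)
        assert axial == pytest.approx(100.0)
        assert lateral == pytest.approx(200.0)

    def test_mirrored_side_flips_sign(self):
        ne_l = _ne((1000.0, 0.0, 0.0), side="left")
        ne_r = _ne((1000.0, 0.0, 0.0), side="right")
        npc = _npc((1000.0, 500.0))
        al, _ = to_ne_frame((1100.0, 700.0), ne_l, npc)
        ar, _ = to_ne_frame((1100.0, 700.0), ne_r, npc)
        assert al == -ar

    def test_matches_numeric_projection(self):
        """Exact cubic projection agrees with brute-force minimization."""
        ne = _ne((1500.0, 0.08, 3e-5))
        npc = _npc((1500.0, 0.0))
        rng = np.random.default_rng(17)
        for _ in range(25):
            p = (1500.0 + rng.uniform(-400, 400), rng.uniform(-2000, 2000))
            axial, _ = to_ne_frame(p, ne, npc)
            res = minimize_scalar(
                lambda y: (p[0] - ne.x_at(y)) ** 2 + (p[1] - y) ** 2,
                bounds=(-5000, 5000), method="bounded",
                options={"xatol": 1e-6})
            assert abs(abs(axial) - math.sqrt(res.fun)) < 0.5

    def test_outside_valid_range_raises(self):
        ne = _ne((1000.0, 0.0, 0.0), yr=(0.0, 1000.0))
        npc = _npc((1000.0, 500.0))
        with pytest.raises(ValueError, match="valid range"):
            to_ne_frame((1000.0, 2000.0), ne, npc)
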