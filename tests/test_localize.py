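"""Spot detection, Gaussian fitting and the precision formula."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from speedkin import (
    CameraModel,
    FrameStack,
    Localization,
    PrecisionParams,
    detect_spots,
    filter_by_precision,
    fit_gaussian_2d,
    localization_precision,
    render_gaussian_spot,
    apply_camera,
    locs_to_dataframe,
    write_locs_csv,
    read_locs_csv,
)


class TestPrecisionFormula:
    def test_background_free_small_pixel_limit(self):
        """With b=0, F=1 and a -> 0 the formula reduces to (4/3) s/sqrt(N)."""
        params = PrecisionParams(F=1.0, a_nm=1e-6, s0_nm=150.0)
        sigma = localization_precision(3000, 0.0, params)
        assert sigma == pytest.approx(4.0 / 3.0 * 150.0 / math.sqrt(3000), rel=1e-9)

    def test_static_equals_moving_with_zero_diffusion(self):
        params = PrecisionParams(F=2.0, a_nm=107.0, s0_nm=150.0, D_um2_s=0.0)
        assert localization_precision(3000, 2.0, params, moving=False) == \
            localization_precision(3000, 2.0, params, moving=True)

    def test_default_parameters_against_independent_arithmetic(self):
        """Closed form evaluated independently, term by term."""
        F, a, s0, b, N = 2.0, 107.0, 150.0, 2.0, 3000.0
        sa2 = s0 * s0 + a * a / 12.0
        expected = math.sqrt(F * (16.0 * sa2 / (9.0 * N)
                                  + 8.0 * math.pi * b ** 2 * sa2 ** 2 / (a * a * N * N)))
        got = localization_precision(N, b, PrecisionParams(F=F, a_nm=a, s0_nm=s0))
        assert got == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        N=st.floats(100, 1e5),
        b=st.floats(0.0, 20.0),
        s0=st.floats(100.0, 300.0),
        a=st.floats(50.0, 200.0),
    )
    def test_monotonic_in_photons_and_background(self, N, b, s0, a):
        """Precision improves with photons, degrades with background."""
        p = PrecisionParams(F=2.0, a_nm=a, s0_nm=s0)
        assert localization_precision(2 * N, b, p) < localization_precision(N, b, p)
        assert localization_precision(N, b + 1.0, p) > localization_precision(N, b, p)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(D=st.floats(0.0, 5.0))
    def test_motion_broadening_never_helps(self, D):
        p = PrecisionParams(F=2.0, a_nm=107.0, s0_nm=150.0, D_um2_s=D)
        moving = localization_precision(3000, 2.0, p, moving=True)
        static = localization_precision(3000, 2.0, p, moving=False)
        assert moving >= static
        if D > 1e-6:
            assert moving > static

    def test_rejects_nonpositive_photons(self):
        with pytest.raises(ValueError):
            localization_precision(0, 1.0, PrecisionParams())


class TestDetectSpots:
    def test_blank_frame_yields_nothing(self, camera):
        stack = FrameStack(np.zeros((3, 32, 32), dtype=np.uint16), camera)
        assert all(len(c) == 0 for c in detect_spots(stack))

    def test_single_clean_spot_found_once(self, camera):
        img = np.full((32, 32), 2.0)
        render_gaussian_spot((32, 32), 15 * 107.0, 17 * 107.0, 3000.0, 150.0,
                             107.0, out=img)
        rng = np.random.default_rng(0)
        counts = apply_camera(img, camera, rng)
        cands = detect_spots(FrameStack(counts[None], camera))
        assert len(cands[0]) == 1
        r, c = cands[0][0]
        assert abs(r - 17) <= 1 and abs(c - 15) <= 1

    def test_detection_rate_on_simulated_movie(self, camera, optics):
        """Nearly every frame with an emitting particle yields one candidate."""
        from speedkin import SimScene, simulate_transport_movie
        scene = SimScene(n_events=10, rng_seed=31)
        stack, truth = simulate_transport_movie(scene, camera, optics)
        cands = detect_spots(stack, expected_sigma_px=150.0 / 107.0)
        emitting = set(truth.per_frame.frame)
        hits = sum(1 for f in emitting if len(cands[f]) == 1)
        assert hits / len(emitting) >= 0.95


class TestFitGaussian2D:
    def test_noise_free_center_and_width_recovery(self, quiet_camera):
        """Sub-pixel centers recovered to <0.01 px, width to <1% (pixelation
        broadening removed) over a grid of true offsets."""
        px = 107.0
        sa = math.sqrt(150.0 ** 2 + px ** 2 / 12.0)
        for fx in (-0.4, -0.1, 0.2, 0.45):
            for fy in (-0.3, 0.35):
                x0, y0 = (10 + fx) * px, (10 + fy) * px
                img = render_gaussian_spot((21, 21), x0, y0, 1e5, 150.0, px)
                loc = fit_gaussian_2d(img, (10, 10), quiet_camera)
                assert loc.fit_ok
                assert abs(loc.x_nm - x0) < 0.01 * px
                assert abs(loc.y_nm - y0) < 0.01 * px
                assert loc.sigma_x_nm == pytest.approx(sa, rel=0.01)

    def test_elliptical_width_ratio_recovery(self, quiet_camera):
        px = 107.0
        img = render_gaussian_spot((25, 25), 12 * px, 12 * px, 2e5, 130.0, px,
                                   sigma_y_nm=260.0)
        loc = fit_gaussian_2d(img, (12, 12), quiet_camera, model="elliptical")
        pix2 = px * px / 12.0
        ratio = math.sqrt((loc.sigma_y_nm ** 2 - pix2) /
                          (loc.sigma_x_nm ** 2 - pix2))
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_photon_count_round_trip(self, camera):
        """photons -> counts (simulator) -> photons (fit) within shot noise."""
        rng = np.random.default_rng(7)
        px = camera.pixel_size_nm
        est = []
        for _ in range(100):
            img = np.full((21, 21), 2.0)
            render_gaussian_spot((21, 21), 10 * px, 10 * px, 3000.0, 150.0, px,
                                 out=img)
            counts = apply_camera(img, camera, rng)
            loc = fit_gaussian_2d(counts, (10, 10), camera)
            assert loc.fit_ok
            est.append(loc.photons)
        assert np.mean(est) == pytest.approx(3000.0, rel=0.05)

    def test_empirical_scatter_matches_formula(self, camera):
        """Monte-Carlo center scatter agrees with the closed form within 20%."""
        rng = np.random.default_rng(11)
        px = camera.pixel_size_nm
        errs = []
        for _ in range(300):
            x0 = (10 + rng.uniform(-0.5, 0.5)) * px
            y0 = (10 + rng.uniform(-0.5, 0.5)) * px
            img = np.full((21, 21), 2.0)
            render_gaussian_spot((21, 21), x0, y0, float(rng.poisson(3000)),
                                 150.0, px, out=img)
            loc = fit_gaussian_2d(apply_camera(img, camera, rng), (10, 10), camera)
            if loc.fit_ok:
                errs += [loc.x_nm - x0, loc.y_nm - y0]
        empirical = float(np.std(errs))
        predicted = localization_precision(
            3000, 2.0, PrecisionParams(F=2.0, a_nm=px, s0_nm=150.0))
        assert empirical == pytest.approx(predicted, rel=0.2)

    def test_edge_window_flagged_not_raised(self, camera):
        frame = np.full((20, 20), 100.0)
        loc = fit_gaussian_2d(frame, (1, 1), camera)
        assert not loc.fit_ok
        assert "edge" in loc.fail_reason


class TestFilterByPrecision:
    def _loc(self, prec, ok=True):
        return Localization(0, 0, 0, 1000, 1, 150, 150, prec, ok)

    def test_empty_in_empty_out(self):
        assert filter_by_precision([], 30.0) == []

    def test_all_above_cutoff_removed(self):
        locs = [self._loc(50.0) for _ in range(5)]
        assert filter_by_precision(locs, 30.0) == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        locs = [self._loc(float(p), ok=bool(o))
                for p, o in zip(rng.uniform(5, 60, 50), rng.integers(0, 2, 50))]
        got = filter_by_precision(locs, 30.0)
        expected = [l for l in locs if l.fit_ok and l.precision_nm < 30.0]
        assert got == expected


class TestTableIO:
    def test_csv_round_trip(self, tmp_path):
        locs = [Localization(i, i * 10.0, 5.0, 3000.0, 2.0, 150.0, 150.0,
                             7.0, True) for i in range(4)]
        path = tmp_path / "locs.csv"
        write_locs_csv(locs, path)
        df = read_locs_csv(path)
        assert list(df.columns) == list(locs_to_dataframe(locs).columns)
        assert len(df) == 4
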