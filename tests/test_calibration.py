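"""Primary-matrix fitting, radial chromaticity correction, inversion, ΔE."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hmdcal.calibration import (
    DisplayCalibrator,
    PrimaryMatrix,
    chromaticity_correction,
    cube_targets,
    fit_primary_matrix,
    invert_chromaticity_correction,
    luminance_correction,
    predict_xyY,
    rgb_for_target,
    validate,
)
from hmdcal.characterization import ClippedLinearResponse
from hmdcal.colorimetry import XYZ_to_Lab, XYZ_to_xyY, xyY_to_XYZ
from hmdcal.virtual_display import VirtualDisplay, run_protocol

D65_XY = np.array([0.3127, 0.3290])


class TestPrimaryMatrixFit:
    def test_three_primaries_interpolate_exactly(self):
        XYZ = np.array([[41.2, 21.3, 1.9], [35.8, 71.5, 11.9], [18.0, 7.2, 95.0]])
        M = fit_primary_matrix(np.eye(3), XYZ)
        assert np.allclose(M, XYZ.T)

    def test_recovers_random_matrix_from_noiseless_drives(self, rng):
        for _ in range(100):
            M0 = rng.uniform(0.5, 50, (3, 3))
            D = rng.uniform(0, 1, (8, 3))
            M = fit_primary_matrix(D, D @ M0.T)
            assert np.allclose(M, M0, atol=1e-10 * np.abs(M0).max())

    def test_agrees_with_normal_equations_oracle(self, rng):
        for _ in range(100):
            D = rng.uniform(0, 1, (12, 3))
            X = rng.uniform(0, 100, (12, 3))
            M = fit_primary_matrix(D, X)
            oracle = np.linalg.solve(D.T @ D, D.T @ X).T
            assert np.allclose(M, oracle, atol=1e-10 * np.abs(oracle).max())

    def test_noise_perturbation_is_order_sigma(self, rng):
        M0 = rng.uniform(1, 20, (3, 3))
        D = rng.uniform(0, 1, (20, 3))
        sigma = 0.01
        errs = [
            np.abs(fit_primary_matrix(D, D @ M0.T + rng.normal(0, sigma, (20, 3)))
                   - M0).max()
            for _ in range(500)
        ]
        # least-squares perturbation: error scales with σ, comfortably < 100σ
        assert np.mean(errs) < 100 * sigma

    def test_rank_deficient_rejected(self):
        D = np.array([[1, 0, 0], [2, 0, 0], [3, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="rank"):
            fit_primary_matrix(D, D * 2.0)

    def test_sklearn_wrapper_round_trips(self, rng):
        M0 = rng.uniform(1, 20, (3, 3))
        D = rng.uniform(0, 1, (10, 3))
        est = PrimaryMatrix().fit(D, D @ M0.T)
        assert np.allclose(est.inverse_transform(est.transform(D)), D, atol=1e-10)
        assert est.get_params() == {}


class TestChromaticityCorrection:
    def test_zero_strength_is_identity(self, rng):
        xy = rng.uniform(0.05, 0.6, (100, 2))
        assert np.allclose(chromaticity_correction(xy, D65_XY, 0.0), xy)

    def test_white_point_is_fixed(self):
        for B in (0.0, 0.01, 1.0, 50.0):
            assert np.allclose(chromaticity_correction(D65_XY, D65_XY, B), D65_XY)

    def test_hand_value_red_primary(self):
        out = chromaticity_correction([0.64, 0.33], D65_XY, 0.01)
        assert np.allclose(out, [0.63893, 0.33000], atol=5e-5)

    @given(
        x=st.floats(0.02, 0.7), y=st.floats(0.02, 0.7),
        B=st.floats(1e-6, 10.0),
    )
    def test_radial_contraction_preserving_direction(self, x, y, B):
        xy = np.array([x, y])
        out = chromaticity_correction(xy, D65_XY, B)
        r_in = np.linalg.norm(xy - D65_XY)
        r_out = np.linalg.norm(out - D65_XY)
        assert r_out <= r_in + 1e-15
        if B > 0 and r_in > 1e-12:
            assert r_out < r_in
            cos = (out - D65_XY) @ (xy - D65_XY) / (r_in * r_out)
            assert cos == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_inverse_round_trip(self, rng):
        xy = rng.uniform(0.02, 0.7, (10000, 2))
        for B in (0.01, 0.5, 2.0):
            fwd = chromaticity_correction(xy, D65_XY, B)
            back = invert_chromaticity_correction(fwd, D65_XY, B)
            assert np.max(np.abs(back - xy)) < 1e-12

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            chromaticity_correction([0.3, 0.3], D65_XY, -0.1)


class TestLuminanceCorrection:
    @pytest.fixture()
    def fit(self):
        f = ClippedLinearResponse()
        f.m_, f.t_, f.rss_, f.exposure_saturated_ = 50.0, 30.0, 0.0, False
        return f

    def test_linear_branch(self, fit):
        assert luminance_correction(0.4, fit) == pytest.approx(20.0)

    def test_clip_branch(self, fit):
        assert luminance_correction(0.9, fit) == pytest.approx(30.0)

    def test_continuous_at_breakpoint(self, fit):
        xb = fit.t_ / fit.m_
        below = luminance_correction(xb - 1e-12, fit)
        above = luminance_correction(xb + 1e-12, fit)
        assert below == pytest.approx(above, abs=1e-9)


class TestCubeTargets:
    def test_sixteen_distinct_corners(self):
        t = cube_targets()
        assert t.shape == (16, 3)
        assert len({tuple(row) for row in t}) == 16

    def test_contains_protocol_corners(self):
        rows = {tuple(r) for r in cube_targets()}
        for corner in [(0.2, 0.2, 0.2), (0.8, 0.8, 0.8),
                       (0.4, 0.4, 0.4), (0.6, 0.6, 0.6)]:
            assert corner in rows

    def test_gray_code_order_with_achromatic_last(self):
        t = cube_targets()
        for cube in (t[:8], t[8:]):
            # adjacent corners differ on exactly one axis
            assert np.all((np.abs(np.diff(cube, axis=0)) > 1e-12).sum(axis=1) == 1)
            assert len(set(cube[0])) == 1 and len(set(cube[-1])) == 1  # gray corners
            assert cube[-1].max() > cube[0].max()  # dark first, bright last


class TestPredictAndInvert:
    def test_black_drive_has_zero_luminance(self):
        M = np.diag([1.0, 2.0, 3.0]) + 0.1
        out = predict_xyY(M, [0.0, 0.0, 0.0])
        assert out[2] == 0.0

    def test_pure_red_hits_first_column_chromaticity(self):
        M = np.array([[30.0, 20.0, 5.0], [15.0, 40.0, 2.0], [1.0, 5.0, 25.0]])
        out = predict_xyY(M, [1.0, 0.0, 0.0])
        col = M[:, 0]
        assert np.allclose(out[:2], col[:2] / col.sum())
        assert out[2] == pytest.approx(col[1])

    def test_out_of_range_drive_rejected(self):
        with pytest.raises(ValueError):
            predict_xyY(np.eye(3), [1.2, 0.0, 0.0])

    def test_prediction_matches_simulator_for_linear_display(self, display_model):
        cfg = display_model.model_copy(
            update={"tonemap": "none", "autoexposure": "off",
                    "response": "linear", "chromatic_compression": 0.0})
        disp = VirtualDisplay(cfg)
        drives = np.array([[0.3, 0.1, 0.9], [1.0, 1.0, 1.0], [0.05, 0.5, 0.2]])
        for d in drives:
            m = disp.measure(d)
            pred = predict_xyY(disp.matrix, d)
            assert np.allclose(pred, [m.x, m.y, m.Y], atol=1e-12)


class TestDisplayCalibrator:
    def test_white_round_trips_to_unit_drive(self, sessions):
        cal = DisplayCalibrator(mode="tonemap_disabled").fit(
            sessions["tonemap_disabled"])
        drive, oog = cal.transform(cal.white_xyY_)
        assert np.allclose(drive, 1.0, atol=1e-9)
        assert not oog

    def test_primary_round_trips_to_basis_drive(self, sessions):
        s = sessions["tonemap_disabled"]
        cal = DisplayCalibrator(mode="tonemap_disabled").fit(s)
        p = s.primaries["G"]
        drive, oog = cal.transform([p.x, p.y, p.Y])
        # near-zero linear components blow up under the 1/γ root; 1e-6 in
        # drive units is far below one 8-bit step
        assert np.allclose(drive, [0.0, 1.0, 0.0], atol=1e-6)
        assert not oog

    def test_closed_loop_random_targets(self, display_model, rng):
        """Drive computed for a realisable color reproduces it, ΔE < 0.1."""
        session = run_protocol(display_model, "tonemap_disabled", seed=3)
        cal = DisplayCalibrator(mode="tonemap_disabled").fit(session)
        disp = VirtualDisplay(display_model.configured("tonemap_disabled"))
        drives_in = rng.uniform(0.05, 1.0, (100, 3))
        targets = np.array([[m.x, m.y, m.Y]
                            for m in (disp.measure(d) for d in drives_in)])
        drives, oog = cal.transform(targets)
        realised = np.array([[m.x, m.y, m.Y]
                             for m in (disp.measure(d) for d in drives)])
        rep = validate(realised, targets, cal.white_XYZ_)
        assert not oog.any()
        assert rep.mean_delta_e < 0.1

    def test_out_of_gamut_flagged_not_silent(self, sessions):
        cal = DisplayCalibrator(mode="tonemap_disabled").fit(
            sessions["tonemap_disabled"])
        # a saturated cyan outside any three-primary display gamut
        drive, oog = cal.transform([0.08, 0.45, 5.0])
        assert oog
        assert np.all((drive >= 0) & (drive <= 1))

    def test_degenerate_target_rejected(self, sessions):
        cal = DisplayCalibrator(mode="tonemap_disabled").fit(
            sessions["tonemap_disabled"])
        with pytest.raises(ValueError):
            cal.transform([0.3, 0.0, 10.0])

    def test_serialization_preserves_predictions(self, sessions):
        cal = DisplayCalibrator(mode="selective").fit(sessions["selective"])
        clone = DisplayCalibrator.from_dict(cal.to_dict())
        drives = cube_targets()
        assert np.allclose(clone.predict(drives), cal.predict(drives), atol=1e-12)

    def test_functional_wrapper_matches_method(self, sessions):
        cal = DisplayCalibrator(mode="tonemap_disabled").fit(
            sessions["tonemap_disabled"])
        target = [0.35, 0.4, 10.0]
        assert np.allclose(rgb_for_target(cal, target)[0],
                           cal.transform(target)[0])

    def test_lab_targets_accepted(self, sessions):
        s = sessions["tonemap_disabled"]
        cal = DisplayCalibrator(mode="tonemap_disabled").fit(s)
        lab = XYZ_to_Lab(xyY_to_XYZ([0.33, 0.36, 12.0]), cal.white_XYZ_)
        d1, _ = cal.transform(lab, space="lab")
        d2, _ = cal.transform([0.33, 0.36, 12.0], space="xyY")
        assert np.allclose(d1, d2, atol=1e-9)


class TestValidationReport:
    def white(self):
        return xyY_to_XYZ([0.3127, 0.3290, 100.0])

    def test_identical_pairs_are_all_imperceptible(self):
        xyY = np.array([[0.3, 0.35, 20.0], [0.5, 0.4, 10.0]])
        rep = validate(xyY, xyY, self.white())
        assert np.allclose(rep.delta_e, 0.0)
        assert rep.band_counts["<1"] == 2
        assert rep.mean_delta_e == 0.0

    def test_lab_offset_3_4_lands_in_glance_band(self):
        from hmdcal.colorimetry import Lab_to_XYZ

        w = self.white()
        lab = np.array([[55.0, 5.0, 5.0]])
        lab_off = lab + np.array([0.0, 3.0, 4.0])
        pred = XYZ_to_xyY(Lab_to_XYZ(lab, w))
        meas = XYZ_to_xyY(Lab_to_XYZ(lab_off, w))
        rep = validate(pred, meas, w)
        assert rep.delta_e[0] == pytest.approx(5.0, abs=1e-9)
        assert rep.band_counts["2-10"] == 1

    def test_band_counts_partition(self, rng):
        xyY = np.column_stack([rng.uniform(0.25, 0.4, 50),
                               rng.uniform(0.25, 0.4, 50),
                               rng.uniform(1, 50, 50)])
        noisy = xyY * rng.uniform(0.9, 1.1, xyY.shape)
        rep = validate(xyY, np.clip(noisy, 1e-3, None), self.white())
        assert sum(rep.band_counts.values()) == rep.n_colors

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            validate(np.empty((0, 3)), np.empty((0, 3)), self.white())
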