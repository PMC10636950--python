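"""SUV quantification and two-tissue compartment modeling."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mpq.core import (
    DynamicPetSeries,
    ImageVolume,
    MpqError,
    PatientPhysiology,
    TimeActivityCurve,
    TwoTissueParams,
)
from mpq.pet import (
    extract_tac,
    fit_two_tissue,
    locate_lesion_center,
    metabolic_rate_fdg,
    summed_suv_image,
    suvmax_in_voi,
    two_tissue_frame_activity,
)
from mpq.synth import (
    InputFunctionSpec,
    default_frame_schedule,
    make_pet_phantom,
    PhantomSpec,
    simulate_input_function,
    simulate_tumor_tac,
)

from conftest import volume


def uniform_series(values, durations=None, start=30.0, shape=(2, 2, 2)):
    durations = durations or [15.0] * len(values)
    edges = start + np.concatenate(([0.0], np.cumsum(durations)))
    frames = [volume(np.full(shape, float(v))) for v in values]
    return DynamicPetSeries(frames, edges[:-1], edges[1:])


def ode_oracle(params, cp_times, cp_values, frame_start, frame_end):
    """Independent oracle: integrate the compartment ODEs directly.

    dC1/dt = K1*Cp - (k2+k3)*C1 ; dC2/dt = k3*C1 ; measured = C1 + C2.
    Frame averages by fine trapezoidal quadrature of the dense solution.
    """
    cp = lambda t: np.interp(t, cp_times, cp_values)  # noqa: E731

    def rhs(t, y):
        c1, c2 = y
        return [params.k1 * cp(t) - (params.k2 + params.k3) * c1, params.k3 * c1]

    t_end = float(np.max(frame_end))
    sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0], rtol=1e-10, atol=1e-12,
                    dense_output=True, max_step=0.05)
    out = []
    for lo, hi in zip(frame_start, frame_end):
        tt = np.linspace(lo, hi, 201)
        ct = sol.sol(tt).sum(axis=0)
        out.append(np.trapezoid(ct, tt) / (hi - lo))
    return np.array(out)


class TestSummedSuv:
    def test_definition_identity(self):
        # activity equal to dose/weight in kBq/mL gives SUV == 1
        dose, weight = 185.0, 70.0
        c = dose * 1000.0 / (weight * 1000.0)  # kBq per mL (= per g)
        series = uniform_series([c, c], durations=[15.0, 15.0])
        suv = summed_suv_image(series, PatientPhysiology(dose, weight))
        np.testing.assert_allclose(suv.voxels, 1.0)

    def test_linear_in_body_weight(self):
        series = uniform_series([5.0, 5.0])
        s1 = summed_suv_image(series, PatientPhysiology(200.0, 60.0))
        s2 = summed_suv_image(series, PatientPhysiology(200.0, 120.0))
        np.testing.assert_allclose(s2.voxels, 2.0 * s1.voxels)

    def test_duration_weighted_mean(self):
        # frames 30-45 and 45-60 with activities 10 and 20 -> mean 15
        series = uniform_series([10.0, 20.0], durations=[15.0, 15.0])
        phys = PatientPhysiology(1.0, 1.0)  # weight/dose factor = 1
        np.testing.assert_allclose(summed_suv_image(series, phys).voxels, 15.0)

    def test_rebinning_invariance(self):
        phys = PatientPhysiology(300.0, 75.0)
        coarse = uniform_series([10.0, 20.0], durations=[15.0, 15.0])
        fine = uniform_series([10.0, 10.0, 20.0, 20.0], durations=[7.5] * 4)
        np.testing.assert_allclose(
            summed_suv_image(coarse, phys).voxels,
            summed_suv_image(fine, phys).voxels,
        )

    def test_window_outside_acquisition_raises(self):
        series = uniform_series([1.0], durations=[10.0], start=0.0)
        with pytest.raises(MpqError, match="window"):
            summed_suv_image(series, PatientPhysiology(100.0, 70.0), window=(30, 60))


class TestSuvMaxVoi:
    def test_uniform_image(self):
        img = volume(np.full((9, 15, 15), 3.3))
        assert suvmax_in_voi(img, (4, 7, 7)) == pytest.approx(3.3)

    def test_hot_voxel_inside_voi(self):
        vox = np.ones((9, 15, 15))
        vox[4, 9, 7] = 9.0  # 2 mm from center, inside r=6.2 mm sphere
        assert suvmax_in_voi(volume(vox), (4, 7, 7)) == pytest.approx(9.0)

    def test_hot_voxel_outside_voi_excluded(self):
        vox = np.ones((9, 17, 17))
        vox[4, 15, 8] = 9.0  # 7 mm from center, outside 1 cc sphere (r=6.2 mm)
        assert suvmax_in_voi(volume(vox), (4, 8, 8)) == pytest.approx(1.0)

    def test_center_outside_image_raises(self):
        with pytest.raises(MpqError, match="outside"):
            suvmax_in_voi(volume(np.ones((4, 4, 4))), (10, 0, 0))

    def test_lesion_center_locates_hot_sphere(self):
        spec = PhantomSpec(noise_sd_rel=0.05, seed=9)
        series, _, _ = make_pet_phantom(spec)
        suv = summed_suv_image(series, PatientPhysiology(300, 70), window=(30, 60))
        center = locate_lesion_center(suv)
        assert np.allclose(center, spec.center, atol=1.5)


class TestExtractTac:
    def test_uniform_frames_constant_tac(self):
        series = uniform_series([2.0, 2.0, 2.0])
        voi = np.ones((2, 2, 2), bool)
        tac = extract_tac(series, voi)
        np.testing.assert_allclose(tac.activity, 2.0)

    def test_round_trips_simulated_phantom(self, frame_schedule):
        spec = PhantomSpec()  # noiseless
        series, cp, mask = make_pet_phantom(spec)
        tac = extract_tac(series, mask)
        expected = simulate_tumor_tac(spec.tumor.pet, cp, *frame_schedule)
        np.testing.assert_allclose(tac.activity, expected.activity, rtol=1e-12)

    def test_single_voxel_voi(self):
        series = uniform_series([1.0, 4.0])
        series.frames[1].voxels[0, 0, 0] = 7.0
        voi = np.zeros((2, 2, 2), bool)
        voi[0, 0, 0] = True
        np.testing.assert_allclose(extract_tac(series, voi).activity, [1.0, 7.0])

    def test_empty_voi_raises(self):
        with pytest.raises(MpqError, match="empty VOI"):
            extract_tac(uniform_series([1.0]), np.zeros((2, 2, 2), bool))


class TestForwardModel:
    def test_zero_k1_gives_zero_curve(self, blood_curve, frame_schedule):
        tac = simulate_tumor_tac(TwoTissueParams(0.0, 0.2, 0.05), blood_curve, *frame_schedule)
        np.testing.assert_allclose(tac.activity, 0.0)

    def test_no_trapping_equilibrates_to_k1_over_k2(self, frame_schedule):
        # constant Cp: with k3=0 the free pool approaches K1/k2 * Cp
        t = np.arange(0.0, 60.5, 0.25)
        cp = TimeActivityCurve(t, np.full_like(t, 10.0), "blood")
        params = TwoTissueParams(0.1, 0.5, 0.0)
        tac = simulate_tumor_tac(params, cp, *frame_schedule)
        assert params.ki == 0.0
        assert tac.activity[-1] == pytest.approx(10.0 * 0.1 / 0.5, rel=1e-3)

    def test_matches_ode_oracle_boxcar(self):
        """K1=0.1, k2=0.2, k3=0.05 with boxcar Cp vs independent fine-grid oracle."""
        t = np.arange(0.0, 20.01, 0.01)
        cp_vals = np.where(t <= 1.0, 50.0, 0.0)
        cp = TimeActivityCurve(t, cp_vals, "blood")
        fs, fe = np.arange(0.0, 19.0, 1.0), np.arange(1.0, 20.0, 1.0)
        params = TwoTissueParams(0.1, 0.2, 0.05)
        sim = simulate_tumor_tac(params, cp, fs, fe, dt=0.01)
        oracle = ode_oracle(params, t, cp_vals, fs, fe)
        np.testing.assert_allclose(sim.activity, oracle, rtol=5e-3)

    def test_matches_ode_oracle_feng_input(self, frame_schedule):
        t = np.arange(0.0, 60.01, 0.01)
        cp = simulate_input_function(InputFunctionSpec(), t)
        params = TwoTissueParams(0.15, 0.4, 0.08)
        sim = simulate_tumor_tac(params, cp, *frame_schedule)
        oracle = ode_oracle(params, t, cp.activity, *frame_schedule)
        err = np.abs(sim.activity - oracle) / oracle.max()
        assert err.max() < 5e-3

    def test_k3_infinity_limit_is_flow_limited_trapping(self, blood_curve):
        # k3 >> k2: C_T -> K1 * integral of Cp
        fs, fe = default_frame_schedule()
        params = TwoTissueParams(0.1, 0.2, 500.0)
        sim = simulate_tumor_tac(params, blood_curve, fs, fe, dt=0.01)
        dt = 0.01
        t = np.arange(0.0, fe[-1] + dt, dt)
        cp_grid = np.interp(t, blood_curve.midtimes, blood_curve.activity)
        integral = np.cumsum(cp_grid) * dt
        expected_last = 0.1 * np.interp(fe[-1] - 2.5, t, integral)  # mid of last frame
        assert sim.activity[-1] == pytest.approx(expected_last, rel=0.02)

    def test_identical_inputs_identical_outputs(self, blood_curve, frame_schedule):
        p = TwoTissueParams(0.2, 0.3, 0.02)
        a = simulate_tumor_tac(p, blood_curve, *frame_schedule).activity
        b = simulate_tumor_tac(p, blood_curve, *frame_schedule).activity
        np.testing.assert_array_equal(a, b)


class TestFit:
    def test_noiseless_recovery(self, blood_curve, frame_schedule):
        truth = TwoTissueParams(0.1, 0.2, 0.05)
        tac = simulate_tumor_tac(truth, blood_curve, *frame_schedule)
        fit = fit_two_tissue(tac, blood_curve, *frame_schedule)
        assert fit.success
        assert fit.params.k1 == pytest.approx(0.1, rel=1e-4)
        assert fit.params.k2 == pytest.approx(0.2, rel=1e-4)
        assert fit.params.k3 == pytest.approx(0.05, rel=1e-4)
        assert fit.ki == pytest.approx(0.02, rel=1e-4)

    def test_zero_tac_flagged_degenerate(self, blood_curve, frame_schedule):
        fs, fe = frame_schedule
        tac = TimeActivityCurve(0.5 * (fs + fe), np.zeros_like(fs))
        fit = fit_two_tissue(tac, blood_curve, fs, fe)
        assert fit.degenerate and fit.params.k1 == 0.0

    def test_strongly_negative_activity_rejected(self, blood_curve, frame_schedule):
        fs, fe = frame_schedule
        act = np.full_like(fs, 10.0)
        act[5] = -8.0
        with pytest.raises(MpqError, match="negative"):
            fit_two_tissue(TimeActivityCurve(0.5 * (fs + fe), act), blood_curve, fs, fe)

    def test_ki_monotone_in_k3_noiseless(self, blood_curve, frame_schedule):
        fitted = []
        for k3 in (0.02, 0.05, 0.10):
            tac = simulate_tumor_tac(TwoTissueParams(0.1, 0.3, k3), blood_curve, *frame_schedule)
            fitted.append(fit_two_tissue(tac, blood_curve, *frame_schedule).ki)
        assert fitted[0] < fitted[1] < fitted[2]

    def test_noisy_recovery_of_macro_parameters(self, blood_curve, frame_schedule):
        """5% noise, 50 replicates: median relative error of Ki and K1 < 5%;
        k2 and k3 individually are less stable and only sanity-bounded."""
        truth = TwoTissueParams(0.1, 0.2, 0.05)
        fs, fe = frame_schedule
        clean = simulate_tumor_tac(truth, blood_curve, fs, fe).activity
        rng = np.random.default_rng(23)
        err_ki, err_k1, err_k3 = [], [], []
        for _ in range(50):
            noisy = clean * (1.0 + 0.05 * rng.standard_normal(clean.size))
            fit = fit_two_tissue(
                TimeActivityCurve(0.5 * (fs + fe), noisy), blood_curve, fs, fe
            )
            err_ki.append(abs(fit.ki - truth.ki) / truth.ki)
            err_k1.append(abs(fit.params.k1 - truth.k1) / truth.k1)
            err_k3.append(abs(fit.params.k3 - truth.k3) / truth.k3)
        assert np.median(err_ki) < 0.05
        assert np.median(err_k1) < 0.05
        assert np.median(err_k3) < 0.5  # micro-parameter, much looser


class TestMrfdg:
    def test_direct_multiplication(self):
        p = TwoTissueParams(0.1, 0.2, 0.05)  # ki = 0.02
        phys = PatientPhysiology(300, 70, plasma_glucose=5.0)
        assert metabolic_rate_fdg(p, phys) == pytest.approx(0.10)

    def test_zero_ki_gives_zero(self):
        phys = PatientPhysiology(300, 70, plasma_glucose=5.0)
        assert metabolic_rate_fdg(TwoTissueParams(0.1, 0.2, 0.0), phys) == 0.0

    def test_missing_glucose_raises(self):
        with pytest.raises(MpqError, match="glucose"):
            metabolic_rate_fdg(TwoTissueParams(0.1, 0.2, 0.05), PatientPhysiology(300, 70))

    def test_unit_mismatch_raises(self):
        phys = PatientPhysiology(300, 70, plasma_glucose=90.0, glucose_unit="mg/dL")
        with pytest.raises(MpqError, match="unit mismatch"):
            metabolic_rate_fdg(
                TwoTissueParams(0.1, 0.2, 0.05), phys, expected_glucose_unit="mmol/L"
            )
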