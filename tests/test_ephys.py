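import numpy as np
import pytest

from orthoexpress.ephys import (
    F1_HZ, F2_HZ, MotilityParams, NLCParams, PatchCircuit, Recording,
    SAMPLE_RATE_HZ, alpha_from_slope_factor, boltzmann_length, boltzmann_slope,
    correct_series_resistance, detect_voltage_dependence, fit_motility,
    fit_nlc, nlc_curve, simulate_two_sine_current, slope_factor_from_alpha,
    two_sine_capacitance, two_sine_voltage,
)

OHC_TRUTH = NLCParams(qmax=1135.0, alpha=alpha_from_slope_factor(27.0),
                      vhalf=-54.0, clin=7.9)
STAIRCASE = np.arange(-120.0, 60.0 + 1e-9, 4.0)


class TestBoltzmannCurves:
    def test_half_maximum_at_vhalf(self):
        p = MotilityParams(lmax=1.0, alpha=0.03, vhalf=-50.0)
        assert boltzmann_length(-50.0, p) == pytest.approx(0.5)

    def test_limits(self):
        p = MotilityParams(lmax=1.0, alpha=0.03, vhalf=-50.0)
        assert boltzmann_length(-1e4, p) == pytest.approx(0.0, abs=1e-12)
        assert boltzmann_length(1e4, p) == pytest.approx(1.0)

    def test_three_quarters_point_solves_logistic(self):
        # L = 0.75 Lmax at V = Vhalf + ln(3)/alpha
        p = MotilityParams(lmax=1.0, alpha=0.03, vhalf=-50.0)
        v = -50.0 + np.log(3.0) / 0.03
        assert boltzmann_length(v, p) == pytest.approx(0.75)

    def test_strictly_increasing(self):
        p = MotilityParams(lmax=1.0, alpha=0.03, vhalf=-50.0)
        v = np.linspace(-150, 100, 100)
        assert (np.diff(boltzmann_length(v, p)) > 0).all()

    def test_slope_is_derivative(self):
        p = MotilityParams(lmax=0.4, alpha=0.04, vhalf=-40.0)
        v = np.linspace(-100, 20, 50)
        num = np.gradient(boltzmann_length(v, p), v)
        # endpoints use one-sided differences; compare the interior
        assert boltzmann_slope(v, p)[1:-1] == pytest.approx(num[1:-1], rel=1e-2)

    def test_slope_factor_conversions_invert(self):
        assert slope_factor_from_alpha(alpha_from_slope_factor(27.0)) == 27.0
        with pytest.raises(ValueError):
            alpha_from_slope_factor(-1.0)


class TestNLCCurve:
    def test_analytic_peak(self):
        assert nlc_curve(OHC_TRUTH.vhalf, OHC_TRUTH) == pytest.approx(
            OHC_TRUTH.qmax * OHC_TRUTH.alpha / 4.0 + OHC_TRUTH.clin)

    def test_tails_decay_to_clin(self):
        far = OHC_TRUTH.vhalf + 200.0 / OHC_TRUTH.alpha
        assert abs(nlc_curve(far, OHC_TRUTH) - OHC_TRUTH.clin) < 1e-3 * OHC_TRUTH.qmax * OHC_TRUTH.alpha
        assert abs(nlc_curve(2 * OHC_TRUTH.vhalf - far, OHC_TRUTH) - OHC_TRUTH.clin) \
            < 1e-3 * OHC_TRUTH.qmax * OHC_TRUTH.alpha

    def test_symmetric_about_vhalf(self):
        dv = np.linspace(0, 150, 40)
        left = nlc_curve(OHC_TRUTH.vhalf - dv, OHC_TRUTH)
        right = nlc_curve(OHC_TRUTH.vhalf + dv, OHC_TRUTH)
        assert left == pytest.approx(right)

    def test_bell_integrates_to_qmax(self):
        # quadrature oracle over vhalf +/- 300/alpha
        v = np.linspace(OHC_TRUTH.vhalf - 300 / OHC_TRUTH.alpha,
                        OHC_TRUTH.vhalf + 300 / OHC_TRUTH.alpha, 200001)
        integral = np.trapezoid(nlc_curve(v, OHC_TRUTH) - OHC_TRUTH.clin, v)
        assert integral == pytest.approx(OHC_TRUTH.qmax, rel=1e-3)


class TestFitNLC:
    def test_noiseless_recovery_of_printed_parameter_set(self):
        rec = Recording(voltage=STAIRCASE, capacitance=nlc_curve(STAIRCASE, OHC_TRUTH))
        fit = fit_nlc(rec)
        assert fit.converged and not fit.flat
        assert fit.params.vhalf == pytest.approx(-54.0, rel=1e-6)
        assert fit.params.clin == pytest.approx(7.9, rel=1e-6)
        assert fit.params.qmax == pytest.approx(1135.0, rel=1e-6)
        assert fit.params.alpha == pytest.approx(1 / 27.0, rel=1e-6)

    def test_constant_trace_flagged_flat(self):
        rec = Recording(voltage=STAIRCASE, capacitance=np.full(len(STAIRCASE), 7.0))
        fit = fit_nlc(rec)
        assert fit.flat
        assert fit.params.peak_nlc == pytest.approx(0.0, abs=1e-6)

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(11)
        noisy = nlc_curve(STAIRCASE, OHC_TRUTH) + rng.normal(0, 0.05, len(STAIRCASE))
        fit = fit_nlc(Recording(voltage=STAIRCASE, capacitance=noisy))
        truth = {"qmax": OHC_TRUTH.qmax, "alpha": OHC_TRUTH.alpha, "vhalf": OHC_TRUTH.vhalf,
                 "clin": OHC_TRUTH.clin}
        got = vars(fit.params)
        for name, true_val in truth.items():
            assert abs(got[name] - true_val) <= 3.0 * fit.stderr[name], name

    def test_round_trip_identity_on_random_physiological_draws(self):
        # fit(nlc_curve(params)) == params on noiseless data
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = NLCParams(
                qmax=rng.uniform(100, 2000),
                alpha=1.0 / rng.uniform(20, 40),
                vhalf=rng.uniform(-100, 0),
                clin=rng.uniform(3, 12),
            )
            rec = Recording(voltage=STAIRCASE, capacitance=nlc_curve(STAIRCASE, p))
            fit = fit_nlc(rec)
            assert fit.params.qmax == pytest.approx(p.qmax, rel=1e-6)
            assert fit.params.alpha == pytest.approx(p.alpha, rel=1e-6)
            assert fit.params.vhalf == pytest.approx(p.vhalf, rel=1e-6)
            assert fit.params.clin == pytest.approx(p.clin, rel=1e-6)

    def test_too_few_points_rejected(self):
        v = np.linspace(-120, 60, 5)
        with pytest.raises(ValueError):
            fit_nlc(Recording(voltage=v, capacitance=np.ones(5)))

    def test_narrow_span_rejected(self):
        v = np.linspace(-10, 10, 20)
        with pytest.raises(ValueError):
            fit_nlc(Recording(voltage=v, capacitance=np.ones(20)))


class TestFitMotility:
    def test_noiseless_logistic_recovered_exactly(self):
        p = MotilityParams(lmax=0.35, alpha=1 / 27.0, vhalf=-54.0)
        rec = Recording(voltage=STAIRCASE, displacement=boltzmann_length(STAIRCASE, p))
        fit = fit_motility(rec)
        assert fit.params.lmax == pytest.approx(0.35, rel=1e-6)
        assert fit.params.vhalf == pytest.approx(-54.0, rel=1e-6)
        assert not fit.flat

    def test_flat_displacement_flagged_non_motile(self):
        rec = Recording(voltage=STAIRCASE, displacement=np.zeros(len(STAIRCASE)))
        assert fit_motility(rec).flat

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(11)
        p = MotilityParams(lmax=0.35, alpha=1 / 27.0, vhalf=-54.0)
        d = boltzmann_length(STAIRCASE, p) + rng.normal(0, 0.01, len(STAIRCASE))
        fit = fit_motility(Recording(voltage=STAIRCASE, displacement=d))
        for name, true_val in (("lmax", 0.35), ("alpha", 1 / 27.0), ("vhalf", -54.0)):
            assert abs(vars(fit.params)[name] - true_val) <= 3.0 * fit.stderr[name]


class TestTwoSine:
    N = 2560  # 10 periods of f1, 5 of f2, at 100 kHz

    def test_noiseless_circuit_recovered(self):
        circ = PatchCircuit(rs_mohm=10.0, rm_mohm=500.0, cm_pf=10.0)
        v, i = simulate_two_sine_current(circ, self.N)
        res = two_sine_capacitance(i, v)
        assert res.ok
        assert res.cm_pf == pytest.approx(10.0, rel=1e-3)
        assert res.rs_mohm == pytest.approx(10.0, rel=1e-3)
        assert res.rm_mohm == pytest.approx(500.0, rel=1e-3)

    def test_pure_rc_matches_single_frequency_closed_form(self):
        circ = PatchCircuit(rs_mohm=0.0, rm_mohm=300.0, cm_pf=8.0)
        v, i = simulate_two_sine_current(circ, self.N)
        res = two_sine_capacitance(i, v)
        # with Rs = 0 the admittance at one frequency already gives
        # Cm = Im(Y)/omega
        y1 = complex(circ.admittance(F1_HZ))
        cm_closed = y1.imag / (2 * np.pi * F1_HZ) * 1e12
        assert res.ok
        assert res.cm_pf == pytest.approx(cm_closed, rel=1e-6)
        assert res.rs_mohm == pytest.approx(0.0, abs=1e-3)

    def test_small_parameter_grid_exact(self):
        for rs in (5.0, 12.0):
            for rm in (100.0, 800.0):
                for cm in (4.0, 15.0):
                    circ = PatchCircuit(rs, rm, cm)
                    v, i = simulate_two_sine_current(circ, self.N)
                    res = two_sine_capacitance(i, v)
                    assert res.ok
                    assert res.cm_pf == pytest.approx(cm, rel=1e-6)

    def test_misaligned_frequencies_rejected_with_guidance(self):
        v = np.zeros(1000)
        with pytest.raises(ValueError, match="record length"):
            two_sine_capacitance(v, v, fs_hz=SAMPLE_RATE_HZ)

    def test_identical_admittances_flagged_ill_conditioned(self):
        # a pure resistor gives the same admittance at both frequencies
        t = np.arange(self.N) / SAMPLE_RATE_HZ
        v = 10 * np.sin(2 * np.pi * F1_HZ * t) + 10 * np.sin(2 * np.pi * F2_HZ * t)
        i = v / 100.0
        res = two_sine_capacitance(i, v, min_separation=1e-3)
        assert not res.ok

    def test_staircase_nlc_reconstruction_within_one_percent(self):
        # per-step dual-sine traces generated from the NLC truth; the
        # estimator must reproduce Cm(V) at each 4 mV step
        v_steps = np.arange(-120.0, 60.0 + 1e-9, 4.0)
        for v_step in v_steps[::6]:
            cm_true = float(nlc_curve(v_step, OHC_TRUTH))
            circ = PatchCircuit(rs_mohm=10.0, rm_mohm=500.0, cm_pf=cm_true)
            v, i = simulate_two_sine_current(circ, self.N, v_dc_mv=float(v_step))
            res = two_sine_capacitance(i, v)
            assert res.ok
            assert res.cm_pf == pytest.approx(cm_true, rel=0.01)

    def test_series_resistance_correction(self):
        v = np.array([10.0, 20.0])
        i = np.array([0.5, 1.0])
        assert correct_series_resistance(v, i, 10.0) == pytest.approx([5.0, 10.0])

    def test_stimulus_requires_bin_alignment(self):
        with pytest.raises(ValueError):
            two_sine_voltage(1000)


class TestDetectVoltageDependence:
    def test_ohc_like_sweep_detected(self):
        rng = np.random.default_rng(3)
        cap = nlc_curve(STAIRCASE, OHC_TRUTH) + rng.normal(0, 0.1, len(STAIRCASE))
        res = detect_voltage_dependence(Recording(voltage=STAIRCASE, capacitance=cap))
        assert res.voltage_dependent
        assert res.p < 0.05

    def test_flat_sweep_not_detected(self):
        rng = np.random.default_rng(3)
        cap = 7.0 + rng.normal(0, 0.1, len(STAIRCASE))
        res = detect_voltage_dependence(Recording(voltage=STAIRCASE, capacitance=cap))
        assert not res.voltage_dependent

    def test_noiseless_flat_sweep_not_detected(self):
        cap = np.full(len(STAIRCASE), 7.0)
        res = detect_voltage_dependence(Recording(voltage=STAIRCASE, capacitance=cap))
        assert not res.voltage_dependent

    def test_detection_rate_monotone_in_gating_charge(self):
        rng = np.random.default_rng(8)
        rates = []
        for qmax in (20.0, 120.0, 1135.0):
            p = NLCParams(qmax=qmax, alpha=OHC_TRUTH.alpha, vhalf=-54.0, clin=7.9)
            hits = 0
            for _ in range(25):
                cap = nlc_curve(STAIRCASE, p) + rng.normal(0, 0.1, len(STAIRCASE))
                rec = Recording(voltage=STAIRCASE, capacitance=cap)
                hits += detect_voltage_dependence(rec).voltage_dependent
            rates.append(hits / 25)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 1.0
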