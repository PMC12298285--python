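"""Virtual-instrument properties: kinetics, optics, noise, ground truth."""

import numpy as np
import pytest

from atassay import (
    DarkCurrentModel,
    InstrumentNoise,
    InterferentProfile,
    KineticsParams,
    OpticalConfig,
    PLASMA_LINE,
    compute_rate,
    concentration_to_absorbance,
    simulate_calibration_set,
    simulate_reaction,
    simulate_run,
    simulate_trace,
    simulate_whole_blood,
    subtract_dark,
)
from atassay.errors import DomainError, RankDeficiencyError
from atassay import fit_calibration

NOISELESS = InstrumentNoise.noiseless()


def measured_rate(run):
    """Process a simulated trace exactly as the pipeline would."""
    trace = run.trace
    if not trace.dark_subtracted:
        trace = subtract_dark(
            trace,
            DarkCurrentModel(run.noise.dark_mean_counts, max(run.noise.dark_sd_counts, 1.0), 30),
        )
    return compute_rate(trace).rate_per_min


class TestReactionKinetics:
    def test_full_inhibition_no_product(self):
        params = KineticsParams(fxa0_uM=0.01, inhibition_capacity_uM=0.02,
                                at_activity_fraction=1.0)
        _, pna = simulate_reaction(params, 60.0, 1.0)
        assert np.all(pna == 0.0)

    def test_zero_order_limit(self):
        """With substrate far above Km, product grows linearly at kcat*E."""
        params = KineticsParams(
            fxa0_uM=0.01, inhibition_capacity_uM=0.0, substrate0_uM=5000.0,
            km_uM=1.0, kcat_per_s=10.0,
        )
        t, pna = simulate_reaction(params, 60.0, 1.0)
        expected = params.kcat_per_s * params.fxa0_uM * t
        mask = t > 0
        assert np.all(np.abs(pna[mask] / expected[mask] - 1.0) < 0.01)

    def test_doubling_enzyme_doubles_product(self):
        base = dict(inhibition_capacity_uM=0.0, substrate0_uM=5000.0, km_uM=1.0)
        _, p1 = simulate_reaction(KineticsParams(fxa0_uM=0.01, **base), 60.0, 1.0)
        _, p2 = simulate_reaction(KineticsParams(fxa0_uM=0.02, **base), 60.0, 1.0)
        assert p2[-1] == pytest.approx(2 * p1[-1], rel=1e-3)

    def test_substrate_conservation(self):
        """Product can never exceed the initial substrate pool."""
        params = KineticsParams(
            fxa0_uM=5.0, inhibition_capacity_uM=0.0, substrate0_uM=20.0,
            kcat_per_s=100.0, km_uM=10.0,
        )
        t, pna = simulate_reaction(params, 600.0, 1.0)
        assert np.all(pna <= params.substrate0_uM + 1e-12)
        assert np.all(np.diff(pna) >= -1e-12)
        assert pna[-1] == pytest.approx(params.substrate0_uM, rel=1e-3)

    def test_second_order_mode_slower_than_instantaneous(self):
        """Finite-rate inhibition leaves more active enzyme early on, so
        early product formation exceeds the instantaneous-inhibition case."""
        kw = dict(fxa0_uM=0.02, inhibition_capacity_uM=0.01, at_activity_fraction=1.0)
        _, p_inst = simulate_reaction(KineticsParams(**kw), 60.0, 1.0)
        _, p_slow = simulate_reaction(
            KineticsParams(inhibition_mode="second_order", k_inhib_per_uM_per_s=1.0, **kw),
            60.0, 1.0,
        )
        assert p_slow[10] > p_inst[10]

    def test_negative_parameters_rejected(self):
        with pytest.raises(DomainError):
            KineticsParams(fxa0_uM=-1.0, inhibition_capacity_uM=0.0)


class TestConcentrationToAbsorbance:
    def test_zero_everything(self, optics):
        a = concentration_to_absorbance([0.0, 60.0], [0.0, 0.0], optics)
        assert np.all(a == 0.0)

    def test_static_interferent_constant(self, optics):
        interf = InterferentProfile(static_absorbance_AU=0.3)
        a = concentration_to_absorbance([0, 30, 60], [0, 0, 0], optics, interf)
        assert np.all(a == 0.3)

    def test_epsilon_arithmetic(self, optics):
        # 0.99 /(mM mm) * 10 uM * 0.6 mm double pass
        a = concentration_to_absorbance([0.0], [10.0], optics)
        assert a[0] == pytest.approx(0.00594, rel=1e-10)


class TestSimulateTrace:
    def test_flat_noiseless(self, optics):
        t = np.arange(0.0, 61.0)
        trace = simulate_trace(t, np.zeros_like(t), NOISELESS, optics)
        assert np.allclose(trace.counts, NOISELESS.source_mean_counts)

    def test_exact_transmittance_ratio(self, optics):
        a = np.array([0.0, 0.01])
        trace = simulate_trace(np.array([0.0, 60.0]), a, NOISELESS, optics)
        assert trace.counts[1] / trace.counts[0] == pytest.approx(
            10 ** (-0.01), rel=1e-12
        )

    def test_poisson_cv_law(self, optics, rng):
        noise = InstrumentNoise.noiseless(shot_noise="poisson", source_mean_counts=1e6)
        t = np.arange(0.0, 400.0)
        trace = simulate_trace(t, np.zeros_like(t), noise, optics, rng=rng)
        cv = np.std(trace.counts, ddof=1) / np.mean(trace.counts)
        expected = 1.0 / np.sqrt(1e6)
        assert abs(cv - expected) <= 3 * expected / np.sqrt(2 * (len(t) - 1))

    def test_seed_reproducibility(self, optics):
        t = np.arange(0.0, 90.0)
        a = np.linspace(0.0, 0.05, len(t))
        noise = InstrumentNoise(seed=42)
        tr1 = simulate_trace(t, a, noise, optics)
        tr2 = simulate_trace(t, a, noise, optics)
        assert np.array_equal(tr1.counts, tr2.counts)


class TestEndToEnd:
    def test_noiseless_identity(self, optics):
        """simulate -> dark-subtract -> compute_rate reproduces the
        analytic epsilon*d[pNA]*l_total value."""
        run = simulate_run(0.5, noise=NOISELESS, config=optics)
        trace = subtract_dark(run.trace, DarkCurrentModel(0.0, 0.0, 2))
        rate = compute_rate(trace).rate_per_min
        k = run.kinetics
        i60 = int(np.argmin(np.abs(run.times_s - 60.0)))
        # independent analytic route: epsilon * pNA(60s) * l_total per minute
        _, pna = simulate_reaction(k, 90.0, 1.0)
        analytic = k.epsilon405_per_M_per_mm * 1e-6 * pna[i60] * optics.total_path_mm
        assert rate == pytest.approx(analytic, abs=1e-8)
        assert rate == pytest.approx(run.true_rate_per_min, abs=1e-8)

    @pytest.mark.parametrize("static", [0.0, 0.2, 1.0])
    def test_static_interferent_cancels(self, optics, static):
        """Icteric/hemolyzed baselines shift counts but not dA/min."""
        ref = simulate_run(0.75, noise=NOISELESS, config=optics)
        shifted = simulate_run(
            0.75, noise=NOISELESS, config=optics,
            interferent=InterferentProfile(static_absorbance_AU=static),
        )
        assert shifted.true_rate_per_min == pytest.approx(
            ref.true_rate_per_min, abs=1e-10
        )

    def test_drift_biases_rate(self, optics):
        """A lipemic-like drift does not cancel: dA/min shifts by the drift."""
        drift = 0.002
        ref = simulate_run(0.75, noise=NOISELESS, config=optics)
        drifted = simulate_run(
            0.75, noise=NOISELESS, config=optics,
            interferent=InterferentProfile(drift_AU_per_min=drift),
        )
        assert drifted.true_rate_per_min - ref.true_rate_per_min == pytest.approx(
            drift, rel=1e-6
        )

    def test_rate_monotone_decreasing_in_activity(self, optics):
        activities = [0.0, 0.25, 0.5, 0.75, 1.0, 1.25]
        rates = [
            simulate_run(a, noise=NOISELESS, config=optics).true_rate_per_min
            for a in activities
        ]
        assert np.all(np.diff(rates) < 0)

    def test_higher_activity_slower_color_reaction(self, optics, rng):
        """A 25%-activity sample darkens faster than a 100% one, even with
        full instrument noise."""
        run_hi = simulate_run(1.0, config=optics, rng=rng)
        run_lo = simulate_run(0.25, config=optics, rng=rng)
        assert measured_rate(run_lo) > measured_rate(run_hi)

    def test_true_activity_recoverable_through_pipeline(self, optics, rng):
        """Quantify a noisy simulated sample against a noiseless synthetic
        calibration: recovered activity lands near the simulated truth."""
        x, y = simulate_calibration_set([0.25, 0.5, 0.75, 1.0], noise_sd=0.0)
        curve = fit_calibration(x, y)
        run = simulate_run(0.8, config=optics, rng=rng)
        rate = measured_rate(run)
        recovered = (rate - curve.intercept) / curve.slope
        assert recovered == pytest.approx(0.8, abs=0.15)


class TestCalibrationSet:
    def test_zero_noise_on_line(self):
        x, y = simulate_calibration_set([0.25, 1.0], replicates=3, noise_sd=0.0)
        assert np.allclose(y, PLASMA_LINE[0] + PLASMA_LINE[1] * x)

    def test_recovery_within_3se(self, rng):
        x, y = simulate_calibration_set([0.25, 0.5, 0.75, 1.0], replicates=8,
                                        noise_sd=5e-4, rng=rng)
        c = fit_calibration(x, y)
        assert abs(c.slope - PLASMA_LINE[1]) <= 3 * c.slope_se
        assert abs(c.intercept - PLASMA_LINE[0]) <= 3 * c.intercept_se

    def test_degenerate_levels_propagate_to_fit_error(self):
        x, y = simulate_calibration_set([0.5, 0.5], replicates=2, noise_sd=1e-4)
        with pytest.raises(RankDeficiencyError):
            fit_calibration(x, y)


class TestWholeBlood:
    def test_background_scales_inversely_with_dilution(self):
        run1 = simulate_whole_blood(0.5, dilution_factor=1.0, noise=NOISELESS)
        run10 = simulate_whole_blood(0.5, dilution_factor=10.0, noise=NOISELESS)
        assert run1.interferent.static_absorbance_AU == pytest.approx(
            10 * run10.interferent.static_absorbance_AU
        )

    def test_rate_decreases_and_flattens_with_dilution(self):
        dilutions = [1.0, 2.0, 5.0, 10.0, 20.0]
        rates = [
            simulate_whole_blood(0.5, d, noise=NOISELESS).true_rate_per_min
            for d in dilutions
        ]
        assert np.all(np.diff(rates) < 0)
        # convex: successive secant slopes become less negative
        secants = np.diff(rates) / np.diff(dilutions)
        assert np.all(np.diff(secants) > 0)

    def test_whole_blood_line_holds_at_standard_dilution(self):
        for a in (0.25, 1.0):
            run = simulate_whole_blood(a, dilution_factor=10.0, noise=NOISELESS)
            expected = 0.01363 - 0.00916 * a
            assert run.true_rate_per_min == pytest.approx(expected, rel=5e-3)

    def test_activity_ordering_at_fixed_dilution(self):
        r_full = simulate_whole_blood(1.0, 10.0, noise=NOISELESS).true_rate_per_min
        r_quarter = simulate_whole_blood(0.25, 10.0, noise=NOISELESS).true_rate_per_min
        assert r_full < r_quarter

    def test_invalid_dilution_rejected(self):
        with pytest.raises(DomainError):
            simulate_whole_blood(0.5, dilution_factor=0.5)
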