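"""Synthetic-data generators: determinism, noise structure, closed loops."""

import numpy as np
import pytest
from scipy.integrate import quad

from tslecc import (
    CalibrationCurve,
    FeasibilityError,
    InputValidationError,
    NoiseSpec,
    fit_release_model,
    generate_blood_samples,
    generate_filter_decay_profile,
    generate_fluorescence_readings,
    generate_release_assay,
    monitor_stream,
)

CURVE = CalibrationCurve(form="linear", background=100.0, slope=50.0,
                         conc_range=(0.0, 250.0))


def test_seeded_generators_reproduce_bit_for_bit(ecc_trajectory, release_model):
    times = np.arange(30.0, 91.0, 20.0)
    noise = NoiseSpec(cv=0.2, seed=42)
    s1 = generate_blood_samples(ecc_trajectory, times, "before_filter", noise)
    s2 = generate_blood_samples(ecc_trajectory, times, "before_filter", noise)
    assert np.array_equal(s1.concentrations, s2.concentrations)

    r1 = generate_fluorescence_readings(ecc_trajectory, CURVE, times, noise)
    r2 = generate_fluorescence_readings(ecc_trajectory, CURVE, times, noise)
    assert [x.mean_intensity for x in r1] == [x.mean_intensity for x in r2]

    a1 = generate_release_assay(release_model, [37, 43], [1.0, 2.0], noise)
    a2 = generate_release_assay(release_model, [37, 43], [1.0, 2.0], noise)
    assert [p.released_fraction for p in a1] == [p.released_fraction for p in a2]

    different = generate_blood_samples(
        ecc_trajectory, times, "before_filter", NoiseSpec(cv=0.2, seed=43)
    )
    assert not np.array_equal(s1.concentrations, different.concentrations)


def test_zero_noise_samples_equal_trajectory(ecc_trajectory):
    times = np.arange(30.0, 91.0, 20.0)
    series = generate_blood_samples(
        ecc_trajectory, times, "systemic", NoiseSpec(cv=0.0, seed=1)
    )
    expected = np.interp(times, ecc_trajectory.t, ecc_trajectory.conc_total)
    assert np.array_equal(series.concentrations, expected)


def test_sample_noise_has_requested_cv(ecc_trajectory):
    """Empirical CV over 200 draws matches the nominal 0.1 within MC error."""
    times = np.linspace(31.0, 89.0, 200)
    truth = generate_blood_samples(
        ecc_trajectory, times, "before_filter", NoiseSpec(cv=0.0, seed=7)
    ).concentrations
    noisy = generate_blood_samples(
        ecc_trajectory, times, "before_filter", NoiseSpec(cv=0.1, seed=7)
    ).concentrations
    ratios = noisy / truth
    assert np.std(ratios) == pytest.approx(0.1, abs=0.02)
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)


def test_out_of_horizon_times_rejected(ecc_trajectory):
    with pytest.raises(InputValidationError):
        generate_blood_samples(
            ecc_trajectory, [0.0, 1e4], "systemic", NoiseSpec(seed=0)
        )
    with pytest.raises(InputValidationError):
        # circuit sites only exist during the filtration window
        generate_blood_samples(
            ecc_trajectory, [5.0], "before_filter", NoiseSpec(seed=0)
        )


class TestFilterProfile:
    def test_constant_profile(self):
        fm = generate_filter_decay_profile(0.55, 0.55, 60.0)
        assert fm.at(0.0) == fm.at(60.0) == 0.55

    def test_reference_decay_profile(self):
        """~80% initial efficacy decaying toward ~40% with a 55% average."""
        fm = generate_filter_decay_profile(0.80, 0.40, 60.0, target_mean=0.55)
        assert fm.at(0.0) == pytest.approx(0.80)
        assert fm.at(60.0) == pytest.approx(0.40, abs=0.05)
        assert fm.mean(60.0) == pytest.approx(0.55, abs=1e-6)

    def test_mean_matches_quadrature_oracle(self):
        fm = generate_filter_decay_profile(0.80, 0.40, 60.0, target_mean=0.55)
        numeric = quad(fm.at, 0.0, 60.0)[0] / 60.0
        assert numeric == pytest.approx(0.55, abs=1e-6)

    def test_infeasible_target_mean(self):
        with pytest.raises(FeasibilityError):
            generate_filter_decay_profile(0.80, 0.40, 60.0, target_mean=0.9)
        with pytest.raises(InputValidationError):
            generate_filter_decay_profile(0.40, 0.80, 60.0)


class TestFluorescenceGeneration:
    def test_zero_noise_inverts_exactly(self, ecc_trajectory):
        times = np.arange(30.0, 91.0, 20.0)
        readings = generate_fluorescence_readings(
            ecc_trajectory, CURVE, times, NoiseSpec(cv=0.0, seed=0)
        )
        report = monitor_stream(CURVE, readings, 0.35, 0.45)
        inside = ~np.isnan(ecc_trajectory.conc_before_filter)
        expected_bf = np.interp(
            times, ecc_trajectory.t[inside], ecc_trajectory.conc_before_filter[inside]
        )
        assert np.allclose(report["c_bf"], expected_bf, rtol=1e-9)

    def test_out_of_range_concentration_rejected(self, ecc_trajectory):
        narrow = CalibrationCurve(form="linear", background=0.0, slope=1.0,
                                  conc_range=(0.0, 1.0))
        with pytest.raises(Exception):
            generate_fluorescence_readings(
                ecc_trajectory, narrow, [40.0], NoiseSpec(cv=0.0, seed=0)
            )

    def test_pipeline_recovers_removed_mass(self, scenario, ecc_trajectory):
        """Generate noisy readings -> monitor -> removed mass within 10% of ODE."""
        times = np.arange(30.0, 91.0, 20.0)
        readings = generate_fluorescence_readings(
            ecc_trajectory, CURVE, times, NoiseSpec(cv=0.05, seed=11)
        )
        report = monitor_stream(CURVE, readings, scenario.ecc.blood_flow,
                                scenario.subject.hematocrit)
        assert report["removed_cum_ug"].iloc[-1] == pytest.approx(
            float(ecc_trajectory.removed_cum[-1]), rel=0.10
        )

    def test_before_filter_concentration_drops_during_filtration(self, ecc_trajectory):
        """Circulating drug falls several-fold over the filtration hour.

        Mirrors the monitored in vivo run, where the before-filter
        concentration dropped steeply within 60 min of starting filtration.
        """
        times = np.arange(30.0, 91.0, 20.0)
        readings = generate_fluorescence_readings(
            ecc_trajectory, CURVE, times, NoiseSpec(cv=0.0, seed=0)
        )
        report = monitor_stream(CURVE, readings, 0.35, 0.45)
        assert report["c_bf"].is_monotonic_decreasing
        assert report["c_bf"].iloc[0] > 2 * report["c_bf"].iloc[-1]


class TestReleaseAssayGeneration:
    def test_zero_noise_refit_recovers_model(self, release_model):
        points = generate_release_assay(
            release_model, [37, 39, 41, 43, 45], [0.5, 1.0, 2.0, 2.5],
            NoiseSpec(cv=0.0, seed=0),
        )
        refit = fit_release_model(points)
        assert refit.release_fraction(37.0, 2.5) == pytest.approx(
            release_model.release_fraction(37.0, 2.5), abs=1e-6
        )

    def test_noisy_refit_near_reference_fraction(self, release_model):
        points = generate_release_assay(
            release_model, [37, 39, 41, 43, 45], [0.5, 1.0, 1.5, 2.0, 2.5],
            NoiseSpec(cv=0.05, seed=3),
        )
        refit = fit_release_model(points, tol=0.2)
        assert refit.release_fraction(37.0, 2.5) == pytest.approx(0.30, abs=0.08)

    def test_large_noise_stays_in_unit_interval(self, release_model):
        points = generate_release_assay(
            release_model, [37, 41, 45], [0.5, 1.0, 2.0], NoiseSpec(cv=2.0, seed=9)
        )
        assert all(0.0 <= p.released_fraction <= 1.0 for p in points)
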