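"""Core ODE model: closed forms, mass balance, an independent Euler oracle."""

import math

import numpy as np
import pytest

from tslecc import (
    CardiacParams,
    DoseParams,
    ECCParams,
    FilterModel,
    FreeDrugParams,
    InputValidationError,
    ScenarioConfig,
    SolverSettings,
    SubjectParams,
    TSLParams,
    cardiac_concentration,
    default_release_model,
    removed_percent,
    simulate,
    simulate_scenario,
)
from tslecc.calibration import auc_ratio_for, removal_percent_for

SUBJECT = SubjectParams()
DOSE = DoseParams()


def test_no_ecc_zero_leak_matches_single_exponential():
    """With no leak and no circuit the carrier is a pure exponential."""
    traj = simulate(
        SUBJECT,
        DOSE,
        TSLParams(leak_fraction=0.0),
        FreeDrugParams(k_e_free=0.05),
        horizon=240.0,
    )
    k = math.log(2) / 55.0
    expected = traj.dose_ug * np.exp(-k * traj.t)
    assert np.max(np.abs(traj.L - expected) / traj.dose_ug) < 1e-6
    assert np.all(traj.D == 0.0)
    assert np.all(traj.removed_cum == 0.0)


def test_mass_balance_all_scenario_shapes(scenario):
    """Pools plus sinks equal the dose to 1e-6 relative, with and without ECC."""
    for cfg in (
        scenario.without_ecc(),
        scenario.with_constant_efficacy(0.55),
        scenario.model_copy(
            update={
                "ecc": scenario.ecc.model_copy(
                    update={"filter": FilterModel.exponential(0.8, 0.4, 24.0)}
                )
            }
        ),
    ):
        traj = simulate_scenario(cfg)
        assert traj.mass_balance_error() < 1e-6


def test_removed_mass_is_nondecreasing(ecc_trajectory):
    assert np.all(np.diff(ecc_trajectory.removed_cum) >= -1e-9)
    assert np.all(ecc_trajectory.total_in_system() > 0)


def test_zero_flow_equals_no_ecc(scenario):
    """A connected circuit with negligible flow changes nothing."""
    near_zero = scenario.ecc.model_copy(update={"blood_flow": 1e-9})
    cfg = scenario.model_copy(update={"ecc": near_zero})
    traj = simulate_scenario(cfg)
    ref = simulate_scenario(scenario.without_ecc())
    assert removed_percent(traj) < 1e-6
    assert np.max(np.abs(traj.L - ref.L)) / traj.dose_ug < 1e-6
    assert np.max(np.abs(traj.D - ref.D)) / traj.dose_ug < 1e-6


def test_zero_duration_equals_no_ecc(scenario):
    cfg = scenario.model_copy(
        update={"ecc": scenario.ecc.model_copy(update={"duration": 0.0})}
    )
    traj = simulate_scenario(cfg)
    ref = simulate_scenario(scenario.without_ecc())
    assert removed_percent(traj) == 0.0
    assert np.max(np.abs(traj.L - ref.L)) / traj.dose_ug < 1e-6


def test_removal_monotone_in_efficacy_and_duration(scenario):
    removed_eta = [
        removal_percent_for(scenario, eta, duration=60.0)
        for eta in (0.1, 0.25, 0.5, 0.75, 1.0)
    ]
    assert all(b > a for a, b in zip(removed_eta, removed_eta[1:]))
    removed_dur = [
        removal_percent_for(scenario, 0.55, duration=d) for d in (15.0, 30.0, 60.0, 120.0)
    ]
    assert all(b > a for a, b in zip(removed_dur, removed_dur[1:]))


def test_auc_ratio_at_least_one_with_active_filter(scenario):
    assert auc_ratio_for(scenario, eta=0.3) >= 1.0


def euler_oracle(scenario, release, horizon, dt=0.001):
    """Independent fixed-step explicit-Euler integration of the model equations.

    Written directly from the model definition (not via the package RHS) so
    it can serve as an oracle for the adaptive solver.
    """
    sub, tsl, fd, ecc, card = (
        scenario.subject,
        scenario.tsl,
        scenario.free_drug,
        scenario.ecc,
        scenario.cardiac,
    )
    dose = scenario.dose.dose_per_mass * sub.body_mass
    k_L = math.log(2) / tsl.plasma_half_life
    V_p = sub.blood_volume * (1 - sub.hematocrit)
    kdraw = ecc.blood_flow / sub.blood_volume
    kout = ecc.blood_flow / ecc.circuit_volume
    r = release.release_fraction(ecc.heater_temperature, ecc.heater_dwell)
    khe = card.k_h_enc * sub.heart_mass / V_p
    khf = card.k_h_free * sub.heart_mass / V_p
    L, D, Le, De, rem, clr, He, Hf = dose, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    n = int(round(horizon / dt))
    for i in range(n):
        t = i * dt
        active = ecc.start_time <= t < ecc.start_time + ecc.duration
        dL = -k_L * L - khe * L
        dD = tsl.leak_fraction * k_L * L - fd.k_e_free * D - khf * D
        dClr = (1 - tsl.leak_fraction) * k_L * L + fd.k_e_free * D
        dLe = dDe = dRem = 0.0
        if active:
            eta = ecc.filter.at(t - ecc.start_time)
            at_filter = r * kdraw * L + kdraw * D
            dL += -kdraw * L + kout * Le
            dD += -kdraw * D + kout * De
            dLe = (1 - r) * kdraw * L - kout * Le
            dDe = (1 - eta) * at_filter - kout * De
            dRem = eta * at_filter
        L += dt * dL
        D += dt * dD
        Le += dt * dLe
        De += dt * dDe
        rem += dt * dRem
        clr += dt * dClr
        He += dt * khe * L
        Hf += dt * khf * D
    return {"L": L, "D": D, "removed": rem, "cardiac": He + Hf}


def test_adaptive_solver_agrees_with_euler_oracle(scenario, release_model):
    """Reference filtration scenario: solver vs fixed-step Euler at dt=0.001."""
    cfg = scenario.with_constant_efficacy(0.55)
    horizon = 120.0
    oracle = euler_oracle(cfg, release_model, horizon)
    traj = simulate_scenario(cfg, horizon=horizon)
    for key, value in (
        ("L", traj.L[-1]),
        ("D", traj.D[-1]),
        ("removed", traj.removed_cum[-1]),
        ("cardiac", traj.cardiac_total[-1]),
    ):
        assert value == pytest.approx(oracle[key], rel=1e-3)


def test_halving_solver_tolerance_is_inconsequential(scenario):
    cfg = scenario.with_constant_efficacy(0.55)
    loose = simulate_scenario(cfg)
    tight = simulate_scenario(
        cfg.model_copy(
            update={"solver": SolverSettings(rtol=5e-9, atol=5e-11)}
        )
    )
    assert abs(removed_percent(loose) - removed_percent(tight)) < 0.01


def test_cardiac_zero_rates_zero_uptake(scenario):
    cfg = scenario.model_copy(update={"cardiac": CardiacParams()})
    res = cardiac_concentration(simulate_scenario(cfg.without_ecc()))
    assert res.total == 0.0


def test_cardiac_pathway_split_sums(noecc_trajectory):
    res = cardiac_concentration(noecc_trajectory)
    assert res.total == pytest.approx(res.free_pathway + res.encapsulated_pathway)
    assert res.free_pathway > res.encapsulated_pathway > 0


def test_before_after_filter_concentrations_consistent(ecc_trajectory):
    """c_BF >= c_AF, and their gap carries exactly the removal flux."""
    bf = ecc_trajectory.conc_before_filter
    af = ecc_trajectory.conc_after_filter
    inside = ~np.isnan(bf)
    assert inside.any()
    assert np.all(bf[inside] >= af[inside] - 1e-12)
    assert np.all(af[inside] >= 0)


def test_filter_model_mean_matches_quadrature():
    from scipy.integrate import quad

    fm = FilterModel.exponential(0.8, 0.4, 24.0)
    numeric = quad(fm.at, 0.0, 60.0)[0] / 60.0
    assert fm.mean(60.0) == pytest.approx(numeric, rel=1e-9)


def test_invalid_inputs_rejected():
    with pytest.raises(Exception):
        SubjectParams(blood_volume=-1.0)
    with pytest.raises(Exception):
        CardiacParams(k_h_free=0.1, k_h_enc=0.2)
    with pytest.raises(InputValidationError):
        simulate(
            SUBJECT,
            DOSE,
            TSLParams(),
            FreeDrugParams(k_e_free=0.05),
            ecc=ECCParams(),
            horizon=60.0,  # ends before the filtration window does
        )


def test_trajectory_export_columns(tmp_path, ecc_trajectory):
    path = tmp_path / "traj.csv"
    ecc_trajectory.to_csv(path)
    header = path.read_text().splitlines()[0].split(",")
    assert header == [
        "time_min",
        "L_ug",
        "D_ug",
        "ecc_enc_ug",
        "ecc_free_ug",
        "removed_cum_ug",
        "cleared_cum_ug",
        "cardiac_ug",
        "conc_enc_ug_per_ml",
        "conc_free_ug_per_ml",
    ]
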