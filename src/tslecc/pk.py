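"""Compartmental pharmacokinetics of TSL-Dox with an extracorporeal circuit.

Model structure
---------------
All drug amounts are tracked in micrograms; time in minutes.  Solutes are
carried in plasma: the systemic plasma volume is ``V_p = blood_volume *
(1 - Hct)`` and the circuit plasma flow is ``Q_p = F * (1 - Hct)``, so the
systemic draw rate constant is ``Q_p / V_p = F / blood_volume``.

State variables (µg):

* ``L``   systemic encapsulated (liposomal) drug
* ``D``   systemic free (released) drug
* ``Le``  encapsulated drug inside the extracorporeal circuit (ECC)
* ``De``  free drug inside the ECC
* ``m_rem``  cumulative drug removed by the filter (sink)
* ``m_clr``  cumulative non-filter clearance (sink)
* ``H_enc``, ``H_free``  cumulative cardiac uptake per pathway (sinks)

Encapsulated drug is eliminated first-order with ``k_L = ln 2 / t_half``;
a fraction ``phi`` of that elimination appears as free drug in plasma (the
leak that drives systemic toxicity), the rest is cleared without systemic
exposure.  Free drug is eliminated first-order with ``k_e_free``.

While the ECC runs, plasma flow draws both pools out of systemic plasma.
The in-line heater converts a fraction ``r = release_fraction(T_heater,
dwell)`` of the drawn encapsulated drug to free drug, and the filter
immediately downstream removes a fraction ``eta(t)`` of the free drug
arriving at it.  Whatever survives enters a well-mixed circuit compartment
of volume ``V_ECC`` (the priming/return-line volume; mean whole-blood
transit ``V_ECC / F``) before washing back into systemic plasma.  The
circuit is primed drug-free, so connecting it dilutes the circulating pool
by ``V_ECC``.  Cardiac uptake is irreversible and proportional to the
plasma concentration of each pool.

The right-hand side sums to zero over all states, so total drug is conserved
exactly up to solver error (checked by :meth:`Trajectory.mass_balance_error`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.integrate import solve_ivp

from .errors import InputValidationError, IntegrationError
from .release import ReleaseModel, default_release_model

__all__ = [
    "SubjectParams",
    "DoseParams",
    "TSLParams",
    "FreeDrugParams",
    "FilterModel",
    "ECCParams",
    "CardiacParams",
    "SolverSettings",
    "Trajectory",
    "simulate",
    "removed_percent",
    "cardiac_concentration",
    "CardiacResult",
]


class SubjectParams(BaseModel):
    """Animal-level parameters (defaults: 250 g rat, 16 mL blood)."""

    body_mass: float = Field(250.0, gt=0, description="body mass [g]")
    blood_volume: float = Field(16.0, gt=0, description="blood volume [mL]")
    hematocrit: float = Field(0.45, gt=0, lt=0.7, description="Hct fraction")
    heart_mass: float = Field(1.0, gt=0, description="heart mass [g]")

    @property
    def plasma_volume(self) -> float:
        """Systemic plasma volume [mL]."""
        return self.blood_volume * (1.0 - self.hematocrit)


class DoseParams(BaseModel):
    """Bolus dose at time zero."""

    dose_per_mass: float = Field(7.0, gt=0, description="dose [mg/kg]")

    def total_dose_ug(self, subject: SubjectParams) -> float:
        # mg/kg * g == µg  (7 mg/kg * 250 g -> 1750 µg)
        return self.dose_per_mass * subject.body_mass


class TSLParams(BaseModel):
    """Liposome-carrier kinetics."""

    plasma_half_life: float = Field(55.0, gt=0, description="TSL t1/2 [min]")
    leak_fraction: float = Field(
        1.0,
        ge=0,
        le=1,
        description="fraction of TSL elimination appearing as free plasma drug",
    )

    @property
    def k_elim(self) -> float:
        return math.log(2.0) / self.plasma_half_life


class FreeDrugParams(BaseModel):
    """Free (released) doxorubicin kinetics: one-compartment first-order."""

    k_e_free: float = Field(..., gt=0, description="free-drug elimination [1/min]")

    @classmethod
    def from_half_life(cls, half_life_min: float) -> "FreeDrugParams":
        return cls(k_e_free=math.log(2.0) / half_life_min)


class FilterModel(BaseModel):
    """Filter efficacy: constant or exponential time-decay profile.

    ``eta(t) = eta_end + (eta0 - eta_end) * exp(-t / tau)`` with ``t`` in
    minutes since the start of filtration.  A constant filter has
    ``eta0 == eta_end`` (``tau`` is then irrelevant).
    """

    eta0: float = Field(..., ge=0, le=1)
    eta_end: float = Field(..., ge=0, le=1)
    tau: float = Field(1.0, gt=0, description="decay time constant [min]")

    @model_validator(mode="after")
    def _check(self) -> "FilterModel":
        if self.eta_end > self.eta0:
            raise ValueError("eta_end must not exceed eta0 for a decaying filter")
        return self

    @classmethod
    def constant(cls, efficacy: float) -> "FilterModel":
        return cls(eta0=efficacy, eta_end=efficacy, tau=1.0)

    @classmethod
    def exponential(cls, eta0: float, eta_end: float, tau: float) -> "FilterModel":
        return cls(eta0=eta0, eta_end=eta_end, tau=tau)

    @property
    def is_constant(self) -> bool:
        return self.eta0 == self.eta_end

    def at(self, t_since_start: float | np.ndarray) -> float | np.ndarray:
        """Efficacy at ``t_since_start`` minutes into filtration."""
        t = np.asarray(t_since_start, dtype=float)
        eta = self.eta_end + (self.eta0 - self.eta_end) * np.exp(-t / self.tau)
        return float(eta) if np.isscalar(t_since_start) else eta

    def mean(self, duration: float) -> float:
        """Time-average efficacy over [0, duration] (closed form)."""
        if duration <= 0:
            return self.eta0
        if self.is_constant:
            return self.eta0
        x = duration / self.tau
        return self.eta_end + (self.eta0 - self.eta_end) * (-np.expm1(-x)) / x


class ECCParams(BaseModel):
    """Extracorporeal circuit configuration (reference in vivo defaults)."""

    blood_flow: float = Field(0.35, gt=0, description="whole-blood flow F [mL/min]")
    circuit_volume: float = Field(4.2, ge=0, description="priming volume V_ECC [mL]")
    heater_temperature: float = Field(43.0, description="heater set point [degC]")
    heater_dwell: float = Field(5.0, ge=0, description="dwell in heater [s]")
    start_time: float = Field(30.0, ge=0, description="ECC start after bolus [min]")
    duration: float = Field(60.0, ge=0, description="filtration duration [min]")
    filter: FilterModel = Field(default_factory=lambda: FilterModel.constant(0.55))

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


class CardiacParams(BaseModel):
    """Irreversible cardiac uptake, one rate per drug pool.

    Rates are plasma clearances per gram of heart tissue
    [mL plasma / (min * g heart)].  Encapsulated drug enters the heart much
    more slowly than free drug (``k_h_enc <= k_h_free``).
    """

    k_h_free: float = Field(0.0, ge=0)
    k_h_enc: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "CardiacParams":
        if self.k_h_enc > self.k_h_free:
            raise ValueError("k_h_enc must not exceed k_h_free")
        return self


class SolverSettings(BaseModel):
    """ODE solver configuration."""

    rtol: float = Field(1e-8, gt=0)
    atol: float = Field(1e-10, gt=0, description="absolute tolerance [µg]")
    dt_out: float = Field(0.25, gt=0, description="output grid spacing [min]")
    method: str = "LSODA"


# state indices
_L, _D, _LE, _DE, _REM, _CLR, _HENC, _HFREE = range(8)


@dataclass
class Trajectory:
    """Time-resolved drug pools from one simulation (amounts in µg).

    ``ecc_enc``/``ecc_free`` hold the circuit content; after the circuit is
    disconnected they stay frozen at their residual values (that drug never
    returns to the animal but still counts toward the mass balance).
    Filter-efficacy values are recorded as ``eta`` (NaN outside the
    filtration window).
    """

    t: np.ndarray
    L: np.ndarray
    D: np.ndarray
    ecc_enc: np.ndarray
    ecc_free: np.ndarray
    removed_cum: np.ndarray
    cleared_cum: np.ndarray
    cardiac_enc: np.ndarray
    cardiac_free: np.ndarray
    eta: np.ndarray
    dose_ug: float
    plasma_volume: float
    ecc_plasma_volume: float
    heart_mass: float
    ecc_window: Optional[tuple[float, float]]
    heater_release: float = 0.0

    @property
    def conc_enc(self) -> np.ndarray:
        """Systemic encapsulated plasma concentration [µg/mL]."""
        return self.L / self.plasma_volume

    @property
    def conc_free(self) -> np.ndarray:
        """Systemic free plasma concentration [µg/mL]."""
        return self.D / self.plasma_volume

    @property
    def conc_total(self) -> np.ndarray:
        """Total systemic plasma concentration (what a lysis assay measures)."""
        return (self.L + self.D) / self.plasma_volume

    @property
    def cardiac_total(self) -> np.ndarray:
        return self.cardiac_enc + self.cardiac_free

    def _require_ecc(self) -> None:
        if self.ecc_window is None:
            raise InputValidationError("trajectory has no ECC stage")

    @property
    def conc_before_filter(self) -> np.ndarray:
        """Total plasma concentration arriving at the filter [µg/mL] (NaN off-window).

        The drawn stream is systemic plasma; the heater converts encapsulated
        to free drug but leaves the total unchanged.
        """
        self._require_ecc()
        return np.where(self._in_window(), self.conc_total, np.nan)

    @property
    def conc_after_filter(self) -> np.ndarray:
        """Total plasma concentration just past the filter [µg/mL] (NaN off-window)."""
        self._require_ecc()
        r = self.heater_release
        c_af = (
            self.conc_total
            - self.eta * (r * self.L + self.D) / self.plasma_volume
        )
        return np.where(self._in_window(), c_af, np.nan)

    def _in_window(self) -> np.ndarray:
        t0, t1 = self.ecc_window  # type: ignore[misc]
        return (self.t >= t0) & (self.t <= t1)

    def total_in_system(self) -> np.ndarray:
        """Sum of all pools and sinks at each time (should equal the dose)."""
        return (
            self.L
            + self.D
            + self.ecc_enc
            + self.ecc_free
            + self.removed_cum
            + self.cleared_cum
            + self.cardiac_enc
            + self.cardiac_free
        )

    def mass_balance_error(self) -> float:
        """Worst relative deviation of total drug from the administered dose."""
        return float(np.max(np.abs(self.total_in_system() - self.dose_ug)) / self.dose_ug)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.t,
                "L_ug": self.L,
                "D_ug": self.D,
                "ecc_enc_ug": self.ecc_enc,
                "ecc_free_ug": self.ecc_free,
                "removed_cum_ug": self.removed_cum,
                "cleared_cum_ug": self.cleared_cum,
                "cardiac_ug": self.cardiac_total,
                "conc_enc_ug_per_ml": self.conc_enc,
                "conc_free_ug_per_ml": self.conc_free,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _make_rhs(
    k_L: float,
    phi: float,
    k_e: float,
    k_draw: float,
    k_out: float,
    r: float,
    eta_fn,
    ecc_start: float,
    kh_enc_over_vp: float,
    kh_free_over_vp: float,
    ecc_active: bool,
):
    """Build the ODE right-hand side for one integration segment."""

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        L, D, Le, De = y[_L], y[_D], y[_LE], y[_DE]
        uptake_enc = kh_enc_over_vp * L
        uptake_free = kh_free_over_vp * D
        dL = -k_L * L - uptake_enc
        dD = phi * k_L * L - k_e * D - uptake_free
        dLe = 0.0
        dDe = 0.0
        dRem = 0.0
        dClr = (1.0 - phi) * k_L * L + k_e * D
        if ecc_active:
            eta = eta_fn(t - ecc_start)
            free_at_filter = r * k_draw * L + k_draw * D
            dL += -k_draw * L + k_out * Le
            dD += -k_draw * D + k_out * De
            dLe = (1.0 - r) * k_draw * L - k_out * Le
            dDe = (1.0 - eta) * free_at_filter - k_out * De
            dRem = eta * free_at_filter
        return np.array(
            [dL, dD, dLe, dDe, dRem, dClr, uptake_enc, uptake_free]
        )

    return rhs


def simulate(
    subject: SubjectParams,
    dose: DoseParams,
    tsl: TSLParams,
    free_drug: FreeDrugParams,
    ecc: Optional[ECCParams] = None,
    cardiac: Optional[CardiacParams] = None,
    release: Optional[ReleaseModel] = None,
    horizon: float = 480.0,
    solver: Optional[SolverSettings] = None,
) -> Trajectory:
    """Integrate the TSL-Dox model and return a :class:`Trajectory`.

    Parameters
    ----------
    ecc:
        Circuit configuration, or ``None`` for a control (no-filtration) run.
    release:
        Release model used by the in-line heater; defaults to the package
        calibration when the ECC is present.
    horizon:
        Total simulated time [min]; must cover the filtration window.
    """
    solver = solver or SolverSettings()
    if horizon <= 0:
        raise InputValidationError("horizon must be positive")
    if ecc is not None and horizon < ecc.end_time:
        raise InputValidationError(
            f"horizon {horizon} min ends before the ECC window "
            f"({ecc.start_time}+{ecc.duration} min)"
        )
    cardiac = cardiac or CardiacParams()

    k_L = tsl.k_elim
    phi = tsl.leak_fraction
    k_e = free_drug.k_e_free
    V_p = subject.plasma_volume
    kh_enc_over_vp = cardiac.k_h_enc * subject.heart_mass / V_p
    kh_free_over_vp = cardiac.k_h_free * subject.heart_mass / V_p

    if ecc is not None:
        rel = release or default_release_model()
        r = float(rel.release_fraction(ecc.heater_temperature, ecc.heater_dwell))
        k_draw = ecc.blood_flow / subject.blood_volume
        k_out = (
            ecc.blood_flow / ecc.circuit_volume if ecc.circuit_volume > 0 else 0.0
        )
        ecc_plasma_volume = ecc.circuit_volume * (1.0 - subject.hematocrit)
        window: Optional[tuple[float, float]] = (ecc.start_time, ecc.end_time)
        eta_fn = ecc.filter.at
        ecc_start = ecc.start_time
    else:
        r, k_draw, k_out = 0.0, 0.0, 0.0
        ecc_plasma_volume = np.nan
        window = None
        eta_fn = None
        ecc_start = 0.0

    # integration segments split at the on/off switching times
    breaks = [0.0, horizon]
    if window is not None:
        for b in window:
            if 0.0 < b < horizon:
                breaks.append(b)
    breaks = sorted(set(breaks))

    dose_ug = dose.total_dose_ug(subject)
    y0 = np.zeros(8)
    y0[_L] = dose_ug

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        active = window is not None and a >= window[0] - 1e-12 and b <= window[1] + 1e-12
        rhs = _make_rhs(
            k_L, phi, k_e, k_draw, k_out, r, eta_fn, ecc_start,
            kh_enc_over_vp, kh_free_over_vp, active,
        )
        n = max(int(math.ceil((b - a) / solver.dt_out)), 1)
        t_eval = np.linspace(a, b, n + 1)
        sol = solve_ivp(
            rhs,
            (a, b),
            y0,
            method=solver.method,
            t_eval=t_eval,
            rtol=solver.rtol,
            atol=solver.atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE solver failed on [{a}, {b}] min: {sol.message}"
            )
        y0 = sol.y[:, -1].copy()
        start_idx = 1 if ts else 0  # avoid duplicating segment boundaries
        ts.append(sol.t[start_idx:])
        ys.append(sol.y[:, start_idx:])

    t = np.concatenate(ts)
    y = np.concatenate(ys, axis=1)
    y = np.clip(y, 0.0, None)  # clip solver noise at the nonnegativity boundary

    if window is not None:
        in_win = (t >= window[0]) & (t <= window[1])
        eta_arr = np.where(in_win, ecc.filter.at(np.maximum(t - ecc_start, 0.0)), np.nan)
    else:
        eta_arr = np.full_like(t, np.nan)

    return Trajectory(
        t=t,
        L=y[_L],
        D=y[_D],
        ecc_enc=y[_LE],
        ecc_free=y[_DE],
        removed_cum=y[_REM],
        cleared_cum=y[_CLR],
        cardiac_enc=y[_HENC],
        cardiac_free=y[_HFREE],
        eta=eta_arr,
        dose_ug=dose_ug,
        plasma_volume=V_p,
        ecc_plasma_volume=ecc_plasma_volume,
        heart_mass=subject.heart_mass,
        ecc_window=window,
        heater_release=r,
    )


def removed_percent(traj: Trajectory) -> float:
    """Cumulative filter-removed drug at the end, as % of the administered dose."""
    return 100.0 * float(traj.removed_cum[-1]) / traj.dose_ug


@dataclass(frozen=True)
class CardiacResult:
    """Cardiac drug concentration split by uptake pathway [µg/g heart]."""

    total: float
    free_pathway: float
    encapsulated_pathway: float
    plateau_reached: bool


def cardiac_concentration(
    traj: Trajectory, *, plateau_rel_rate: float = 1e-3
) -> CardiacResult:
    """Cardiac drug concentration at the end of the run [µg per g heart].

    The run is considered at plateau when the relative increase of the
    cardiac pool over the final tenth of the horizon is below
    ``plateau_rel_rate``.
    """
    total = traj.cardiac_total
    hm = traj.heart_mass
    if total[-1] <= 0:
        return CardiacResult(0.0, 0.0, 0.0, True)
    i = np.searchsorted(traj.t, traj.t[-1] - 0.1 * (traj.t[-1] - traj.t[0]))
    plateau = (total[-1] - total[min(i, len(total) - 1)]) / total[-1] < plateau_rel_rate
    return CardiacResult(
        total=float(total[-1]) / hm,
        free_pathway=float(traj.cardiac_free[-1]) / hm,
        encapsulated_pathway=float(traj.cardiac_enc[-1]) / hm,
        plateau_reached=bool(plateau),
    )
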