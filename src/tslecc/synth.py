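"""Synthetic-data generators emulating the in vivo study conditions.

Every input the pipeline consumes can be generated here from a simulated
trajectory: serial blood samples (every 20 min before/after the filter, as
in the animal runs), fluorescence readings through a standard curve,
release-assay tables at the five assay temperatures, and the
exponential filter-efficacy decay (~80% -> ~40% over 60 min with a 55%
time-average).

Noise model: concentrations and intensities get multiplicative lognormal
noise with a given coefficient of variation (non-negativity guaranteed);
release fractions get additive Gaussian noise clipped to [0, 1].  One
global seed expands into independent per-generator substreams, so adding a
generator does not perturb the outputs of existing ones, and identical
seeds reproduce outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import FeasibilityError, InputValidationError, OutOfRangeError
from .estimators import SampleSeries
from .fluorescence import CalibrationCurve, IntensityReading
from .pk import FilterModel, Trajectory
from .release import ReleaseAssayPoint, ReleaseModel

__all__ = [
    "NoiseSpec",
    "generate_blood_samples",
    "generate_filter_decay_profile",
    "generate_fluorescence_readings",
    "generate_release_assay",
]

# Fixed substream ids: the global seed is combined with one of these so each
# generator draws from its own independent stream.
_STREAMS = {
    "blood_samples": 1,
    "fluorescence": 2,
    "release_assay": 3,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative noise level (coefficient of variation) and seed."""

    cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise InputValidationError("cv must be nonnegative")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def lognormal_factors(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Unit-mean multiplicative factors with CV == ``cv``."""
        if self.cv == 0:
            return np.ones(n)
        sigma = np.sqrt(np.log1p(self.cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _site_concentration(traj: Trajectory, times: np.ndarray, site: str) -> np.ndarray:
    if np.any(times < traj.t[0]) or np.any(times > traj.t[-1]):
        raise InputValidationError("requested times fall outside the trajectory horizon")
    if site == "systemic":
        return np.interp(times, traj.t, traj.conc_total)
    if site in ("before_filter", "after_filter"):
        if traj.ecc_window is None:
            raise InputValidationError(f"site {site!r} requires an ECC trajectory")
        t0, t1 = traj.ecc_window
        tol = 1e-9 * max(1.0, t1)  # absorb float fuzz from arange-style grids
        if np.any(times < t0 - tol) or np.any(times > t1 + tol):
            raise InputValidationError(
                f"{site} samples must lie inside the filtration window [{t0}, {t1}] min"
            )
        times = np.clip(times, t0, t1)
        series = (
            traj.conc_before_filter if site == "before_filter" else traj.conc_after_filter
        )
        inside = ~np.isnan(series)
        return np.interp(times, traj.t[inside], series[inside])
    raise InputValidationError(f"unknown site {site!r}")


def generate_blood_samples(
    traj: Trajectory,
    times: Sequence[float],
    site: str,
    noise: NoiseSpec,
) -> SampleSeries:
    """Sample the trajectory at ``times`` [min] with lognormal noise.

    Site ``systemic`` reads total plasma concentration; ``before_filter``
    and ``after_filter`` read the circuit concentrations entering and
    leaving the filter (only defined during the filtration window).
    """
    t = np.asarray(times, dtype=float)
    conc = _site_concentration(traj, t, site)
    factors = noise.lognormal_factors(noise.rng("blood_samples"), t.size)
    return SampleSeries(site=site, times=t, concentrations=conc * factors)


def generate_filter_decay_profile(
    eta0: float,
    eta_end: float,
    duration: float,
    target_mean: float | None = None,
    tau: float | None = None,
) -> FilterModel:
    """Exponential filter-efficacy decay, optionally solved for a target mean.

    When ``target_mean`` is given, the decay constant ``tau`` is solved
    numerically so the time-average of ``eta(t)`` over ``[0, duration]``
    equals it (to ~1e-12; feasible means lie strictly between ``eta_end``
    and ``eta0``).  Otherwise ``tau`` defaults to ``duration / 3``.
    """
    if not 0 <= eta_end <= eta0 <= 1:
        raise InputValidationError("need 0 <= eta_end <= eta0 <= 1")
    if eta0 == eta_end:
        return FilterModel.constant(eta0)
    if duration <= 0:
        raise InputValidationError("duration must be positive")
    if target_mean is None:
        return FilterModel.exponential(eta0, eta_end, tau if tau else duration / 3.0)
    if not eta_end < target_mean < eta0:
        raise FeasibilityError(
            f"target mean {target_mean} not strictly between eta_end {eta_end} "
            f"and eta0 {eta0}"
        )

    def gap(log_tau: float) -> float:
        return FilterModel.exponential(eta0, eta_end, np.exp(log_tau)).mean(
            duration
        ) - target_mean

    # mean is increasing in tau: from eta_end (tau -> 0) to eta0 (tau -> inf)
    lo, hi = np.log(duration * 1e-6), np.log(duration * 1e6)
    log_tau = brentq(gap, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return FilterModel.exponential(eta0, eta_end, float(np.exp(log_tau)))


def generate_fluorescence_readings(
    traj: Trajectory,
    curve: CalibrationCurve,
    times: Sequence[float],
    noise: NoiseSpec,
) -> list[IntensityReading]:
    """Paired before/after-filter intensity readings through a standard curve.

    Concentrations are forward-mapped to intensities and perturbed with
    multiplicative lognormal noise on the background-corrected signal, so
    zero-noise readings invert exactly and noisy ones invert within noise.
    Concentrations outside the curve's calibrated range raise
    :class:`OutOfRangeError`.
    """
    t = np.asarray(times, dtype=float)
    c_bf = _site_concentration(traj, t, "before_filter")
    c_af = _site_concentration(traj, t, "after_filter")
    lo, hi = curve.conc_range
    for name, c in (("before_filter", c_bf), ("after_filter", c_af)):
        if np.any(c < lo) or np.any(c > hi):
            raise OutOfRangeError(
                f"{name} concentration leaves the calibrated range [{lo}, {hi}] ug/mL"
            )
    rng = noise.rng("fluorescence")
    out: list[IntensityReading] = []
    for site, conc in (("before_filter", c_bf), ("after_filter", c_af)):
        signal = np.asarray(curve.forward(conc)) - curve.background
        factors = noise.lognormal_factors(rng, t.size)
        intensities = curve.background + signal * factors
        out.extend(
            IntensityReading(float(ti), site, float(ii))
            for ti, ii in zip(t, intensities)
        )
    out.sort(key=lambda r: (r.time, r.site))
    return out


def generate_release_assay(
    model: ReleaseModel,
    temperatures: Sequence[float],
    dwell_times: Sequence[float],
    noise: NoiseSpec,
) -> list[ReleaseAssayPoint]:
    """Release-assay table on a temperature x dwell grid with clipped noise.

    Additive Gaussian noise with standard deviation ``cv * fraction`` is
    applied and the result clipped to [0, 1], mimicking replicate scatter
    in the millifluidic release assay.
    """
    rng = noise.rng("release_assay")
    points: list[ReleaseAssayPoint] = []
    for temp in temperatures:
        for dwell in dwell_times:
            f = float(model.release_fraction(temp, dwell))
            if noise.cv > 0:
                f = float(np.clip(f + rng.normal(0.0, noise.cv * max(f, 1e-12)), 0.0, 1.0))
            points.append(ReleaseAssayPoint(temp, dwell, f))
    return points
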