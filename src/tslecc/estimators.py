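"""Measurement-side estimators: removed mass, half-life, AUC, transit time.

These mirror what is computed from serial blood samples during an
extracorporeal filtration run: the trapezoid approximation of the removed
drug mass

    m_Dox = integral of F * (1 - Hct) * (c_BF - c_AF) dt,

a log-linear terminal half-life, the area under the plasma
concentration-time curve (with optional tail extrapolation from the
terminal slope), the time for one blood volume to transit the circuit, and
the predicted single-pass removal of the heater + filter combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ExtrapolationError,
    InputValidationError,
    NoDecayError,
)
from .pk import Trajectory
from .release import ReleaseModel

__all__ = [
    "BloodSample",
    "SampleSeries",
    "SAMPLING_SITES",
    "trapezoid_removed_mass",
    "cumulative_removed_mass",
    "fit_half_life",
    "auc",
    "one_volume_pass_time",
    "single_pass_removal",
    "read_sample_series",
]

SAMPLING_SITES = ("systemic", "before_filter", "after_filter")


@dataclass(frozen=True)
class BloodSample:
    """One plasma concentration measurement."""

    time: float
    site: str
    plasma_concentration: float

    def __post_init__(self) -> None:
        if self.site not in SAMPLING_SITES:
            raise InputValidationError(
                f"site {self.site!r} not one of {SAMPLING_SITES}"
            )
        if self.time < 0:
            raise InputValidationError("sample time must be nonnegative")
        if self.plasma_concentration < 0:
            raise InputValidationError("concentration must be nonnegative")


@dataclass(frozen=True)
class SampleSeries:
    """Time-ordered plasma concentrations at one sampling site."""

    site: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if self.site not in SAMPLING_SITES:
            raise InputValidationError(
                f"site {self.site!r} not one of {SAMPLING_SITES}"
            )
        if t.ndim != 1 or t.shape != c.shape:
            raise InputValidationError("times and concentrations must be 1-d and equal length")
        if t.size < 2:
            raise InputValidationError("a series needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise InputValidationError("sample times must be strictly increasing")
        if np.any(c < 0):
            raise InputValidationError("concentrations must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_samples(cls, samples: Sequence[BloodSample]) -> "SampleSeries":
        sites = {s.site for s in samples}
        if len(sites) != 1:
            raise InputValidationError("samples mix sites; one series per site")
        ordered = sorted(samples, key=lambda s: s.time)
        return cls(
            site=ordered[0].site,
            times=np.array([s.time for s in ordered]),
            concentrations=np.array([s.plasma_concentration for s in ordered]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "site": self.site,
                "conc_ug_per_ml": self.concentrations,
            }
        )


def read_sample_series(path: str | Path) -> dict[str, SampleSeries]:
    """Read delimited text with columns time_min, site, conc_ug_per_ml.

    Returns one :class:`SampleSeries` per site present in the file.
    """
    df = pd.read_csv(path)
    required = {"time_min", "site", "conc_ug_per_ml"}
    missing = required - set(df.columns)
    if missing:
        raise InputValidationError(f"sample file missing columns: {sorted(missing)}")
    out: dict[str, SampleSeries] = {}
    for site, grp in df.groupby("site"):
        grp = grp.sort_values("time_min")
        out[str(site)] = SampleSeries(
            site=str(site),
            times=grp["time_min"].to_numpy(float),
            concentrations=grp["conc_ug_per_ml"].to_numpy(float),
        )
    return out


def _trapezoid_cumulative(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid integral of y dx, starting at 0.

    Shared by the batch and streaming removed-mass estimators so the two are
    bit-for-bit identical on the same data (sequential accumulation order).
    """
    inc = np.diff(x) * 0.5 * (y[1:] + y[:-1])
    return np.concatenate([[0.0], np.cumsum(inc)])


def cumulative_removed_mass(
    before: SampleSeries, after: SampleSeries, flow: float, hct: float
) -> np.ndarray:
    """Running trapezoid estimate of removed mass [µg] at each sample time."""
    if flow <= 0:
        raise InputValidationError("blood flow must be positive")
    if not 0 < hct < 1:
        raise InputValidationError("hematocrit must be in (0, 1)")
    if before.times.shape != after.times.shape or np.any(
        before.times != after.times
    ):
        raise InputValidationError(
            "before- and after-filter series must share identical sampling times"
        )
    diff = before.concentrations - after.concentrations
    if np.any(diff < 0):
        warnings.warn(
            "after-filter concentration exceeds before-filter at some times; "
            "negative removal increments retained (measurement noise)",
            stacklevel=2,
        )
    return flow * (1.0 - hct) * _trapezoid_cumulative(before.times, diff)


def trapezoid_removed_mass(
    before: SampleSeries, after: SampleSeries, flow: float, hct: float
) -> float:
    """Removed drug mass [µg] by trapezoid integration of paired samples.

    ``flow`` is the whole-blood flow [mL/min]; multiplying by ``1 - Hct``
    converts it to the plasma flow that carries the drug.
    """
    return float(cumulative_removed_mass(before, after, flow, hct)[-1])


def fit_half_life(series: SampleSeries) -> float:
    """Log-linear terminal half-life [min] from a concentration series.

    Requires at least 3 strictly positive samples; raises
    :class:`NoDecayError` when the fitted slope is not negative.
    """
    if len(series) < 3:
        raise InputValidationError("half-life fit needs at least 3 samples")
    if np.any(series.concentrations <= 0):
        raise InputValidationError("half-life fit needs strictly positive concentrations")
    res = stats.linregress(series.times, np.log(series.concentrations))
    if res.slope >= 0:
        raise NoDecayError(f"fitted slope {res.slope:.3g} >= 0: no decay")
    return float(np.log(2.0) / -res.slope)


def _lambda_z(times: np.ndarray, conc: np.ndarray, n_tail: int) -> float:
    if n_tail < 2:
        raise InputValidationError("lambda_z needs at least 2 tail points")
    t = times[-n_tail:]
    c = conc[-n_tail:]
    if np.any(c <= 0):
        raise ExtrapolationError("non-positive terminal concentrations")
    res = stats.linregress(t, np.log(c))
    if res.slope >= 0:
        raise ExtrapolationError(
            f"terminal slope {res.slope:.3g} >= 0; cannot extrapolate to infinity"
        )
    return float(-res.slope)


def auc(
    series: "SampleSeries | Trajectory | tuple[np.ndarray, np.ndarray]",
    *,
    extrapolate_to_infinity: bool = False,
    n_tail: int = 3,
    log_trapezoid_tail: bool = False,
) -> float:
    """Area under the concentration-time curve [µg·min/mL].

    Accepts a :class:`SampleSeries`, a ``(times, concentrations)`` pair, or a
    :class:`~tslecc.pk.Trajectory` (total systemic plasma concentration).
    With ``extrapolate_to_infinity`` the observed trapezoid area is extended
    by ``C_last / lambda_z``, where the terminal rate ``lambda_z`` comes from
    a log-linear fit of the last ``n_tail`` points.  ``log_trapezoid_tail``
    switches the observed-range rule to log-trapezoid between the tail
    points (default off: plain trapezoid, matching the removal integral).
    """
    if isinstance(series, Trajectory):
        t, c = series.t, series.conc_total
    elif isinstance(series, SampleSeries):
        t, c = series.times, series.concentrations
    else:
        t, c = (np.asarray(a, dtype=float) for a in series)
    if t.size < 2:
        raise InputValidationError("AUC needs at least 2 points")

    if log_trapezoid_tail:
        area = 0.0
        for i in range(t.size - 1):
            c0, c1 = c[i], c[i + 1]
            dt = t[i + 1] - t[i]
            if i >= t.size - 1 - n_tail and c0 > 0 and c1 > 0 and c0 != c1:
                area += dt * (c0 - c1) / np.log(c0 / c1)
            else:
                area += dt * 0.5 * (c0 + c1)
    else:
        area = float(np.trapezoid(c, t))

    if extrapolate_to_infinity:
        lz = _lambda_z(t, c, n_tail)
        area += float(c[-1]) / lz
    return float(area)


def one_volume_pass_time(
    blood_volume: float, priming_volume: float, flow: float
) -> float:
    """Minutes for one circulating volume (blood + priming) to transit the filter."""
    if flow <= 0:
        raise InputValidationError("flow must be positive")
    if blood_volume <= 0 or priming_volume < 0:
        raise InputValidationError("volumes must be positive (priming may be zero)")
    return (blood_volume + priming_volume) / flow


def single_pass_removal(
    release: ReleaseModel,
    temperature: float,
    dwell: float,
    filter_efficacy: float,
) -> float:
    """Predicted fraction of total drug removed in one heater + filter pass.

    Only drug released by the heater is adsorbable; intact liposomes pass
    through the filter unretained, so the prediction is
    ``release_fraction(T, dwell) * filter_efficacy``.
    """
    if not 0.0 <= filter_efficacy <= 1.0:
        raise InputValidationError("filter_efficacy must be in [0, 1]")
    return float(release.release_fraction(temperature, dwell)) * filter_efficacy
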