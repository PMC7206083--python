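"""Real-time impedance (RTCA) cytotoxicity quantification.

An impedance biosensor reports adherent target-cell mass as resistance.
The instrument conventions implemented here:

    CI(t)  = (R(f_n, t) - R(f_n, t0)) / Z_n
    NCI(t) = CI(t) / CI(t_norm),   requiring CI(t_norm) != 0

where f_n is the measurement frequency, R(f_n, t0) the background
impedance and Z_n the frequency factor of f_n.  Normalization time t_norm
defaults to the moment effector cells are added, so every well starts the
co-culture at NCI = 1 and killing reads out as NCI falling below the
no-effector control well.

Percent cytolysis against the matched control,
``100 * (NCI_control - NCI_effector) / NCI_control``, is a standard RTCA
killing readout (documented convention; negative values — effector wells
outgrowing the control — are reported as-is).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ImpedanceTrace",
    "NciSeries",
    "MonotonicityVerdict",
    "cell_index",
    "cell_index_series",
    "normalized_cell_index",
    "percent_cytolysis",
    "cytolysis_series",
    "dose_monotonicity",
    "rescue_effect",
]

_CI_ZERO_EPS = 1e-12


class NormalizationError(ValueError):
    """CI at the normalization time is zero; NCI is undefined."""


@dataclass(frozen=True)
class ImpedanceTrace:
    """Resistance of one well over time at a single measurement frequency."""

    well: str
    condition: str
    times: np.ndarray  # hours, strictly increasing
    resistance: np.ndarray  # ohm
    r0: float  # background impedance R(f_n, t0)
    zn: float  # frequency factor of f_n

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        resistance = np.asarray(self.resistance, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "resistance", resistance)
        if times.ndim != 1 or times.shape != resistance.shape:
            raise ValueError("times and resistance must be 1-D and equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.zn <= 0:
            raise ValueError("Zn must be positive")

    def _index_of(self, t: float) -> int:
        if self.times.size == 0:
            raise ValueError("empty trace")
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(
                f"t={t} outside trace support [{self.times[0]}, {self.times[-1]}]"
            )
        return int(np.argmin(np.abs(self.times - t)))


def cell_index(trace: ImpedanceTrace, t: float) -> float:
    """CI(t) = (R(t) - R0) / Zn at the nearest sampled time (no
    extrapolation outside the trace)."""
    i = trace._index_of(t)
    return float((trace.resistance[i] - trace.r0) / trace.zn)


def cell_index_series(trace: ImpedanceTrace) -> np.ndarray:
    return (trace.resistance - trace.r0) / trace.zn


@dataclass(frozen=True)
class NciSeries:
    condition: str
    times: np.ndarray
    values: np.ndarray
    t_norm: float

    def at(self, t: float) -> float:
        """Value at time t; linear interpolation between samples (the
        study sampled every 30 min on a uniform grid, so this is a
        fallback for mismatched grids)."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} outside series support")
        return float(np.interp(t, self.times, self.values))


def normalized_cell_index(trace: ImpedanceTrace, t_norm: float) -> NciSeries:
    """NCI(t) = CI(t) / CI(t_norm); exact 1 at the normalization time.

    Raises :class:`NormalizationError` when CI(t_norm) = 0 (the formula's
    stated exclusion).
    """
    ci = cell_index_series(trace)
    ci_norm = ci[trace._index_of(t_norm)]
    if abs(ci_norm) <= _CI_ZERO_EPS:
        raise NormalizationError(
            f"CI(t_norm={t_norm}) = 0 in well {trace.well!r}; NCI undefined"
        )
    return NciSeries(
        condition=trace.condition,
        times=trace.times.copy(),
        values=ci / ci_norm,
        t_norm=t_norm,
    )


def percent_cytolysis(
    effector_nci: NciSeries, control_nci: NciSeries, t: float
) -> float:
    """100 * (NCI_control(t) - NCI_effector(t)) / NCI_control(t).

    Both series must share the normalization time (effector addition);
    the control is the no-effector ("media") well.
    """
    if effector_nci.t_norm != control_nci.t_norm:
        raise ValueError("series must share the normalization time")
    c = control_nci.at(t)
    e = effector_nci.at(t)
    if c == 0:
        raise ZeroDivisionError("control NCI is 0 at the requested time")
    return 100.0 * (c - e) / c


def cytolysis_series(
    effector_nci: NciSeries, control_nci: NciSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Cytolysis over the overlap of the two time grids, evaluated on the
    effector grid."""
    t0 = max(effector_nci.times[0], control_nci.times[0])
    t1 = min(effector_nci.times[-1], control_nci.times[-1])
    mask = (effector_nci.times >= t0) & (effector_nci.times <= t1)
    times = effector_nci.times[mask]
    ctrl = np.interp(times, control_nci.times, control_nci.values)
    eff = effector_nci.values[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        lysis = 100.0 * (ctrl - eff) / ctrl
    return times, lysis


@dataclass(frozen=True)
class MonotonicityVerdict:
    dose_dependent: bool
    violations: tuple[tuple[float, float], ...]  # (lower ratio, higher ratio)


def dose_monotonicity(
    cytolysis_by_ratio: Mapping[float, float],
) -> MonotonicityVerdict:
    """Verdict "dose-dependent" iff terminal cytolysis is non-decreasing
    in the effector:target ratio; otherwise the violating ratio pairs are
    listed."""
    ratios = sorted(cytolysis_by_ratio)
    if len(ratios) < 2:
        raise ValueError("need at least two E:T ratios")
    violations = [
        (lo, hi)
        for lo, hi in zip(ratios, ratios[1:])
        if cytolysis_by_ratio[hi] < cytolysis_by_ratio[lo]
    ]
    return MonotonicityVerdict(
        dose_dependent=not violations, violations=tuple(violations)
    )


def rescue_effect(
    treated_nci: NciSeries,
    untreated_nci: NciSeries,
    control_nci: NciSeries,
    horizon: float = 21.0,
) -> float:
    """Percentage-point attenuation of killing by a treatment (blocking
    antibody or drug): cytolysis(untreated) - cytolysis(treated) at the
    horizon.  Positive values mean the treatment rescued target viability.
    """
    return percent_cytolysis(untreated_nci, control_nci, horizon) - percent_cytolysis(
        treated_nci, control_nci, horizon
    )
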