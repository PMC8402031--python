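"""One-compartment, first-order-elimination kinetics for intermittent IV infusions.

Closed-form solutions for zero-order input (constant-rate infusion) into a single
well-stirred compartment, linear superposition across repeated doses, and the
steady-state exposure identity AUC24 = daily dose / CL.  All times are hours on a
single internal clock whose origin is the start of the first infusion; sampling
schedules quoted as "h after end of infusion" are converted by adding the infusion
duration before they reach this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParameters",
    "DoseEvent",
    "Regimen",
    "elimination_params",
    "conc_single_infusion",
    "conc_profile",
    "auc_steady_state",
]


@dataclass(frozen=True)
class PKParameters:
    """Individual disposition parameters.

    Attributes
    ----------
    CL : float
        Clearance (L/h); must be positive.
    Vd : float
        Apparent volume of distribution (L); must be positive.
    """

    CL: float
    Vd: float

    def __post_init__(self) -> None:
        if not (self.CL > 0):
            raise ValueError(f"CL must be positive, got {self.CL}")
        if not (self.Vd > 0):
            raise ValueError(f"Vd must be positive, got {self.Vd}")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant (1/h)."""
        return self.CL / self.Vd

    @property
    def t_half(self) -> float:
        """Elimination half-life (h)."""
        return math.log(2.0) / self.ke


@dataclass(frozen=True)
class DoseEvent:
    """A single constant-rate IV infusion.

    ``start_time`` is hours since the first dose; ``amount`` in mg;
    ``infusion_duration`` in hours (0.5 h = the 30-min infusions used clinically).
    """

    start_time: float
    amount: float
    infusion_duration: float = 0.5

    def __post_init__(self) -> None:
        if not (self.amount > 0):
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if not (self.infusion_duration > 0):
            raise ValueError(
                f"infusion duration must be positive, got {self.infusion_duration}"
            )
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")

    @property
    def rate(self) -> float:
        """Zero-order input rate R0 (mg/h)."""
        return self.amount / self.infusion_duration


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of infusions with a nominal dosing interval (h)."""

    events: tuple[DoseEvent, ...]
    interval: float

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise ValueError("regimen must contain at least one dose event")
        starts = [e.start_time for e in self.events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("dose events must be sorted by start_time")
        if not (self.interval > 0):
            raise ValueError(f"interval must be positive, got {self.interval}")

    @property
    def daily_dose(self) -> float:
        """Nominal daily dose (mg/day) for a uniform regimen."""
        return 24.0 / self.interval * self.events[0].amount

    @classmethod
    def uniform(
        cls,
        amount: float,
        interval: float,
        n_doses: int,
        infusion_duration: float = 0.5,
    ) -> "Regimen":
        """Build an every-``interval``-hours regimen of ``n_doses`` equal infusions."""
        if n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        events = tuple(
            DoseEvent(i * interval, amount, infusion_duration) for i in range(n_doses)
        )
        return cls(events=events, interval=interval)


def elimination_params(pk: PKParameters) -> tuple[float, float]:
    """Return ``(ke, t_half)`` — elimination rate constant (1/h) and half-life (h)."""
    return pk.ke, pk.t_half


def conc_single_infusion(pk: PKParameters, event: DoseEvent, t) -> np.ndarray | float:
    """Concentration (mg/L) from one infusion at time(s) ``t`` on the dosing clock.

    During the infusion (elapsed tau <= T_inf)::

        C = (R0 / CL) * (1 - exp(-ke * tau))

    after the infusion::

        C = (R0 / CL) * (1 - exp(-ke * T_inf)) * exp(-ke * (tau - T_inf))

    The two branches agree at tau = T_inf (continuity).  Raises for times before
    the infusion starts.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < event.start_time):
        raise ValueError("time precedes the start of this infusion")
    out = _conc_infusion_raw(
        pk.CL, pk.Vd, event.start_time, event.amount, event.infusion_duration, t_arr
    )
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def _conc_infusion_raw(CL, Vd, start, amount, dur, t):
    """Vectorised single-infusion concentration; zero before the dose starts.

    Accepts array-valued CL/Vd broadcastable against ``t`` (used by the
    population machinery where every subject has its own parameters).
    """
    CL = np.asarray(CL, dtype=float)
    Vd = np.asarray(Vd, dtype=float)
    t = np.asarray(t, dtype=float)
    ke = CL / Vd
    tau = t - start
    r0 = amount / dur
    active = tau > 0
    tau_inf = np.minimum(np.where(active, tau, 0.0), dur)
    decay = np.where(active, np.maximum(tau - dur, 0.0), 0.0)
    c = (r0 / CL) * (1.0 - np.exp(-ke * tau_inf)) * np.exp(-ke * decay)
    return np.where(active | (tau == 0), c, 0.0)


def conc_profile(pk: PKParameters, regimen: Regimen, times) -> np.ndarray:
    """Total concentration at ``times`` (h) by superposition over all infusions.

    Linear kinetics: contributions of every dose with start_time <= t add.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    total = np.zeros_like(t)
    for ev in regimen.events:
        total += _conc_infusion_raw(
            pk.CL, pk.Vd, ev.start_time, ev.amount, ev.infusion_duration, t
        )
    return total


def auc_steady_state(pk: PKParameters, daily_dose: float) -> float:
    """Steady-state 24-h area under the curve, AUC24 = daily dose / CL (mg·h/L).

    Holds exactly for any linear-elimination model regardless of Vd.
    """
    if not (daily_dose > 0):
        raise ValueError(f"daily_dose must be positive, got {daily_dose}")
    return daily_dose / pk.CL
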