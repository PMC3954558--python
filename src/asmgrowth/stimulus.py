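"""Exacerbation forcing: event schedules and prescribed inflammation profiles.

Acute inflammatory events ("exacerbations") are modelled as instantaneous
additive impulses of magnitude ``a`` applied to the inflammatory status mu,
which otherwise decays exponentially at the clearance rate lambda_d.  Event
timing is either strictly periodic with frequency omega (events/day) or a
homogeneous Poisson process of the same rate, so that both share the mean
event count ``omega * horizon`` over the observation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

__all__ = [
    "StimulusSpec",
    "EventSchedule",
    "PrescribedMuProfile",
    "make_schedule",
    "apply_event",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Statistical description of the exacerbation stimulus.

    ``magnitude`` is the per-event jump of mu (units of mu, i.e. of mu1);
    ``omega`` the (mean) event frequency in events/day; ``horizon`` the
    observation window in days.  ``seed`` is required for the Poisson mode;
    ``first_event_at_zero`` fixes the phase of the periodic mode (the event
    train then carries exactly ceil/floor(omega*horizon) events in the
    window, the first at t = 0).
    """

    mode: str
    magnitude: float
    omega: float
    horizon: float
    seed: Optional[int] = None
    first_event_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("periodic", "poisson"):
            raise ValidationError(f"mode must be 'periodic' or 'poisson', got {self.mode!r}")
        if not np.isfinite(self.magnitude) or self.magnitude < 0:
            raise ValidationError(f"magnitude must be non-negative, got {self.magnitude!r}")
        if not np.isfinite(self.omega) or self.omega < 0:
            raise ValidationError(f"omega must be non-negative, got {self.omega!r}")
        if not self.horizon > 0:
            raise ValidationError(f"horizon must be positive, got {self.horizon!r}")
        if self.mode == "poisson" and self.seed is None:
            raise ValidationError("poisson mode requires an integer seed")


@dataclass(frozen=True)
class EventSchedule:
    """Ordered exacerbation times on [0, horizon) with per-event magnitudes."""

    times: np.ndarray
    magnitudes: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        mags = np.asarray(self.magnitudes, dtype=float)
        if times.shape != mags.shape or times.ndim != 1:
            raise ValidationError("times and magnitudes must be 1-d arrays of equal length")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValidationError("event times must be strictly increasing")
            if times[0] < 0 or times[-1] >= self.horizon:
                raise ValidationError("event times must lie in [0, horizon)")
            if np.any(mags < 0):
                raise ValidationError("event magnitudes must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "magnitudes", mags)

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def empty(cls, horizon: float) -> "EventSchedule":
        return cls(times=np.empty(0), magnitudes=np.empty(0), horizon=horizon)


@dataclass(frozen=True)
class PrescribedMuProfile:
    """Piecewise-constant inflammatory status: level i holds on [breakpoints[i], breakpoints[i+1]).

    The last level extends beyond the final breakpoint.  Used to drive the
    cell population directly (no events, no decay), e.g. for the stepwise
    hysteresis experiment.
    """

    breakpoints: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        bps = np.asarray(self.breakpoints, dtype=float)
        lvl = np.asarray(self.levels, dtype=float)
        if bps.ndim != 1 or bps.shape != lvl.shape or bps.size == 0:
            raise ValidationError("breakpoints and levels must be equal-length 1-d arrays")
        if bps.size > 1 and np.any(np.diff(bps) <= 0):
            raise ValidationError("breakpoints must be strictly increasing")
        if np.any(lvl < 0):
            raise ValidationError("mu levels must be non-negative")
        object.__setattr__(self, "breakpoints", bps)
        object.__setattr__(self, "levels", lvl)

    def mu_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        if idx < 0:
            raise ValidationError(f"profile does not cover t={t}")
        return float(self.levels[idx])


def make_schedule(spec: StimulusSpec) -> EventSchedule:
    """Realise an event schedule from a stimulus description.

    Periodic: events at ``t_k = k/omega`` truncated to [0, horizon), with
    ``k`` starting at 0 or 1 depending on ``first_event_at_zero``.  Poisson:
    i.i.d. exponential inter-arrival gaps of mean ``1/omega`` drawn from a
    generator seeded with ``spec.seed`` (same seed, bit-identical schedule).
    ``omega = 0`` yields an empty schedule in either mode.
    """
    if spec.omega == 0:
        return EventSchedule.empty(spec.horizon)
    # guard against float round-up emitting an event at the horizon
    edge = spec.horizon * (1.0 - 1e-12)
    if spec.mode == "periodic":
        k0 = 0 if spec.first_event_at_zero else 1
        k_max = int(np.floor(spec.omega * spec.horizon)) + 1
        times = np.arange(k0, k_max + 1, dtype=float) / spec.omega
        times = times[times < edge]
    else:
        rng = np.random.default_rng(spec.seed)
        times_list: list[float] = []
        t = 0.0
        while True:
            t += rng.exponential(1.0 / spec.omega)
            if t >= edge:
                break
            times_list.append(t)
        times = np.asarray(times_list)
    mags = np.full(times.shape, spec.magnitude)
    return EventSchedule(times=times, magnitudes=mags, horizon=spec.horizon)


def apply_event(mu_before: float, magnitude: float) -> float:
    """Instantaneous impulse: mu jumps additively by the event magnitude."""
    if mu_before < 0:
        raise ValidationError(f"mu_before must be non-negative, got {mu_before}")
    if magnitude < 0:
        raise ValidationError(f"magnitude must be non-negative, got {magnitude}")
    return mu_before + magnitude
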