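"""Core dynamical system for inflammation-driven airway smooth muscle (ASM) hyperplasia.

The model tracks two ASM cell sub-populations in an airway wall, normalised
by the wall's carrying capacity ``V``:

* ``p`` — cells in the proliferative state (replication plus recruitment),
* ``c`` — cells in the non-proliferative state,

with total population ``s = p + c`` (so ``s <= 1``).  Proliferation is
logistic with rate ``lambda_p``; cells leave the proliferative state at
rate ``lambda_pc`` and re-enter it at rate ``lambda_cp``; non-proliferative
cells undergo apoptosis at rate ``lambda_a``:

    dp/dt = lambda_p * p * (1 - p - c) - lambda_pc * p + lambda_cp * c
    dc/dt = lambda_pc * p - lambda_cp * c - lambda_a * c

A scalar *inflammatory status* ``mu`` — a lumped surrogate for all
downstream triggers of ASM mass increase — modulates the recruitment rate
``lambda_cp`` through two sensitivity thresholds ``mu1 < mu2``, defining
three regimes (healthy / moderate / severe) with step-wise increasing
``lambda_cp``.  Between exacerbation events ``mu`` decays exponentially at
the inflammation clearance rate ``lambda_d``, so regime switching times are
available in closed form; the cell subsystem is integrated with an adaptive
Runge-Kutta scheme on segments of constant regime.

Rates are expressed per day and ``mu`` in units of the first threshold
``mu1`` (only the ratios ``mu/mu1`` and ``mu2/mu1`` matter).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from ._integrators import HAVE_NUMBA, _dp45_cells
from .errors import IntegrationError, ValidationError

__all__ = [
    "Regime",
    "ModelParams",
    "CellState",
    "RegimeSegment",
    "DEFAULT_LAMBDA_P",
    "switching_rate",
    "smoothed_switching_rate",
    "regime_from_mu",
    "mu_decay",
    "mu_decay_and_crossings",
    "integrate_cells_segment",
    "integrate_cells_segment_dense",
]

#: Reference ASM proliferation rate, 1/day (in vitro estimate).
DEFAULT_LAMBDA_P = 1.0 / 3.0

#: Slow "remodelling" timescale, days (documentation-only alias).
REMODELLING_TIMESCALE_DAYS = 100.0


class Regime(IntEnum):
    """Inflammation regime, set by mu relative to the thresholds.

    ``HEALTHY``: mu < mu1; ``MODERATE``: mu1 <= mu < mu2;
    ``SEVERE``: mu >= mu2 (thresholds inclusive upward).
    """

    HEALTHY = 0
    MODERATE = 1
    SEVERE = 2


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and thresholds of the ASM growth model.

    All rates are per day.  Defaults encode the reference ratios
    ``lambda_pc/lambda_p = 50``, ``lambda_cp/lambda_p in {0.016, 0.8, 40}``
    across the healthy/moderate/severe regimes, ``lambda_a/lambda_p =
    4e-4`` and ``mu2/mu1 = 2.5``, with ``lambda_p = 1/3 / day``.

    ``mu`` is measured in units of ``mu1`` (default ``mu1 = 1``); absolute
    values of the thresholds never enter the dynamics, only ratios do.
    """

    lambda_p: float = DEFAULT_LAMBDA_P
    lambda_pc: float = 50.0 * DEFAULT_LAMBDA_P
    lambda_cp_levels: tuple[float, float, float] = (
        0.016 * DEFAULT_LAMBDA_P,
        0.8 * DEFAULT_LAMBDA_P,
        40.0 * DEFAULT_LAMBDA_P,
    )
    lambda_a: float = 4.0e-4 * DEFAULT_LAMBDA_P
    lambda_d: float = DEFAULT_LAMBDA_P
    mu1: float = 1.0
    mu2: float = 2.5

    def __post_init__(self) -> None:
        rates = {
            "lambda_p": self.lambda_p,
            "lambda_pc": self.lambda_pc,
            "lambda_a": self.lambda_a,
            "lambda_d": self.lambda_d,
        }
        for name, value in rates.items():
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"{name} must be a finite non-negative rate, got {value!r}")
        levels = tuple(float(v) for v in self.lambda_cp_levels)
        if len(levels) != 3:
            raise ValidationError("lambda_cp_levels must have exactly three entries")
        if any(not np.isfinite(v) or v < 0 for v in levels):
            raise ValidationError("lambda_cp_levels must be finite and non-negative")
        if not (levels[0] < levels[1] < levels[2]):
            raise ValidationError("lambda_cp_levels must be strictly increasing across regimes")
        if not (0 < self.mu1 < self.mu2):
            raise ValidationError(
                f"thresholds must satisfy 0 < mu1 < mu2, got mu1={self.mu1!r}, mu2={self.mu2!r}"
            )
        object.__setattr__(self, "lambda_cp_levels", levels)
        # Timescale-separation assumptions are advisory: explorations outside
        # them are allowed but flagged.
        if self.lambda_p > 0 and self.lambda_a > 0.1 * self.lambda_p:
            warnings.warn(
                "lambda_a is not << lambda_p; the slow-apoptosis assumption is violated",
                stacklevel=2,
            )
        if self.lambda_p > 0 and self.lambda_pc < 10.0 * self.lambda_p:
            warnings.warn(
                "lambda_pc is not >> lambda_p; the fast p->c switching assumption is violated",
                stacklevel=2,
            )

    @classmethod
    def from_ratios(
        cls,
        *,
        lambda_p: float = DEFAULT_LAMBDA_P,
        lambda_pc_rel: float = 50.0,
        lambda_cp_rel_levels: Sequence[float] = (0.016, 0.8, 40.0),
        lambda_a_rel: float = 4.0e-4,
        ir: float = 1.0,
        mu1: float = 1.0,
        mu2_rel: float = 2.5,
    ) -> "ModelParams":
        """Build parameters from the normalised ratios of the growth survey.

        ``ir = lambda_d / lambda_p`` is the inflammation resolution rate.
        """
        return cls(
            lambda_p=lambda_p,
            lambda_pc=lambda_pc_rel * lambda_p,
            lambda_cp_levels=tuple(v * lambda_p for v in lambda_cp_rel_levels),
            lambda_a=lambda_a_rel * lambda_p,
            lambda_d=ir * lambda_p,
            mu1=mu1,
            mu2=mu2_rel * mu1,
        )

    def with_ir(self, ir: float) -> "ModelParams":
        """Return a copy with the inflammation resolution rate set to ``ir``."""
        return replace(self, lambda_d=ir * self.lambda_p)

    @property
    def ir(self) -> float:
        """Inflammation resolution rate IR = lambda_d / lambda_p."""
        return self.lambda_d / self.lambda_p if self.lambda_p > 0 else math.inf

    @property
    def mu2_rel(self) -> float:
        """Severe threshold relative to the mild one, mu2/mu1."""
        return self.mu2 / self.mu1

    @property
    def remodelling_timescale(self) -> float:
        """Slow remodelling timescale T, days (documentation-only alias)."""
        return REMODELLING_TIMESCALE_DAYS

    @property
    def epsilon(self) -> float:
        """Timescale-separation parameter 1/(lambda_p*T) (documentation only).

        Never used in any computation; reported for reference alongside T.
        """
        return 1.0 / (self.lambda_p * self.remodelling_timescale)


@dataclass(frozen=True)
class CellState:
    """ASM sub-population sizes as fractions of the wall capacity V."""

    p: float
    c: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.p) and np.isfinite(self.c)):
            raise ValidationError("cell populations must be finite")
        if self.p < 0 or self.c < 0:
            raise ValidationError(f"cell populations must be non-negative, got p={self.p}, c={self.c}")
        if self.p + self.c > 1.0 + 1e-9:
            raise ValidationError(f"total population p + c = {self.p + self.c} exceeds capacity 1")

    @property
    def s(self) -> float:
        """Total ASM population s = p + c."""
        return self.p + self.c


@dataclass(frozen=True)
class RegimeSegment:
    """A maximal time interval on which the inflammation regime is constant."""

    t_start: float
    t_end: float
    regime: Regime
    mu_at_start: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValidationError("segment must have t_end > t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def regime_from_mu(mu: float, params: ModelParams) -> Regime:
    """Classify the inflammatory status into a regime (thresholds inclusive upward)."""
    if mu < 0:
        raise ValidationError(f"inflammatory status must be non-negative, got {mu}")
    if mu >= params.mu2:
        return Regime.SEVERE
    if mu >= params.mu1:
        return Regime.MODERATE
    return Regime.HEALTHY


def switching_rate(mu, params: ModelParams):
    """Recruitment rate lambda_cp(mu), a three-level step function (1/day).

    Accepts a scalar or an array of ``mu`` values.  Uses the inclusive-upward
    convention: ``mu >= mu2`` is severe, ``mu1 <= mu < mu2`` moderate.
    """
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(mu_arr < 0):
        raise ValidationError("inflammatory status must be non-negative")
    l0, l1, l2 = params.lambda_cp_levels
    out = np.select([mu_arr >= params.mu2, mu_arr >= params.mu1], [l2, l1], default=l0)
    if np.isscalar(mu) or mu_arr.ndim == 0:
        return float(out)
    return out


def smoothed_switching_rate(mu, params: ModelParams, delta: float = 0.01):
    """Logistic smoothing of lambda_cp(mu) with transition width ``delta*mu1``.

    Interpolates between the three levels in log-rate space so the smoothed
    curve converges to the step function as ``delta -> 0``.  Intended for
    convergence checks against dense smooth-ODE integrations, not for
    production simulations.
    """
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(mu_arr < 0):
        raise ValidationError("inflammatory status must be non-negative")
    if delta <= 0:
        raise ValidationError("smoothing width delta must be positive")
    l0, l1, l2 = (math.log(v) for v in params.lambda_cp_levels)
    w = delta * params.mu1
    sig1 = expit((mu_arr - params.mu1) / w)
    sig2 = expit((mu_arr - params.mu2) / w)
    log_rate = l0 + (l1 - l0) * sig1 + (l2 - l1) * sig2
    out = np.exp(log_rate)
    if np.isscalar(mu) or mu_arr.ndim == 0:
        return float(out)
    return out


def mu_decay(mu0: float, params: ModelParams, t) -> float:
    """Closed-form inflammatory status mu0 * exp(-lambda_d * t)."""
    return mu0 * np.exp(-params.lambda_d * np.asarray(t, dtype=float))


def mu_decay_and_crossings(
    mu0: float, params: ModelParams, dt_max: float
) -> tuple[list[tuple[float, Regime]], float]:
    """Threshold crossings of the decaying inflammatory status on (0, dt_max).

    Between events mu decays as ``mu0 * exp(-lambda_d * t)``, so each
    downward crossing of a threshold ``mu_th < mu0`` occurs at
    ``t = ln(mu0/mu_th) / lambda_d``.  Returns the strictly interior
    crossings in increasing time order, each tagged with the regime entered
    *after* the crossing, together with the terminal value ``mu(dt_max)``.

    ``lambda_d = 0`` is valid: mu is constant and there are no crossings.
    """
    if mu0 < 0:
        raise ValidationError(f"inflammatory status must be non-negative, got {mu0}")
    if not dt_max > 0:
        raise ValidationError(f"dt_max must be positive, got {dt_max}")
    lam = params.lambda_d
    mu_end = mu0 * math.exp(-lam * dt_max) if lam > 0 else mu0
    crossings: list[tuple[float, Regime]] = []
    if lam > 0 and mu0 > 0:
        for mu_th, new_regime in ((params.mu2, Regime.MODERATE), (params.mu1, Regime.HEALTHY)):
            if mu0 > mu_th:
                t_cross = math.log(mu0 / mu_th) / lam
                if 0.0 < t_cross < dt_max:
                    crossings.append((t_cross, new_regime))
    crossings.sort(key=lambda item: item[0])
    return crossings, mu_end


def _cell_rhs(lam_cp: float, params: ModelParams):
    lp, lpc, la = params.lambda_p, params.lambda_pc, params.lambda_a

    def rhs(t, y):
        p, c = y
        growth = lp * p * (1.0 - p - c)
        flux = lpc * p - lam_cp * c
        return (growth - flux, flux - la * c)

    return rhs


def _check_and_clip(y: np.ndarray, rtol: float) -> np.ndarray:
    slack = 10.0 * rtol
    if np.any(y < -slack) or np.any(y.sum(axis=0) > 1.0 + slack):
        raise IntegrationError(
            f"integrator output violates population invariants beyond tolerance: {y!r}"
        )
    return np.clip(y, 0.0, 1.0)


def integrate_cells_segment(
    state0: CellState,
    lambda_cp_const: float,
    params: ModelParams,
    dt: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CellState:
    """Advance the (p, c) subsystem by ``dt`` days at constant lambda_cp.

    Uses adaptive Runge-Kutta (RK45); the system is only mildly stiff within
    a regime because lambda_cp is held constant per segment.
    """
    if lambda_cp_const < 0:
        raise ValidationError("lambda_cp_const must be non-negative")
    if not dt > 0:
        raise ValidationError("dt must be positive")
    y = integrate_cells_segment_dense(
        state0, lambda_cp_const, params, np.array([dt]), rtol=rtol, atol=atol
    )
    return CellState(p=float(y[0, -1]), c=float(y[1, -1]))


def integrate_cells_segment_dense(
    state0: CellState,
    lambda_cp_const: float,
    params: ModelParams,
    t_eval: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """As :func:`integrate_cells_segment`, sampling the solution at ``t_eval``.

    ``t_eval`` are offsets from the segment start, increasing, with the last
    entry defining the segment length.  Returns an array of shape
    ``(2, len(t_eval))`` holding p and c.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    dt = float(t_eval[-1])
    y0 = (state0.p, state0.c)
    if state0.p == 0.0 and state0.c == 0.0:
        return np.zeros((2, t_eval.size))
    if HAVE_NUMBA:
        ys, status = _dp45_cells(
            state0.p,
            state0.c,
            params.lambda_p,
            params.lambda_pc,
            lambda_cp_const,
            params.lambda_a,
            t_eval,
            rtol,
            atol,
        )
        if status != 0:
            raise IntegrationError("segment integration failed: step size underflow")
        return _check_and_clip(ys, rtol)
    sol = solve_ivp(
        _cell_rhs(lambda_cp_const, params),
        (0.0, dt),
        y0,
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"segment integration failed: {sol.message}")
    return _check_and_clip(sol.y, rtol)
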