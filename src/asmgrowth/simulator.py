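"""Hybrid simulation of ASM growth under episodic inflammation.

Between consecutive breakpoints — exacerbation times plus analytically
computed threshold crossings of the decaying inflammatory status — mu
follows its closed form and the (p, c) cell subsystem is integrated with
the segment-constant recruitment rate lambda_cp.  At an event mu jumps by
the event magnitude.  Threshold crossings are therefore exact (up to float
rounding), which makes time-in-regime accounting exact as well.

Outcome metrics: the fold-increase s(horizon)/s(0); the outcome class
(healthy < 2-fold, moderate 2-8-fold, severe >= 8-fold, boundaries
inclusive upward); per-regime residence times; and an integral inflammation
severity (IS) index, IS = (omega/lambda_d) * ln(a/mu2) for a > mu2 (zero
otherwise), proportional to the expected total time spent above the severe
threshold when resolution is fast enough for events to act independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .model_core import (
    CellState,
    ModelParams,
    Regime,
    RegimeSegment,
    integrate_cells_segment_dense,
    mu_decay_and_crossings,
    regime_from_mu,
    switching_rate,
)
from .stimulus import EventSchedule, PrescribedMuProfile, StimulusSpec, apply_event

__all__ = [
    "Trajectory",
    "OutcomeSummary",
    "DEFAULT_INITIAL_STATE",
    "DEFAULT_HORIZON_DAYS",
    "simulate",
    "simulate_prescribed_mu",
    "summarize_outcome",
    "classify_fold",
    "inflammation_severity_index",
]

#: "Healthy" initial condition used throughout the growth-scenario survey.
DEFAULT_INITIAL_STATE = CellState(p=0.01, c=0.1)

#: Default observation window, days.
DEFAULT_HORIZON_DAYS = 300.0

#: Fold-increase boundaries of the outcome classes (inclusive upward).
FOLD_MODERATE = 2.0
FOLD_SEVERE = 8.0

_TIME_EPS = 1e-12


@dataclass
class Trajectory:
    """Sampled hybrid-simulation output plus the exact regime segmentation."""

    t: np.ndarray
    p: np.ndarray
    c: np.ndarray
    mu: np.ndarray
    regime: np.ndarray
    segments: list[RegimeSegment]
    events: EventSchedule
    params: ModelParams
    meta: dict = field(default_factory=dict)

    @property
    def s(self) -> np.ndarray:
        """Total ASM population s = p + c at the sample times."""
        return self.p + self.c

    @property
    def horizon(self) -> float:
        return float(self.t[-1])

    def fold_increase(self) -> float:
        s0 = self.p[0] + self.c[0]
        if s0 <= 0:
            raise ValidationError("fold-increase undefined for zero initial population")
        return float((self.p[-1] + self.c[-1]) / s0)

    def time_in_regime(self) -> dict[Regime, float]:
        """Exact residence time per regime, from the segment decomposition."""
        out = {regime: 0.0 for regime in Regime}
        for seg in self.segments:
            out[seg.regime] += seg.duration
        return out

    def final_state(self) -> CellState:
        return CellState(p=float(self.p[-1]), c=float(self.c[-1]))


@dataclass(frozen=True)
class OutcomeSummary:
    """End-of-horizon remodelling outcome of a single simulation."""

    fold_increase: float
    outcome_class: str
    time_in_regime: dict
    is_index: Optional[float] = None


def classify_fold(fold: float) -> str:
    """Outcome class from the fold-increase (boundaries inclusive upward)."""
    if fold >= FOLD_SEVERE:
        return "severe"
    if fold >= FOLD_MODERATE:
        return "moderate"
    return "healthy"


def inflammation_severity_index(spec: StimulusSpec, params: ModelParams) -> float:
    """Integral inflammation severity IS = (omega/lambda_d) * ln(a/mu2).

    Defined (positive) only when the event magnitude exceeds the severe
    threshold; otherwise individual events never reach the severe regime
    from rest and the index is zero.  At fast resolution, horizon * omega *
    ln(a/mu2)/lambda_d is the expected total time above mu2, so constant IS
    traces isolines of predicted long-term growth.
    """
    if params.lambda_d <= 0:
        raise ValidationError("IS index requires a positive clearance rate lambda_d")
    if spec.magnitude <= params.mu2:
        return 0.0
    return (spec.omega / params.lambda_d) * math.log(spec.magnitude / params.mu2)


def _sample_times(horizon: float, sample_dt: Optional[float]) -> np.ndarray:
    if sample_dt is None:
        return np.array([0.0, horizon])
    n = int(math.floor(horizon / sample_dt + 1e-9))
    grid = np.arange(n + 1, dtype=float) * sample_dt
    if grid[-1] < horizon - _TIME_EPS:
        grid = np.append(grid, horizon)
    else:
        grid[-1] = horizon
    return grid


class _TrajectoryBuilder:
    """Accumulates per-segment dense output into a single sampled trajectory."""

    def __init__(self, grid: np.ndarray, rtol: float, atol: float):
        self.grid = grid
        self.rtol = rtol
        self.atol = atol
        self.t: list[float] = []
        self.p: list[float] = []
        self.c: list[float] = []
        self.mu: list[float] = []
        self.regime: list[int] = []
        self.segments: list[RegimeSegment] = []

    def add_initial(self, state: CellState, mu: float, regime: Regime) -> None:
        self.t.append(0.0)
        self.p.append(state.p)
        self.c.append(state.c)
        self.mu.append(mu)
        self.regime.append(int(regime))

    def run_segment(
        self,
        t_a: float,
        t_b: float,
        state: CellState,
        mu_fn,
        regime: Regime,
        lam_cp: float,
        params: ModelParams,
    ) -> CellState:
        """Integrate one constant-regime segment, recording samples in (t_a, t_b]."""
        lo = np.searchsorted(self.grid, t_a + _TIME_EPS, side="left")
        hi = np.searchsorted(self.grid, t_b - _TIME_EPS, side="right")
        interior = self.grid[lo:hi]
        t_out = np.append(interior, t_b)
        y = integrate_cells_segment_dense(
            state, lam_cp, params, t_out - t_a, rtol=self.rtol, atol=self.atol
        )
        self.t.extend(t_out.tolist())
        self.p.extend(y[0].tolist())
        self.c.extend(y[1].tolist())
        self.mu.extend(np.asarray(mu_fn(t_out), dtype=float).tolist())
        self.regime.extend([int(regime)] * t_out.size)
        self.segments.append(
            RegimeSegment(
                t_start=t_a, t_end=t_b, regime=regime, mu_at_start=float(mu_fn(np.array([t_a]))[0])
            )
        )
        return CellState(p=float(y[0, -1]), c=float(y[1, -1]))

    def build(self, events: EventSchedule, params: ModelParams, meta: dict) -> Trajectory:
        return Trajectory(
            t=np.asarray(self.t),
            p=np.asarray(self.p),
            c=np.asarray(self.c),
            mu=np.asarray(self.mu),
            regime=np.asarray(self.regime, dtype=int),
            segments=self.segments,
            events=events,
            params=params,
            meta=meta,
        )


def simulate(
    params: ModelParams,
    schedule: EventSchedule,
    initial: CellState = DEFAULT_INITIAL_STATE,
    mu0: float = 0.0,
    horizon: float = DEFAULT_HORIZON_DAYS,
    sample_dt: Optional[float] = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    meta: Optional[dict] = None,
) -> Trajectory:
    """Run the full hybrid scheme over ``[0, horizon]`` days.

    ``sample_dt`` sets the uniform output grid (breakpoints are always
    included so regime accounting is exact); pass ``None`` to record only
    segment boundaries, which is cheaper for outcome-only ensembles.
    """
    if mu0 < 0:
        raise ValidationError("mu0 must be non-negative")
    if not horizon > 0:
        raise ValidationError("horizon must be positive")
    builder = _TrajectoryBuilder(_sample_times(horizon, sample_dt), rtol, atol)

    ev_mask = schedule.times < horizon
    ev_times = schedule.times[ev_mask]
    ev_mags = schedule.magnitudes[ev_mask]

    mu_cur = mu0
    state = initial
    # event exactly at t = 0 fires before the first segment
    start_idx = 0
    if ev_times.size and ev_times[0] <= _TIME_EPS:
        mu_cur = apply_event(mu_cur, float(ev_mags[0]))
        start_idx = 1

    bounds = np.concatenate([[0.0], ev_times[start_idx:], [horizon]])
    event_at_bound = [False] * 1 + [True] * (ev_times.size - start_idx) + [False]
    mags_at_bound = np.concatenate([[0.0], ev_mags[start_idx:], [0.0]])

    builder.add_initial(state, mu_cur, regime_from_mu(mu_cur, params))

    lam_d = params.lambda_d
    for i in range(len(bounds) - 1):
        t_a, t_b = float(bounds[i]), float(bounds[i + 1])
        if t_b - t_a <= _TIME_EPS:
            pass
        else:
            crossings, mu_end = mu_decay_and_crossings(mu_cur, params, t_b - t_a)
            sub = [t_a] + [t_a + tc for tc, _ in crossings] + [t_b]
            mu_at_ta = mu_cur
            for u, v in zip(sub[:-1], sub[1:]):
                if v - u <= _TIME_EPS:
                    continue
                mu_mid = mu_at_ta * math.exp(-lam_d * (0.5 * (u + v) - t_a))
                regime = regime_from_mu(mu_mid, params)
                lam_cp = params.lambda_cp_levels[int(regime)]

                def mu_fn(ts, _mu0=mu_at_ta, _t0=t_a):
                    return _mu0 * np.exp(-lam_d * (np.asarray(ts) - _t0))

                state = builder.run_segment(u, v, state, mu_fn, regime, lam_cp, params)
            mu_cur = mu_end
        if event_at_bound[i + 1]:
            mu_cur = apply_event(mu_cur, float(mags_at_bound[i + 1]))

    run_meta = {"mu0": mu0, "horizon": horizon, "sample_dt": sample_dt}
    if meta:
        run_meta.update(meta)
    return builder.build(schedule, params, run_meta)


def simulate_prescribed_mu(
    params: ModelParams,
    profile: PrescribedMuProfile,
    initial: CellState = DEFAULT_INITIAL_STATE,
    horizon: float = DEFAULT_HORIZON_DAYS,
    sample_dt: Optional[float] = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Hybrid simulation with mu clamped to a piecewise-constant profile.

    No clearance and no events apply: the profile *is* the inflammatory
    status.  The profile must start at t = 0 (its last level extends to the
    horizon).
    """
    if not horizon > 0:
        raise ValidationError("horizon must be positive")
    if profile.breakpoints[0] > _TIME_EPS:
        raise ValidationError("prescribed-mu profile must start at t = 0 (no gaps)")
    builder = _TrajectoryBuilder(_sample_times(horizon, sample_dt), rtol, atol)

    bps = profile.breakpoints
    levels = profile.levels
    keep = bps < horizon
    bps = bps[keep]
    levels = levels[keep]
    bounds = np.append(bps, horizon)

    state = initial
    builder.add_initial(state, float(levels[0]), regime_from_mu(float(levels[0]), params))
    for i in range(len(bounds) - 1):
        t_a, t_b = float(bounds[i]), float(bounds[i + 1])
        if t_b - t_a <= _TIME_EPS:
            continue
        level = float(levels[i])
        regime = regime_from_mu(level, params)
        lam_cp = switching_rate(level, params)

        def mu_fn(ts, _level=level):
            return np.full(np.asarray(ts).shape, _level)

        state = builder.run_segment(t_a, t_b, state, mu_fn, regime, lam_cp, params)

    meta = {"prescribed_mu": True, "horizon": horizon, "sample_dt": sample_dt}
    return builder.build(EventSchedule.empty(horizon), params, meta)


def summarize_outcome(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    spec: Optional[StimulusSpec] = None,
) -> OutcomeSummary:
    """Condense a trajectory into its end-of-horizon remodelling outcome.

    The IS index is reported only when the stimulus description is supplied
    (it is a property of the forcing statistics, not of one realisation).
    """
    params = params if params is not None else traj.params
    fold = traj.fold_increase()
    tir = {regime.name.lower(): t for regime, t in traj.time_in_regime().items()}
    is_index = inflammation_severity_index(spec, params) if spec is not None else None
    return OutcomeSummary(
        fold_increase=fold,
        outcome_class=classify_fold(fold),
        time_in_regime=tir,
        is_index=is_index,
    )
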