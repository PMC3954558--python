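"""Parameter sweeps over the inflammation landscape and growth isolines.

Maps the long-term remodelling outcome (300-day fold-increase) over planes
spanned by the normalised stimulus parameters — magnitude ``a/mu1``,
frequency ``omega/lambda_p`` and resolution rate ``IR = lambda_d/lambda_p``
— either deterministically (periodic schedules, one run per cell) or
stochastically (Poisson ensembles per cell: mean and CV).  Isolines of the
2- and 8-fold boundaries are extracted with marching squares and, on the
fast-resolution branch (IR > 1), compared against the analytic scaling
``IR ~ (omega/lambda_p) * ln(a/mu2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import linregress
from skimage.measure import find_contours

from .errors import InsufficientDataError, ValidationError
from .ensemble_uq import run_ensemble
from .model_core import CellState, ModelParams
from .simulator import DEFAULT_HORIZON_DAYS, DEFAULT_INITIAL_STATE, simulate
from .stimulus import StimulusSpec, make_schedule

__all__ = [
    "SweepAxis",
    "OutcomeGrid",
    "IsolineFit",
    "AXIS_NAMES",
    "default_axis",
    "run_sweep",
    "extract_isolines",
    "analytic_isoline_check",
]

#: Sweepable normalised parameters.
AXIS_NAMES = ("a_rel", "omega_rel", "ir")

#: Reference parameter ranges (log-spaced sweeps span these by default).
_AXIS_RANGES = {"a_rel": (0.1, 10.0), "omega_rel": (0.1, 1.0), "ir": (0.1, 10.0)}


@dataclass(frozen=True)
class SweepAxis:
    """One sweep dimension: a normalised parameter name and its values."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in AXIS_NAMES:
            raise ValidationError(f"axis name must be one of {AXIS_NAMES}, got {self.name!r}")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValidationError("axis values must be a non-empty 1-d array")
        if np.any(values <= 0):
            raise ValidationError("axis values must be positive")
        if np.any(np.diff(values) <= 0):
            raise ValidationError("axis values must be strictly increasing")
        object.__setattr__(self, "values", values)


def default_axis(name: str, num: int = 25) -> SweepAxis:
    """Log-spaced axis over the reference range of a normalised parameter."""
    lo, hi = _AXIS_RANGES[name]
    return SweepAxis(name=name, values=np.geomspace(lo, hi, num))


@dataclass
class OutcomeGrid:
    """Fold-increase matrix over a 2-d parameter sweep.

    ``fold[iy, ix]`` corresponds to ``(y.values[iy], x.values[ix])``.  In
    stochastic mode ``fold`` holds the ensemble mean and ``cv`` the ratio of
    ensemble SD to mean.  ``fixed`` records the non-swept normalised
    parameters; per-cell failures are listed in ``failures`` (as
    ``(iy, ix, message)``) with NaN entries in the matrices.
    """

    x: SweepAxis
    y: SweepAxis
    fold: np.ndarray
    mode: str
    fixed: dict
    cv: Optional[np.ndarray] = None
    n_runs: int = 1
    master_seed: Optional[int] = None
    failures: list = field(default_factory=list)


@dataclass(frozen=True)
class IsolineFit:
    """Regression of IR against ln(a/mu2) along a computed growth isoline."""

    slope: float
    intercept: float
    correlation: float
    n_points: int


def _cell_settings(
    base_params: ModelParams, fixed: dict, axis_values: dict
) -> tuple[ModelParams, float, float]:
    values = dict(fixed)
    values.update(axis_values)
    params = base_params.with_ir(values["ir"])
    magnitude = values["a_rel"] * params.mu1
    omega = values["omega_rel"] * params.lambda_p
    return params, magnitude, omega


def run_sweep(
    x_axis: SweepAxis,
    y_axis: SweepAxis,
    *,
    base_params: Optional[ModelParams] = None,
    a_rel: float = 1.0,
    omega_rel: float = 0.25,
    ir: float = 1.0,
    mode: str = "deterministic",
    horizon: float = DEFAULT_HORIZON_DAYS,
    initial: CellState = DEFAULT_INITIAL_STATE,
    n_runs: int = 1,
    master_seed: Optional[int] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OutcomeGrid:
    """Evaluate the 300-day fold-increase over a 2-d parameter grid.

    Deterministic mode runs one periodic-schedule simulation per cell;
    stochastic mode runs a Poisson ensemble of ``n_runs`` per cell, with
    per-cell seeds derived from ``(master_seed, iy, ix)`` so the grid is
    invariant under reordering or parallel evaluation of its cells.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ValidationError(f"mode must be 'deterministic' or 'stochastic', got {mode!r}")
    if x_axis.name == y_axis.name:
        raise ValidationError("sweep axes must differ")
    if mode == "stochastic":
        if master_seed is None:
            raise ValidationError("stochastic sweeps require a master_seed")
        if n_runs < 2:
            raise ValidationError("stochastic sweeps need n_runs >= 2")
    base_params = base_params if base_params is not None else ModelParams()
    fixed_all = {"a_rel": a_rel, "omega_rel": omega_rel, "ir": ir}
    fixed = {k: v for k, v in fixed_all.items() if k not in (x_axis.name, y_axis.name)}

    ny, nx = y_axis.values.size, x_axis.values.size
    fold = np.full((ny, nx), np.nan)
    cv = np.full((ny, nx), np.nan) if mode == "stochastic" else None
    failures: list = []

    for iy, yv in enumerate(y_axis.values):
        for ix, xv in enumerate(x_axis.values):
            axis_values = {y_axis.name: float(yv), x_axis.name: float(xv)}
            params, magnitude, omega = _cell_settings(base_params, fixed, axis_values)
            try:
                if mode == "deterministic":
                    spec = StimulusSpec(
                        mode="periodic", magnitude=magnitude, omega=omega, horizon=horizon
                    )
                    traj = simulate(
                        params,
                        make_schedule(spec),
                        initial=initial,
                        horizon=horizon,
                        sample_dt=None,
                        rtol=rtol,
                        atol=atol,
                    )
                    fold[iy, ix] = traj.fold_increase()
                else:
                    cell_seed = int(
                        np.random.SeedSequence([int(master_seed), iy, ix]).generate_state(1)[0]
                    )
                    spec = StimulusSpec(
                        mode="poisson", magnitude=magnitude, omega=omega, horizon=horizon, seed=0
                    )
                    dist = run_ensemble(
                        params,
                        spec,
                        initial=initial,
                        n_runs=n_runs,
                        master_seed=cell_seed,
                        rtol=rtol,
                        atol=atol,
                    )
                    fold[iy, ix] = dist.mean
                    cv[iy, ix] = dist.cv
            except Exception as exc:  # noqa: BLE001 - recorded, grid completes
                failures.append((iy, ix, str(exc)))

    return OutcomeGrid(
        x=x_axis,
        y=y_axis,
        fold=fold,
        mode=mode,
        fixed=fixed,
        cv=cv,
        n_runs=n_runs if mode == "stochastic" else 1,
        master_seed=master_seed,
        failures=failures,
    )


def _index_to_value(indices: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Map fractional grid indices to parameter values, linearly in log-space."""
    log_values = np.log(values)
    return np.exp(np.interp(indices, np.arange(values.size), log_values))


def extract_isolines(
    grid: OutcomeGrid, levels: Sequence[float] = (2.0, 8.0)
) -> dict[float, list[np.ndarray]]:
    """Marching-squares contours of the fold matrix at the requested levels.

    Contouring is linear on the grid indices (i.e. on log-transformed axes
    for log-spaced sweeps); each polyline is returned as an ``(n, 2)`` array
    of ``(x_value, y_value)`` parameter coordinates.  A level outside the
    data range yields an empty list, not an error.
    """
    out: dict[float, list[np.ndarray]] = {}
    for level in levels:
        polylines: list[np.ndarray] = []
        for contour in find_contours(grid.fold, float(level)):
            xs = _index_to_value(contour[:, 1], grid.x.values)
            ys = _index_to_value(contour[:, 0], grid.y.values)
            polylines.append(np.column_stack([xs, ys]))
        out[float(level)] = polylines
    return out


def analytic_isoline_check(
    polyline: np.ndarray,
    mu2_rel: float = 2.5,
    ir_min: float = 1.0,
) -> IsolineFit:
    """Fit the fast-resolution branch of an isoline to IR = k*ln(a/mu2) + b.

    ``polyline`` must be in ``(a_rel, ir)`` coordinates (a magnitude-vs-IR
    sweep).  Points with ``ir <= ir_min`` are outside the independent-events
    regime and points with ``a <= mu2`` are outside the law's domain; both
    are excluded.  The proportionality constant is fitted, not assumed.
    """
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or polyline.shape[1] != 2:
        raise ValidationError("polyline must be an (n, 2) array of (a_rel, ir) points")
    a_rel = polyline[:, 0]
    ir = polyline[:, 1]
    mask = (ir > ir_min) & (a_rel > mu2_rel)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 isoline points with ir > {ir_min} and a_rel > {mu2_rel}, got {int(mask.sum())}"
        )
    x = np.log(a_rel[mask] / mu2_rel)
    fit = linregress(x, ir[mask])
    return IsolineFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        correlation=float(fit.rvalue),
        n_points=int(mask.sum()),
    )
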