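"""Adaptive Dormand-Prince RK45 stepper specialised to the 2-state cell system.

The hybrid scheme integrates tens of constant-regime segments per
simulation and Monte Carlo ensembles run thousands of simulations, so the
per-segment overhead of a general-purpose ODE interface dominates the run
time.  This module provides a compiled adaptive RK45 (Dormand-Prince 5(4)
pair with standard proportional step control) for the specific two-variable
right-hand side; the integrator steps exactly onto every requested output
time.  If numba is unavailable the caller falls back to scipy's solve_ivp,
and the test suite cross-checks the two paths against each other and
against a fixed-step oracle.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard install
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


_MAX_STEPS_PER_SEGMENT = 10_000_000


@njit(cache=True)
def _dp45_cells(p0, c0, lp, lpc, lcp, la, t_out, rtol, atol):  # pragma: no cover - compiled
    """Integrate dp/dt, dc/dt at constant lambda_cp, sampling at t_out.

    Returns (ys, status) where ys has shape (2, len(t_out)) and status is
    0 on success, 1 if the step size underflowed.
    """
    n_out = t_out.shape[0]
    ys = np.empty((2, n_out))
    p = p0
    c = c0
    t = 0.0
    h = min(1e-3, t_out[n_out - 1])
    status = 0
    safety = 0.9

    for i_out in range(n_out):
        target = t_out[i_out]
        n_steps = 0
        while t < target - 1e-14:
            n_steps += 1
            if n_steps > _MAX_STEPS_PER_SEGMENT or h < 1e-13:
                status = 1
                break
            h_try = h
            clamped = False
            if t + h_try > target:
                h_try = target - t
                clamped = True

            # k1
            g = lp * p * (1.0 - p - c)
            f = lpc * p - lcp * c
            k1p = g - f
            k1c = f - la * c
            # k2
            yp = p + h_try * 0.2 * k1p
            yc = c + h_try * 0.2 * k1c
            g = lp * yp * (1.0 - yp - yc)
            f = lpc * yp - lcp * yc
            k2p = g - f
            k2c = f - la * yc
            # k3
            yp = p + h_try * (3.0 / 40.0 * k1p + 9.0 / 40.0 * k2p)
            yc = c + h_try * (3.0 / 40.0 * k1c + 9.0 / 40.0 * k2c)
            g = lp * yp * (1.0 - yp - yc)
            f = lpc * yp - lcp * yc
            k3p = g - f
            k3c = f - la * yc
            # k4
            yp = p + h_try * (44.0 / 45.0 * k1p - 56.0 / 15.0 * k2p + 32.0 / 9.0 * k3p)
            yc = c + h_try * (44.0 / 45.0 * k1c - 56.0 / 15.0 * k2c + 32.0 / 9.0 * k3c)
            g = lp * yp * (1.0 - yp - yc)
            f = lpc * yp - lcp * yc
            k4p = g - f
            k4c = f - la * yc
            # k5
            yp = p + h_try * (
                19372.0 / 6561.0 * k1p
                - 25360.0 / 2187.0 * k2p
                + 64448.0 / 6561.0 * k3p
                - 212.0 / 729.0 * k4p
            )
            yc = c + h_try * (
                19372.0 / 6561.0 * k1c
                - 25360.0 / 2187.0 * k2c
                + 64448.0 / 6561.0 * k3c
                - 212.0 / 729.0 * k4c
            )
            g = lp * yp * (1.0 - yp - yc)
            f = lpc * yp - lcp * yc
            k5p = g - f
            k5c = f - la * yc
            # k6
            yp = p + h_try * (
                9017.0 / 3168.0 * k1p
                - 355.0 / 33.0 * k2p
                + 46732.0 / 5247.0 * k3p
                + 49.0 / 176.0 * k4p
                - 5103.0 / 18656.0 * k5p
            )
            yc = c + h_try * (
                9017.0 / 3168.0 * k1c
                - 355.0 / 33.0 * k2c
                + 46732.0 / 5247.0 * k3c
                + 49.0 / 176.0 * k4c
                - 5103.0 / 18656.0 * k5c
            )
            g = lp * yp * (1.0 - yp - yc)
            f = lpc * yp - lcp * yc
            k6p = g - f
            k6c = f - la * yc
            # 5th-order solution (also k7 stage point)
            y5p = p + h_try * (
                35.0 / 384.0 * k1p
                + 500.0 / 1113.0 * k3p
                + 125.0 / 192.0 * k4p
                - 2187.0 / 6784.0 * k5p
                + 11.0 / 84.0 * k6p
            )
            y5c = c + h_try * (
                35.0 / 384.0 * k1c
                + 500.0 / 1113.0 * k3c
                + 125.0 / 192.0 * k4c
                - 2187.0 / 6784.0 * k5c
                + 11.0 / 84.0 * k6c
            )
            g = lp * y5p * (1.0 - y5p - y5c)
            f = lpc * y5p - lcp * y5c
            k7p = g - f
            k7c = f - la * y5c
            # embedded 4th-order solution
            y4p = p + h_try * (
                5179.0 / 57600.0 * k1p
                + 7571.0 / 16695.0 * k3p
                + 393.0 / 640.0 * k4p
                - 92097.0 / 339200.0 * k5p
                + 187.0 / 2100.0 * k6p
                + 1.0 / 40.0 * k7p
            )
            y4c = c + h_try * (
                5179.0 / 57600.0 * k1c
                + 7571.0 / 16695.0 * k3c
                + 393.0 / 640.0 * k4c
                - 92097.0 / 339200.0 * k5c
                + 187.0 / 2100.0 * k6c
                + 1.0 / 40.0 * k7c
            )

            sp = atol + rtol * max(abs(p), abs(y5p))
            sc = atol + rtol * max(abs(c), abs(y5c))
            ep = (y5p - y4p) / sp
            ec = (y5c - y4c) / sc
            err = np.sqrt(0.5 * (ep * ep + ec * ec))

            if err <= 1.0:
                t = target if (clamped or target - (t + h_try) < 1e-14) else t + h_try
                p = y5p
                c = y5c
                if err == 0.0:
                    factor = 5.0
                else:
                    factor = min(5.0, max(0.2, safety * err ** -0.2))
                h = h_try * factor if not clamped else max(h, h_try * factor)
            else:
                h = h_try * max(0.2, safety * err ** -0.2)
        if status == 1:
            break
        ys[0, i_out] = p
        ys[1, i_out] = c
    return ys, status
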