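"""Independent fixed-step integrators used as oracles by the test suite.

Implemented in plain Python/math, deliberately sharing no code with the
package's adaptive hybrid integrator.
"""

import math


def rk4_cells_constant(p0, c0, lp, lpc, lcp, la, dt, h=1e-3):
    """Fixed-step RK4 for the two-compartment system at constant lambda_cp."""

    def rhs(p, c):
        growth = lp * p * (1.0 - p - c)
        flux = lpc * p - lcp * c
        return growth - flux, flux - la * c

    n = max(1, round(dt / h))
    h = dt / n
    p, c = p0, c0
    for _ in range(n):
        k1p, k1c = rhs(p, c)
        k2p, k2c = rhs(p + 0.5 * h * k1p, c + 0.5 * h * k1c)
        k3p, k3c = rhs(p + 0.5 * h * k2p, c + 0.5 * h * k2c)
        k4p, k4c = rhs(p + h * k3p, c + h * k3c)
        p += h / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p)
        c += h / 6.0 * (k1c + 2 * k2c + 2 * k3c + k4c)
    return p, c


def _sigmoid(x):
    if x > 40.0:
        return 1.0
    if x < -40.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


def rk4_cells_smoothed_decay(
    p0, c0, lp, lpc, la, levels, mu1, mu2, mu_peak, ld, horizon, delta=0.003, h=1e-3
):
    """Dense RK4 with smoothly interpolated switching, mu(t) = mu_peak * exp(-ld*t).

    The recruitment rate interpolates the three step levels in log-rate
    space with logistic transitions of width ``delta * mu1``; as delta -> 0
    this converges to the threshold model, so the result is an independent
    reference for the event-free part of the hybrid scheme.
    """
    l0, l1, l2 = (math.log(v) for v in levels)
    w = delta * mu1

    def lcp_of(mu):
        s1 = _sigmoid((mu - mu1) / w)
        s2 = _sigmoid((mu - mu2) / w)
        return math.exp(l0 + (l1 - l0) * s1 + (l2 - l1) * s2)

    def rhs(t, p, c):
        lcp = lcp_of(mu_peak * math.exp(-ld * t))
        growth = lp * p * (1.0 - p - c)
        flux = lpc * p - lcp * c
        return growth - flux, flux - la * c

    n = round(horizon / h)
    h = horizon / n
    t, p, c = 0.0, p0, c0
    for _ in range(n):
        k1p, k1c = rhs(t, p, c)
        k2p, k2c = rhs(t + 0.5 * h, p + 0.5 * h * k1p, c + 0.5 * h * k1c)
        k3p, k3c = rhs(t + 0.5 * h, p + 0.5 * h * k2p, c + 0.5 * h * k2c)
        k4p, k4c = rhs(t + h, p + h * k3p, c + h * k3c)
        p += h / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p)
        c += h / 6.0 * (k1c + 2 * k2c + 2 * k3c + k4c)
        t += h
    return p, c
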