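"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: a fixed-step
classical RK4 integrator with step halving, plus brute-force grid search.
"""

import numpy as np


def rk4_integrate(rhs, y0, t_end, rtol=1e-8, n0=64):
    """Classic RK4 with step halving until successive answers agree."""
    prev = None
    n = n0
    while True:
        h = t_end / n
        y = np.array(y0, dtype=float)
        t = 0.0
        for _ in range(n):
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        if prev is not None and np.all(
            np.abs(y - prev) <= rtol * np.maximum(np.abs(y), 1e-12)
        ):
            return y
        prev = y
        n *= 2
        if n > 2**20:
            raise RuntimeError("RK4 oracle failed to converge")


def rk4_model(p, t_end, rtol=1e-8):
    """Integrate the full (X, S, P) system for KineticParameters p."""

    def rhs(t, y):
        x = y[0]
        dx = p.mu_max * x * (1.0 - x / p.X_max)
        ds = -(dx / p.Y_XS + p.M_s * x)
        dp = p.alpha * dx + p.beta * x
        return np.array([dx, ds, dp])

    return rk4_integrate(rhs, [p.X0, p.S0, p.P0], t_end, rtol=rtol)


def logistic_sse_grid(t, x_obs, x0, mu_grid, xmax_grid):
    """Brute-force SSE surface of the logistic fit with X0 held fixed."""
    sse = np.empty((mu_grid.size, xmax_grid.size))
    for i, mu in enumerate(mu_grid):
        for j, xmax in enumerate(xmax_grid):
            z = np.exp(-mu * t)
            pred = xmax * x0 / (x0 + (xmax - x0) * z)
            sse[i, j] = np.sum((pred - x_obs) ** 2)
    return sse
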