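"""Closed-form and ODE trajectories of the unstructured batch model.

The model couples three ordinary differential equations:

* biomass ``X`` follows logistic growth,
  ``dX/dt = mu_max * X * (1 - X / X_max)``;
* product ``P`` follows Luedeking-Piret kinetics,
  ``dP/dt = alpha * dX/dt + beta * X``;
* sugar ``S`` is consumed by growth plus maintenance,
  ``-dS/dt = (1 / Y_XS) * dX/dt + M_s * X``.

All three admit closed forms once the logistic solution and its running
integral are known, so trajectories can be evaluated either analytically
(``method="closed_form"``) or by numerical integration (``method="ode"``);
the two must agree and that agreement is exercised by the test suite.

Units: time in days, biomass in g DW/L, sugar and product titer in g/L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    DomainError,
    InvalidParameterError,
    NegativeConcentrationWarning,
)

__all__ = [
    "KineticParameters",
    "ModelState",
    "TimeCourse",
    "logistic_biomass",
    "biomass_integral",
    "product_titer",
    "sugar_residual",
    "simulate",
    "peak_growth_rate",
]


@dataclass(frozen=True)
class KineticParameters:
    """The six model constants plus initial conditions.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate, 1/day.
    X_max : float
        Carrying capacity (maximum biomass dry weight), g DW/L.
    alpha : float
        Growth-associated product yield, g product per g DW.
    beta : float
        Non-growth-associated production rate, g product per g DW per day.
    Y_XS : float
        Biomass-on-sugar yield, g DW per g sugar.  May be ``inf`` when the
        data support no growth-linked consumption.
    M_s : float
        Maintenance coefficient, g sugar per g DW per day.
    X0, S0, P0 : float
        Initial biomass, sugar and product titer.  Defaults match the
        synthetic-data conventions used throughout the package.
    """

    mu_max: float
    X_max: float
    alpha: float = 0.0
    beta: float = 0.0
    Y_XS: float = 1.0
    M_s: float = 0.0
    X0: float = 0.5
    S0: float = 35.0
    P0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_max) or self.mu_max < 0:
            raise InvalidParameterError(f"mu_max must be finite and >= 0, got {self.mu_max}")
        if not np.isfinite(self.X_max) or self.X_max <= 0:
            raise InvalidParameterError(f"X_max must be finite and > 0, got {self.X_max}")
        if not np.isfinite(self.X0) or self.X0 <= 0 or self.X0 > self.X_max:
            raise InvalidParameterError(
                f"X0 must satisfy 0 < X0 <= X_max, got X0={self.X0}, X_max={self.X_max}"
            )
        if not (self.Y_XS > 0):  # inf allowed
            raise InvalidParameterError(f"Y_XS must be > 0, got {self.Y_XS}")
        for name in ("alpha", "beta", "M_s", "S0", "P0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")

    def replace(self, **changes) -> "KineticParameters":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {
            "mu_max": self.mu_max,
            "X_max": self.X_max,
            "alpha": self.alpha,
            "beta": self.beta,
            "Y_XS": self.Y_XS,
            "M_s": self.M_s,
            "X0": self.X0,
            "S0": self.S0,
            "P0": self.P0,
        }


@dataclass(frozen=True)
class ModelState:
    """Instantaneous state of the culture."""

    X: float
    S: float
    P: float
    t: float


@dataclass
class TimeCourse:
    """Observed or simulated (t, X, S, P) series with optional replicates.

    Any of ``X``/``S``/``P`` may be ``None``; fitting uses whatever is
    present.  Rows must be sorted by time (replicates may share a time).
    """

    times: np.ndarray
    X: Optional[np.ndarray] = None
    S: Optional[np.ndarray] = None
    P: Optional[np.ndarray] = None
    replicate: Optional[np.ndarray] = None
    strain_label: str = field(default="")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.size and (np.any(self.times < 0) or np.any(np.diff(self.times) < 0)):
            raise ValueError("times must be non-negative and sorted ascending")
        for name in ("X", "S", "P"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must have the same length as times")
            if np.any(arr[np.isfinite(arr)] < 0):
                # model-predicted sugar may dip below zero; observed data are
                # checked strictly at the I/O layer instead
                warnings.warn(
                    f"{name} contains negative values",
                    NegativeConcentrationWarning,
                    stacklevel=2,
                )
            setattr(self, name, arr)
        if self.replicate is not None:
            rep = np.asarray(self.replicate)
            if rep.shape != self.times.shape:
                raise ValueError("replicate must have the same length as times")
            self.replicate = rep.astype(int)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_points(self) -> int:
        return int(np.unique(self.times).size)


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    return t


def logistic_biomass(t, p: KineticParameters):
    """Biomass X(t) of the logistic law, g DW/L.

    Evaluates ``X(t) = X_max / (1 + ((X_max - X0)/X0) * exp(-mu_max t))``,
    which is numerically stable for large ``mu_max * t``.
    """
    t = _check_times(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    z = np.exp(-p.mu_max * t)
    denom = p.X0 + (p.X_max - p.X0) * z
    x = p.X_max * p.X0 / denom
    return float(x[0]) if scalar else x


def biomass_integral(t, p: KineticParameters):
    """Running integral of biomass, ``int_0^t X dtau``, g DW day/L.

    Closed form ``(X_max/mu_max) * ln[(X_max - X0 + X0 e^{mu t}) / X_max]``,
    rewritten to avoid overflow; reduces to ``X0 * t`` when ``mu_max = 0``.
    """
    t = _check_times(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if p.mu_max == 0:
        out = p.X0 * t
    else:
        z = np.exp(-p.mu_max * t)
        denom = p.X0 + (p.X_max - p.X0) * z
        out = (p.X_max / p.mu_max) * (p.mu_max * t + np.log(denom / p.X_max))
    return float(out[0]) if scalar else out


def product_titer(t, p: KineticParameters):
    """Product titer P(t), g/L.

    Closed form ``P0 + alpha*(X(t) - X0) + beta * int_0^t X``.
    """
    x = logistic_biomass(t, p)
    integral = biomass_integral(t, p)
    return p.P0 + p.alpha * (x - p.X0) + p.beta * integral


def sugar_residual(t, p: KineticParameters):
    """Residual sugar S(t), g/L.

    Closed form ``S0 - (X(t) - X0)/Y_XS - M_s * int_0^t X``.  The value can
    become negative mathematically; a warning is emitted, no clamping.
    """
    x = logistic_biomass(t, p)
    integral = biomass_integral(t, p)
    growth_term = 0.0 if np.isinf(p.Y_XS) else (x - p.X0) / p.Y_XS
    s = p.S0 - growth_term - p.M_s * integral
    if np.any(np.atleast_1d(s) < 0):
        warnings.warn(
            "predicted residual sugar is negative; model extrapolated past depletion",
            NegativeConcentrationWarning,
            stacklevel=2,
        )
    return s


def _ode_rhs(t, y, p: KineticParameters):
    x = y[0]
    dx = p.mu_max * x * (1.0 - x / p.X_max)
    ds = -((0.0 if np.isinf(p.Y_XS) else dx / p.Y_XS) + p.M_s * x)
    dp = p.alpha * dx + p.beta * x
    return [dx, ds, dp]


def simulate(
    p: KineticParameters,
    times: Sequence[float],
    method: str = "closed_form",
    strain_label: str = "",
) -> TimeCourse:
    """Simulate the noiseless trajectory at the requested times.

    Parameters
    ----------
    method : {"closed_form", "ode"}
        Analytical solution or adaptive Runge-Kutta integration of the
        coupled system; the two agree to ~1e-6 relative error.
    """
    t = _check_times(times)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) < 0)):
        raise DomainError("times must be a sorted one-dimensional sequence")
    if method == "closed_form":
        x = logistic_biomass(t, p)
        s = sugar_residual(t, p)
        prod = product_titer(t, p)
    elif method == "ode":
        t_span = (0.0, float(t[-1]) if t.size else 0.0)
        sol = solve_ivp(
            _ode_rhs,
            t_span,
            [p.X0, p.S0, p.P0],
            t_eval=t,
            args=(p,),
            method="RK45",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        x, s, prod = sol.y
    else:
        raise DomainError(f"unknown simulation method {method!r}; use 'closed_form' or 'ode'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeConcentrationWarning)
        return TimeCourse(
            times=t,
            X=np.asarray(x, dtype=float),
            S=np.asarray(s, dtype=float),
            P=np.asarray(prod, dtype=float),
            strain_label=strain_label,
        )


def peak_growth_rate(p: KineticParameters) -> float:
    """Maximum volumetric growth rate max_t dX/dt, g DW/L/day.

    For the logistic law the rate peaks at ``X = X_max / 2`` giving
    ``mu_max * X_max / 4``; if the culture starts past the inflection point
    (``X0 >= X_max/2``) the maximum over t >= 0 is the initial rate.
    """
    if p.X0 < p.X_max / 2.0:
        return p.mu_max * p.X_max / 4.0
    return p.mu_max * p.X0 * (1.0 - p.X0 / p.X_max)
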