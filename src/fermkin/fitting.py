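"""Nonlinear least-squares estimation of the kinetic parameters.

The model has a triangular structure: biomass dynamics do not depend on
product or sugar, and given a biomass trajectory both the product equation
(linear in ``alpha``, ``beta``) and the sugar equation (linear in
``1/Y_XS``, ``M_s``) reduce to non-negative linear least squares.  The
default *sequential* strategy exploits this: a multi-start trust-region fit
of the logistic growth curve, followed by two conditional linear solves.
A *joint* strategy refits all parameters simultaneously against the three
weighted responses for parity with one-shot curve-fitting software.

Multi-start local optimization with seeded random starts inside the bounds
replaces global optimizers; starts are drawn sequentially from one
generator so that increasing ``n_starts`` only ever adds candidate starts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares, nnls

from .errors import (
    DegenerateDataError,
    DegenerateStatisticError,
    MissingResponseError,
    UnderdeterminedError,
)
from .kinetics import (
    KineticParameters,
    TimeCourse,
    biomass_integral,
    logistic_biomass,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "GoodnessOfFit",
    "goodness_of_fit",
    "fit_biomass",
    "fit_product",
    "fit_sugar",
    "fit_full",
]


@dataclass(frozen=True)
class FitConfig:
    """Controls the estimation strategy, bounds and multi-start behavior."""

    strategy: str = "sequential"
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 20
    seed: int = 0
    tolerance: float = 1e-12
    fix: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in ("sequential", "joint"):
            raise ValueError(f"strategy must be 'sequential' or 'joint', got {self.strategy!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bound for {name} has lower > upper")


@dataclass
class FitResult:
    """Estimated parameters with per-response and pooled goodness of fit.

    ``r2``/``f_value``/``sse``/``sst``/``n_obs`` are keyed by response name
    ("X", "S", "P"); ``r2`` additionally carries a "pooled" entry
    ``1 - sum(SSE)/sum(SST)`` across the fitted responses.
    """

    params: KineticParameters
    se: Optional[Dict[str, float]] = None
    r2: Dict[str, float] = field(default_factory=dict)
    f_value: Dict[str, float] = field(default_factory=dict)
    sse: Dict[str, float] = field(default_factory=dict)
    sst: Dict[str, float] = field(default_factory=dict)
    n_obs: Dict[str, int] = field(default_factory=dict)
    converged: bool = False
    n_starts_used: int = 0
    seed: int = 0

    @property
    def total_sse(self) -> float:
        return float(sum(self.sse.values()))

    def to_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "se": self.se,
            "r2": self.r2,
            "f_value": {k: (None if math.isinf(v) else v) for k, v in self.f_value.items()},
            "sse": self.sse,
            "sst": self.sst,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


GoodnessOfFit = Tuple[float, float, float, float]


def goodness_of_fit(observed, predicted, n_params: int) -> GoodnessOfFit:
    """Return ``(r2, f_value, sse, sst)`` for one response.

    ``r2 = 1 - SSE/SST`` with SST about the observed mean;
    ``F = (SSR / p) / (SSE / (n - p - 1))`` with ``p = n_params`` and
    ``SSR = SST - SSE``.  A perfect fit reports ``F = inf``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < n_params + 2:
        raise UnderdeterminedError(
            f"need at least n_params + 2 = {n_params + 2} observations, got {n}"
        )
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateStatisticError("constant observations: R^2 undefined (SST = 0)")
    r2 = 1.0 - sse / sst
    ssr = sst - sse
    if sse == 0.0:
        f = math.inf
    else:
        f = (ssr / n_params) / (sse / (n - n_params - 1))
    return r2, f, sse, sst


# ---------------------------------------------------------------------------
# helpers

def _require(data: TimeCourse, name: str) -> np.ndarray:
    arr = getattr(data, name)
    if arr is None:
        raise MissingResponseError(f"time course has no {name!r} series")
    mask = np.isfinite(arr)
    if not mask.any():
        raise MissingResponseError(f"{name!r} series contains no finite values")
    return mask


def _initial_value(data: TimeCourse, name: str) -> float:
    """Mean of the observations at the earliest sampled time."""
    arr = getattr(data, name)
    t0 = data.times.min()
    at0 = arr[(data.times == t0) & np.isfinite(arr)]
    if at0.size == 0:
        raise DegenerateDataError(f"no finite {name} observation at the earliest time")
    return float(at0.mean())


def _default_bounds(data: TimeCourse) -> Dict[str, Tuple[float, float]]:
    xmax_obs = float(np.nanmax(data.X)) if data.X is not None else 10.0
    xmax_obs = max(xmax_obs, 1e-6)
    return {
        "mu_max": (0.0, 5.0),
        "X_max": (1e-6, 5.0 * xmax_obs),
        "X0": (1e-9, 5.0 * xmax_obs),
        "alpha": (0.0, np.inf),
        "beta": (0.0, np.inf),
        "Y_XS": (1e-9, np.inf),
        "M_s": (0.0, np.inf),
    }


def _biomass_guess(t: np.ndarray, x: np.ndarray) -> Tuple[float, float, float]:
    """Heuristic (mu_max, X_max, X0) start from the data."""
    xmax0 = 1.05 * float(np.max(x))
    x00 = max(float(x[np.argmin(t)]), 1e-6)
    # slope of ln X over the first three distinct times
    order = np.argsort(t)
    ts, xs = t[order], x[order]
    distinct = np.unique(ts)[:3]
    pick = np.isin(ts, distinct) & (xs > 0)
    if pick.sum() >= 2 and np.ptp(ts[pick]) > 0:
        slope = np.polyfit(ts[pick], np.log(xs[pick]), 1)[0]
        mu0 = float(np.clip(slope, 1e-3, 4.9))
    else:
        mu0 = 0.3
    return mu0, min(xmax0, 5.0 * float(np.max(x))), min(x00, xmax0)


def _logistic_pred(t: np.ndarray, mu: float, xmax: float, x0: float) -> np.ndarray:
    # tolerate x0 > xmax transiently during optimization (still well-defined)
    z = np.exp(-mu * t)
    return xmax * x0 / (x0 + (xmax - x0) * z)


def _draw_starts(rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray, n: int) -> np.ndarray:
    """n starts drawn one at a time so a longer run extends a shorter one."""
    span_hi = np.where(np.isinf(hi), np.maximum(10.0 * np.abs(lo), 10.0), hi)
    return np.array([rng.uniform(lo, span_hi) for _ in range(n)])


# ---------------------------------------------------------------------------
# biomass

def fit_biomass(data: TimeCourse, cfg: FitConfig = FitConfig()) -> FitResult:
    """Fit the logistic growth curve: estimates (mu_max, X_max, X0).

    Multi-start trust-region least squares; the first start is a heuristic
    built from the data, the rest are seeded random points in the bounds.
    """
    mask = _require(data, "X")
    t = data.times[mask]
    x = data.X[mask]
    if np.unique(t).size < 4:
        raise UnderdeterminedError("need at least 4 distinct time points with biomass")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("biomass is constant: growth parameters unidentifiable")

    bounds = {**_default_bounds(data), **cfg.bounds}
    names = ["mu_max", "X_max", "X0"]
    free = [n for n in names if n not in cfg.fix]
    if len(t) < len(free):
        raise UnderdeterminedError("fewer observations than free parameters")
    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])

    def unpack(theta: np.ndarray) -> Tuple[float, float, float]:
        vals = dict(zip(free, theta))
        vals = {**cfg.fix, **vals}
        return vals["mu_max"], vals["X_max"], vals["X0"]

    def residuals(theta: np.ndarray) -> np.ndarray:
        mu, xmax, x0 = unpack(theta)
        return _logistic_pred(t, mu, xmax, x0) - x

    guess_full = dict(zip(names, _biomass_guess(t, x)))
    x0_heuristic = np.clip(np.array([guess_full[n] for n in free]), lo, np.minimum(hi, 1e12))

    rng = np.random.default_rng(cfg.seed)
    starts = [x0_heuristic]
    if cfg.n_starts > 1:
        starts.extend(_draw_starts(rng, lo, hi, cfg.n_starts - 1))

    best = None
    for s in starts:
        try:
            sol = least_squares(
                residuals, s, bounds=(lo, hi), method="trf",
                xtol=cfg.tolerance, ftol=cfg.tolerance, gtol=cfg.tolerance,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimization starts failed")

    mu, xmax, x0 = unpack(best.x)
    x0 = min(x0, xmax)  # boundary solutions may overshoot by rounding
    params = KineticParameters(mu_max=mu, X_max=xmax, X0=x0)
    pred = _logistic_pred(t, mu, xmax, x0)
    r2, f, sse, sst = goodness_of_fit(x, pred, n_params=len(free))
    return FitResult(
        params=params,
        r2={"X": r2, "pooled": r2},
        f_value={"X": f},
        sse={"X": sse},
        sst={"X": sst},
        n_obs={"X": int(len(x))},
        converged=bool(best.success),
        n_starts_used=len(starts),
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# conditionally linear responses

def _conditional_linear_fit(
    data: TimeCourse,
    growth: KineticParameters,
    response: str,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Design matrix [(X - X0), int X] and shifted response for NNLS."""
    mask = _require(data, response)
    t = data.times[mask]
    y_raw = getattr(data, response)[mask]
    if len(t) < 4:
        raise UnderdeterminedError(f"need at least 4 {response} observations")

    x_model = logistic_biomass(t, growth)
    integral = biomass_integral(t, growth)
    a = np.column_stack([x_model - growth.X0, integral])
    y0 = _initial_value(data, response)
    y = (y_raw - y0) if response == "P" else (y0 - y_raw)
    if np.linalg.norm(a[:, 0]) < 1e-12 and np.linalg.norm(a[:, 1]) < 1e-12:
        raise DegenerateDataError("biomass trajectory is flat: coefficients unidentifiable")
    return a, y, y_raw, y0


def fit_product(
    data: TimeCourse,
    growth: KineticParameters,
    cfg: FitConfig = FitConfig(),
) -> FitResult:
    """Estimate (alpha, beta) given fitted growth parameters.

    The product equation is linear in (alpha, beta) once X(t) is known, so
    the estimate is the exact non-negative linear least-squares solution.
    """
    a, y, y_raw, p0 = _conditional_linear_fit(data, growth, "P")
    p0 = cfg.fix.get("P0", p0)
    if "P0" in cfg.fix:
        y = y_raw - p0
    coef, _ = nnls(a, y)
    alpha, beta = float(coef[0]), float(coef[1])
    if "alpha" in cfg.fix:
        alpha = cfg.fix["alpha"]
        coef_b, _ = nnls(a[:, 1:], y - alpha * a[:, 0])
        beta = float(coef_b[0])
    if "beta" in cfg.fix:
        beta = cfg.fix["beta"]
        coef_a, _ = nnls(a[:, :1], y - beta * a[:, 1])
        alpha = float(coef_a[0])
    params = growth.replace(alpha=alpha, beta=beta, P0=p0)
    pred = p0 + a @ [alpha, beta]
    r2, f, sse, sst = goodness_of_fit(y_raw, pred, n_params=2)
    return FitResult(
        params=params,
        r2={"P": r2, "pooled": r2},
        f_value={"P": f},
        sse={"P": sse},
        sst={"P": sst},
        n_obs={"P": int(len(y_raw))},
        converged=True,
        n_starts_used=1,
        seed=cfg.seed,
    )


def fit_sugar(
    data: TimeCourse,
    growth: KineticParameters,
    cfg: FitConfig = FitConfig(),
) -> FitResult:
    """Estimate (Y_XS, M_s) given fitted growth parameters.

    Regresses consumed sugar on [(X - X0), int X] under non-negativity of
    (1/Y_XS, M_s).  A zero growth-consumption coefficient maps to
    ``Y_XS = inf``.
    """
    a, y, y_raw, s0 = _conditional_linear_fit(data, growth, "S")
    s0 = cfg.fix.get("S0", s0)
    if "S0" in cfg.fix:
        y = s0 - y_raw
    if np.ptp(y_raw) == 0.0 and np.ptp(logistic_biomass(data.times, growth)) < 1e-12:
        raise DegenerateDataError("constant sugar and biomass: yield unidentifiable")
    coef, _ = nnls(a, y)
    inv_y, m_s = float(coef[0]), float(coef[1])
    if "Y_XS" in cfg.fix:
        inv_y = 1.0 / cfg.fix["Y_XS"]
        coef_m, _ = nnls(a[:, 1:], y - inv_y * a[:, 0])
        m_s = float(coef_m[0])
    if "M_s" in cfg.fix:
        m_s = cfg.fix["M_s"]
        coef_y, _ = nnls(a[:, :1], y - m_s * a[:, 1])
        inv_y = float(coef_y[0])
    y_xs = math.inf if inv_y == 0.0 else 1.0 / inv_y
    params = growth.replace(Y_XS=y_xs, M_s=m_s, S0=s0)
    pred = s0 - a @ [inv_y, m_s]
    r2, f, sse, sst = goodness_of_fit(y_raw, pred, n_params=2)
    return FitResult(
        params=params,
        r2={"S": r2, "pooled": r2},
        f_value={"S": f},
        sse={"S": sse},
        sst={"S": sst},
        n_obs={"S": int(len(y_raw))},
        converged=True,
        n_starts_used=1,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# full model

def _merge_results(parts: Dict[str, FitResult], params: KineticParameters,
                   converged: bool, n_starts: int, seed: int) -> FitResult:
    out = FitResult(params=params, converged=converged,
                    n_starts_used=n_starts, seed=seed)
    for res in parts.values():
        for attr in ("r2", "f_value", "sse", "sst", "n_obs"):
            for k, v in getattr(res, attr).items():
                if k != "pooled":
                    getattr(out, attr)[k] = v
    tot_sse = sum(out.sse.values())
    tot_sst = sum(out.sst.values())
    out.r2["pooled"] = 1.0 - tot_sse / tot_sst if tot_sst > 0 else math.nan
    return out


def fit_full(data: TimeCourse, cfg: FitConfig = FitConfig()) -> FitResult:
    """Fit every parameter the available responses can identify.

    Sequential strategy (default): biomass first, then the two conditional
    linear solves.  Joint strategy: one weighted nonlinear least-squares
    problem over all free parameters, started from the sequential solution
    plus seeded random starts; residuals of each response are scaled by its
    observed range so the responses contribute comparably.
    """
    if data.X is None:
        raise MissingResponseError("biomass (X) is required to fit the growth model")

    fb = fit_biomass(data, cfg)
    parts: Dict[str, FitResult] = {"X": fb}
    params = fb.params
    if data.P is not None:
        fp = fit_product(data, params, cfg)
        params = params.replace(alpha=fp.params.alpha, beta=fp.params.beta, P0=fp.params.P0)
        parts["P"] = fp
    if data.S is not None:
        fs = fit_sugar(data, params, cfg)
        params = params.replace(Y_XS=fs.params.Y_XS, M_s=fs.params.M_s, S0=fs.params.S0)
        parts["S"] = fs

    sequential = _merge_results(parts, params, fb.converged, fb.n_starts_used, cfg.seed)
    if cfg.strategy == "sequential":
        return sequential
    return _fit_joint(data, cfg, warm=params)


def _fit_joint(data: TimeCourse, cfg: FitConfig, warm: KineticParameters) -> FitResult:
    names = ["mu_max", "X_max", "X0"]
    responses = {"X": data.X}
    if data.P is not None:
        names += ["alpha", "beta"]
        responses["P"] = data.P
    if data.S is not None:
        names += ["Y_XS", "M_s"]
        responses["S"] = data.S
    free = [n for n in names if n not in cfg.fix]

    bounds = {**_default_bounds(data), **cfg.bounds}
    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])

    p0_val = _initial_value(data, "P") if data.P is not None else 0.0
    s0_val = _initial_value(data, "S") if data.S is not None else 0.0
    p0_val = cfg.fix.get("P0", p0_val)
    s0_val = cfg.fix.get("S0", s0_val)

    masks = {k: np.isfinite(v) for k, v in responses.items()}
    weights = {
        k: 1.0 / max(float(np.ptp(v[masks[k]])), 1e-9) for k, v in responses.items()
    }

    def build(theta: np.ndarray) -> KineticParameters:
        vals = {**{n: getattr(warm, n) for n in names}, **cfg.fix, **dict(zip(free, theta))}
        x0 = min(vals["X0"], vals["X_max"])
        return KineticParameters(
            mu_max=vals["mu_max"], X_max=vals["X_max"], X0=max(x0, 1e-12),
            alpha=vals.get("alpha", 0.0), beta=vals.get("beta", 0.0),
            Y_XS=vals.get("Y_XS", 1.0), M_s=vals.get("M_s", 0.0),
            S0=s0_val, P0=p0_val,
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = build(theta)
        out = []
        for k, obs in responses.items():
            t = data.times[masks[k]]
            if k == "X":
                pred = logistic_biomass(t, p)
            elif k == "P":
                pred = p.P0 + p.alpha * (logistic_biomass(t, p) - p.X0) + p.beta * biomass_integral(t, p)
            else:
                growth = (logistic_biomass(t, p) - p.X0) / p.Y_XS
                pred = p.S0 - growth - p.M_s * biomass_integral(t, p)
            out.append(weights[k] * (pred - obs[masks[k]]))
        return np.concatenate(out)

    warm_theta = np.array([
        np.clip(getattr(warm, n) if np.isfinite(getattr(warm, n)) else 1.0,
                bounds[n][0], min(bounds[n][1], 1e12))
        for n in free
    ])
    rng = np.random.default_rng(cfg.seed)
    starts = [warm_theta]
    if cfg.n_starts > 1:
        starts.extend(_draw_starts(rng, lo, hi, cfg.n_starts - 1))

    best = None
    for s in starts:
        try:
            sol = least_squares(
                residuals, s, bounds=(lo, hi), method="trf",
                xtol=cfg.tolerance, ftol=cfg.tolerance, gtol=cfg.tolerance,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimization starts failed")

    params = build(best.x)
    out = FitResult(params=params, converged=bool(best.success),
                    n_starts_used=len(starts), seed=cfg.seed)
    n_free = {"X": 3, "P": 2, "S": 2}
    for k, obs in responses.items():
        t = data.times[masks[k]]
        if k == "X":
            pred = logistic_biomass(t, params)
        elif k == "P":
            pred = params.P0 + params.alpha * (logistic_biomass(t, params) - params.X0) \
                + params.beta * biomass_integral(t, params)
        else:
            growth = (logistic_biomass(t, params) - params.X0) / params.Y_XS
            pred = params.S0 - growth - params.M_s * biomass_integral(t, params)
        r2, f, sse, sst = goodness_of_fit(obs[masks[k]], pred, n_params=n_free[k])
        out.r2[k] = r2
        out.f_value[k] = f
        out.sse[k] = sse
        out.sst[k] = sst
        out.n_obs[k] = int(masks[k].sum())
    tot_sse = sum(out.sse.values())
    tot_sst = sum(out.sst.values())
    out.r2["pooled"] = 1.0 - tot_sse / tot_sst if tot_sst > 0 else math.nan
    return out
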