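"""Derived production metrics and two-strain significance testing.

Summaries follow the display conventions of the source tables: fold
changes to two decimals, percent increases to the nearest integer, titers
to three decimals.  Raw (unrounded) values are always retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from scipy import stats

from .errors import DomainError, UndefinedRatioError, ValidationError
from .fitting import FitResult
from .kinetics import peak_growth_rate, product_titer

__all__ = [
    "ContentRecord",
    "DerivedMetrics",
    "fold_change",
    "productivity",
    "percent_increase",
    "two_sample_t",
    "compare_strains",
]


@dataclass(frozen=True)
class ContentRecord:
    """One row of a metabolite-content table (mean +/- SD of n replicates)."""

    strain: str
    analyte: str
    mean: float
    sd: float
    n: int = 3
    unit: str = ""

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValidationError(f"mean must be >= 0, got {self.mean}")
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")


@dataclass
class DerivedMetrics:
    """Per-strain production metrics plus treated-vs-control comparison maps."""

    P_max: Dict[str, float] = field(default_factory=dict)
    productivity: Dict[str, float] = field(default_factory=dict)
    V_max: Dict[str, float] = field(default_factory=dict)
    fold_changes: Dict[str, float] = field(default_factory=dict)
    percent_increases: Dict[str, float] = field(default_factory=dict)


def fold_change(treated: ContentRecord, control: ContentRecord) -> float:
    """Ratio of treated to control mean for the same analyte and unit."""
    if treated.analyte != control.analyte:
        raise ValidationError(
            f"analyte mismatch: {treated.analyte!r} vs {control.analyte!r}"
        )
    if treated.unit != control.unit:
        raise ValidationError(f"unit mismatch: {treated.unit!r} vs {control.unit!r}")
    if control.mean <= 0:
        raise UndefinedRatioError("control mean must be > 0 for a fold change")
    return treated.mean / control.mean


def productivity(p_max: float, duration: float) -> float:
    """Volumetric productivity, g/L/day: final titer over batch duration."""
    if duration <= 0:
        raise DomainError(f"duration must be > 0, got {duration}")
    if p_max < 0:
        raise DomainError(f"p_max must be >= 0, got {p_max}")
    return p_max / duration


def percent_increase(new: float, old: float) -> float:
    """Relative increase 100 * (new - old) / old, percent."""
    if old <= 0:
        raise DomainError(f"reference value must be > 0, got {old}")
    return 100.0 * (new - old) / old


def two_sample_t(
    a: ContentRecord,
    b: ContentRecord,
    kind: str = "pooled",
) -> Tuple[float, float, float]:
    """Two-tailed two-sample t test from summary statistics.

    ``kind="pooled"`` is the classic Student test (default, equal
    variances); ``kind="welch"`` uses the Welch-Satterthwaite correction.
    Returns ``(t, df, p)``.  When both groups have zero variance and equal
    means the test is vacuous and ``(0, df, 1.0)`` is returned.
    """
    if a.n < 2 or b.n < 2:
        raise ValidationError("need n >= 2 in both groups for a t test")
    if kind not in ("pooled", "welch"):
        raise ValidationError(f"kind must be 'pooled' or 'welch', got {kind!r}")
    equal_var = kind == "pooled"
    if a.sd == 0.0 and b.sd == 0.0:
        df = float(a.n + b.n - 2)
        if a.mean == b.mean:
            return 0.0, df, 1.0
        sign = 1.0 if a.mean > b.mean else -1.0
        return sign * float("inf"), df, 0.0
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def _round_report(metrics: DerivedMetrics) -> dict:
    return {
        "P_max": {k: round(v, 3) for k, v in metrics.P_max.items()},
        "productivity": {k: round(v, 3) for k, v in metrics.productivity.items()},
        "V_max": {k: round(v, 3) for k, v in metrics.V_max.items()},
        "fold_changes": {k: round(v, 2) for k, v in metrics.fold_changes.items()},
        "percent_increases": {k: int(round(v)) for k, v in metrics.percent_increases.items()},
    }


def compare_strains(
    fit_wt: FitResult,
    fit_tr: FitResult,
    contents: Optional[List[ContentRecord]] = None,
    duration: float = 12.0,
    control_strain: str = "WT",
    treated_strain: Optional[str] = None,
    t_test_kind: str = "pooled",
) -> Tuple[DerivedMetrics, dict]:
    """Assemble the full control-vs-treated comparison report.

    Model-derived metrics (``V_max``, ``P_max`` at ``duration``,
    productivity) come from the two fits; content fold changes and t tests
    come from the optional metabolite table.  Returns the raw metrics and a
    JSON-serializable report with display rounding applied.
    """
    if not (fit_wt.converged and fit_tr.converged):
        raise ValidationError("both fits must have converged before comparison")
    if duration <= 0:
        raise DomainError("duration must be > 0")

    metrics = DerivedMetrics()
    labels = ("control", "treated")
    for label, fit in zip(labels, (fit_wt, fit_tr)):
        p = fit.params
        pmax = float(product_titer(duration, p))
        metrics.P_max[label] = pmax
        metrics.productivity[label] = productivity(pmax, duration)
        metrics.V_max[label] = peak_growth_rate(p)

    for name, getter in (
        ("mu_max", lambda f: f.params.mu_max),
        ("X_max", lambda f: f.params.X_max),
        ("V_max", lambda f: peak_growth_rate(f.params)),
        ("P_max", lambda f: float(product_titer(duration, f.params))),
        ("productivity", lambda f: productivity(float(product_titer(duration, f.params)), duration)),
    ):
        old, new = getter(fit_wt), getter(fit_tr)
        if old > 0:
            metrics.percent_increases[name] = percent_increase(new, old)
    if metrics.P_max["control"] > 0:
        metrics.fold_changes["P_max"] = metrics.P_max["treated"] / metrics.P_max["control"]

    t_tests = {}
    if contents:
        if treated_strain is None:
            others = sorted({c.strain for c in contents} - {control_strain})
            if not others:
                raise ValidationError("no treated strain found in contents")
            treated_strain = others[0]
        by_analyte_control = {c.analyte: c for c in contents if c.strain == control_strain}
        by_analyte_treated = {c.analyte: c for c in contents if c.strain == treated_strain}
        if set(by_analyte_control) != set(by_analyte_treated):
            raise ValidationError(
                "control and treated strains report different analyte sets: "
                f"{sorted(by_analyte_control)} vs {sorted(by_analyte_treated)}"
            )
        for analyte in sorted(by_analyte_control):
            ctrl, trt = by_analyte_control[analyte], by_analyte_treated[analyte]
            metrics.fold_changes[analyte] = fold_change(trt, ctrl)
            t, df, pval = two_sample_t(trt, ctrl, kind=t_test_kind)
            t_tests[analyte] = {
                "t": t,
                "df": df,
                "p": pval,
                "significant_0.05": bool(pval < 0.05),
            }

    report = {
        "control": control_strain,
        "treated": treated_strain,
        "duration_days": duration,
        "metrics": _round_report(metrics),
        "raw": {
            "P_max": metrics.P_max,
            "productivity": metrics.productivity,
            "V_max": metrics.V_max,
            "fold_changes": metrics.fold_changes,
            "percent_increases": metrics.percent_increases,
        },
        "t_tests": t_tests,
        "params": {
            "control": fit_wt.params.as_dict(),
            "treated": fit_tr.params.as_dict(),
        },
    }
    return metrics, report
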