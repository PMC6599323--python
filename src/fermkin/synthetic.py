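"""Synthetic fermentation time courses with a controlled noise model.

The generator evaluates the closed-form model and overlays seeded Gaussian
noise (additive in g/L, or proportional to the signal), with an optional
replicate structure emulating triplicate sampling.  It is the test bed for
every downstream fitting and comparison stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError
from .kinetics import KineticParameters, TimeCourse, simulate
from .reference import FPS_PARAMS, WT_PARAMS

__all__ = ["NoiseSpec", "generate", "make_strain_pair", "DEFAULT_TIMES"]

#: Default sampling grid: every 2 days over a 12-day batch.
DEFAULT_TIMES = tuple(float(t) for t in range(0, 13, 2))

_KINDS = ("none", "additive", "proportional")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for the generator.

    ``sd`` is in g/L for additive noise and a unitless fraction of the
    signal for proportional noise.  ``negative_clip`` truncates negative
    draws at zero (concentrations cannot be negative).
    """

    kind: str = "none"
    sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    negative_clip: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"noise kind must be one of {_KINDS}, got {self.kind!r}")
        if not np.isfinite(self.sd) or self.sd < 0:
            raise ConfigurationError(f"noise sd must be finite and >= 0, got {self.sd}")
        if self.n_replicates < 1:
            raise ConfigurationError(f"n_replicates must be >= 1, got {self.n_replicates}")


def _perturb(values: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(values.shape)
    if noise.kind == "additive":
        out = values + noise.sd * eps
    else:  # proportional
        out = values * (1.0 + noise.sd * eps)
    if noise.negative_clip:
        out = np.clip(out, 0.0, None)
    return out


def generate(
    p: KineticParameters,
    times: Sequence[float] = DEFAULT_TIMES,
    noise: NoiseSpec = NoiseSpec(),
    strain_label: str = "",
) -> TimeCourse:
    """Generate a (possibly noisy, possibly replicated) time course.

    Deterministic given identical inputs and seed.  With ``kind="none"``
    and one replicate the output equals ``simulate(p, times)`` exactly.
    Rows are ordered by time, then replicate.
    """
    base = simulate(p, times, method="closed_form", strain_label=strain_label)
    if noise.kind == "none" and noise.n_replicates == 1:
        return base

    rng = np.random.default_rng(noise.seed)
    nrep = noise.n_replicates
    nt = base.times.size
    cols = {}
    for name in ("X", "S", "P"):
        series = getattr(base, name)
        tiled = np.tile(series, (nrep, 1))  # (rep, time)
        if noise.kind != "none":
            tiled = _perturb(tiled, noise, rng)
        cols[name] = tiled.T.ravel()  # time-major: all reps of t0, then t1...
    rep_labels = np.tile(np.arange(1, nrep + 1), nt)
    return TimeCourse(
        times=np.repeat(base.times, nrep),
        X=cols["X"],
        S=cols["S"],
        P=cols["P"],
        replicate=rep_labels if nrep > 1 else None,
        strain_label=strain_label,
    )


def make_strain_pair(
    wt: KineticParameters = WT_PARAMS,
    fps: KineticParameters = FPS_PARAMS,
    times: Sequence[float] = DEFAULT_TIMES,
    noise: NoiseSpec = NoiseSpec(),
    labels: Tuple[str, str] = ("WT", "FPS"),
) -> Tuple[TimeCourse, TimeCourse]:
    """Generate a labeled wild-type / transgenic pair of time courses.

    The two strains receive independent sub-streams spawned from
    ``noise.seed`` so their noise realizations are uncorrelated yet the
    pair as a whole is reproducible from one seed.
    """
    children = np.random.SeedSequence(noise.seed).spawn(2)
    out = []
    for p, label, child in zip((wt, fps), labels, children):
        sub = replace(noise, seed=int(child.generate_state(1)[0]))
        out.append(generate(p, times, sub, strain_label=label))
    return tuple(out)
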