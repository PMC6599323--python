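"""Published reference values for the two Ganoderma lucidum strains.

These are the estimated kinetic parameters and the mycelium metabolite
content table (mean +/- SD of triplicates) reported for the wild-type (WT)
strain and the farnesyl-diphosphate-synthase-overexpressing (FPS)
transformants of a 12-day submerged batch culture.  They serve as the
default inputs for synthetic-data generation and strain comparison.

Notes on the printed values (kept verbatim, not "corrected"):

* The FPS ``beta`` of 1.151 g/g/day is dimensionally inconsistent with the
  printed final titer of 0.209 g/L over 12 days (``beta * X * t`` would far
  exceed it); it is retained as printed, and fitting simply reports what
  the data support.
* The printed WT final titer appears both as 0.112 g/L and 0.171 g/L in
  different places of the source; 0.112 (the tabulated value) is used here.
"""

from __future__ import annotations

from .kinetics import KineticParameters

__all__ = [
    "WT_PARAMS",
    "FPS_PARAMS",
    "REFERENCE_PMAX",
    "REFERENCE_DURATION_DAYS",
    "REFERENCE_CONTENTS",
]

#: Default initial conditions for synthetic work (the published study does
#: not state them): X0 = 0.5 g DW/L, S0 = 35 g/L, P0 = 0 g/L.
WT_PARAMS = KineticParameters(
    mu_max=0.45,
    X_max=9.41,
    alpha=0.015,
    beta=0.0,
    Y_XS=0.63,
    M_s=0.12,
    X0=0.5,
    S0=35.0,
    P0=0.0,
)

FPS_PARAMS = KineticParameters(
    mu_max=0.49,
    X_max=9.72,
    alpha=0.026,
    beta=1.151,
    Y_XS=0.70,
    M_s=0.13,
    X0=0.5,
    S0=35.0,
    P0=0.0,
)

#: Final product titers as printed in the reference parameter table, g/L.
REFERENCE_PMAX = {"WT": 0.112, "FPS": 0.209}

#: Peak volumetric growth rates as printed in the reference table, g/L/day
#: (consistent with mu_max * X_max / 4 up to the table's rounding).
REFERENCE_VMAX = {"WT": 1.05, "FPS": 1.18}

#: Batch duration, days.
REFERENCE_DURATION_DAYS = 12.0

#: Metabolite content table: strain -> analyte -> (mean, sd, n, unit).
#: "total_ga" is in mg/100 mg DW; individual acids in ug/100 mg DW.
REFERENCE_CONTENTS = [
    # strain, analyte, mean, sd, n, unit
    ("WT", "total_ga", 1.21, 0.09, 3, "mg/100 mg DW"),
    ("WT", "ga_mk", 2.0, 0.0, 3, "ug/100 mg DW"),
    ("WT", "ga_t", 18.0, 1.0, 3, "ug/100 mg DW"),
    ("WT", "ga_s", 8.0, 1.0, 3, "ug/100 mg DW"),
    ("WT", "ga_me", 10.0, 1.0, 3, "ug/100 mg DW"),
    ("FPS1", "total_ga", 2.76, 0.38, 3, "mg/100 mg DW"),
    ("FPS1", "ga_mk", 4.0, 1.0, 3, "ug/100 mg DW"),
    ("FPS1", "ga_t", 41.0, 2.0, 3, "ug/100 mg DW"),
    ("FPS1", "ga_s", 21.0, 5.0, 3, "ug/100 mg DW"),
    ("FPS1", "ga_me", 28.0, 1.0, 3, "ug/100 mg DW"),
    ("FPS2", "total_ga", 2.61, 0.21, 3, "mg/100 mg DW"),
    ("FPS2", "ga_mk", 3.0, 0.0, 3, "ug/100 mg DW"),
    ("FPS2", "ga_t", 44.0, 2.0, 3, "ug/100 mg DW"),
    ("FPS2", "ga_s", 22.0, 4.0, 3, "ug/100 mg DW"),
    ("FPS2", "ga_me", 30.0, 2.0, 3, "ug/100 mg DW"),
    ("FPS3", "total_ga", 2.57, 0.31, 3, "mg/100 mg DW"),
    ("FPS3", "ga_mk", 4.0, 0.0, 3, "ug/100 mg DW"),
    ("FPS3", "ga_t", 42.0, 2.0, 3, "ug/100 mg DW"),
    ("FPS3", "ga_s", 21.0, 4.0, 3, "ug/100 mg DW"),
    ("FPS3", "ga_me", 27.0, 1.0, 3, "ug/100 mg DW"),
]
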