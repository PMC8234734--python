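"""Published reference values from the in vivo HAEE tetrapeptide study.

Raw concentration–time curves of the study exist only as figures, but its
derived parameter tables were printed and serve here as *inputs* for
desk-check recomputation: internal-consistency relations (ClT = D/AUC,
T1/2 = ln2/Kel, Vd(β) = ClT/Kel, MRT = 1/Kel), the dose-linearity Pearson
analysis, and the tissue-bioavailability ratios.

Parameter-set values per dose group (i.v. bolus):
``D`` ng, ``Cmax`` ng/mL, ``Tmax`` min, ``AUC0_inf`` (ng/mL)·min,
``ClT`` mL/min, ``MRT`` min, ``Kel`` min⁻¹, ``T12_el`` min,
``Vd_c``/``Vd_beta``/``Vd_extrap`` mL.
"""
from __future__ import annotations

import pandas as pd

__all__ = [
    "PK_TABLE",
    "TISSUE_AUC_0_20",
    "RAT_SINGLE_DOSE_GROUPS",
    "pk_table",
    "tissue_auc_table",
]

#: Reported PK parameters by group.  Keys are group labels: rabbit at
#: 120 µg/kg; rats at 50/300/900 µg/kg single dose; rat300_chronic after a
#: 28-day course of 300 µg/kg/day.
PK_TABLE: dict[str, dict[str, float]] = {
    "rabbit120": dict(dose_ug_per_kg=120, D=440_000, Cmax=255, Tmax=4,
                      AUC0_inf=4421, ClT=100, MRT=29, Kel=0.035, T12_el=20,
                      Vd_c=862, Vd_beta=2860, Vd_extrap=3194),
    "rat50": dict(dose_ug_per_kg=50, D=18_000, Cmax=73.9, Tmax=4,
                  AUC0_inf=1383, ClT=13.0, MRT=33, Kel=0.031, T12_el=23,
                  Vd_c=107, Vd_beta=425, Vd_extrap=504),
    "rat300": dict(dose_ug_per_kg=300, D=105_000, Cmax=439, Tmax=4,
                   AUC0_inf=11_340, ClT=9.3, MRT=32, Kel=0.031, T12_el=22,
                   Vd_c=122, Vd_beta=299, Vd_extrap=296),
    "rat300_chronic": dict(dose_ug_per_kg=300, D=105_000, Cmax=444, Tmax=4,
                           AUC0_inf=12_137, ClT=8.7, MRT=42, Kel=0.024, T12_el=29,
                           Vd_c=111, Vd_beta=362, Vd_extrap=382),
    "rat900": dict(dose_ug_per_kg=900, D=315_000, Cmax=1322, Tmax=4,
                   AUC0_inf=47_133, ClT=6.7, MRT=36, Kel=0.028, T12_el=25,
                   Vd_c=108, Vd_beta=237, Vd_extrap=291),
}

#: Single-dose rat groups used in the dose-linearity analysis.
RAT_SINGLE_DOSE_GROUPS = ("rat50", "rat300", "rat900")

#: Reported tissue AUC(0–20), (ng/g)·min, mice after 300 µg/kg i.p. bolus.
TISSUE_AUC_0_20: dict[str, float] = {
    "blood": 2110,
    "kidney": 3437,
    "liver": 777,
    "heart": 845,
    "omentum": 395,
    "brain": 70,
}


def pk_table() -> pd.DataFrame:
    """The reference PK parameter table, groups as rows."""
    return pd.DataFrame(PK_TABLE).T


def tissue_auc_table() -> pd.Series:
    """Reported tissue AUC(0–20) values as a Series."""
    return pd.Series(TISSUE_AUC_0_20, name="auc_0_20")
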