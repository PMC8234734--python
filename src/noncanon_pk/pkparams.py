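"""Derived pharmacokinetic parameter sets, dose-linearity and group comparison.

From the dose, the fitted macro-constants and the hybrid moments this module
derives the standard i.v.-bolus parameter set:

    ClT       = D / AUC(0–∞)           total body clearance
    Kel       = β                      terminal elimination rate constant
    T1/2(el)  = ln2 / β                elimination half-life
    MRT_el    = 1 / β                  residence time in the elimination limit
    MRT_nca   = AUMC(0–∞) / AUC(0–∞)   model-free mean residence time
    Vd(c)     = D / (A + B)            central volume (back-extrapolated intercept)
    Vd(β)     = ClT / β                elimination-phase distribution volume
    Vd(extrap)= D / B                  volume referenced to macro-constant B

Dose linearity is assessed by the Pearson correlation between dose and a
dose-dependent parameter; time- and volume-type parameters are instead
checked for invariance across doses via their coefficient of variation.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .compartmental import MacroConstants
from .io import DoseRecord

__all__ = [
    "PKParameterSet",
    "LinearityClass",
    "LinearityReport",
    "derive_parameters",
    "dose_linearity",
    "parameter_invariance",
    "compare_groups",
]

#: Standard bioequivalence bounds used to flag "practically the same" parameters.
EQUIVALENCE_BOUNDS = (0.8, 1.25)

#: CV threshold (percent) below which a parameter is called dose-invariant.
INVARIANCE_CV_PERCENT = 25.0


@dataclass(frozen=True)
class PKParameterSet:
    """Full parameter set for one dose group (one column of a PK summary table)."""

    group_id: str
    D: float  # ng
    Cmax: float  # ng/mL
    Tmax: float  # min
    AUC0_inf: float  # (ng/mL)·min
    ClT: float  # mL/min
    MRT_el: float  # min
    MRT_nca: float  # min
    Kel: float  # 1/min
    T12_el: float  # min
    Vd_c: float  # mL
    Vd_beta: float  # mL
    Vd_extrap: float  # mL

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        d.pop("group_id")
        return d


class LinearityClass(str, enum.Enum):
    DOSE_DEPENDENT_LINEAR = "dose_dependent_linear"
    DOSE_INVARIANT = "dose_invariant"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class LinearityReport:
    """Pearson dose-proportionality summary for one parameter across dose groups."""

    parameter: str
    doses: tuple[float, ...]
    values: tuple[float, ...]
    pearson_r: float
    p_value: float
    classed_as: LinearityClass
    note: str = ""


def derive_parameters(
    dose: DoseRecord,
    macro: MacroConstants,
    auc0_inf: float,
    aumc0_inf: float,
    cmax: float,
    tmax: float,
) -> PKParameterSet:
    """Derive the full parameter set from dose, macro-constants and hybrid moments."""
    D = dose.dose_amount_ng
    if auc0_inf <= 0:
        raise ValueError("AUC0_inf must be positive")
    if macro.beta <= 0:
        raise ValueError("Kel (= beta) must be positive")
    intercept = macro.A + macro.B
    if intercept <= 0:
        raise ValueError("A + B must be positive (Vd_c denominator)")
    clt = D / auc0_inf
    return PKParameterSet(
        group_id=dose.group_id,
        D=D,
        Cmax=cmax,
        Tmax=tmax,
        AUC0_inf=auc0_inf,
        ClT=clt,
        MRT_el=1.0 / macro.beta,
        MRT_nca=aumc0_inf / auc0_inf,
        Kel=macro.beta,
        T12_el=math.log(2) / macro.beta,
        Vd_c=D / intercept,
        Vd_beta=clt / macro.beta,
        Vd_extrap=D / macro.B,
    )


def dose_linearity(
    doses: Sequence[float],
    values: Sequence[float],
    parameter: str = "",
) -> LinearityReport:
    """Pearson correlation between dose and a parameter across dose groups.

    The two-sided p-value comes from the t-statistic r·√((n−2)/(1−r²)) on
    n−2 degrees of freedom.  A constant value vector leaves r undefined and
    is classed inconclusive rather than raising.
    """
    doses = tuple(float(d) for d in doses)
    values = tuple(float(v) for v in values)
    if len(doses) != len(values) or len(doses) < 3:
        raise ValueError("need >= 3 (dose, value) pairs")
    if len(set(doses)) != len(doses):
        raise ValueError("doses must be distinct")
    if np.ptp(values) == 0.0:
        return LinearityReport(
            parameter, doses, values, math.nan, math.nan,
            LinearityClass.INCONCLUSIVE, note="constant values: Pearson r undefined",
        )
    r, p = stats.pearsonr(doses, values)
    cv, invariant = parameter_invariance(values)
    if invariant:
        classed = LinearityClass.DOSE_INVARIANT
    elif r >= 0.99:
        classed = LinearityClass.DOSE_DEPENDENT_LINEAR
    else:
        classed = LinearityClass.INCONCLUSIVE
    return LinearityReport(parameter, doses, values, float(r), float(p), classed)


def parameter_invariance(values: Sequence[float]) -> tuple[float, bool]:
    """Coefficient of variation (%) and whether it is below the invariance threshold."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    mean = v.mean()
    if mean == 0:
        return math.inf, False
    cv = 100.0 * v.std(ddof=1) / abs(mean)
    return float(cv), bool(cv < INVARIANCE_CV_PERCENT)


def compare_groups(pk_a: PKParameterSet, pk_b: PKParameterSet) -> dict[str, dict]:
    """Per-parameter ratios b/a with bioequivalence-style flags.

    A ratio inside [0.8, 1.25] is flagged equivalent; a zero denominator
    leaves the ratio undefined and the flag False.
    """
    lo, hi = EQUIVALENCE_BOUNDS
    out: dict[str, dict] = {}
    for name, a in pk_a.as_dict().items():
        b = pk_b.as_dict()[name]
        if a == 0:
            out[name] = {"ratio": math.nan, "equivalent": False, "note": "zero denominator"}
        else:
            ratio = b / a
            out[name] = {"ratio": ratio, "equivalent": bool(lo <= ratio <= hi), "note": ""}
    return out
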