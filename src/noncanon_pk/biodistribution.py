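"""Tissue bioavailability coefficients and peak (mode) structure of tissue curves.

The tissue bioavailability coefficient over a common window (0–20 min here)
is the ratio of tissue to blood exposure,

    f_T = AUC(0–20) tissue / AUC(0–20) blood,

a partition-like exposure index (f_T(blood) = 1 by construction).  Tissue
curves after intraperitoneal bolus dosing are bimodal — a first peak near
4 min from the absorption/distribution phase and a second near 10–15 min
from slower interstitial redistribution — so a simple prominence-based peak
detector on the sampled grid is provided to characterise that structure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import BLOOD_DENSITY_G_PER_ML, ConcProfile, ConcUnits, Tissue
from .nca import auc_trapezoid

__all__ = ["TissueAUCRow", "Mode", "tissue_bioavailability", "detect_modes"]


@dataclass(frozen=True)
class TissueAUCRow:
    """One row of the tissue-bioavailability table."""

    tissue: Tissue
    auc_0_20: float  # (ng/g or ng/mL)·min
    f_T: float
    f_T_percent: float


@dataclass(frozen=True)
class Mode:
    """A local maximum of a sampled concentration–time curve."""

    time: float  # min
    height: float
    prominence: float


def tissue_bioavailability(
    profiles: dict[Tissue, ConcProfile] | list[ConcProfile],
    window: tuple[float, float] = (0.0, 20.0),
    *,
    back_extrapolate: bool = False,
) -> list[TissueAUCRow]:
    """Per-tissue AUC over ``window`` and f_T ratios against blood.

    When gravimetric (ng/g) tissue data are supplied alongside volumetric
    blood, the blood AUC is converted to ng/g (divided by the blood density)
    so numerator and denominator share units.  Rows are sorted descending by
    f_T; missing tissues are simply absent (a warning is emitted).  Unless
    back-extrapolation is requested, a window start before the first common
    sample is clipped to the first observed time (integration starts at the
    first sample, as everywhere in the model-free layer).
    """
    if not isinstance(profiles, dict):
        profiles = {p.tissue: p for p in profiles}
    if Tissue.BLOOD not in profiles:
        raise ValueError("blood profile is required to compute f_T")
    t1, t2 = window
    if not back_extrapolate:
        t1 = max(t1, max(float(p.times[0]) for p in profiles.values()))
    missing = [t for t in Tissue if t not in profiles]
    if missing:
        warnings.warn(f"tissues missing from input, omitted: {[t.value for t in missing]}")

    aucs: dict[Tissue, float] = {}
    units = {p.units for p in profiles.values()}
    gravimetric = ConcUnits.NG_PER_G in {profiles[t].units for t in profiles if t is not Tissue.BLOOD}
    for tissue, prof in profiles.items():
        a = auc_trapezoid(prof, t1, t2, back_extrapolate=back_extrapolate)
        if tissue is Tissue.BLOOD and gravimetric and prof.units is ConcUnits.NG_PER_ML:
            a = a / BLOOD_DENSITY_G_PER_ML  # ng/mL·min -> ng/g·min
        aucs[tissue] = a
    blood_auc = aucs[Tissue.BLOOD]
    if blood_auc == 0:
        raise ValueError("blood AUC over the window is zero; f_T undefined")

    rows = [
        TissueAUCRow(tissue=t, auc_0_20=a, f_T=a / blood_auc, f_T_percent=100.0 * a / blood_auc)
        for t, a in aucs.items()
    ]
    rows.sort(key=lambda r: -r.f_T)
    return rows


def detect_modes(profile: ConcProfile, min_prominence_frac: float = 0.1) -> list[Mode]:
    """Strict local maxima of the sampled curve, filtered by relative prominence.

    A peak is kept when its prominence is at least ``min_prominence_frac``
    times the global maximum.  Endpoints count as maxima only when strictly
    above their single neighbour.  A flat profile has no modes.
    """
    c = profile.concentrations
    t = profile.times
    if len(c) < 3:
        raise ValueError("need >= 3 points to detect modes")
    cmax = float(c.max())
    if cmax == 0 or np.ptp(c) == 0:
        return []
    # pad with -inf so find_peaks can see endpoint maxima (strictly above neighbour)
    padded = np.concatenate([[-np.inf], c, [-np.inf]])
    idx, props = find_peaks(padded, prominence=0.0)
    modes = []
    for i, prom in zip(idx, props["prominences"]):
        j = i - 1
        prom = min(prom, cmax)  # -inf padding makes endpoint prominences infinite
        if prom >= min_prominence_frac * cmax:
            modes.append(Mode(time=float(t[j]), height=float(c[j]), prominence=float(prom)))
    modes.sort(key=lambda m: m.time)
    return modes
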