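"""Non-compartmental (model-free) quantities: Cmax/Tmax and trapezoidal AUC/AUMC.

All areas use the linear trapezoid rule on the observed samples, with linear
interpolation where a window edge falls between sample times.  A log-linear
"down" rule is available but off by default; integration starts at the first
observed time unless back-extrapolation (holding the first observed
concentration constant back to the window start) is explicitly enabled —
curves here rise to their maximum, so extrapolating the terminal fit to t=0
would be wrong.
"""
from __future__ import annotations

import numpy as np

from .io import ConcProfile

__all__ = ["cmax_tmax", "auc_trapezoid", "aumc_trapezoid"]


def cmax_tmax(profile: ConcProfile) -> tuple[float, float]:
    """Maximum observed concentration and the time of that observation.

    Ties are broken by the earliest time.
    """
    if len(profile) == 0:
        raise ValueError("profile is empty")
    i = int(np.argmax(profile.concentrations))  # argmax returns the first max
    return float(profile.concentrations[i]), float(profile.times[i])


def _window_series(
    profile: ConcProfile,
    t1: float,
    t2: float,
    back_extrapolate: bool,
    log_linear_down: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample times/concentrations restricted to [t1, t2] with edge interpolation."""
    t = profile.times
    c = profile.concentrations
    if len(t) == 0:
        raise ValueError("profile is empty")
    if t1 >= t2:
        raise ValueError(f"require t1 < t2, got ({t1}, {t2})")
    if t2 > t[-1] or (t1 < t[0] and not back_extrapolate):
        raise ValueError(
            f"window [{t1}, {t2}] outside observed range [{t[0]}, {t[-1]}] "
            "(back-extrapolation disabled)"
        )
    if back_extrapolate and t1 < t[0]:
        # hold the first observed concentration constant on [t1, t_first]
        t = np.concatenate([[t1], t])
        c = np.concatenate([[c[0]], c])

    def interp(tq: float) -> float:
        if log_linear_down:
            j = np.searchsorted(t, tq)
            lo, hi = t[j - 1], t[j]
            clo, chi = c[j - 1], c[j]
            if clo > 0 and chi > 0 and chi < clo:
                return float(clo * (chi / clo) ** ((tq - lo) / (hi - lo)))
        return float(np.interp(tq, t, c))

    inner = (t > t1) & (t < t2)
    tt = np.concatenate([[t1], t[inner], [t2]])
    cc = np.concatenate([[interp(t1)], c[inner], [interp(t2)]])
    return tt, cc


def auc_trapezoid(
    profile: ConcProfile,
    t1: float,
    t2: float,
    *,
    back_extrapolate: bool = False,
    log_linear_down: bool = False,
) -> float:
    """Area under the concentration–time curve over [t1, t2], (ng/mL)·min.

    Linear trapezoid by default; with ``log_linear_down=True`` segments where
    the concentration falls use the log-linear rule instead.
    """
    tt, cc = _window_series(profile, t1, t2, back_extrapolate, log_linear_down)
    if log_linear_down:
        total = 0.0
        for i in range(len(tt) - 1):
            dt = tt[i + 1] - tt[i]
            lo, hi = cc[i], cc[i + 1]
            if lo > 0 and hi > 0 and hi < lo:
                total += dt * (lo - hi) / np.log(lo / hi)
            else:
                total += dt * (lo + hi) / 2.0
        return float(total)
    return float(np.trapezoid(cc, tt))


def aumc_trapezoid(
    profile: ConcProfile,
    t1: float,
    t2: float,
    *,
    back_extrapolate: bool = False,
) -> float:
    """Area under the first-moment curve t·C(t) over [t1, t2], (ng/mL)·min²."""
    tt, cc = _window_series(profile, t1, t2, back_extrapolate, False)
    return float(np.trapezoid(tt * cc, tt))
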