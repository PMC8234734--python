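"""Bi-exponential disposition fitting and analytic tail integrals.

The canonical segment of a bolus curve (t >= Tmax, where the curve decays
monotonically) is described by the two-compartment macro-constant form

    C(t) = A·exp(-α·t) + B·exp(-β·t),        α > β > 0,

whose mono-exponential reduction (A = 0) is the one-compartment model.  Fits
are initialised by curve stripping (method of residuals), refined by weighted
nonlinear least squares with deterministic multi-start, and compared by AICc.
Analytic integrals of the fitted curve supply the tail of the hybrid
AUC(0–∞): trapezoid over the observed rising segment plus model tail beyond
the split point.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import ConcProfile
from .nca import auc_trapezoid, aumc_trapezoid

__all__ = [
    "Model",
    "Weighting",
    "MacroConstants",
    "FitResult",
    "predict",
    "strip_estimates",
    "fit_decay",
    "select_model",
    "model_tail_auc",
    "model_tail_aumc",
    "hybrid_auc_inf",
    "hybrid_aumc_inf",
]


class Model(str, enum.Enum):
    MONO = "mono"
    BI = "bi"


class Weighting(str, enum.Enum):
    """Residual weighting for the nonlinear fit.

    LOG — least squares on log-concentration (relative-error weighting),
    robust over curves spanning several decades; UNIFORM — ordinary least
    squares; INV_C2 — residuals scaled by 1/C_obs.
    """

    LOG = "log"
    UNIFORM = "uniform"
    INV_C2 = "inv_c2"


@dataclass(frozen=True)
class MacroConstants:
    """Hybrid (macro-)constants of the disposition curve.

    A, B in ng/mL; alpha, beta in min⁻¹ with alpha > beta for a true
    bi-exponential.  The mono-exponential case is encoded as A = 0 (alpha
    unused).
    """

    A: float
    B: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.B <= 0 or self.beta <= 0:
            raise ValueError("B and beta must be positive")
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if self.A > 0 and self.alpha <= self.beta:
            raise ValueError(f"require alpha > beta, got alpha={self.alpha}, beta={self.beta}")

    @property
    def is_mono(self) -> bool:
        return self.A == 0.0


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one decay model to the canonical segment."""

    model: Model
    macro: MacroConstants
    t_start: float
    rss: float
    n_points: int
    aicc: float
    weighting: Weighting
    stderr: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be non-negative")
        k = 2 if self.model is Model.MONO else 4
        if self.n_points < k + 1:
            raise ValueError("too few points for the number of free parameters")


def predict(macro: MacroConstants, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate C(t) = A·e^(−α·t) + B·e^(−β·t)."""
    t = np.asarray(t, dtype=float)
    out = macro.B * np.exp(-macro.beta * t)
    if macro.A > 0:
        out = out + macro.A * np.exp(-macro.alpha * t)
    return float(out) if out.ndim == 0 else out


def _loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Regress ln(c) on t; returns (intercept_conc, rate)."""
    slope, intercept = np.polyfit(t, np.log(c), 1)
    return float(np.exp(intercept)), float(-slope)


def strip_estimates(profile: ConcProfile, t_start: float, n_terminal: int = 3) -> MacroConstants:
    """Initial macro-constants by curve stripping (method of residuals).

    B and β come from a log-linear regression on the last ``n_terminal``
    positive points; A and α from a log-linear regression on the positive
    residuals C(t) − B·e^(−β·t) of the earlier points.  With fewer than two
    positive residuals a mono-type estimate (A = 0) is returned.  Zero
    concentrations are excluded from log-domain regressions.
    """
    if n_terminal < 2:
        raise ValueError("n_terminal must be >= 2")
    mask = (profile.times >= t_start) & (profile.concentrations > 0)
    t, c = profile.times[mask], profile.concentrations[mask]
    if len(t) < 2:
        raise ValueError("fewer than 2 usable (positive, t >= t_start) points")
    n_term = min(n_terminal, len(t))

    def strip_fast_phase(B: float, beta: float):
        """A, alpha from residuals where the fast phase still contributes."""
        th, ch = t[: len(t) - n_term], c[: len(t) - n_term]
        resid = ch - B * np.exp(-beta * th)
        # keep residuals that are a material fraction of the terminal curve;
        # late near-zero residuals carry only the B-phase estimation error
        keep = resid > 0.1 * B * np.exp(-beta * th)
        if keep.sum() < 2:
            keep = resid > 0
        if keep.sum() < 2:
            return None
        return _loglinear(th[keep], resid[keep])

    B, beta = _loglinear(t[-n_term:], c[-n_term:])
    beta = max(beta, 1e-6)  # guard against non-decaying terminal segments
    fast = strip_fast_phase(B, beta)
    if fast is None:
        return MacroConstants(A=0.0, B=B, alpha=0.0, beta=beta)
    A, alpha = fast
    if alpha > beta:
        # one refinement pass: remove the fast phase from the terminal
        # points, re-estimate (B, beta), then re-strip
        tl, cl = t[-n_term:], c[-n_term:]
        corrected = cl - A * np.exp(-alpha * tl)
        if np.all(corrected > 0):
            B, beta = _loglinear(tl, corrected)
            beta = max(beta, 1e-6)
            fast = strip_fast_phase(B, beta)
            if fast is not None:
                A, alpha = fast
    if alpha <= beta:  # phases not separated; fall back to a mild separation
        alpha = 2.0 * beta
    return MacroConstants(A=A, B=B, alpha=alpha, beta=beta)


def _residuals(params: np.ndarray, t: np.ndarray, c: np.ndarray, model: Model, weighting: Weighting) -> np.ndarray:
    # overflow/log(0) during optimizer exploration is handled by clipping
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        if model is Model.MONO:
            pred = np.exp(params[0]) * np.exp(-np.exp(params[1]) * t)
        else:
            A, alpha, B, beta = np.exp(params)
            pred = A * np.exp(-alpha * t) + B * np.exp(-beta * t)
        pred = np.nan_to_num(pred, nan=np.inf, posinf=np.finfo(float).max)
        if weighting is Weighting.LOG:
            return np.log(np.clip(pred, 1e-300, None)) - np.log(c)
        if weighting is Weighting.INV_C2:
            return (pred - c) / c
        return pred - c


def _aicc(rss: float, n: int, n_params: int) -> float:
    """AICc with k = n_params + 1 (residual variance counted as estimated)."""
    k = n_params + 1
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 <= 0:
        return np.inf
    return float(aic + 2 * k * (k + 1) / (n - k - 1))


def fit_decay(
    profile: ConcProfile,
    model: Model | str = Model.BI,
    t_start: float | None = None,
    weighting: Weighting | str = Weighting.LOG,
    n_restarts: int = 5,
) -> FitResult:
    """Weighted nonlinear least-squares fit of the decay segment.

    Parameters are optimised in log space (positivity by construction), with
    initial values from :func:`strip_estimates` plus ``n_restarts``
    deterministically perturbed restarts; the best solution is kept and
    α > β is enforced by relabelling.  ``t_start`` defaults to the observed
    Tmax, the start of the canonical (monotone-decay) segment.
    """
    model = Model(model)
    weighting = Weighting(weighting)
    if t_start is None:
        t_start = float(profile.times[np.argmax(profile.concentrations)])
    mask = (profile.times >= t_start) & (profile.concentrations > 0)
    t, c = profile.times[mask], profile.concentrations[mask]
    n_params = 2 if model is Model.MONO else 4
    min_pts = 3 if model is Model.MONO else 5
    if len(t) == 0:
        raise ValueError(f"t_start={t_start} excludes all points")
    if len(t) < min_pts:
        raise ValueError(f"{model.value} fit needs >= {min_pts} points with t >= {t_start}, got {len(t)}")

    init = strip_estimates(profile, t_start)
    if model is Model.MONO:
        x0 = np.log([max(init.B, 1e-12), max(init.beta, 1e-6)])
    else:
        A0 = init.A if init.A > 0 else 0.5 * init.B
        a0 = init.alpha if init.alpha > init.beta else 5.0 * init.beta
        x0 = np.log([A0, a0, max(init.B, 1e-12), max(init.beta, 1e-6)])

    rng = np.random.default_rng(20210618)  # fixed: fits must be reproducible
    best = None
    last_err: Exception | None = None
    for i in range(n_restarts + 1):
        start = x0 if i == 0 else x0 + rng.normal(0.0, 0.3, size=len(x0))
        try:
            sol = least_squares(_residuals, start, args=(t, c, model, weighting), method="lm", max_nfev=2000)
        except Exception as err:  # singular Jacobian etc.
            last_err = err
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"optimizer failed to converge after {n_restarts + 1} starts: {last_err}")

    if model is Model.MONO:
        B, beta = np.exp(best.x)
        macro = MacroConstants(A=0.0, B=float(B), alpha=0.0, beta=float(beta))
    else:
        A, alpha, B, beta = np.exp(best.x)
        if alpha < beta:  # relabel so that alpha is the fast phase
            A, alpha, B, beta = B, beta, A, alpha
        elif alpha == beta:
            alpha = beta * (1 + 1e-9)
        macro = MacroConstants(A=float(A), B=float(B), alpha=float(alpha), beta=float(beta))

    pred = predict(macro, t)
    rss = float(np.sum((pred - c) ** 2))
    # AICc on the residuals actually optimised, so models share the scale
    wres = _residuals(best.x, t, c, model, weighting)
    aicc = _aicc(float(np.sum(wres**2)), len(t), n_params)

    stderr = None
    try:
        J = best.jac
        dof = len(t) - n_params
        if dof > 0:
            cov = np.linalg.inv(J.T @ J) * 2 * best.cost / dof
            se = np.sqrt(np.diag(cov))  # se of log-parameters
            names = ["B", "beta"] if model is Model.MONO else ["A", "alpha", "B", "beta"]
            vals = [macro.B, macro.beta] if model is Model.MONO else [macro.A, macro.alpha, macro.B, macro.beta]
            stderr = {k: float(s * v) for k, s, v in zip(names, se, vals)}
    except np.linalg.LinAlgError:
        pass

    return FitResult(
        model=model,
        macro=macro,
        t_start=float(t_start),
        rss=rss,
        n_points=len(t),
        aicc=aicc,
        weighting=weighting,
        stderr=stderr,
    )


def select_model(fit_mono: FitResult, fit_bi: FitResult) -> Model:
    """Pick the model with lower AICc; the simpler model wins ties."""
    if fit_mono.n_points != fit_bi.n_points or fit_mono.t_start != fit_bi.t_start:
        raise ValueError("fits must be on identical data (same t_start and point count)")
    return Model.MONO if fit_mono.aicc <= fit_bi.aicc else Model.BI


def model_tail_auc(macro: MacroConstants, t_star: float) -> float:
    """∫_{t*}^{∞} C(t) dt = (A/α)·e^(−α·t*) + (B/β)·e^(−β·t*)."""
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    tail = (macro.B / macro.beta) * np.exp(-macro.beta * t_star)
    if macro.A > 0:
        tail += (macro.A / macro.alpha) * np.exp(-macro.alpha * t_star)
    return float(tail)


def model_tail_aumc(macro: MacroConstants, t_star: float) -> float:
    """∫_{t*}^{∞} t·C(t) dt, closed form for the bi-exponential."""
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    b, B = macro.beta, macro.B
    tail = B * np.exp(-b * t_star) * (t_star / b + 1.0 / b**2)
    if macro.A > 0:
        a, A = macro.alpha, macro.A
        tail += A * np.exp(-a * t_star) * (t_star / a + 1.0 / a**2)
    return float(tail)


def hybrid_auc_inf(
    profile: ConcProfile,
    fit: FitResult,
    t_split: float | None = None,
    *,
    back_extrapolate: bool = False,
) -> float:
    """Hybrid AUC(0–∞): trapezoid over the observed rising segment + model tail.

    The observed (typically non-canonical, rising) part up to ``t_split`` is
    integrated by the linear trapezoid rule from the first observation (or
    from 0 with ``back_extrapolate``); beyond the split the analytic integral
    of the fitted curve is used.  ``t_split`` defaults to the fit's t_start.
    """
    if t_split is None:
        t_split = fit.t_start
    t_lo = 0.0 if back_extrapolate else float(profile.times[0])
    trap = 0.0 if t_split <= t_lo else auc_trapezoid(profile, t_lo, t_split, back_extrapolate=back_extrapolate)
    return trap + model_tail_auc(fit.macro, t_split)


def hybrid_aumc_inf(
    profile: ConcProfile,
    fit: FitResult,
    t_split: float | None = None,
    *,
    back_extrapolate: bool = False,
) -> float:
    """Hybrid AUMC(0–∞), first-moment analogue of :func:`hybrid_auc_inf`."""
    if t_split is None:
        t_split = fit.t_start
    t_lo = 0.0 if back_extrapolate else float(profile.times[0])
    trap = 0.0 if t_split <= t_lo else aumc_trapezoid(profile, t_lo, t_split, back_extrapolate=back_extrapolate)
    return trap + model_tail_aumc(fit.macro, t_split)
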