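"""Closed-form compartmental models, least-squares fitting and derived parameters.

Mammillary 1/2/3-compartment models with first-order micro rate constants
(K10 elimination, K12/K21 and K13/K31 peripheral exchange) and their macro
(sum-of-exponentials) representation.  All times in minutes, dose in mg,
concentration in the unit carried by the series; V1 is therefore in
mg per concentration-unit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DataError,
    DegenerateModelError,
    FitFailureError,
    InconsistentMacroError,
    MetricsUnavailableError,
)
from .preprocessing import ConcentrationSeries

logger = logging.getLogger(__name__)

# optimizer box constraints (1/min for rates, mg/conc-unit for V1)
RATE_BOUNDS = (1e-4, 10.0)
V1_BOUNDS = (1e-3, 10.0)

_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: bolus (duration 0) or zero-order infusion."""

    amount: float  # mg
    start_time: float = 0.0  # min
    duration: float = 0.0  # min; 0 = instantaneous bolus

    def __post_init__(self):
        if not self.amount > 0:
            raise ValueError("dose amount must be positive")
        if self.duration < 0:
            raise ValueError("dose duration must be non-negative")


@dataclass(frozen=True)
class MicroParams:
    """Micro rate constants of a mammillary compartment model."""

    n_compartments: int
    V1: float
    K10: float
    K12: Optional[float] = None
    K21: Optional[float] = None
    K13: Optional[float] = None
    K31: Optional[float] = None

    def __post_init__(self):
        if self.n_compartments not in (1, 2, 3):
            raise ValueError("n_compartments must be 1, 2 or 3")
        required = {"V1": self.V1, "K10": self.K10}
        if self.n_compartments >= 2:
            required.update(K12=self.K12, K21=self.K21)
        if self.n_compartments == 3:
            required.update(K13=self.K13, K31=self.K31)
        for name, value in required.items():
            if value is None or not value > 0:
                raise ValueError(f"{name} must be positive for a {self.n_compartments}-compartment model")

    def rates(self) -> Dict[str, float]:
        out = {"K10": self.K10}
        if self.n_compartments >= 2:
            out.update(K12=self.K12, K21=self.K21)
        if self.n_compartments == 3:
            out.update(K13=self.K13, K31=self.K31)
        return out


@dataclass(frozen=True)
class MacroParams:
    """Sum-of-exponentials representation: C(t) = sum A_i exp(-lambda_i t).

    Exponents are sorted descending; for two compartments the convention is
    (A, alpha) then (B, beta).
    """

    coefficients: tuple
    exponents: tuple

    def __post_init__(self):
        if len(self.coefficients) != len(self.exponents):
            raise ValueError("coefficients and exponents must have equal length")
        lam = np.asarray(self.exponents, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("exponents must be strictly positive")
        if np.any(np.diff(lam) >= 0):
            raise ValueError("exponents must be sorted strictly descending")

    @property
    def n_compartments(self) -> int:
        return len(self.exponents)


@dataclass(frozen=True)
class DerivedParams:
    """Half-lives, clearance and AUCs derived from a two-compartment fit."""

    t_half_alpha: float  # min
    t_half_beta: float  # min
    cl: float  # mg/(min*conc-unit)
    auc_0_T: float  # min*conc-unit
    auc_inf: float  # min*conc-unit


@dataclass(frozen=True)
class ObservedMetrics:
    c_max: float
    t_max: float


@dataclass
class PKFitResult:
    micro: MicroParams
    macro: MacroParams
    ssr: float
    n_points: int
    aic: float
    derived: Optional[DerivedParams] = None
    aic_by_model: Optional[Dict[int, float]] = field(default=None, repr=False)

    @property
    def n_compartments(self) -> int:
        return self.micro.n_compartments


def micro_to_macro(params: MicroParams, dose: DoseEvent) -> MacroParams:
    """Convert micro constants to bolus macro constants (hybrid exponents).

    Two compartments: alpha/beta are the roots of
    ``l^2 - (K10+K12+K21) l + K10*K21 = 0`` with A, B weighting chosen so that
    A+B = dose/V1.  Three compartments use the corresponding cubic.
    """
    if dose.duration != 0:
        raise ValueError("closed-form macro conversion requires a bolus dose")
    c0 = dose.amount / params.V1
    if params.n_compartments == 1:
        return MacroParams((c0,), (params.K10,))
    if params.n_compartments == 2:
        k10, k12, k21 = params.K10, params.K12, params.K21
        s, p = k10 + k12 + k21, k10 * k21
        disc = s * s - 4.0 * p
        if disc <= _DEGENERACY_RTOL * s * s:
            raise DegenerateModelError("two-compartment exponents are not distinct")
        root = math.sqrt(disc)
        alpha, beta = (s + root) / 2.0, (s - root) / 2.0
        A = c0 * (alpha - k21) / (alpha - beta)
        B = c0 * (k21 - beta) / (alpha - beta)
        return MacroParams((A, B), (alpha, beta))
    # three compartments: characteristic cubic of the mammillary system
    k10, k12, k21, k13, k31 = params.K10, params.K12, params.K21, params.K13, params.K31
    a2 = k10 + k12 + k21 + k13 + k31
    a1 = k10 * k21 + k10 * k31 + k21 * k31 + k12 * k31 + k13 * k21
    a0 = k10 * k21 * k31
    roots = np.roots([1.0, -a2, a1, -a0])
    if np.any(np.abs(roots.imag) > 1e-9 * np.abs(roots).max()):
        raise DegenerateModelError("three-compartment cubic has complex roots")
    lam = np.sort(roots.real)[::-1]
    if np.any(lam <= 0) or np.any(np.diff(lam) > -_DEGENERACY_RTOL * lam[0]):
        raise DegenerateModelError("three-compartment exponents are not distinct/positive")
    coeffs = []
    for i in range(3):
        num = (k21 - lam[i]) * (k31 - lam[i])
        den = np.prod([lam[j] - lam[i] for j in range(3) if j != i])
        coeffs.append(c0 * num / den)
    return MacroParams(tuple(coeffs), tuple(lam))


def macro_to_micro(macro: MacroParams, dose: DoseEvent) -> MicroParams:
    """Invert macro constants to micro constants (1- and 2-compartment)."""
    if macro.n_compartments == 1:
        (A,), (lam,) = macro.coefficients, macro.exponents
        return MicroParams(1, V1=dose.amount / A, K10=lam)
    if macro.n_compartments != 2:
        raise InconsistentMacroError("macro inversion is defined for 1 or 2 compartments")
    (A, B), (alpha, beta) = macro.coefficients, macro.exponents
    if A <= 0 or B <= 0:
        raise InconsistentMacroError("macro coefficients must be positive")
    k21 = (A * beta + B * alpha) / (A + B)
    k10 = alpha * beta / k21
    k12 = alpha + beta - k10 - k21
    v1 = dose.amount / (A + B)
    if min(k21, k10, k12, v1) <= 0:
        raise InconsistentMacroError("macro constants imply non-positive micro rates")
    return MicroParams(2, V1=v1, K10=k10, K12=k12, K21=k21)


def predict_concentration(
    macro: MacroParams, dose: DoseEvent, times: Sequence[float]
) -> np.ndarray:
    """Evaluate the closed-form concentration at the given times.

    Bolus: ``C(t) = sum A_i exp(-l_i t)``.  Zero-order infusion of duration
    tau replaces each term by
    ``(A_i/(l_i tau)) (1 - exp(-l_i min(t,tau))) exp(-l_i max(0, t-tau))``.
    Times before the dose start evaluate to 0.
    """
    t = np.asarray(times, dtype=float) - dose.start_time
    A = np.asarray(macro.coefficients, dtype=float)
    lam = np.asarray(macro.exponents, dtype=float)
    out = np.zeros_like(t)
    active = t >= 0
    ta = t[active]
    if dose.duration == 0:
        out[active] = np.exp(-np.outer(ta, lam)) @ A
    else:
        tau = dose.duration
        rise = 1.0 - np.exp(-np.outer(np.minimum(ta, tau), lam))
        decay = np.exp(-np.outer(np.maximum(ta - tau, 0.0), lam))
        out[active] = (rise * decay) @ (A / (lam * tau))
    return out


def derived_params(fit: PKFitResult, T: float) -> DerivedParams:
    """Half-lives, clearance and AUC(0..T)/AUC(inf) from a 2-compartment fit."""
    if fit.micro.n_compartments != 2:
        raise ValueError("derived parameters require a two-compartment fit")
    return _derived(fit.micro, fit.macro, T)


def _derived(micro: MicroParams, macro: MacroParams, T: float) -> DerivedParams:
    alpha, beta = macro.exponents
    A = np.asarray(macro.coefficients)
    lam = np.asarray(macro.exponents)
    return DerivedParams(
        t_half_alpha=math.log(2) / alpha,
        t_half_beta=math.log(2) / beta,
        cl=micro.K10 * micro.V1,
        auc_0_T=float(np.sum(A / lam * (1.0 - np.exp(-lam * T)))),
        auc_inf=float(np.sum(A / lam)),
    )


def observed_metrics(series: ConcentrationSeries) -> ObservedMetrics:
    """Cmax and its sampling time (earliest on ties) over uncensored points."""
    mask = series.observed_mask()
    if not np.any(mask):
        raise MetricsUnavailableError(
            f"no uncensored post-dose points for {series.subject_id}/{series.matrix}"
        )
    t, v = series.times[mask], series.values[mask]
    i = int(np.argmax(v))  # first occurrence = earliest time (times sorted)
    return ObservedMetrics(c_max=float(v[i]), t_max=float(t[i]))


# ---------------------------------------------------------------------------
# least-squares fitting
# ---------------------------------------------------------------------------

_PARAM_NAMES = {
    1: ("V1", "K10"),
    2: ("V1", "K10", "K12", "K21"),
    3: ("V1", "K10", "K12", "K21", "K13", "K31"),
}


def _strip_exponentials(t: np.ndarray, y: np.ndarray, n_exp: int):
    """Curve stripping (residual peeling) for deterministic start values.

    Fits the terminal phase log-linearly, peels it off, and repeats on the
    residuals.  Returns (coefficients, exponents) sorted fastest-first.
    """
    pos = y > 0
    t, y = t[pos], y[pos]
    if t.size < 2:
        raise DataError("not enough positive points for curve stripping")
    terms = []
    resid = y.astype(float).copy()
    for k in range(n_exp):
        pos = resid > 0
        tt, rr = t[pos], resid[pos]
        if tt.size < 2:
            break
        if k < n_exp - 1:
            n_tail = max(2, tt.size // 3)
            tt_fit, rr_fit = tt[-n_tail:], rr[-n_tail:]
        else:
            tt_fit, rr_fit = tt, rr
        slope, icpt = np.polyfit(tt_fit, np.log(rr_fit), 1)
        lam = max(-slope, 1e-4)
        amp = max(math.exp(icpt), 1e-12)
        terms.append((amp, lam))
        resid = resid - amp * np.exp(-lam * t)
    while len(terms) < n_exp:  # degenerate stripping: split the fastest term
        amp, lam = terms[-1]
        terms[-1] = (amp / 2, lam)
        terms.append((amp / 2, lam * 5.0))
    terms.sort(key=lambda p: -p[1])
    amps, lams = zip(*terms)
    return np.array(amps), np.array(lams)


def _initial_micro(t, y, dose: DoseEvent, n: int) -> MicroParams:
    lo_r, hi_r = RATE_BOUNDS
    lo_v, hi_v = V1_BOUNDS

    def clip_r(x):
        return float(np.clip(x, lo_r * 1.01, hi_r * 0.99))

    if n == 1:
        amps, lams = _strip_exponentials(t, y, 1)
        v1 = np.clip(dose.amount / amps.sum(), lo_v * 1.01, hi_v * 0.99)
        return MicroParams(1, V1=float(v1), K10=clip_r(lams[0]))
    amps, lams = _strip_exponentials(t, y, 2)
    A, B = amps
    alpha, beta = lams
    if alpha <= beta * (1 + 1e-6):
        alpha = beta * 5.0
    try:
        micro2 = macro_to_micro(MacroParams((A, B), (alpha, beta)), dose)
        v1, k10, k12, k21 = micro2.V1, micro2.K10, micro2.K12, micro2.K21
    except (InconsistentMacroError, ValueError):
        v1, k10, k12, k21 = dose.amount / (A + B), beta * 2, alpha / 4, alpha / 8
    v1 = float(np.clip(v1, lo_v * 1.01, hi_v * 0.99))
    if n == 2:
        return MicroParams(2, V1=v1, K10=clip_r(k10), K12=clip_r(k12), K21=clip_r(k21))
    return MicroParams(
        3,
        V1=v1,
        K10=clip_r(k10),
        K12=clip_r(k12 * 0.7),
        K21=clip_r(k21),
        K13=clip_r(k12 * 0.3),
        K31=clip_r(k21 * 0.3),
    )


def _unpack(x: np.ndarray, n: int) -> MicroParams:
    names = _PARAM_NAMES[n]
    return MicroParams(n, **dict(zip(names, x)))


def fit_compartment_model(
    series: ConcentrationSeries,
    dose: DoseEvent,
    n_compartments: int,
    weighting: str = "none",
    auc_horizon: float = 120.0,
) -> PKFitResult:
    """Fit a compartment model to one subject's series by least squares.

    Minimizes the unweighted SSR by default (``weighting="inverse_y2"`` scales
    residuals by 1/prediction).  Start values come from curve stripping, so
    the fit is deterministic.  AIC = n ln(SSR/n) + 2p.
    """
    if n_compartments not in (1, 2, 3):
        raise ValueError("n_compartments must be 1, 2 or 3")
    if weighting not in ("none", "inverse_y2"):
        raise ValueError("weighting must be 'none' or 'inverse_y2'")
    t, y = series.fit_points()
    n_params = 2 * n_compartments
    if t.size < n_params + 1:
        raise DataError(
            f"need at least {n_params + 1} usable points for a "
            f"{n_compartments}-compartment fit, got {t.size}"
        )
    start = _initial_micro(t, y, dose, n_compartments)
    names = _PARAM_NAMES[n_compartments]
    x0 = np.log([getattr(start, nm) for nm in names])
    lo = np.log([V1_BOUNDS[0]] + [RATE_BOUNDS[0]] * (n_params - 1))
    hi = np.log([V1_BOUNDS[1]] + [RATE_BOUNDS[1]] * (n_params - 1))

    big = max(1.0, float(np.abs(y).max())) * 1e3
    bolus = DoseEvent(dose.amount, dose.start_time, 0.0)  # macro conversion is bolus-form

    def residuals(logx):
        try:
            micro = _unpack(np.exp(logx), n_compartments)
            macro = micro_to_macro(micro, bolus)
        except (DegenerateModelError, ValueError):
            return np.full_like(y, big)
        pred = predict_concentration(macro, dose, t)
        r = pred - y
        if weighting == "inverse_y2":
            r = r / np.clip(pred, 1e-12, None)
        return r

    res = least_squares(
        residuals, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=2000,
    )
    micro = _unpack(np.exp(res.x), n_compartments)
    macro = micro_to_macro(micro, bolus)
    pred = predict_concentration(macro, dose, t)
    ssr = float(np.sum((pred - y) ** 2))
    aic = _aic(ssr, t.size, n_params)
    derived = _derived(micro, macro, auc_horizon) if n_compartments == 2 else None
    result = PKFitResult(
        micro=micro, macro=macro, ssr=ssr, n_points=int(t.size), aic=aic, derived=derived
    )
    if not res.success:
        raise FitFailureError(f"fit did not converge: {res.message}", best=result)
    return result


def _aic(ssr: float, n: int, p: int) -> float:
    return n * math.log(max(ssr, 1e-300) / n) + 2 * p


def select_model(
    series: ConcentrationSeries,
    dose: DoseEvent,
    weighting: str = "none",
    auc_horizon: float = 120.0,
) -> PKFitResult:
    """Fit 1/2/3-compartment structures and return the lowest-AIC result.

    SSRs are floored at numerical-noise level relative to the data scale when
    comparing, so that exactly-interpolating nested models do not win on
    log-of-roundoff differences.
    """
    t, y = series.fit_points()
    floor = t.size * (1e-8 * max(1.0, float(np.abs(y).max()))) ** 2
    fits: Dict[int, PKFitResult] = {}
    errors: Dict[int, Exception] = {}
    aics: Dict[int, float] = {}
    for n in (1, 2, 3):
        try:
            fit = fit_compartment_model(series, dose, n, weighting=weighting, auc_horizon=auc_horizon)
        except FitFailureError as exc:
            fit = exc.best
        except Exception as exc:  # insufficient points, degenerate model, ...
            errors[n] = exc
            continue
        fits[n] = fit
        aics[n] = _aic(max(fit.ssr, floor), fit.n_points, 2 * n)
    if not fits:
        raise FitFailureError(f"all compartment fits failed: {errors}")
    logger.info("model selection AICs (ssr-floored): %s", aics)
    best_n = min(aics, key=aics.get)
    best = fits[best_n]
    best.aic_by_model = aics
    return best
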