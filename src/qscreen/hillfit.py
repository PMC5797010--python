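"""Four-parameter Hill fitting, qHTS curve classification, and curve AUC.

The response model is the four-parameter logistic in log-concentration,

    r(c) = s0 + (s_inf - s0) / (1 + (10^L / c)^h),     L = log10 IC50,

with r in percent activity (0 = neutral control, -100 = positive control).
The reported IC50 is the relative IC50: the concentration at the half-way
point between the fitted asymptotes.

Curve classes follow the qHTS convention: class 1 (both plateaus observed
within the tested range), class 2 (upper plateau outside range), class 3
(response at the single highest concentration only), class 4 (inactive);
subclasses .1 / .2 split high-efficacy, well-determined fits (> 80% efficacy,
r^2 >= 0.9) from partial or noisier ones.  Cytotoxic (signal-decreasing)
curves carry a negative sign, e.g. -1.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InvalidParameterError
from .qc import NormalizedSeries

__all__ = [
    "HillFit",
    "CurveClass",
    "ClassThresholds",
    "hill_response",
    "fit_hill",
    "classify_curve",
    "compute_auc",
]


def hill_response(c, log10_ic50: float, hill_slope: float, s0: float, s_inf: float):
    """Four-parameter logistic response at concentration(s) ``c`` (molar)."""
    c = np.asarray(c, dtype=float)
    return s0 + (s_inf - s0) / (1.0 + (10.0 ** log10_ic50 / c) ** hill_slope)


@dataclass(frozen=True)
class HillFit:
    """A fitted four-parameter Hill model for one response series.

    ``max_response`` is the fitted response at the tested concentration where
    its magnitude is largest (signed percent activity); ``efficacy`` is
    |s_inf - s0|.  A fit with ``converged=False`` carries NaN parameters and
    no IC50.
    """

    log10_ic50: float
    hill_slope: float
    s0: float
    s_inf: float
    r2: float
    converged: bool
    max_response: float

    @property
    def ic50(self) -> float | None:
        """IC50 in molar, or None for unconverged fits."""
        return 10.0 ** self.log10_ic50 if self.converged else None

    @property
    def efficacy(self) -> float:
        return abs(self.s_inf - self.s0) if self.converged else 0.0

    def predict(self, c):
        return hill_response(c, self.log10_ic50, self.hill_slope, self.s0, self.s_inf)


_UNCONVERGED = dict(
    log10_ic50=float("nan"), hill_slope=float("nan"),
    s0=float("nan"), s_inf=float("nan"), converged=False,
)


def fit_hill(
    series: NormalizedSeries,
    *,
    response_floor: float = 30.0,
    clip_low: float = -150.0,
) -> HillFit:
    """Bounded multi-start least-squares fit of the Hill model to one series.

    Bounds: log10 IC50 within [min tested - 2, max tested + 2] decades, Hill
    slope in [0.3, 10], s0 in [-30, 30], s_inf in [-150, 30].  Three
    deterministic starts place the IC50 at the tested-range midpoint and one
    decade either side; the lowest-cost solution wins.  Responses below
    ``clip_low`` are clipped before fitting (guards against control
    misestimation).  ``converged`` is False when the optimizer fails, when the
    series shows no response beyond ``response_floor`` and the fit explains
    nothing (r^2 < 0), or when the series is flat.

    Raises
    ------
    FitError
        Fewer than 5 concentration points.
    InvalidParameterError
        Non-finite responses or non-positive concentrations.
    """
    if series.n_points < 5:
        raise FitError(
            f"{series.compound_id}/{series.cell_line}: need >= 5 points, "
            f"got {series.n_points}"
        )
    c = series.concentrations
    r = series.responses
    if not np.all(np.isfinite(r)):
        raise InvalidParameterError(
            f"{series.compound_id}/{series.cell_line}: non-finite responses"
        )
    if not np.all(c > 0):
        raise InvalidParameterError("concentrations must be positive")
    r = np.clip(r, clip_low, None)

    max_abs = float(np.max(np.abs(r)))
    if max_abs < 1e-9:
        return HillFit(**_UNCONVERGED, r2=0.0, max_response=0.0)

    lo_c, hi_c = math.log10(c.min()), math.log10(c.max())
    lower = np.array([lo_c - 2.0, 0.3, -30.0, -150.0])
    upper = np.array([hi_c + 2.0, 10.0, 30.0, 30.0])

    extreme = float(r[np.argmax(np.abs(r))])
    s_inf0 = float(np.clip(extreme, -150.0, 30.0))
    mid = 0.5 * (lo_c + hi_c)

    def residuals(p):
        return hill_response(c, *p) - r

    best = None
    for l0 in (mid, mid - 1.0, mid + 1.0):
        x0 = np.clip(np.array([l0, 1.0, 0.0, s_inf0]), lower, upper)
        try:
            res = least_squares(
                residuals, x0, bounds=(lower, upper), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return HillFit(**_UNCONVERGED, r2=-np.inf, max_response=extreme)

    log_ic50, slope, s0, s_inf = (float(v) for v in best.x)
    ss_res = float(np.sum((hill_response(c, *best.x) - r) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    converged = not (r2 < 0 and max_abs < response_floor)
    fitted = hill_response(c, *best.x)
    max_response = float(fitted[np.argmax(np.abs(fitted))])
    if not converged:
        return HillFit(**_UNCONVERGED, r2=r2, max_response=max_response)
    return HillFit(log_ic50, slope, s0, s_inf, r2, True, max_response)


@dataclass(frozen=True)
class CurveClass:
    """qHTS curve class: value in {1.1, 1.2, 2.1, 2.2, 3, 4} plus direction.

    ``direction`` is -1 for signal-decreasing (cytotoxic) curves, +1 for
    signal-increasing ones, 0 for class 4 (no response).  ``signed`` is the
    conventional signed label (class 4 is unsigned).
    """

    value: float
    direction: int

    @property
    def signed(self) -> float:
        return self.value if self.value == 4 else self.direction * self.value

    @property
    def is_high_quality(self) -> bool:
        """Complete or incomplete curve (|class| 1.x or 2.x)."""
        return self.value in (1.1, 1.2, 2.1, 2.2)


@dataclass(frozen=True)
class ClassThresholds:
    """Configurable curve-class heuristics (qHTS conventions as defaults).

    ``floor`` is the minimum percent response treated as real (the larger of
    this and a 6-SD noise equivalent, when one is supplied); ``efficacy_high``
    and ``r2_high`` gate subclass .1; ``efficacy_min`` demotes shallow
    incomplete curves to class 3; ``s0_tol`` and ``plateau_frac`` define when
    the lower/upper plateaus count as observed within the tested range.
    """

    floor: float = 30.0
    efficacy_high: float = 80.0
    efficacy_min: float = 30.0
    r2_high: float = 0.9
    s0_tol: float = 10.0
    plateau_frac: float = 0.1
    noise_sd_equiv: float = 0.0  # percent-activity equivalent of 6 control SDs


def classify_curve(
    fit: HillFit,
    series: NormalizedSeries,
    thresholds: ClassThresholds | None = None,
) -> CurveClass:
    """Assign a qHTS curve class to a fitted series.

    Decision cascade: (a) no observed point beyond the response floor ->
    class 4; (b) only the single highest tested concentration beyond the
    floor -> class 3; (c) both plateaus observed within the tested range ->
    class 1, else class 2; (d) subclass .1 for efficacy > 80% with r^2 >= 0.9,
    else .2, demoting class-2 curves with efficacy <= 30% to class 3.
    """
    t = thresholds or ClassThresholds()
    floor = max(t.floor, t.noise_sd_equiv)
    r = series.responses
    beyond = np.abs(r) >= floor
    extreme = float(r[np.argmax(np.abs(r))]) if len(r) else 0.0
    direction = -1 if extreme < 0 else 1

    if not beyond.any():
        return CurveClass(4.0, 0)
    top_idx = int(np.argmax(series.concentrations))
    if beyond.sum() == 1 and beyond[top_idx]:
        return CurveClass(3.0, direction)
    if not fit.converged:
        return CurveClass(3.0, direction)

    direction = -1 if fit.s_inf < fit.s0 else 1
    c_min, c_max = series.concentrations.min(), series.concentrations.max()
    r_lo = float(fit.predict(c_min))
    r_hi = float(fit.predict(c_max))
    eff = fit.efficacy
    low_plateau = abs(r_lo - fit.s0) <= t.s0_tol
    high_plateau = abs(r_hi - fit.s_inf) <= t.plateau_frac * eff
    base = 1.0 if (low_plateau and high_plateau) else 2.0

    if eff > t.efficacy_high and fit.r2 >= t.r2_high:
        return CurveClass(base + 0.1, direction)
    if eff > t.efficacy_min:
        return CurveClass(base + 0.2, direction)
    # shallow curve: a "complete" shape below the efficacy floor is not a
    # meaningful class-1; both fall through to single-point quality
    return CurveClass(3.0, direction)


def compute_auc(
    fit: HillFit,
    series_range: tuple[float, float],
    curve_class: CurveClass | None = None,
    n_grid: int = 1000,
) -> float:
    """Normalized area under the fitted |response| over the tested log range.

    ``auc = (1/span) * integral |r(c)| dlog10 c`` on a 1000-point trapezoid
    grid, so a constant -100% response scores 100.  Class-4 (or unconverged)
    curves score 0.
    """
    if curve_class is not None and curve_class.value == 4.0:
        return 0.0
    if not fit.converged:
        return 0.0
    c_min, c_max = series_range
    if not (0 < c_min < c_max):
        raise InvalidParameterError("series_range must satisfy 0 < c_min < c_max")
    logs = np.linspace(math.log10(c_min), math.log10(c_max), n_grid)
    vals = np.abs(fit.predict(10.0 ** logs))
    span = logs[-1] - logs[0]
    return float(np.trapezoid(vals, logs) / span)
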