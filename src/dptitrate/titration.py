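"""Elastic-limit detection on P–V maneuvers and ventilation recommendations.

The individualized driving pressure is read off the quasi-static inflation
curve at the point where the lung leaves its elastic regime: below the
elastic limit extra volume costs pressure at the (low) elastic elastance,
above it the curve steepens as recoverable distension gives way to
structural strain.  The detector fits a continuous two-segment ("hinge")
piecewise-linear model with the knot restricted to the measured volume grid
and picks the knot minimizing the residual sum of squares; the driving
pressure is the fitted hinge pressure minus the fitted zero-volume pressure,
which denoises the baseline reading.  A curvature-based alternative (the
grid point with the greatest slope increase) is kept for comparison.

The same hinge fit applied to the deflation limb yields the pressure below
which expiratory compliance falls — the derecruitment onset — used as the
recommended PEEP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mechanics import PVManeuver

__all__ = [
    "ElasticPoint",
    "VentSettings",
    "DPRecommendation",
    "PeepRecommendation",
    "NoPlasticTransition",
    "local_slopes",
    "fit_two_segment",
    "detect_elastic_point",
    "recommend_dp",
    "recommend_peep",
    "elastic_modulus_summary",
    "round_to_half",
]

FLAG_NO_TRANSITION = "no_plastic_transition"
DEFAULT_PEEP_CMH2O = 5.0  # baseline ventilator setting before titration
HIGH_DP_CMH2O = 15.0  # conventional protective upper bound
TV_LIMIT_ML_PER_KG = 6.0

_MIN_POINTS = 6
_MIN_SEGMENT = 3


class NoPlasticTransition(RuntimeError):
    """Raised when a recommendation is requested from a flagged fit."""


@dataclass(frozen=True)
class ElasticPoint:
    """Detected elastic limit of one maneuver.

    ``dp_individual`` is the fitted pressure rise from zero volume to the
    elastic limit — the individualized driving pressure over PEEP.  ``flag``
    is ``None`` for a valid plastic transition, else a reason string (a fit
    whose upper-segment elastance does not exceed the lower one carries
    ``no_plastic_transition``).
    """

    index: int
    v_el_hat: float  # mL
    p_el_hat: float  # cmH2O
    dp_individual: float  # cmH2O
    e1_hat: float  # cmH2O/mL
    e2_hat: float  # cmH2O/mL
    p0_hat: float  # fitted pressure at v = 0, cmH2O
    sse: float  # cmH2O^2
    method: str  # "piecewise" | "max_acceleration"
    flag: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.flag is None


@dataclass(frozen=True)
class VentSettings:
    """Ventilator settings and subject size used for safety checks."""

    peep: float  # cmH2O
    dp: float = 14.0  # cmH2O
    fio2: float = 0.8
    rr: float = 55.0  # breaths/min
    weight_g: float = 357.0
    predicted_tv_ml: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 <= self.fio2 <= 1:
            raise ValueError("fio2 must be in [0, 1]")
        if self.peep <= 0 or self.dp <= 0 or self.rr <= 0:
            raise ValueError("peep, dp and rr must be > 0")
        if self.weight_g <= 0:
            raise ValueError("weight_g must be > 0")


@dataclass(frozen=True)
class DPRecommendation:
    dp: float  # cmH2O, rounded to 0.5
    warnings: tuple[str, ...]


@dataclass(frozen=True)
class PeepRecommendation:
    peep: float  # cmH2O, rounded to 0.5
    warnings: tuple[str, ...]
    fit: Optional[ElasticPoint]


def round_to_half(x: float) -> float:
    """Round to the nearest 0.5 cmH2O, halves away from zero-free (half-up)."""
    return math.floor(x * 2.0 + 0.5) / 2.0


def local_slopes(m: PVManeuver) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference elastances between consecutive samples.

    Returns (segment midpoint volumes, slopes (p[i+1]-p[i])/(v[i+1]-v[i])),
    each of length n-1.  Duplicate volumes are rejected by the maneuver
    container itself.
    """
    dv = np.diff(m.v)
    if np.any(dv == 0):
        raise ValueError("duplicate volumes in maneuver")
    return (m.v[:-1] + m.v[1:]) / 2.0, np.diff(m.p) / dv


def _hinge_fit(v: np.ndarray, p: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Least-squares continuous two-segment fit with the knot at v[k].

    Basis: [1, v, max(0, v - v[k])]; returns (coefficients, SSE).
    """
    X = np.column_stack([np.ones_like(v), v, np.maximum(v - v[k], 0.0)])
    beta, _, _, _ = np.linalg.lstsq(X, p, rcond=None)
    resid = p - X @ beta
    return beta, float(resid @ resid)


def fit_two_segment(m: PVManeuver) -> ElasticPoint:
    """Exhaustive-knot continuous piecewise-linear fit of a maneuver.

    Every interior grid volume leaving at least three points on each side is
    tried as the knot; the knot with the smallest SSE wins, ties going to
    the lower volume (the conservative, smaller-DP choice).  If the selected
    fit's upper slope does not exceed its lower slope the maneuver shows no
    plastic transition and the result is flagged rather than raised — the
    caller decides the fallback.
    """
    if m.n < _MIN_POINTS:
        raise ValueError(f"need at least {_MIN_POINTS} points, got {m.n}")
    v, p = m.v, m.p

    best_k = -1
    best_sse = math.inf
    best_beta: np.ndarray | None = None
    for k in range(_MIN_SEGMENT - 1, m.n - _MIN_SEGMENT + 1):
        beta, sse = _hinge_fit(v, p, k)
        # ties (within numerical noise) keep the earlier, lower-volume knot
        if best_beta is None or sse < best_sse - 1e-12 * max(1.0, best_sse):
            best_k, best_sse, best_beta = k, sse, beta

    assert best_beta is not None
    b0, b1, b2 = best_beta
    e1_hat = float(b1)
    e2_hat = float(b1 + b2)
    p_el_hat = float(b0 + b1 * v[best_k])
    tol = 1e-9 * max(1.0, abs(e1_hat))
    flag = FLAG_NO_TRANSITION if e2_hat <= e1_hat + tol else None
    return ElasticPoint(
        index=best_k,
        v_el_hat=float(v[best_k]),
        p_el_hat=p_el_hat,
        dp_individual=p_el_hat - float(b0),
        e1_hat=e1_hat,
        e2_hat=e2_hat,
        p0_hat=float(b0),
        sse=max(best_sse, 0.0),
        method="piecewise",
        flag=flag,
    )


def _max_acceleration(m: PVManeuver) -> ElasticPoint:
    """Grid point with the greatest increase in local slope.

    The second finite difference of pressure over volume is evaluated at
    every interior point; the maximum wins, ties broken toward the lower
    volume.  No smoothing is applied, so this estimator is noise-sensitive
    and kept mainly as a cross-check of the hinge fit.
    """
    _, slopes = local_slopes(m)
    accel = np.diff(slopes)  # accel[i-1] = slope change at interior point i
    # ties within numerical noise break toward the lower volume
    tol = 1e-9 * max(1.0, float(np.max(np.abs(accel))))
    j = int(np.flatnonzero(accel >= np.max(accel) - tol)[0])
    i = j + 1
    e1_hat = float(slopes[j])
    e2_hat = float(slopes[j + 1])
    flag = FLAG_NO_TRANSITION if e2_hat <= e1_hat + 1e-9 * max(1.0, abs(e1_hat)) else None
    return ElasticPoint(
        index=i,
        v_el_hat=float(m.v[i]),
        p_el_hat=float(m.p[i]),
        dp_individual=float(m.p[i] - m.p[0]),
        e1_hat=e1_hat,
        e2_hat=e2_hat,
        p0_hat=float(m.p[0]),
        sse=float("nan"),
        method="max_acceleration",
        flag=flag,
    )


def detect_elastic_point(m: PVManeuver, method: str = "piecewise") -> ElasticPoint:
    """Detect the elastic limit by the chosen method.

    ``piecewise`` (default) is the SSE-optimal hinge fit; ``max_acceleration``
    the raw curvature maximum.  Both report the individualized driving
    pressure as elastic-point pressure minus zero-volume pressure.
    """
    if method == "piecewise":
        return fit_two_segment(m)
    if method == "max_acceleration":
        return _max_acceleration(m)
    raise ValueError(f"unknown method {method!r}; use 'piecewise' or 'max_acceleration'")


def recommend_dp(ep: ElasticPoint, settings: VentSettings) -> DPRecommendation:
    """Turn an elastic point into a settable driving-pressure recommendation.

    The DP is rounded to the ventilator's 0.5 cmH2O granularity.  Warnings
    flag a recommendation at or above the conventional 15 cmH2O protective
    bound, an elastic-limit volume implying a tidal volume above 6 mL/kg,
    and a degenerate (non-positive) DP.
    """
    if not ep.ok:
        raise NoPlasticTransition(
            "elastic point flagged "
            f"{ep.flag!r}: fall back to standard ventilation settings"
        )
    dp = round_to_half(ep.dp_individual)
    warnings: list[str] = []
    if dp >= HIGH_DP_CMH2O:
        warnings.append("high_dp")
    if ep.v_el_hat / (settings.weight_g / 1000.0) > TV_LIMIT_ML_PER_KG:
        warnings.append("tidal_volume_above_6_ml_per_kg")
    if ep.dp_individual <= 0:
        warnings.append("degenerate_curve")
    return DPRecommendation(dp=dp, warnings=tuple(warnings))


def recommend_peep(m_deflation: PVManeuver) -> PeepRecommendation:
    """Expiratory-limb PEEP: the deflation curve's compliance breakpoint.

    The hinge pressure of the two-segment fit marks the pressure below which
    compliance falls (derecruitment onset) and is returned, rounded to
    0.5 cmH2O.  A deflation limb with no detectable transition yields the
    pre-titration default of 5 cmH2O with a warning.
    """
    if m_deflation.limb != "deflation":
        raise ValueError("recommend_peep expects a deflation-limb maneuver")
    ep = fit_two_segment(m_deflation)
    if not ep.ok:
        return PeepRecommendation(
            peep=DEFAULT_PEEP_CMH2O, warnings=("no_transition_default_peep",), fit=ep
        )
    return PeepRecommendation(peep=round_to_half(ep.p_el_hat), warnings=(), fit=ep)


def elastic_modulus_summary(ep: ElasticPoint) -> tuple[float, float, float]:
    """Segment elastances and their ratio (e1, e2, e2/e1).

    A ratio above 1 indicates a plastic transition; a flagged (linear) fit
    reports its ratio <= 1 unchanged so the caller sees the degeneracy.
    """
    return ep.e1_hat, ep.e2_hat, ep.e2_hat / ep.e1_hat
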