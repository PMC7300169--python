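"""TIAC estimators: mono-exponential planar fit, hybrid rescaling, single TP.

Three estimators of the time-integrated activity coefficient (TIAC) of a
region, given simulated activity values:

* planar-only: the planar series A(t_i) is fitted with
  f(t) = A1 * exp(-(lambda1 + lambda_phys) t) and integrated analytically,
  TIAC_planar = A1 / (A0 (lambda1 + lambda_phys));
* hybrid planar/SPECT: the planar fit defines the curve shape and one
  quantitative SPECT/CT value rescales it,
  TIAC_hybrid = A_SPECT(t_SPECT) / f(t_SPECT) * TIAC_planar — any
  multiplicative bias shared by all planar values cancels exactly;
* single time point: TIAC_1TP = (2/ln 2) * A_SPECT(t_ref) * t_ref / A0,
  which is exact for mono-exponential kinetics when t_ref equals the
  effective half-life.

Fitting is ordinary least squares on log-activity by default (the maximum-
likelihood fit under multiplicative log-normal noise); nonlinear least squares
in linear space is available for sensitivity checks.  A fitted biological
clearance rate below zero would make the integral grow without physical
meaning, so lambda1 is clamped at 0 (pure physical decay) and the fit flagged;
clamped replicates are retained so that pooled moments stay unbiased by
selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .cohort import LAMBDA_PHYS

__all__ = [
    "MonoExpFit",
    "TIACEstimate",
    "fit_monoexp",
    "fit_monoexp_batch",
    "tiac_planar",
    "tiac_hybrid",
    "tiac_single_tp",
]


@dataclass(frozen=True)
class MonoExpFit:
    """Mono-exponential fit A1 * exp(-(lambda1 + lambda_phys) t)."""

    a1: float  # prefactor, MBq
    lambda1: float  # biological clearance rate, 1/h (>= 0 after clamping)
    n_points: int
    clamped: bool = False
    lambda_phys: float = LAMBDA_PHYS

    def __post_init__(self) -> None:
        if self.a1 <= 0:
            raise ValueError("fitted prefactor must be positive")
        if self.lambda1 + self.lambda_phys <= 0:
            raise ValueError("effective decay rate must be positive")

    def predict(self, t):
        """Fitted activity at time(s) ``t`` hours."""
        return self.a1 * np.exp(-(self.lambda1 + self.lambda_phys) * np.asarray(t, float))


@dataclass(frozen=True)
class TIACEstimate:
    """A TIAC value (hours) with provenance."""

    value: float
    method: str  # planar | hybrid | single_tp
    schedule: object = None
    replicate_id: Optional[int] = None
    region_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.value > 0 and math.isfinite(self.value)):
            raise ValueError("TIAC must be positive and finite")


def _validate_samples(samples: Sequence[tuple[float, float]]):
    times = np.asarray([s[0] for s in samples], dtype=float)
    acts = np.asarray([s[1] for s in samples], dtype=float)
    if len(times) < 2:
        raise ValueError("at least two samples are required")
    if len(np.unique(times)) != len(times):
        raise ValueError("sample times must be distinct")
    if np.any(acts <= 0):
        raise ValueError("activities must be positive")
    return times, acts


def fit_monoexp(samples: Sequence[tuple[float, float]], *,
                space: str = "log") -> MonoExpFit:
    """Fit a mono-exponential to (time, activity) samples.

    With two samples the fit is the exact interpolant.  With three or more,
    ``space="log"`` (default) does ordinary least squares on ln(activity)
    versus time; ``space="linear"`` does nonlinear least squares on the
    activities themselves.  If the unconstrained slope implies a negative
    biological clearance rate, ``lambda1`` is clamped to 0 and the prefactor
    refitted with the decay fixed at the physical rate.
    """
    times, acts = _validate_samples(samples)
    if space not in ("log", "linear"):
        raise ValueError("space must be 'log' or 'linear'")

    if space == "linear" and len(times) > 2:
        def model(t, a1, lam_tot):
            return a1 * np.exp(-lam_tot * t)
        slope0, inter0 = np.polyfit(times, np.log(acts), 1)
        p0 = (math.exp(inter0), max(-slope0, LAMBDA_PHYS))
        (a1, lam_tot), _ = curve_fit(model, times, acts, p0=p0, maxfev=10_000)
        lam1 = lam_tot - LAMBDA_PHYS
        if lam1 < 0:
            (a1,), _ = curve_fit(lambda t, a: model(t, a, LAMBDA_PHYS),
                                 times, acts, p0=(p0[0],), maxfev=10_000)
            return MonoExpFit(a1=float(a1), lambda1=0.0, n_points=len(times),
                              clamped=True)
        return MonoExpFit(a1=float(a1), lambda1=float(lam1), n_points=len(times))

    y = np.log(acts)
    tc = times - times.mean()
    slope = float(tc @ (y - y.mean()) / (tc @ tc))
    lam1 = -slope - LAMBDA_PHYS
    if lam1 < 0:
        # slope fixed at pure physical decay; ML intercept in log space
        a1 = math.exp(float(np.mean(y + LAMBDA_PHYS * times)))
        return MonoExpFit(a1=a1, lambda1=0.0, n_points=len(times), clamped=True)
    a1 = math.exp(float(y.mean() - slope * times.mean()))
    return MonoExpFit(a1=a1, lambda1=lam1, n_points=len(times))


def fit_monoexp_batch(times: np.ndarray, log_acts: np.ndarray):
    """Vectorised log-space fit over replicates.

    ``times`` has shape (k,), ``log_acts`` shape (n_reps, k).  Returns
    ``(a1, lambda1, clamped)`` arrays of shape (n_reps,), with the same
    clamping rule as :func:`fit_monoexp`.
    """
    tc = times - times.mean()
    denom = float(tc @ tc)
    ybar = log_acts.mean(axis=1)
    slope = (log_acts @ tc) / denom
    lam1 = -slope - LAMBDA_PHYS
    clamped = lam1 < 0
    log_a1 = ybar - slope * times.mean()
    if np.any(clamped):
        log_a1 = np.where(
            clamped,
            (log_acts + LAMBDA_PHYS * times[None, :]).mean(axis=1),
            log_a1,
        )
        lam1 = np.where(clamped, 0.0, lam1)
    return np.exp(log_a1), lam1, clamped


def tiac_planar(fit: MonoExpFit, a0: float, **provenance) -> TIACEstimate:
    """TIAC from the planar fit alone: A1 / (A0 (lambda1 + lambda_phys))."""
    if a0 <= 0:
        raise ValueError("injected activity must be positive")
    value = fit.a1 / (a0 * (fit.lambda1 + fit.lambda_phys))
    return TIACEstimate(value=value, method="planar", **provenance)


def tiac_hybrid(fit: MonoExpFit, spect: tuple[float, float], a0: float,
                **provenance) -> TIACEstimate:
    """Hybrid TIAC: planar-fit TIAC rescaled by A_SPECT / f_planar(t_SPECT)."""
    t_spect, a_spect = spect
    if a_spect <= 0:
        raise ValueError("SPECT activity must be positive")
    f_at_spect = float(fit.predict(t_spect))
    if f_at_spect <= 0:
        raise ValueError("fitted curve vanishes at the SPECT time")
    base = tiac_planar(fit, a0)
    return TIACEstimate(value=(a_spect / f_at_spect) * base.value,
                        method="hybrid", **provenance)


def tiac_single_tp(spect: tuple[float, float], a0: float,
                   **provenance) -> TIACEstimate:
    """Single-time-point TIAC: (2/ln 2) * A_SPECT(t_ref) * t_ref / A0."""
    t_ref, a_spect = spect
    if t_ref <= 0 or a_spect <= 0 or a0 <= 0:
        raise ValueError("t_ref, activity and A0 must be positive")
    value = (2.0 / math.log(2.0)) * a_spect * t_ref / a0
    return TIACEstimate(value=value, method="single_tp", **provenance)
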